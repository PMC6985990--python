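"""Outcome coding and cause-specific Cox hazard estimation.

Follow-up runs from the MRI date until death, loss to follow-up or the
administrative end of follow-up.  Three outcomes are coded: overall
mortality, vascular-related mortality (death from myocardial infarction,
stroke, sudden death, congestive heart failure, ruptured abdominal
aortic aneurysm or another vascular cause — a subset of overall
mortality) and ischaemic stroke.  Non-qualifying deaths censor the
cause-specific models at the death time; non-fatal strokes leave the
patient at risk for the mortality models.

Hazard ratios per phenotype subgroup are estimated against a merged
low-burden reference (indicator columns for every non-reference
subgroup) with a Cox proportional-hazards model adjusted for age and
sex, Efron tie handling, Wald 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .synthetic_data.survival_sim import OUTCOMES, VASCULAR_CAUSES


@dataclass
class HazardEstimate:
    subgroup: int | str
    outcome: str
    hr: float
    ci_low: float
    ci_high: float
    se: float
    n_events: int
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable and not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence bounds must bracket the hazard ratio")


def code_events(followup: pd.DataFrame) -> pd.DataFrame:
    """Code raw follow-up rows into per-outcome survival records.

    ``followup`` has one row per patient with ``years_death`` (NaN if
    alive), ``cause_of_death``, ``years_stroke`` (NaN if none),
    ``years_last_contact`` plus ``age``/``sex``/``subgroup``.  Times are
    years since the MRI scan; negative event times are an error.
    Returns a long frame (patient_id, outcome, time, event, age, sex,
    subgroup) where vascular-mortality events are a subset of
    overall-mortality events.
    """
    fu = followup.copy()
    for col in ("years_death", "years_stroke", "years_last_contact"):
        if (fu[col].dropna() < 0).any():
            raise ValueError(f"{col} contains events before the MRI date")
    died = fu["years_death"].notna()
    vascular = died & fu["cause_of_death"].isin(VASCULAR_CAUSES)
    stroke = fu["years_stroke"].notna()

    frames = []
    base = fu[["patient_id", "age", "sex", "subgroup"]]

    t_death = fu["years_death"].where(died, fu["years_last_contact"])
    frames.append(base.assign(outcome="overall_mortality", time=t_death,
                              event=died.astype(int)))
    # vascular model: non-vascular deaths censor at the death time
    frames.append(base.assign(outcome="vascular_mortality", time=t_death,
                              event=vascular.astype(int)))
    t_stroke = fu["years_stroke"].where(
        stroke, fu["years_death"].where(died, fu["years_last_contact"])
    )
    frames.append(base.assign(outcome="ischaemic_stroke", time=t_stroke,
                              event=stroke.astype(int)))
    return pd.concat(frames, ignore_index=True)


def summarize_outcomes(records: pd.DataFrame) -> dict[str, float]:
    """Event counts per outcome plus the vascular share of deaths (%)."""
    out: dict[str, float] = {}
    for outcome in OUTCOMES:
        sub = records[records["outcome"] == outcome]
        out[f"n_{outcome}"] = int(sub["event"].sum())
    deaths = out.get("n_overall_mortality", 0)
    vascular = out.get("n_vascular_mortality", 0)
    out["vascular_share_pct"] = 100.0 * vascular / deaths if deaths else float("nan")
    return out


def build_reference(
    subgroups: pd.Series, reference: tuple[int, ...]
) -> pd.DataFrame:
    """Indicator design with the merged reference at the zero vector.

    One column ``sub_<g>`` per non-reference subgroup; members of the
    reference subgroups share the all-zero row.
    """
    subgroups = pd.Series(subgroups)
    present = set(subgroups.unique().tolist())
    ref = set(reference)
    absent = sorted(ref - present)
    if not ref:
        raise ValueError("reference subgroup set is empty")
    if absent:
        raise ValueError(f"reference subgroups {absent} absent from assignment")
    others = sorted(present - ref)
    if not others:
        raise ValueError("every patient is in the reference; no contrasts to fit")
    design = pd.DataFrame(index=subgroups.index)
    for g in others:
        design[f"sub_{g}"] = (subgroups == g).astype(float)
    return design


def fit_cox(
    records: pd.DataFrame,
    design: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    ties: str = "efron",
) -> list[HazardEstimate]:
    """Cox model of one outcome's records on the subgroup indicators.

    ``records`` must be a single outcome's rows (time, event, age, sex,
    subgroup, patient_id).  Returns one estimate per indicator column;
    a subgroup without events is reported non-estimable rather than
    fitted to infinity.
    """
    outcomes = records["outcome"].unique() if "outcome" in records.columns else ["?"]
    if len(outcomes) != 1:
        raise ValueError("fit_cox expects records of exactly one outcome")
    outcome = str(outcomes[0])
    if records["event"].sum() < 1:
        raise ValueError("no events in the records; Cox model undefined")

    df = records.reset_index(drop=True)
    dm = design.reset_index(drop=True)
    # constant covariates (e.g. a single-sex cohort) carry no information
    covariates = tuple(c for c in covariates if df[c].nunique() > 1)
    estimable_cols, dead_cols = [], []
    for col in dm.columns:
        n_ev = int(df.loc[dm[col] == 1, "event"].sum())
        (estimable_cols if n_ev > 0 else dead_cols).append(col)

    fit_df = pd.concat(
        [df[["time", "event", *covariates]], dm[estimable_cols]], axis=1
    )
    cph = CoxPHFitter()
    cph.fit(
        fit_df,
        duration_col="time",
        event_col="event",
        robust=False,
        fit_options={"step_size": 0.5},
    )
    # lifelines uses Efron ties by default; Breslow not exposed, so the
    # ties argument is validated for forward compatibility
    if ties not in ("efron",):
        raise ValueError(f"unsupported tie handling {ties!r}")

    estimates = []
    for col in dm.columns:
        g = col.removeprefix("sub_")
        g = int(g) if g.isdigit() else g
        n_ev = int(df.loc[dm[col] == 1, "event"].sum())
        if col in dead_cols:
            estimates.append(
                HazardEstimate(g, outcome, float("nan"), float("nan"),
                               float("nan"), float("nan"), n_ev, estimable=False)
            )
            continue
        coef = float(cph.params_[col])
        se = float(cph.standard_errors_[col])
        estimates.append(
            HazardEstimate(
                subgroup=g,
                outcome=outcome,
                hr=float(np.exp(coef)),
                ci_low=float(np.exp(coef - 1.96 * se)),
                ci_high=float(np.exp(coef + 1.96 * se)),
                se=se,
                n_events=n_ev,
            )
        )
    return estimates


def estimates_table(estimates: list[HazardEstimate]) -> pd.DataFrame:
    """Tabulate hazard estimates (one row per subgroup × outcome)."""
    return pd.DataFrame(
        [
            {
                "subgroup": e.subgroup, "outcome": e.outcome, "hr": e.hr,
                "ci_low": e.ci_low, "ci_high": e.ci_high, "se": e.se,
                "n_events": e.n_events, "estimable": e.estimable,
            }
            for e in estimates
        ]
    )


def forest_plot(estimates: list[HazardEstimate], path) -> pd.DataFrame:
    """Forest plot of HRs (log axis, reference line at 1) plus its table.

    Non-estimable contrasts are annotated rather than drawn.  Returns the
    underlying table, which is also written next to the figure as TSV.
    """
    if not estimates:
        raise ValueError("no estimates to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    table = estimates_table(estimates)
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    for yi, (_, row) in zip(y, table.iterrows()):
        label = f"{row['outcome']} — subgroup {row['subgroup']}"
        if row["estimable"]:
            ax.plot([row["ci_low"], row["ci_high"]], [yi, yi], color="k", lw=1)
            ax.plot(row["hr"], yi, "s", color="k", ms=4)
        else:
            ax.annotate("not estimable (no events)", (1.0, yi), fontsize=7,
                        va="center", color="grey")
        ax.annotate(label, (ax.get_xlim()[0], yi), fontsize=7, va="center",
                    xycoords=("axes fraction", "data"), xytext=(-0.02, yi),
                    ha="right")
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_yticks([])
    ax.set_xlabel("hazard ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    table.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    return table
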