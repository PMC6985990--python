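"""Survival outcomes with planted subgroup hazards.

Generative mirror of the cause-specific proportional-hazards analysis:
each outcome has an exponential baseline hazard multiplied by
``exp(subgroup offset + age and sex effects)``; observation stops at the
earlier of an administrative horizon and an independent exponential
dropout time.  One latent time per outcome, outcomes independent
(cause-specific view).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OUTCOMES = ("overall_mortality", "vascular_mortality", "ischaemic_stroke")

#: Death causes that qualify as vascular-related mortality.
VASCULAR_CAUSES = (
    "myocardial_infarction",
    "stroke",
    "sudden_death",
    "congestive_heart_failure",
    "aaa_rupture",
    "other_vascular",
)


def subgroup_style_log_hr(n_subgroups: int = 11) -> dict[str, np.ndarray]:
    """Planted per-subgroup log-hazard offsets for an 11-subgroup cohort.

    The low-burden subgroups (1, 2, 3, 7) sit at the baseline; the
    cortical-infarct (5), lacunar (6), small-vessel (9), atrophy (11) and
    multi-burden (10) subgroups carry elevated hazards, strongest for the
    multi-burden group and strongest of all for its stroke hazard.
    """
    if n_subgroups != 11:
        return {o: np.zeros(n_subgroups) for o in OUTCOMES}
    ln = np.log
    return {
        # offsets indexed by subgroup-1
        "overall_mortality": np.array(
            [0, 0, 0, 0.1, ln(1.85), ln(2.58), 0, 0.1, ln(1.72), ln(4.0), ln(2.7)]
        ),
        "vascular_mortality": np.array(
            [0, 0, 0, 0.1, ln(4.0), ln(3.45), 0, 0.1, ln(2.31), ln(8.0), ln(4.14)]
        ),
        "ischaemic_stroke": np.array(
            [0, 0, 0, 0.2, ln(4.19), ln(7.22), 0, 0.2, ln(8.54), ln(10.34), ln(7.17)]
        ),
    }


@dataclass
class HazardSpec:
    """Planted hazards: baseline rates, subgroup offsets, covariate effects.

    ``baseline_rates`` are events per person-year; ``subgroup_log_hr``
    maps each outcome to a per-subgroup log-hazard offset array (0 =
    reference level).  Ages enter centered at ``age_center``.
    """

    baseline_rates: dict[str, float] = field(
        default_factory=lambda: {
            "overall_mortality": 0.012,
            "vascular_mortality": 0.006,
            "ischaemic_stroke": 0.004,
        }
    )
    subgroup_log_hr: dict[str, np.ndarray] = field(default_factory=dict)
    age_coef: float = 0.05
    sex_coef: float = 0.3
    age_center: float = 59.0
    horizon: float = 14.0
    dropout_rate: float = 0.006
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in self.baseline_rates.items():
            if rate < 0:
                raise ValueError(f"baseline rate for {name!r} must be >= 0, got {rate}")
        if self.horizon <= 0:
            raise ValueError("censoring horizon must be > 0")
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be >= 0")


def _linear_predictor(meta: pd.DataFrame, offsets: np.ndarray, spec: HazardSpec):
    sub = meta["subgroup"].to_numpy()
    if sub.min() < 1 or sub.max() > len(offsets):
        raise ValueError(
            f"subgroup labels 1..{len(offsets)} expected, got range "
            f"{sub.min()}..{sub.max()}"
        )
    return (
        offsets[sub - 1]
        + spec.age_coef * (meta["age"].to_numpy() - spec.age_center)
        + spec.sex_coef * meta["sex"].to_numpy()
    )


def _censor_times(rng, n, spec: HazardSpec) -> np.ndarray:
    cens = np.full(n, spec.horizon)
    if spec.dropout_rate > 0:
        cens = np.minimum(cens, rng.exponential(1.0 / spec.dropout_rate, n))
    return cens


def simulate_survival(meta: pd.DataFrame, spec: HazardSpec) -> pd.DataFrame:
    """Simulate per-outcome survival records for a cohort.

    ``meta`` must carry ``age``, ``sex`` and 1-based ``subgroup`` columns.
    Returns a long DataFrame (patient_id, outcome, time, event, age, sex,
    subgroup); the event time is the minimum of the latent exponential
    event time and the censoring time.
    """
    for col in ("age", "sex", "subgroup"):
        if col not in meta.columns:
            raise ValueError(f"meta is missing required column {col!r}")
    rng = np.random.default_rng(spec.seed)
    n = len(meta)
    n_sub = int(meta["subgroup"].max())
    frames = []
    for outcome, h0 in spec.baseline_rates.items():
        offsets = np.asarray(
            spec.subgroup_log_hr.get(outcome, np.zeros(n_sub)), dtype=float
        )
        rate = h0 * np.exp(_linear_predictor(meta, offsets, spec))
        with np.errstate(divide="ignore"):
            latent = np.where(rate > 0, rng.exponential(1.0, n) / np.maximum(rate, 1e-300), np.inf)
        cens = _censor_times(rng, n, spec)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": meta.index,
                    "outcome": outcome,
                    "time": np.minimum(latent, cens),
                    "event": (latent <= cens).astype(int),
                    "age": meta["age"].to_numpy(),
                    "sex": meta["sex"].to_numpy(),
                    "subgroup": meta["subgroup"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_followup(meta: pd.DataFrame, spec: HazardSpec) -> pd.DataFrame:
    """Simulate a raw follow-up table (one row per patient) for event coding.

    Death is the minimum of a vascular and a non-vascular latent death
    time (cause recorded accordingly; vascular deaths get a qualifying
    cause sampled uniformly); stroke is an independent latent time that
    counts only if it precedes death and censoring.  Columns: years_death,
    cause_of_death, years_stroke, years_last_contact plus age/sex/subgroup.
    """
    for col in ("age", "sex", "subgroup"):
        if col not in meta.columns:
            raise ValueError(f"meta is missing required column {col!r}")
    rng = np.random.default_rng(spec.seed)
    n = len(meta)
    n_sub = int(meta["subgroup"].max())

    def latent(outcome: str) -> np.ndarray:
        h0 = spec.baseline_rates[outcome]
        offsets = np.asarray(
            spec.subgroup_log_hr.get(outcome, np.zeros(n_sub)), dtype=float
        )
        rate = h0 * np.exp(_linear_predictor(meta, offsets, spec))
        return np.where(rate > 0, rng.exponential(1.0, n) / np.maximum(rate, 1e-300), np.inf)

    t_vascular = latent("vascular_mortality")
    # non-vascular hazard = overall minus vascular baseline (must be >= 0)
    h_nonvasc = spec.baseline_rates["overall_mortality"] - spec.baseline_rates[
        "vascular_mortality"
    ]
    if h_nonvasc < 0:
        raise ValueError("overall mortality rate must be >= vascular mortality rate")
    offsets0 = np.zeros(n_sub)
    rate_nv = h_nonvasc * np.exp(_linear_predictor(meta, offsets0, spec))
    t_nonvascular = np.where(
        rate_nv > 0, rng.exponential(1.0, n) / np.maximum(rate_nv, 1e-300), np.inf
    )
    t_stroke = latent("ischaemic_stroke")
    cens = _censor_times(rng, n, spec)

    t_death = np.minimum(t_vascular, t_nonvascular)
    died = t_death <= cens
    vascular = died & (t_vascular <= t_nonvascular)
    causes = np.where(
        vascular,
        rng.choice(VASCULAR_CAUSES, n),
        np.where(died, "nonvascular", ""),
    )
    stroke_seen = (t_stroke <= cens) & (t_stroke <= t_death)
    return pd.DataFrame(
        {
            "patient_id": meta.index,
            "years_death": np.where(died, t_death, np.nan),
            "cause_of_death": causes,
            "years_stroke": np.where(stroke_seen, t_stroke, np.nan),
            "years_last_contact": np.where(died, t_death, cens),
            "age": meta["age"].to_numpy(),
            "sex": meta["sex"].to_numpy(),
            "subgroup": meta["subgroup"].to_numpy(),
        }
    )
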