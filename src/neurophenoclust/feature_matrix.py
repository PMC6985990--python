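"""Assembly and normalization of the clustering feature matrix.

The clustering feature set combines ICV volume fractions, per-lobe WMH
fractions split by CPWMH/DWMH class, WMH shape means, infarct counts and
per-lobe indicators, and normalized cerebral blood flow.  Features
declared normally distributed are Z-scored; all others (counts,
indicators, skewed lobe fractions) are affinely scaled so the observed
minimum maps to 0 and the maximum to 2.  The per-column scaling record
makes the normalization invertible; missing entries are imputed at the
column's post-normalization center (0 for Z-scores, the observed median
for 0-2-scaled columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data.cohort import FEATURE_NAMES, LOBES

ZSCORE = "zscore"
MINMAX02 = "minmax02"

#: Default per-column normalization: roughly symmetric continuous markers
#: are Z-scored; counts, indicators and zero-inflated lobe fractions are
#: scaled to [0, 2].
DEFAULT_METHODS: dict[str, str] = {
    **{c: ZSCORE for c in (
        "bpf", "wm_frac", "gm_frac", "csf_frac", "ventricle_frac",
        "solidity", "convexity", "concavity_index", "eccentricity",
        "fd_cpwmh", "fd_dwmh", "cbf",
    )},
    **{f"cpwmh_frac_{lobe}": MINMAX02 for lobe in LOBES},
    **{f"dwmh_frac_{lobe}": MINMAX02 for lobe in LOBES},
    **{c: MINMAX02 for c in ("n_lacunes", "n_cortical_infarcts", "n_subcortical_infarcts")},
    **{f"cortical_infarct_{lobe}": MINMAX02 for lobe in LOBES},
    **{f"lacunes_{lobe}": MINMAX02 for lobe in LOBES},
}


@dataclass
class NormalizedMatrix:
    """Patient × feature matrix with per-column scaling metadata."""

    data: pd.DataFrame
    scaling: dict[str, dict] = field(default_factory=dict)
    imputation: dict[str, int] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def lobe_wmh_fractions(
    voxel_class: np.ndarray,
    lobe_map: np.ndarray,
    icv_ml: float,
    spacing: tuple[float, float, float],
    lobe_labels: dict[str, int] | None = None,
) -> dict[str, float]:
    """Per-lobe WMH volume by class as a percentage of ICV.

    ``voxel_class`` codes 1=CPWMH, 2=DWMH; the lobe map gives the
    parcellation codes of ``lobe_labels`` (default four classical lobes).
    """
    if voxel_class.shape != lobe_map.shape:
        raise ValueError("WMH class map and lobe map are on different grids")
    if icv_ml <= 0:
        raise ValueError("ICV must be > 0")
    if lobe_labels is None:
        lobe_labels = {name: i + 1 for i, name in enumerate(LOBES)}
    vv_ml = float(np.prod(spacing)) / 1000.0
    out = {}
    for prefix, code in (("cpwmh_frac", 1), ("dwmh_frac", 2)):
        cls_mask = voxel_class == code
        for lobe, lcode in lobe_labels.items():
            vol_ml = float((cls_mask & (lobe_map == lcode)).sum()) * vv_ml
            out[f"{prefix}_{lobe}"] = 100.0 * vol_ml / icv_ml
    return out


def assemble_features(
    fractions: pd.DataFrame,
    lobe_wmh: pd.DataFrame,
    shape: pd.DataFrame,
    infarcts: pd.DataFrame,
    cbf: pd.Series,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Merge per-patient sources into one row per patient.

    All inputs are keyed by patient id.  Every patient must appear in
    ``fractions``; a patient absent from another mandatory source raises
    an error naming the patient and the source.  Columns not in
    ``feature_names`` are dropped; missing optional values stay NaN.
    """
    sources = {
        "fractions": fractions,
        "lobe_wmh": lobe_wmh,
        "shape": shape,
        "infarcts": infarcts,
        "cbf": cbf.to_frame("cbf") if isinstance(cbf, pd.Series) else cbf,
    }
    patients = fractions.index
    for name, src in sources.items():
        absent = patients.difference(src.index)
        if len(absent):
            raise ValueError(
                f"patients missing from source {name!r}: {sorted(absent)[:5]}"
            )
    merged = pd.concat(
        [src.loc[patients] for src in sources.values()], axis=1
    )
    missing_cols = [c for c in feature_names if c not in merged.columns]
    if missing_cols:
        raise ValueError(f"assembled table lacks feature columns {missing_cols}")
    return merged.loc[:, list(feature_names)]


def as_normalized(table: pd.DataFrame) -> NormalizedMatrix:
    """Wrap a table already expressed in normalized (Z-score) units.

    Records an identity Z-score scaling per column so imputation and
    denormalization behave consistently.
    """
    scaling = {
        col: {"method": ZSCORE, "mean": 0.0, "sd": 1.0} for col in table.columns
    }
    return NormalizedMatrix(data=table.astype(float).copy(), scaling=scaling)


def normalize_features(
    table: pd.DataFrame,
    methods: dict[str, str] | None = None,
) -> NormalizedMatrix:
    """Apply the mixed Z-score / 0-2 normalization column by column.

    ``methods`` maps column -> 'zscore' or 'minmax02' (defaults from
    ``DEFAULT_METHODS``, unlisted columns fall back to minmax02).
    Statistics are computed over observed (non-NaN) values; constant
    columns are an error since neither scaling is defined.
    """
    methods = {**DEFAULT_METHODS, **(methods or {})}
    data = pd.DataFrame(index=table.index)
    scaling: dict[str, dict] = {}
    for col in table.columns:
        x = table[col].astype(float)
        obs = x.dropna()
        if obs.nunique() < 2:
            raise ValueError(f"column {col!r} is constant; normalization undefined")
        method = methods.get(col, MINMAX02)
        if method == ZSCORE:
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
            data[col] = (x - mu) / sd
            scaling[col] = {"method": ZSCORE, "mean": mu, "sd": sd}
        elif method == MINMAX02:
            lo, hi = float(obs.min()), float(obs.max())
            data[col] = (x - lo) / (hi - lo) * 2.0
            scaling[col] = {"method": MINMAX02, "min": lo, "max": hi}
        else:
            raise ValueError(f"unknown normalization method {method!r} for {col!r}")
    return NormalizedMatrix(data=data, scaling=scaling)


def denormalize(matrix: NormalizedMatrix) -> pd.DataFrame:
    """Invert the per-column scaling using the stored record."""
    out = pd.DataFrame(index=matrix.data.index)
    for col in matrix.data.columns:
        rec = matrix.scaling[col]
        x = matrix.data[col]
        if rec["method"] == ZSCORE:
            out[col] = x * rec["sd"] + rec["mean"]
        else:
            out[col] = x / 2.0 * (rec["max"] - rec["min"]) + rec["min"]
    return out


def impute_missing(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Fill missing entries with the column's post-normalization center.

    Z-scored columns are filled with 0 (the observed mean); 0-2-scaled
    columns with the observed median.  The fill is distance-neutral for
    Ward clustering in the Z-score case.  A fully missing column is an
    error.
    """
    data = matrix.data.copy()
    counts: dict[str, int] = {}
    for col in data.columns:
        n_missing = int(data[col].isna().sum())
        if n_missing == len(data):
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
        if n_missing == 0:
            continue
        method = matrix.scaling.get(col, {}).get("method", ZSCORE)
        fill = 0.0 if method == ZSCORE else float(data[col].median())
        data[col] = data[col].fillna(fill)
        counts[col] = n_missing
    return NormalizedMatrix(data=data, scaling=dict(matrix.scaling), imputation=counts)
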