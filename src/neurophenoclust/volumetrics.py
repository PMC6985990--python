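"""Label volumes, ICV fractions, CBF normalization and exclusion accounting.

Total brain volume is the sum of white matter, grey matter, WMH and
infarct volumes; intracranial volume (ICV) adds the lateral ventricles
and peripheral CSF.  Volume fractions are percentages of ICV; cerebral
blood flow is normalized per 100 ml of total brain volume.  Volumes are
reported in ml (mm^3 / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import SegmentationVolume


@dataclass(frozen=True)
class BrainVolumes:
    """Per-patient tissue volumes in ml."""

    wm: float
    gm: float
    wmh: float
    infarct: float
    ventricles: float
    peripheral_csf: float

    def __post_init__(self) -> None:
        for name in ("wm", "gm", "wmh", "infarct", "ventricles", "peripheral_csf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} volume must be >= 0")

    @property
    def total_brain(self) -> float:
        return self.wm + self.gm + self.wmh + self.infarct

    @property
    def icv(self) -> float:
        return self.total_brain + self.ventricles + self.peripheral_csf


@dataclass(frozen=True)
class VolumeFractions:
    """Volume fractions as percentages of ICV."""

    bpf: float
    wm_frac: float
    gm_frac: float
    csf_frac: float
    ventricle_frac: float
    wmh_frac: float


@dataclass(frozen=True)
class CbfMeasure:
    total_flow: float  # ml/min
    normalized_flow: float  # ml/min per 100 ml total brain volume


@dataclass(frozen=True)
class ExclusionReport:
    n_enrolled: int
    n_no_mri: int
    n_missing_sequences: int
    n_artefacts: int

    @property
    def n_included(self) -> int:
        return self.n_enrolled - self.n_no_mri - self.n_missing_sequences - self.n_artefacts


def compute_volumes(seg: SegmentationVolume) -> BrainVolumes:
    """Per-label volumes (ml) from voxel counts times voxel volume.

    Raises if the grid contains labels absent from the declared label
    dictionary.
    """
    present = set(np.unique(seg.data).tolist())
    known = set(seg.labels.values())
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"unknown labels present in segmentation: {unknown}")
    vv_ml = seg.voxel_volume / 1000.0

    def vol(name: str) -> float:
        return float((seg.data == seg.labels[name]).sum()) * vv_ml

    return BrainVolumes(
        wm=vol("wm"),
        gm=vol("gm"),
        wmh=vol("wmh"),
        infarct=vol("infarct"),
        ventricles=vol("ventricles"),
        peripheral_csf=vol("peripheral_csf"),
    )


def compute_fractions(v: BrainVolumes) -> VolumeFractions:
    """Express volumes as percentages of ICV; bpf + csf + ventricles = 100."""
    if v.icv <= 0:
        raise ValueError("ICV must be > 0 to compute fractions")
    f = 100.0 / v.icv
    return VolumeFractions(
        bpf=v.total_brain * f,
        wm_frac=v.wm * f,
        gm_frac=v.gm * f,
        csf_frac=v.peripheral_csf * f,
        ventricle_frac=v.ventricles * f,
        wmh_frac=v.wmh * f,
    )


def normalize_cbf(total_flow: float, v: BrainVolumes) -> CbfMeasure:
    """Total CBF (ml/min) per 100 ml of total brain volume."""
    if total_flow < 0:
        raise ValueError("total flow must be >= 0")
    if v.total_brain <= 0:
        raise ValueError("total brain volume must be > 0")
    return CbfMeasure(
        total_flow=float(total_flow),
        normalized_flow=100.0 * total_flow / v.total_brain,
    )


def apply_exclusions(manifest: pd.DataFrame) -> ExclusionReport:
    """Study-sample accounting with first-matching exclusion precedence.

    ``manifest`` has one row per enrolled patient with boolean columns
    ``no_mri``, ``missing_sequence``, ``artefact``; a patient carrying
    several flags is counted only under the first matching category
    (no MRI, then missing sequences, then artefacts).
    """
    required = {"no_mri", "missing_sequence", "artefact"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    if "patient_id" in manifest.columns:
        dup = manifest["patient_id"][manifest["patient_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate patient identifiers: {sorted(set(dup))}")
    elif manifest.index.has_duplicates:
        raise ValueError("duplicate patient identifiers in manifest index")

    no_mri = manifest["no_mri"].astype(bool)
    missing_seq = manifest["missing_sequence"].astype(bool) & ~no_mri
    artefact = manifest["artefact"].astype(bool) & ~no_mri & ~missing_seq
    return ExclusionReport(
        n_enrolled=len(manifest),
        n_no_mri=int(no_mri.sum()),
        n_missing_sequences=int(missing_seq.sum()),
        n_artefacts=int(artefact.sum()),
    )


def included_mask(manifest: pd.DataFrame) -> pd.Series:
    """Boolean series marking patients retained after all exclusions."""
    return ~(
        manifest["no_mri"].astype(bool)
        | manifest["missing_sequence"].astype(bool)
        | manifest["artefact"].astype(bool)
    )


def volumes_table(per_patient: dict[str, BrainVolumes]) -> pd.DataFrame:
    """Tabulate BrainVolumes per patient (columns in ml, plus derived sums)."""
    rows = {}
    for pid, v in per_patient.items():
        rows[pid] = {
            "wm": v.wm, "gm": v.gm, "wmh": v.wmh, "infarct": v.infarct,
            "ventricles": v.ventricles, "peripheral_csf": v.peripheral_csf,
            "total_brain": v.total_brain, "icv": v.icv,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "patient_id"
    return out
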