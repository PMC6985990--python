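"""Segmentation label volumes: container, label dictionary, NIfTI I/O.

Per-patient imaging input is a 3D integer label grid with (generally
anisotropic) voxel spacing in mm.  The label dictionary mirrors the tissue
classes of a k-NN probabilistic brain segmentation: white matter, cortical
grey matter, peripheral CSF (outside the brain), lateral ventricles, WMH
and infarcts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical label dictionary. Background is 0 and never counts as tissue.
DEFAULT_LABELS: dict[str, int] = {
    "background": 0,
    "wm": 1,
    "gm": 2,
    "peripheral_csf": 3,
    "ventricles": 4,
    "wmh": 5,
    "infarct": 6,
}

#: Labels whose volumes sum to total brain volume.
BRAIN_LABELS = ("wm", "gm", "wmh", "infarct")


@dataclass
class SegmentationVolume:
    """A 3D integer label grid plus voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    labels: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label grid must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def mask(self, label: str) -> np.ndarray:
        """Binary mask for a named label."""
        if label not in self.labels:
            raise KeyError(f"unknown label {label!r}; known: {sorted(self.labels)}")
        return self.data == self.labels[label]

    def to_nifti(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), affine), str(path))

    @classmethod
    def from_nifti(cls, path, labels: dict[str, int] | None = None) -> "SegmentationVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            data=np.asarray(img.dataobj).astype(np.int32),
            spacing=spacing,
            labels=dict(labels) if labels else dict(DEFAULT_LABELS),
        )
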