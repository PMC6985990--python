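"""Digital phantoms with analytic ground truth.

Two levels of phantom:

* :func:`make_lesion_phantom` — single binary shapes (balls, ellipsoids,
  dented balls, line segments, a Menger-sponge-like fractal) with
  closed-form volume, surface area, principal-moment ratios and, where
  defined, box-counting dimension.  These exercise the shape-feature
  extractors against known answers.
* :func:`make_head_phantom` — a whole-head segmentation label volume
  built from nested ellipsoids (peripheral CSF shell, cortical grey
  matter shell, white matter core, two lateral ventricles) with planted
  WMH and infarct lesions and a four-lobe parcellation, plus the exact
  per-label volume table implied by the construction.

All voxelization uses voxel-center sampling: a voxel belongs to a
primitive iff its center satisfies the analytic inequality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..segmentation import DEFAULT_LABELS, SegmentationVolume

LOBE_LABELS: dict[str, int] = {
    "none": 0,
    "frontal": 1,
    "parietal": 2,
    "temporal": 3,
    "occipital": 4,
}


# ---------------------------------------------------------------------------
# geometry helpers


def _axis_coords(grid_shape, spacing, center):
    """Per-axis physical coordinates (mm) of voxel centers, origin at grid center."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s - c
        for n, s, c in zip(grid_shape, spacing, center)
    ]


def _ellipsoid_mask(grid_shape, spacing, center, semi_axes) -> np.ndarray:
    cx, cy, cz = _axis_coords(grid_shape, spacing, center)
    a, b, c = semi_axes
    return (
        (cx[:, None, None] / a) ** 2
        + (cy[None, :, None] / b) ** 2
        + (cz[None, None, :] / c) ** 2
    ) <= 1.0


def _check_fits(grid_shape, spacing, center, semi_axes) -> None:
    """A primitive must lie strictly inside the grid's physical extent."""
    for ax, (n, s, c, r) in enumerate(zip(grid_shape, spacing, center, semi_axes)):
        half_extent = n * s / 2.0
        if abs(c) + r > half_extent:
            raise ValueError(
                f"primitive exceeds grid along axis {ax}: "
                f"|center|+radius = {abs(c) + r:.1f} mm > half extent {half_extent:.1f} mm"
            )


def _auto_grid(spacing, semi_axes, margin_vox=2) -> tuple[int, ...]:
    return tuple(
        int(math.ceil(2 * r / s)) + 2 * margin_vox + 1
        for r, s in zip(semi_axes, spacing)
    )


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation of the ellipsoid surface area (error < 1.1%)."""
    p = 1.6075
    t = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * math.pi * t ** (1.0 / p)


def _sphere_lens_volume(R: float, r: float, d: float) -> float:
    """Volume of the intersection of spheres with radii R, r at center distance d."""
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        rr = min(R, r)
        return 4.0 / 3.0 * math.pi * rr**3
    return (
        math.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * r - 3 * r**2 + 2 * d * R + 6 * r * R - 3 * R**2)
        / (12 * d)
    )


def _menger_mask(level: int) -> np.ndarray:
    """Menger-sponge voxel set on a 3**level cube.

    A cell is kept iff no base-3 digit position has two or more middle
    digits among its three coordinates.
    """
    n = 3**level
    idx = np.indices((n, n, n))
    keep = np.ones((n, n, n), dtype=bool)
    for lev in range(level):
        digits = (idx // (3**lev)) % 3
        middle = (digits == 1).sum(axis=0)
        keep &= middle < 2
    return keep


# ---------------------------------------------------------------------------
# single-lesion phantoms


def make_lesion_phantom(
    kind: str,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    grid_shape: tuple[int, int, int] | None = None,
    **params,
) -> tuple[np.ndarray, dict]:
    """Voxelize one analytic shape and return (mask, truth record).

    Parameters
    ----------
    kind
        One of ``ball`` (radius), ``ellipsoid`` (semi_axes),
        ``dented_ball`` (radius, dent_radius), ``segment`` (length,
        in voxels along the last axis), ``menger_like`` (level).
    spacing
        Voxel spacing in mm.
    grid_shape
        Optional explicit grid; auto-sized to fit the shape otherwise.

    Returns
    -------
    mask : bool ndarray
    truth : dict with analytic values from the construction — always
        ``kind`` and ``spacing``; ``volume_mm3``/``surface_area_mm2``/
        ``moment_ratios`` for solid shapes; ``fractal_dimension`` and
        exact ``box_counts`` for the fractal/line shapes.
    """
    spacing = tuple(float(s) for s in spacing)
    truth: dict = {"kind": kind, "spacing": spacing}

    if kind == "ball":
        r = float(params.pop("radius", 10.0))
        if r <= 0:
            raise ValueError("radius must be positive")
        semi = (r, r, r)
        if grid_shape is None:
            grid_shape = _auto_grid(spacing, semi)
        _check_fits(grid_shape, spacing, (0, 0, 0), semi)
        mask = _ellipsoid_mask(grid_shape, spacing, (0, 0, 0), semi)
        truth.update(
            volume_mm3=4.0 / 3.0 * math.pi * r**3,
            surface_area_mm2=4.0 * math.pi * r**2,
            moment_ratios=(1.0, 1.0, 1.0),
            eccentricity=0.0,
        )
    elif kind == "ellipsoid":
        a, b, c = (float(x) for x in params.pop("semi_axes", (20.0, 5.0, 5.0)))
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        semi = (a, b, c)
        if grid_shape is None:
            grid_shape = _auto_grid(spacing, semi)
        _check_fits(grid_shape, spacing, (0, 0, 0), semi)
        mask = _ellipsoid_mask(grid_shape, spacing, (0, 0, 0), semi)
        sq = sorted([a * a, b * b, c * c])
        truth.update(
            volume_mm3=4.0 / 3.0 * math.pi * a * b * c,
            surface_area_mm2=_ellipsoid_area(a, b, c),
            moment_ratios=(a * a, b * b, c * c),
            eccentricity=math.sqrt(1.0 - sq[0] / sq[2]),
        )
    elif kind == "dented_ball":
        r = float(params.pop("radius", 10.0))
        rd = float(params.pop("dent_radius", 6.0))
        if r <= 0 or rd <= 0:
            raise ValueError("radii must be positive")
        # dent sphere centered on the ball surface along +x
        semi = (r, r, r)
        if grid_shape is None:
            grid_shape = _auto_grid(spacing, semi)
        _check_fits(grid_shape, spacing, (0, 0, 0), semi)
        ball = _ellipsoid_mask(grid_shape, spacing, (0, 0, 0), semi)
        dent = _ellipsoid_mask(grid_shape, spacing, (r, 0, 0), (rd, rd, rd))
        mask = ball & ~dent
        lens = _sphere_lens_volume(r, rd, r)
        truth.update(
            volume_mm3=4.0 / 3.0 * math.pi * r**3 - lens,
            convex=False,
        )
    elif kind == "segment":
        length = int(params.pop("length", 32))
        if length < 1:
            raise ValueError("length must be >= 1")
        if grid_shape is None:
            grid_shape = (3, 3, length + 2)
        if grid_shape[2] < length:
            raise ValueError(
                f"primitive exceeds grid along axis 2: length {length} > {grid_shape[2]}"
            )
        mask = np.zeros(grid_shape, dtype=bool)
        z0 = (grid_shape[2] - length) // 2
        mask[grid_shape[0] // 2, grid_shape[1] // 2, z0 : z0 + length] = True
        truth.update(fractal_dimension=1.0)
    elif kind == "menger_like":
        level = int(params.pop("level", 2))
        if level < 1:
            raise ValueError("level must be >= 1")
        mask = _menger_mask(level)
        if grid_shape is not None:
            if any(g < m for g, m in zip(grid_shape, mask.shape)):
                ax = next(i for i, (g, m) in enumerate(zip(grid_shape, mask.shape)) if g < m)
                raise ValueError(f"primitive exceeds grid along axis {ax}")
            out = np.zeros(grid_shape, dtype=bool)
            out[: mask.shape[0], : mask.shape[1], : mask.shape[2]] = mask
            mask = out
        # exact box counts at scales 3^i: N(3^i) = 20^(level-i)
        truth.update(
            fractal_dimension=math.log(20) / math.log(3),
            box_scales=tuple(3**i for i in range(level + 1)),
            box_counts=tuple(20 ** (level - i) for i in range(level + 1)),
        )
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    if params:
        raise TypeError(f"unused parameters for kind {kind!r}: {sorted(params)}")
    truth["voxel_count"] = int(mask.sum())
    truth["voxel_volume_mm3"] = truth["voxel_count"] * float(np.prod(spacing))
    return mask, truth


# ---------------------------------------------------------------------------
# whole-head phantom


@dataclass
class Structure:
    """One planted primitive (lesion) inside the head phantom."""

    kind: str  # 'ball' or 'ellipsoid'
    center: tuple[float, float, float]  # mm, relative to head center
    semi_axes: tuple[float, float, float]  # mm
    label: str  # 'wmh' or 'infarct'


@dataclass
class PhantomSpec:
    """Geometry of a whole-head segmentation phantom.

    The head is built from nested ellipsoids (outside in: peripheral CSF,
    cortical grey matter, white matter) with two lateral ventricles;
    ``structures`` are painted last and must lie within white matter.
    Same spec + seed gives a bit-identical volume.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 41)
    spacing: tuple[float, float, float] = (0.9, 0.9, 4.0)
    icv_semi_axes: tuple[float, float, float] = (38.0, 38.0, 60.0)
    csf_thickness: float = 4.0
    gm_thickness: float = 6.0
    ventricle_semi_axes: tuple[float, float, float] = (4.0, 10.0, 8.0)
    ventricle_offset: float = 7.0  # lateral (x) offset of each ventricle, mm
    structures: list[Structure] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")


def default_head_spec(
    n_wmh: int = 3,
    n_infarcts: int = 1,
    seed: int = 0,
    wmh_radius: float = 3.0,
    **overrides,
) -> PhantomSpec:
    """A head spec with randomly placed WMH and infarct balls.

    The first WMH is placed adjacent to a ventricle (periventricular),
    the rest at least 6 mm away from both ventricles (deep).
    """
    spec = PhantomSpec(seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    vx = spec.ventricle_semi_axes[0]
    vent_reach = spec.ventricle_offset + vx  # max |x| of ventricle tissue
    wm_x = spec.icv_semi_axes[0] - spec.csf_thickness - spec.gm_thickness
    if vent_reach + 2 * wmh_radius + 8.0 > wm_x:
        raise ValueError(
            "white-matter core too small for the default lesion layout; "
            "enlarge icv_semi_axes or place structures explicitly"
        )
    structures: list[Structure] = []
    for i in range(n_wmh):
        if i == 0:
            # touching the right ventricle's lateral surface
            center = (vent_reach + wmh_radius, 0.0, 0.0)
        else:
            # deep: nearest surface point > 3 mm lateral of the ventricles
            side = 1 if i % 2 else -1
            lo = vent_reach + wmh_radius + 4.0
            center = (
                side * float(rng.uniform(lo, lo + 4.0)),
                float(rng.uniform(-6, 6)),
                float(rng.uniform(-8, 8)),
            )
        structures.append(Structure("ball", center, (wmh_radius,) * 3, "wmh"))
    for i in range(n_infarcts):
        side = 1 if i % 2 else -1
        center = (
            side * float(rng.uniform(vx + 8, vx + 12)),
            float(rng.uniform(-5, 5)),
            float(rng.uniform(-16, -10)),
        )
        structures.append(Structure("ball", center, (4.0, 4.0, 4.0), "infarct"))
    spec.structures = structures
    return spec


def make_head_phantom(
    spec: PhantomSpec,
) -> tuple[SegmentationVolume, pd.DataFrame, np.ndarray]:
    """Build the label volume, per-label ground-truth table and lobe map.

    Returns
    -------
    seg : SegmentationVolume
    truth : DataFrame with columns label, voxels, volume_mm3 — exact
        voxel accounting of the construction (labels mutually exclusive).
    lobe_map : int ndarray, 0 outside the brain, else LOBE_LABELS codes
        from an axis-aligned quadrant split about the brain centroid
        (frontal/temporal anterior, parietal/occipital posterior;
        frontal/parietal superior, temporal/occipital inferior).
    """
    gs, sp = spec.grid_shape, spec.spacing
    a, b, c = spec.icv_semi_axes
    t_csf, t_gm = spec.csf_thickness, spec.gm_thickness
    if min(a, b, c) <= t_csf + t_gm:
        raise ValueError("ICV semi-axes too small for the CSF + GM shells")
    _check_fits(gs, sp, (0, 0, 0), spec.icv_semi_axes)

    icv = _ellipsoid_mask(gs, sp, (0, 0, 0), (a, b, c))
    brain = _ellipsoid_mask(gs, sp, (0, 0, 0), (a - t_csf, b - t_csf, c - t_csf))
    wm_core = _ellipsoid_mask(
        gs, sp, (0, 0, 0), (a - t_csf - t_gm, b - t_csf - t_gm, c - t_csf - t_gm)
    )

    L = DEFAULT_LABELS
    data = np.zeros(gs, dtype=np.int16)
    data[icv] = L["peripheral_csf"]
    data[brain] = L["gm"]
    data[wm_core] = L["wm"]

    for off in (+spec.ventricle_offset, -spec.ventricle_offset):
        vent = _ellipsoid_mask(gs, sp, (off, 0, 0), spec.ventricle_semi_axes)
        if np.any(vent & ~wm_core):
            raise ValueError("ventricle extends outside the white-matter core")
        data[vent] = L["ventricles"]

    for s in spec.structures:
        if s.label not in L:
            raise KeyError(f"unknown structure label {s.label!r}")
        _check_fits(gs, sp, s.center, s.semi_axes)
        mask = _ellipsoid_mask(gs, sp, s.center, s.semi_axes)
        clash = mask & (data != L["wm"])
        if np.any(clash):
            hit = sorted({int(v) for v in data[clash]})
            names = [k for k, v in L.items() for h in hit if v == h]
            raise ValueError(
                f"structure {s.label!r} at {s.center} overlaps non-WM labels {names}"
            )
        data[mask] = L[s.label]

    seg = SegmentationVolume(data=data, spacing=sp)
    vv = seg.voxel_volume
    rows = [
        {"label": name, "voxels": int((data == code).sum())}
        for name, code in L.items()
        if name != "background"
    ]
    truth = pd.DataFrame(rows)
    truth["volume_mm3"] = truth["voxels"] * vv

    # lobe parcellation: quadrants about the brain centroid in the (y, z) plane
    lobe_map = np.zeros(gs, dtype=np.int16)
    brain_mask = np.isin(data, [L["wm"], L["gm"], L["wmh"], L["infarct"], L["ventricles"]])
    idx = np.argwhere(brain_mask)
    cy, cz = idx[:, 1].mean(), idx[:, 2].mean()
    anterior = idx[:, 1] >= cy
    superior = idx[:, 2] >= cz
    codes = np.where(
        superior,
        np.where(anterior, LOBE_LABELS["frontal"], LOBE_LABELS["parietal"]),
        np.where(anterior, LOBE_LABELS["temporal"], LOBE_LABELS["occipital"]),
    )
    lobe_map[idx[:, 0], idx[:, 1], idx[:, 2]] = codes
    return seg, truth, lobe_map
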