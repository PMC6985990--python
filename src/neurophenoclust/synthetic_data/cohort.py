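"""Feature-space cohorts with planted cluster structure.

The generator works directly in normalized feature space (centroids in SD
units): the downstream clustering consumes Z-scored / 0-2-scaled columns,
and published subgroup profiles are group contrasts, not raw generative
distributions.  Eleven default centroid profiles emulate the qualitative
subgroup structure of a manifest-arterial-disease cohort: several
low-burden groups, a cortical-infarct group, a lacunar group, a prominent
small-vessel-disease group, a neurodegenerative (atrophy) group and a
multi-burden group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOBES = ("frontal", "parietal", "temporal", "occipital")

#: The clustering feature set: volume fractions, per-lobe WMH fractions by
#: class, WMH shape means, infarct counts/indicators and normalized CBF.
FEATURE_NAMES: tuple[str, ...] = (
    "bpf",
    "wm_frac",
    "gm_frac",
    "csf_frac",
    "ventricle_frac",
    *[f"cpwmh_frac_{lobe}" for lobe in LOBES],
    *[f"dwmh_frac_{lobe}" for lobe in LOBES],
    "solidity",
    "convexity",
    "concavity_index",
    "eccentricity",
    "fd_cpwmh",
    "fd_dwmh",
    "n_lacunes",
    "n_cortical_infarcts",
    "n_subcortical_infarcts",
    *[f"cortical_infarct_{lobe}" for lobe in LOBES],
    *[f"lacunes_{lobe}" for lobe in LOBES],
    "cbf",
)

#: Missingness rates of the features that are undefined for some patients
#: (no deep lesions -> no deep-WMH shape values; missing flow acquisition).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "solidity": 0.004,
    "convexity": 0.004,
    "concavity_index": 0.004,
    "fd_cpwmh": 0.004,
    "fd_dwmh": 0.385,
    "eccentricity": 0.385,
    "cbf": 0.064,
}

#: Default subgroup sizes for n=1003 (range 46-188 patients per subgroup).
DEFAULT_SIZE_PROFILE: tuple[int, ...] = (160, 125, 110, 100, 95, 90, 85, 75, 65, 52, 46)

#: Default per-subgroup mean ages (years), ascending; cohort mean ~59.
DEFAULT_AGE_MEANS: tuple[float, ...] = (50, 53, 55, 57, 58, 60, 61, 63, 65, 67, 70)


def _profile(**kw: float) -> dict[str, float]:
    unknown = set(kw) - set(FEATURE_NAMES)
    if unknown:
        raise KeyError(f"unknown features in profile: {sorted(unknown)}")
    return kw


def subgroup_profile_centroids() -> np.ndarray:
    """Eleven centroid profiles (SD units) emulating the subgroup contrasts.

    Groups 1-3 and 7 are low-burden (they form the merged Cox reference);
    4 and 8 carry limited burden; 5 is dominated by cortical infarcts; 6
    by lacunes; 9 by small-vessel disease (high WMH load and shape
    irregularity); 11 by atrophy; 10 is the multi-burden group.
    """
    profiles = [
        _profile(bpf=1.6, gm_frac=1.2, solidity=1.2, convexity=1.0,
                 concavity_index=-1.0, cbf=1.0, fd_cpwmh=-0.8),
        _profile(bpf=1.2, wm_frac=1.4, solidity=1.0, convexity=1.2,
                 concavity_index=-0.8, fd_cpwmh=-1.2, cbf=0.5),
        _profile(bpf=1.0, csf_frac=-0.8, solidity=0.8, convexity=0.6,
                 eccentricity=-0.8, cbf=0.8, wm_frac=0.6),
        _profile(ventricle_frac=0.8, cpwmh_frac_frontal=0.8, fd_cpwmh=0.5,
                 bpf=0.3, eccentricity=0.6),
        _profile(n_cortical_infarcts=2.5, cortical_infarct_frontal=2.0,
                 cortical_infarct_parietal=2.0, cortical_infarct_temporal=1.2,
                 n_subcortical_infarcts=1.0, bpf=-0.4),
        _profile(n_lacunes=2.5, lacunes_frontal=2.0, lacunes_parietal=1.8,
                 lacunes_temporal=1.2, lacunes_occipital=1.0,
                 n_subcortical_infarcts=0.8),
        _profile(bpf=0.6, wm_frac=0.5, solidity=0.5, convexity=0.4,
                 cpwmh_frac_parietal=-0.5, cbf=0.3),
        _profile(csf_frac=1.0, eccentricity=1.0, cpwmh_frac_occipital=0.8,
                 dwmh_frac_frontal=0.6, fd_dwmh=0.6),
        _profile(cpwmh_frac_frontal=2.0, cpwmh_frac_parietal=2.0,
                 cpwmh_frac_temporal=1.5, cpwmh_frac_occipital=1.5,
                 dwmh_frac_frontal=1.5, dwmh_frac_parietal=1.2,
                 fd_cpwmh=1.5, fd_dwmh=1.2, concavity_index=1.2,
                 solidity=-1.2, n_lacunes=0.8),
        _profile(bpf=-2.0, ventricle_frac=2.0, cpwmh_frac_frontal=2.2,
                 cpwmh_frac_parietal=2.0, cpwmh_frac_temporal=1.8,
                 dwmh_frac_frontal=1.8, dwmh_frac_parietal=1.5,
                 concavity_index=2.0, fd_cpwmh=2.0, fd_dwmh=1.5,
                 solidity=-1.8, convexity=-1.5, n_lacunes=1.5, cbf=-1.0),
        _profile(bpf=-2.4, gm_frac=-2.0, csf_frac=2.0, ventricle_frac=1.5,
                 cbf=-0.8, wm_frac=-1.2, eccentricity=0.5),
    ]
    m = np.zeros((len(profiles), len(FEATURE_NAMES)))
    for i, prof in enumerate(profiles):
        for name, value in prof.items():
            m[i, FEATURE_NAMES.index(name)] = value
    return m


@dataclass
class CohortSpec:
    """Generative spec for a feature-space cohort with planted clusters.

    ``centroids`` (k x p, SD units) default to the eleven subgroup-style
    profiles; they are rescaled so the minimum pairwise Euclidean
    separation equals ``min_separation``.  ``dispersions`` is the
    per-feature within-cluster SD (scalar, per-feature vector or k x p).
    """

    n_patients: int = 1003
    n_clusters: int = 11
    centroids: np.ndarray | None = None
    dispersions: float | np.ndarray = 1.0
    min_separation: float = 6.0
    equalize_separation: bool = True
    cluster_sizes: tuple[int, ...] | None = None
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    feature_names: tuple[str, ...] = FEATURE_NAMES
    age_mean: float = 59.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (25.0, 82.0)
    cluster_age_means: tuple[float, ...] | None = None
    male_fraction: float = 0.8
    seed: int = 0

    def resolved_centroids(self) -> np.ndarray:
        if self.centroids is None:
            if self.n_clusters <= 11 and len(self.feature_names) == len(FEATURE_NAMES):
                cent = subgroup_profile_centroids()[: self.n_clusters]
            else:
                raise ValueError(
                    "centroids must be given for more than 11 clusters or a "
                    "non-default feature set"
                )
        else:
            cent = np.asarray(self.centroids, dtype=float)
        if cent.shape != (self.n_clusters, len(self.feature_names)):
            raise ValueError(
                f"centroids shape {cent.shape} != "
                f"({self.n_clusters}, {len(self.feature_names)})"
            )
        if self.min_separation is not None and self.n_clusters > 1:
            if self.equalize_separation:
                # Orthogonalize the profile directions (Gram-Schmidt) and
                # compress the profile magnitudes toward their geometric
                # middle (square root): no subgroup pair is left uniquely
                # close through shared burden patterns, yet strongly
                # contrasting groups stay somewhat farther apart than mildly
                # contrasting ones, as in real subgroup profiles.
                norms = np.sqrt(np.linalg.norm(cent, axis=1))
                q = np.zeros_like(cent)
                for i in range(self.n_clusters):
                    v = cent[i].copy()
                    for j in range(i):
                        v -= (v @ q[j]) * q[j]
                    norm = np.linalg.norm(v)
                    if norm < 1e-9 * max(norms[i], 1.0):
                        raise ValueError(
                            "centroid profiles are linearly dependent; cannot "
                            "equalize separation"
                        )
                    q[i] = v / norm
                cent = q * norms[:, None]
            d = np.sqrt(((cent[:, None] - cent[None, :]) ** 2).sum(-1))
            dmin = d[np.triu_indices(self.n_clusters, 1)].min()
            if dmin == 0:
                raise ValueError("duplicate centroids cannot be separated by scaling")
            cent = cent * (self.min_separation / dmin)
        return cent

    def resolved_sizes(self) -> np.ndarray:
        if self.cluster_sizes is not None:
            sizes = np.asarray(self.cluster_sizes, dtype=int)
            if len(sizes) != self.n_clusters or sizes.sum() != self.n_patients:
                raise ValueError(
                    f"cluster sizes {sizes.tolist()} must be {self.n_clusters} "
                    f"counts summing to {self.n_patients}"
                )
            return sizes
        if self.n_clusters == 11:
            prof = np.asarray(DEFAULT_SIZE_PROFILE, dtype=float)
        else:
            prof = np.ones(self.n_clusters)
        # largest-remainder apportionment to hit n_patients exactly
        quota = prof / prof.sum() * self.n_patients
        sizes = np.floor(quota).astype(int)
        rem = self.n_patients - sizes.sum()
        order = np.argsort(-(quota - sizes))
        sizes[order[:rem]] += 1
        if (sizes < 1).any():
            raise ValueError("cluster sizes must all be >= 1")
        return sizes


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw a cohort of feature vectors with planted cluster labels.

    Returns
    -------
    features : DataFrame (patient_id index, feature columns; NaN where a
        value is missing per the spec's missingness rates)
    meta : DataFrame with age (years), sex (1=male) and the planted
        subgroup label (1-based, ordered by ``cluster_age_means``)
    labels : planted 1-based cluster labels, one per patient
    """
    if spec.n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    disp = np.asarray(spec.dispersions, dtype=float)
    if (disp < 0).any():
        raise ValueError("dispersions must be non-negative")
    rng = np.random.default_rng(spec.seed)
    cent = spec.resolved_centroids()
    sizes = spec.resolved_sizes()
    p = len(spec.feature_names)
    if disp.ndim == 0:
        disp = np.full((spec.n_clusters, p), float(disp))
    elif disp.ndim == 1:
        if disp.shape[0] != p:
            raise ValueError(f"per-feature dispersions must have length {p}")
        disp = np.tile(disp, (spec.n_clusters, 1))
    elif disp.shape != (spec.n_clusters, p):
        raise ValueError(f"dispersion array must be scalar, ({p},) or {(spec.n_clusters, p)}")

    labels = np.repeat(np.arange(1, spec.n_clusters + 1), sizes)
    x = np.empty((spec.n_patients, p))
    start = 0
    for g in range(spec.n_clusters):
        n_g = sizes[g]
        x[start : start + n_g] = cent[g] + rng.normal(size=(n_g, p)) * disp[g]
        start += n_g

    age_means = spec.cluster_age_means
    if age_means is None:
        age_means = (
            DEFAULT_AGE_MEANS
            if spec.n_clusters == 11
            else tuple(
                np.linspace(spec.age_mean - 8, spec.age_mean + 8, spec.n_clusters)
            )
        )
    if len(age_means) != spec.n_clusters:
        raise ValueError("cluster_age_means must give one mean per cluster")
    lo, hi = spec.age_range
    within_sd = max(spec.age_sd - 4.0, 2.0)  # between-cluster spread carries the rest
    age = np.concatenate(
        [
            _truncated_normal(rng, age_means[g], within_sd, lo, hi, sizes[g])
            for g in range(spec.n_clusters)
        ]
    )
    sex = (rng.uniform(size=spec.n_patients) < spec.male_fraction).astype(int)

    ids = [f"P{i:04d}" for i in range(1, spec.n_patients + 1)]
    features = pd.DataFrame(x, index=pd.Index(ids, name="patient_id"),
                            columns=list(spec.feature_names))
    for name, rate in spec.missingness.items():
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"missingness rate for {name!r} must be in [0, 1)")
        if name in features.columns and rate > 0:
            drop = rng.uniform(size=spec.n_patients) < rate
            features.loc[drop, name] = np.nan
    meta = pd.DataFrame(
        {"age": age, "sex": sex, "subgroup": labels},
        index=features.index,
    )
    return features, meta, labels
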