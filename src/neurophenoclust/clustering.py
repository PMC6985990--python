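"""Ward clustering, cut-level selection and subgroup outputs.

Patients are clustered by agglomerative Ward linkage on the Euclidean
distance over the normalized feature matrix (the ward.D2 dialect: merge
heights on the distance scale).  The dendrogram cut is chosen by scanning
a k-range and combining two internal validity indices:

* average silhouette width — mean of (b − a)/max(a, b) over points,
  with 0 assigned to singleton members;
* Dunn index — minimum single-link inter-cluster distance divided by
  the maximum intra-cluster diameter.

The default selection takes the k with the best silhouette/Dunn rank sum
(a human override reproduces a visually guided choice).  Subgroups are
renumbered by ascending mean age so subgroup 1 is always the youngest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score


@dataclass
class ClusterTree:
    """Ward merge tree: scipy linkage matrix plus plotting leaf order."""

    linkage: np.ndarray  # (n-1, 4): child a, child b, height, size
    n_leaves: int

    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.linkage).tolist()


@dataclass
class CutMetrics:
    k: int
    silhouette: float
    dunn: float
    sizes: tuple[int, ...]


@dataclass
class SubgroupAssignment:
    """Patient → subgroup number (1..k), numbered by ascending mean age."""

    labels: pd.Series  # patient id -> subgroup 1..k
    mean_ages: dict[int, float]


def ward_linkage(matrix: np.ndarray | pd.DataFrame) -> ClusterTree:
    """Agglomerative Ward merges over Euclidean distance (ward.D2)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("matrix must be 2D with at least 2 rows")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite entries; impute first")
    z = hierarchy.linkage(x, method="ward")
    return ClusterTree(linkage=z, n_leaves=x.shape[0])


def cut_tree(tree: ClusterTree, k: int) -> np.ndarray:
    """Labels (1..k) from removing the k−1 highest merges."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}], got {k}")
    raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return raw.astype(int)


def dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster single-link distance / max intra-cluster diameter."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    masks = [labels == u for u in uniq]
    max_diam = 0.0
    for m in masks:
        if m.sum() > 1:
            max_diam = max(max_diam, float(dist[np.ix_(m, m)].max()))
    min_inter = np.inf
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            min_inter = min(min_inter, float(dist[np.ix_(masks[i], masks[j])].min()))
    if max_diam == 0.0:
        return float("inf")
    return min_inter / max_diam


def validity_indices(
    matrix: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    dist: np.ndarray | None = None,
) -> CutMetrics:
    """Average silhouette width and Dunn index for one labelling."""
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    uniq, sizes = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("validity indices require k >= 2")
    if dist is None:
        dist = squareform(pdist(x))
    sil = float(silhouette_score(dist, labels, metric="precomputed"))
    return CutMetrics(
        k=len(uniq),
        silhouette=sil,
        dunn=dunn_index(dist, labels),
        sizes=tuple(int(s) for s in sizes),
    )


def select_k(
    tree: ClusterTree,
    matrix: np.ndarray | pd.DataFrame,
    k_range: tuple[int, int] = (2, 20),
    force_k: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Scan cut levels and choose k by silhouette/Dunn rank sum.

    Emits the full metrics table for audit.  ``force_k`` reproduces a
    human override (the metrics table is still computed).  Ties in the
    rank sum go to the smaller k.
    """
    lo, hi = k_range
    hi = min(hi, tree.n_leaves - 1)
    if lo < 2 or lo > hi:
        raise ValueError(f"empty or invalid k range [{lo}, {hi}]")
    x = np.asarray(matrix, dtype=float)
    dist = squareform(pdist(x))
    rows = []
    for k in range(lo, hi + 1):
        labels = cut_tree(tree, k)
        m = validity_indices(x, labels, dist=dist)
        rows.append({"k": k, "silhouette": m.silhouette, "dunn": m.dunn,
                     "min_size": min(m.sizes), "max_size": max(m.sizes)})
    table = pd.DataFrame(rows)
    # rank 1 = best (largest) index value; rank sum over both indices
    table["rank_silhouette"] = table["silhouette"].rank(ascending=False)
    table["rank_dunn"] = table["dunn"].rank(ascending=False)
    table["rank_sum"] = table["rank_silhouette"] + table["rank_dunn"]
    if force_k is not None:
        if not lo <= force_k <= hi:
            raise ValueError(f"force_k={force_k} outside scanned range [{lo}, {hi}]")
        chosen = int(force_k)
    else:
        chosen = int(table.sort_values(["rank_sum", "k"]).iloc[0]["k"])
    return chosen, table


def renumber_by_age(
    labels: np.ndarray | pd.Series,
    ages: np.ndarray | pd.Series,
    index: pd.Index | None = None,
) -> SubgroupAssignment:
    """Renumber subgroups 1..k by ascending mean age (ties by old label)."""
    labels = pd.Series(np.asarray(labels), index=index)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(labels):
        raise ValueError("labels and ages differ in length")
    if np.isnan(ages).any():
        raise ValueError("every patient needs an age")
    means = (
        pd.DataFrame({"label": labels.to_numpy(), "age": ages})
        .groupby("label")["age"]
        .mean()
        .sort_values(kind="stable")
    )
    remap = {old: new for new, old in enumerate(means.index, start=1)}
    new_labels = labels.map(remap)
    return SubgroupAssignment(
        labels=new_labels,
        mean_ages={remap[old]: float(means[old]) for old in means.index},
    )


# ---------------------------------------------------------------------------
# rendered outputs


def heatmap_data(
    matrix: pd.DataFrame, tree: ClusterTree
) -> pd.DataFrame:
    """The normalized matrix row-reordered by dendrogram leaf order."""
    return matrix.iloc[tree.leaf_order()]


def wmh_frequency_maps(
    masks: dict[str, np.ndarray],
    assignment: SubgroupAssignment,
) -> dict[int, np.ndarray]:
    """Voxelwise WMH presence frequency per subgroup on a common grid.

    ``masks`` maps patient id -> binary WMH mask; all masks must share
    one grid (no registration is attempted — mismatching grids raise).
    """
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ValueError(f"WMH masks are on differing grids: {sorted(shapes)}")
    out: dict[int, np.ndarray] = {}
    for sub in sorted(assignment.labels.unique()):
        pids = assignment.labels[assignment.labels == sub].index
        stack = [np.asarray(masks[p], dtype=float) for p in pids if p in masks]
        if stack:
            out[int(sub)] = np.mean(stack, axis=0)
    return out


def render_outputs(
    tree: ClusterTree,
    assignment: SubgroupAssignment,
    matrix: pd.DataFrame,
    out_dir,
    wmh_masks: dict[str, np.ndarray] | None = None,
    spacing: tuple[float, float, float] = (0.9, 0.9, 4.0),
) -> dict[str, str]:
    """Write dendrogram, heatmap (+TSV) and WMH frequency volumes.

    The heatmap shows patients in dendrogram leaf order on a diverging
    scale centered at 0.  Returns the paths written.
    """
    import warnings
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    fig, ax = plt.subplots(figsize=(10, 4))
    hierarchy.dendrogram(tree.linkage, ax=ax, no_labels=True, color_threshold=0)
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    paths["dendrogram"] = str(out_dir / "dendrogram.png")
    fig.savefig(paths["dendrogram"], dpi=120)
    plt.close(fig)

    hm = heatmap_data(matrix, tree)
    lim = float(np.nanmax(np.abs(hm.to_numpy()))) or 1.0
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(hm.to_numpy(), aspect="auto", cmap="RdBu", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(hm.columns)))
    ax.set_xticklabels(hm.columns, rotation=90, fontsize=5)
    ax.set_ylabel("patients (dendrogram leaf order)")
    fig.colorbar(im, ax=ax, label="normalized value")
    fig.tight_layout()
    paths["heatmap"] = str(out_dir / "heatmap.png")
    fig.savefig(paths["heatmap"], dpi=120)
    plt.close(fig)
    paths["heatmap_tsv"] = str(out_dir / "heatmap.tsv")
    hm.to_csv(paths["heatmap_tsv"], sep="\t")

    if wmh_masks:
        try:
            freq = wmh_frequency_maps(wmh_masks, assignment)
        except ValueError as exc:
            warnings.warn(f"skipping WMH frequency maps: {exc}", stacklevel=2)
        else:
            affine = np.diag([*spacing, 1.0])
            for sub, vol in freq.items():
                p = out_dir / f"wmh_frequency_subgroup{sub:02d}.nii"
                nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(p))
                paths[f"frequency_subgroup_{sub}"] = str(p)
    return paths
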