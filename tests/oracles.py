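"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive loops, grid searches,
closed forms) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# connected components: breadth-first flood fill under 26-connectivity


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= wi < si for wi, si in zip(w, mask.shape)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# box counting: reshape-free nested loops over the box grid


def exact_box_counts(mask: np.ndarray, eps: int) -> int:
    idx = np.argwhere(np.asarray(mask, dtype=bool))
    idx = idx - idx.min(axis=0)
    occupied = set()
    for voxel in idx:
        occupied.add((voxel[0] // eps, voxel[1] // eps, voxel[2] // eps))
    return len(occupied)


# ---------------------------------------------------------------------------
# greedy Ward agglomeration evaluating every candidate pair at every step


def ward_merge_sequence(x: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Exhaustive greedy Ward (ward.D2 heights on the distance scale)."""
    clusters: list[tuple[frozenset, np.ndarray, int]] = [
        (frozenset([i]), x[i].astype(float), 1) for i in range(len(x))
    ]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                si, ci, ni = clusters[i]
                sj, cj, nj = clusters[j]
                d = np.sqrt(2.0 * ni * nj / (ni + nj)) * np.linalg.norm(ci - cj)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        si, ci, ni = clusters[i]
        sj, cj, nj = clusters[j]
        merged = (si | sj, (ni * ci + nj * cj) / (ni + nj), ni + nj)
        merges.append((si, sj, float(d)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def linkage_merge_sequence(z: np.ndarray, n: int) -> list[tuple[frozenset, frozenset, float]]:
    """Convert a scipy linkage matrix into (set_a, set_b, height) steps."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, h, _size) in enumerate(z):
        sa, sb = members[int(a)], members[int(b)]
        out.append((sa, sb, float(h)))
        members[n + step] = sa | sb
    return out


# ---------------------------------------------------------------------------
# validity indices from raw pairwise distances


def silhouette_oracle(x: np.ndarray, labels: np.ndarray) -> float:
    n = len(x)
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def dunn_oracle(x: np.ndarray, labels: np.ndarray) -> float:
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    labs = sorted(set(labels))
    inter = min(
        d[i, j]
        for a, b in itertools.combinations(labs, 2)
        for i in np.where(labels == a)[0]
        for j in np.where(labels == b)[0]
    )
    diam = max(
        (
            d[i, j]
            for lab in labs
            for i, j in itertools.combinations(np.where(labels == lab)[0], 2)
        ),
        default=0.0,
    )
    return inter / diam if diam > 0 else float("inf")


# ---------------------------------------------------------------------------
# least squares by normal equations (ANCOVA fixture oracle)


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss = float(((y - X @ beta) ** 2).sum())
    return beta, rss


def ancova_f_oracle(y, groups, age):
    """Partial F for the group block, solved from scratch."""
    groups = np.asarray(groups)
    uniq = sorted(set(groups))
    n = len(y)
    dummies = np.column_stack([(groups == g).astype(float) for g in uniq[1:]])
    X_full = np.column_stack([np.ones(n), dummies, age])
    X_null = np.column_stack([np.ones(n), age])
    _, rss_full = ols_normal_equations(X_full, y)
    _, rss_null = ols_normal_equations(X_null, y)
    q = dummies.shape[1]
    dof = n - X_full.shape[1]
    return ((rss_null - rss_full) / q) / (rss_full / dof), q, dof


# ---------------------------------------------------------------------------
# Cox partial likelihood (no ties) and its grid-search maximizer


def cox_neg_log_partial_likelihood(beta: float, time, event, x) -> float:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return -ll


def cox_grid_mle(time, event, x, lo=-4.0, hi=4.0, step=1e-3) -> float:
    grid = np.arange(lo, hi + step, step)
    vals = [cox_neg_log_partial_likelihood(b, time, event, x) for b in grid]
    best = grid[int(np.argmin(vals))]
    # refine around the coarse optimum to 1e-5
    fine = np.arange(best - 2 * step, best + 2 * step, 1e-5)
    vals = [cox_neg_log_partial_likelihood(b, time, event, x) for b in fine]
    return float(fine[int(np.argmin(vals))])


def cox_score_test_statistic(time, event, x) -> float:
    """Score test at beta=0 (equals the log-rank statistic without ties)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    u = 0.0
    info = 0.0
    for i in np.where(event == 1)[0]:
        risk = x[time >= time[i]]
        u += x[i] - risk.mean()
        info += risk.var()
    return u * u / info


# ---------------------------------------------------------------------------
# multinomial logistic: saturated closed form for a binary predictor


def multinomial_or_oracle(feature, labels, reference):
    """OR_g = odds(feature=1 | g) / odds(feature=1 | reference)."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)

    def odds(g):
        f = feature[labels == g]
        p = f.mean()
        return p / (1 - p)

    return {
        g: odds(g) / odds(reference) for g in sorted(set(labels)) if g != reference
    }
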