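"""Pseudotime ordering and condition comparison along the trajectory.

Cells from all conditions are embedded jointly (a common trajectory): PCA
on highly variable genes, a minimum-spanning path through cluster centroids
rooted at the MG cluster, orthogonal projection of cells onto that
piecewise-linear path, then principal-curve-style refinement. Downstream,
per-gene expression is averaged in 50 equal-width pseudotime bins per
condition; the per-bin condition difference is smoothed, scaled so its
extreme bin is +/-1, and assigned a permutation p-value on the max-|delta|
statistic. Delta-profile shapes are grouped by k-means (the study's eleven
expression patterns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from mgregen.preprocess import ExpressionMatrix, select_hvg

__all__ = [
    "TrajectoryParams",
    "PseudotimeAssignment",
    "BinnedExpression",
    "DeltaProfile",
    "fit_pseudotime",
    "condition_density",
    "bin_and_delta",
    "cluster_profiles",
]


@dataclass(frozen=True)
class TrajectoryParams:
    n_hvg: int = 2000
    n_pcs: int = 30
    root_cluster: str = "MG"
    n_bins: int = 50
    smoothing_span: float = 0.1
    min_bin_cells: int = 5  # evidence floor for a smoothed bin mean
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if not 0 <= self.smoothing_span <= 1:
            raise ValueError("smoothing_span must be in [0,1]")


@dataclass
class PseudotimeAssignment:
    t: np.ndarray  # per-cell, in [0,1]
    cluster: np.ndarray
    path: list[str]  # ordered cluster labels, root first
    cell_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "t": self.t, "cluster": self.cluster}
        )


def _project_onto_polyline(points: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's orthogonal projection onto the
    piecewise-linear path through ``nodes``."""
    seg_vec = np.diff(nodes, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    for i, (a, v, L) in enumerate(zip(nodes[:-1], seg_vec, seg_len)):
        if L == 0:
            proj = np.zeros(len(points))
        else:
            proj = np.clip((points - a) @ v / (L * L), 0.0, 1.0)
        closest = a + proj[:, None] * v
        d = np.linalg.norm(points - closest, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_s[upd] = cum[i] + proj[upd] * L
    total = cum[-1]
    return best_s / total if total > 0 else best_s


def _path_from_root(centroids: np.ndarray, labels: list[str], root: str) -> list[str]:
    """Order clusters along the minimum-spanning path from the root.

    Builds the MST of the complete centroid distance graph, walks from the
    root to its farthest node; clusters off that walk are stranded (error).
    """
    d = cdist(centroids, centroids)
    mst = minimum_spanning_tree(d).toarray()
    adj = (mst > 0) | (mst.T > 0)
    idx = {lab: i for i, lab in enumerate(labels)}
    start = idx[root]
    # BFS farthest walk from root
    order = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [j for j in np.flatnonzero(adj[cur]) if j not in visited]
        if not nxt:
            break
        # continue toward the nearest unvisited neighbor (path expected)
        cur = min(nxt, key=lambda j: d[order[-1], j])
        order.append(cur)
        visited.add(cur)
    if len(order) < len(labels):
        stranded = [labels[i] for i in range(len(labels)) if i not in visited]
        raise ValueError(f"clusters not connected to the root path: {stranded}")
    return [labels[i] for i in order]


def fit_pseudotime(
    norm: ExpressionMatrix,
    cluster_labels: np.ndarray | list[str],
    params: TrajectoryParams | None = None,
) -> PseudotimeAssignment:
    """Order cells along a single MG-rooted lineage in PC space.

    PCA on HVGs -> minimum-spanning path through cluster centroids from the
    root -> orthogonal projection onto the path -> iterative principal-curve
    smoothing (stop when the mean assignment change < 1e-3 or after 50
    iterations). Pseudotime is min-max rescaled to [0,1] with the root
    cluster at the low end.
    """
    params = params or TrajectoryParams()
    clusters = np.asarray(cluster_labels)
    if clusters.size != norm.n_cells:
        raise ValueError("cluster_labels length must match number of cells")
    labels = sorted(set(clusters.tolist()))
    if params.root_cluster not in labels:
        raise ValueError(f"root cluster {params.root_cluster!r} absent from labels")
    hvgs = select_hvg(norm, min(params.n_hvg, norm.n_genes))
    sub = norm.values[norm.gene_index(hvgs), :].T  # cells x genes
    n_pcs = min(params.n_pcs, min(sub.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=params.seed).fit_transform(
        sub - sub.mean(axis=0)
    )
    centroids = np.stack([pcs[clusters == lab].mean(axis=0) for lab in labels])
    path = _path_from_root(centroids, labels, params.root_cluster)
    nodes = np.stack([centroids[labels.index(lab)] for lab in path])
    t = _project_onto_polyline(pcs, nodes)

    # principal-curve refinement: smooth the curve through cells ordered by
    # t, rebuild the polyline, re-project. Ties in t broken by cell id so
    # the result is invariant to cell order.
    n = len(t)
    window = max(11, int(round(0.05 * n)) | 1)  # odd, so smoothing is
    # symmetric and root-reversal mirrors the curve exactly
    cell_ids = np.asarray(norm.cell_ids)
    for _ in range(50):
        order = np.lexsort((cell_ids, t))
        smoothed = uniform_filter1d(pcs[order], size=window, axis=0, mode="nearest")
        n_nodes = min(100, n)
        node_idx = np.linspace(0, n - 1, n_nodes).round().astype(int)
        new_nodes = smoothed[node_idx]
        t_new = _project_onto_polyline(pcs, new_nodes)
        delta = np.mean(np.abs(t_new - t))
        t = t_new
        if delta < 1e-3:
            break
    rng_t = t.max() - t.min()
    t = (t - t.min()) / rng_t if rng_t > 0 else np.zeros_like(t)
    # orient with the root cluster at the low end
    if t[clusters == params.root_cluster].mean() > t.mean():
        t = 1.0 - t
    return PseudotimeAssignment(t=t, cluster=clusters, path=path,
                                cell_ids=list(norm.cell_ids))


@dataclass
class ConditionDensity:
    grid: np.ndarray
    density: dict[str, np.ndarray]
    log_ratio: np.ndarray  # log(density[cond_b] / density[cond_a])
    cond_a: str
    cond_b: str


def condition_density(
    pt: PseudotimeAssignment,
    condition_labels: np.ndarray | list[str],
    cond_a: str,
    cond_b: str,
    grid_size: int = 256,
) -> ConditionDensity:
    """Kernel density of cells along pseudotime, per condition.

    Each density is renormalized to integrate to 1 over [0,1] (trapezoid
    rule); the returned log-ratio is log(density_b / density_a) pointwise.
    """
    cond = np.asarray(condition_labels)
    grid = np.linspace(0.0, 1.0, grid_size)
    density: dict[str, np.ndarray] = {}
    for c in (cond_a, cond_b):
        tc = pt.t[cond == c]
        if tc.size < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 cells")
        kde = stats.gaussian_kde(tc)
        d = kde(grid)
        d = d / np.trapezoid(d, grid)
        density[c] = d
    eps = np.finfo(float).tiny
    log_ratio = np.log(density[cond_b] + eps) - np.log(density[cond_a] + eps)
    return ConditionDensity(grid, density, log_ratio, cond_a, cond_b)


@dataclass
class BinnedExpression:
    means: dict[str, np.ndarray]  # condition -> (n_genes, n_bins)
    bin_edges: np.ndarray  # length n_bins + 1
    gene_ids: list[str]


@dataclass
class DeltaProfile:
    """Smoothed, max-|delta|-normalized condition difference per gene/bin.

    delta > 0 means higher expression in the second (e.g. knockout)
    condition; the extreme bin of any gene with a nonzero raw difference is
    +/-1. ``norm_factor`` is the max |smoothed delta| used for scaling (0
    for flat genes, whose profile is left at 0).
    """

    delta: np.ndarray  # (n_genes, n_bins), in [-1, 1]
    p: np.ndarray  # per-gene permutation p
    norm_factor: np.ndarray
    gene_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.delta, index=self.gene_ids,
            columns=[f"bin{i:02d}" for i in range(self.delta.shape[1])],
        )
        df.insert(0, "p", self.p)
        return df


def _bin_means(
    values: np.ndarray, bin_of: np.ndarray, mask: np.ndarray, n_bins: int
) -> np.ndarray:
    """Per-gene per-bin means over cells in ``mask``; empty bins linearly
    interpolated (endpoints carried from the nearest nonempty bin)."""
    n_genes = values.shape[0]
    b = bin_of[mask]
    v = values[:, mask]
    counts = np.bincount(b, minlength=n_bins).astype(float)
    sums_t = np.zeros((n_bins, n_genes))
    np.add.at(sums_t, b, v.T)
    sums = sums_t.T
    nonempty = counts > 0
    means = np.full((n_genes, n_bins), np.nan)
    means[:, nonempty] = sums[:, nonempty] / counts[nonempty]
    if not nonempty.all():
        x = np.flatnonzero(nonempty)
        xi = np.flatnonzero(~nonempty)
        for g in range(n_genes):
            means[g, xi] = np.interp(xi, x, means[g, x])
    return means


def _smoothed_means(
    values: np.ndarray, bin_of: np.ndarray, mask: np.ndarray,
    n_bins: int, window: int, min_cells: int,
) -> np.ndarray:
    """Count-weighted running-mean bin profile per gene.

    The running mean pools bin sums and bin cell counts over the smoothing
    window, so sparsely populated bins (trajectory ends) contribute in
    proportion to their evidence instead of entering with full weight.
    Windows pooling fewer than ``min_cells`` cells carry no evidence for a
    mean and are NaN (interpolated, endpoints carried, by the caller).
    """
    b = bin_of[mask]
    v = values[:, mask]
    counts = np.bincount(b, minlength=n_bins).astype(float)
    sums_t = np.zeros((n_bins, values.shape[0]))
    np.add.at(sums_t, b, v.T)
    ssum = uniform_filter1d(sums_t.T, size=window, axis=1, mode="nearest")
    scnt = uniform_filter1d(counts, size=window, mode="nearest")
    pooled = scnt * window  # cells contributing to each window
    bad = (scnt == 0) | (pooled < min(min_cells, mask.sum()))
    return ssum / np.where(bad, np.nan, scnt)


def _smoothed_delta(
    values: np.ndarray, bin_of: np.ndarray, cond: np.ndarray,
    cond_a: str, cond_b: str, n_bins: int, window: int, min_cells: int = 5,
) -> np.ndarray:
    raw = (_smoothed_means(values, bin_of, cond == cond_b, n_bins, window,
                           min_cells)
           - _smoothed_means(values, bin_of, cond == cond_a, n_bins, window,
                             min_cells))
    if np.isnan(raw).any():
        if np.isnan(raw[0]).all():
            raise ValueError(
                "no pseudotime window holds enough cells in both conditions"
            )
        for g in range(raw.shape[0]):
            bad = np.isnan(raw[g])
            if bad.any():
                x = np.flatnonzero(~bad)
                raw[g, bad] = np.interp(np.flatnonzero(bad), x, raw[g, x])
    return raw


def bin_and_delta(
    norm: ExpressionMatrix,
    pt: PseudotimeAssignment,
    condition_labels: np.ndarray | list[str],
    params: TrajectoryParams | None = None,
    cond_a: str | None = None,
    cond_b: str | None = None,
) -> tuple[BinnedExpression, DeltaProfile]:
    """Bin expression along pseudotime and contrast two conditions.

    Equal-width bins on [0,1]; per-bin per-condition gene means (empty bins
    interpolated); delta = cond_b - cond_a, smoothed by a count-weighted
    running mean over span*n_bins bins, then scaled per gene by its max
    |smoothed delta| so the extreme bin is +/-1. Per-gene significance is a
    permutation test of condition labels using max |smoothed delta| as the
    statistic.
    """
    params = params or TrajectoryParams()
    cond = np.asarray(condition_labels)
    if cond.size != norm.n_cells:
        raise ValueError("condition_labels length must match number of cells")
    uniq = sorted(set(cond.tolist()))
    if cond_a is None or cond_b is None:
        if len(uniq) != 2:
            raise ValueError("specify cond_a/cond_b when more than two conditions")
        cond_a, cond_b = uniq
    n_bins = params.n_bins
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_of = np.clip(np.digitize(pt.t, edges[1:-1]), 0, n_bins - 1)
    for c in (cond_a, cond_b):
        occupied = np.unique(bin_of[cond == c]).size
        if occupied < n_bins / 2:
            raise ValueError(
                f"condition {c!r} present in only {occupied}/{n_bins} bins"
            )
    window = max(1, int(round(params.smoothing_span * n_bins)))
    ma = _bin_means(norm.values, bin_of, cond == cond_a, n_bins)
    mb = _bin_means(norm.values, bin_of, cond == cond_b, n_bins)
    smoothed = _smoothed_delta(norm.values, bin_of, cond, cond_a, cond_b,
                               n_bins, window, params.min_bin_cells)
    factor = np.abs(smoothed).max(axis=1)
    delta = np.zeros_like(smoothed)
    nz = factor > 0
    delta[nz] = smoothed[nz] / factor[nz, None]
    obs_stat = factor
    rng = np.random.default_rng(params.seed)
    exceed = np.zeros(norm.n_genes)
    for _ in range(params.n_permutations):
        perm = rng.permutation(cond)
        stat = np.abs(
            _smoothed_delta(norm.values, bin_of, perm, cond_a, cond_b,
                            n_bins, window, params.min_bin_cells)
        ).max(axis=1)
        exceed += stat >= obs_stat
    p = (1.0 + exceed) / (1.0 + params.n_permutations)
    binned = BinnedExpression({cond_a: ma, cond_b: mb}, edges, list(norm.gene_ids))
    profile = DeltaProfile(delta, p, factor, list(norm.gene_ids))
    return binned, profile


def cluster_profiles(
    profiles: np.ndarray | pd.DataFrame, k: int = 11, seed: int = 0
) -> np.ndarray:
    """k-means pattern labels for per-gene bin profiles.

    Profiles are z-scored per gene (flat genes left at zero); 10 restarts,
    best inertia kept; labels renumbered by descending cluster size.
    """
    X = np.asarray(profiles, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of genes")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1, sd), 0.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]
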