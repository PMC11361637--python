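"""Quality control, normalization, variable-gene selection and marker tests.

Counts are stored gene-by-cell. QC removes low-complexity cells first
(fewer than 200 detected genes or fewer than 1000 UMIs by default), then
genes detected in fewer than three surviving cells. Marker/DEG calling is a
Wilcoxon rank-sum test on log-normalized expression with log2 fold-change
and detection-fraction (min.pct) pre-filters, mirroring the findMarkers /
findAllMarkers conventions used in single-cell toolkits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "QCParams",
    "DEGParams",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "rank_sum_markers",
]


@dataclass
class CountMatrix:
    """Integer gene-by-cell expression matrix with identifiers."""

    values: np.ndarray  # (n_genes, n_cells) nonnegative integers
    gene_ids: list[str]
    cell_ids: list[str]
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ExpressionMatrix:
    """Real-valued gene-by-cell matrix (e.g. log-normalized expression)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match identifier lists")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class QCParams:
    min_genes_per_cell: int = 200
    min_umis_per_cell: int = 1000
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        for name in ("min_genes_per_cell", "min_umis_per_cell", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DEGParams:
    """Thresholds for marker / differential-expression calling.

    Three presets reproduce the study's printed settings: condition DEGs
    (log2fc > 0.2, min.pct 0.05, raw p < 0.05), cell-type markers
    (log2fc > 0.5, min.pct 0.05, adjusted p < 0.05) and timepoint DEGs
    (log2fc > 0.25, i.e. fold change > 1.18, adjusted p < 0.05).
    """

    logfc_threshold: float = 0.25
    min_pct: float = 0.05
    alpha: float = 0.05
    adjust: str = "BH"  # "none" or "BH"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must be in [0,1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")

    @classmethod
    def condition_degs(cls) -> "DEGParams":
        return cls(logfc_threshold=0.2, min_pct=0.05, alpha=0.05, adjust="none")

    @classmethod
    def cell_type_markers(cls) -> "DEGParams":
        return cls(logfc_threshold=0.5, min_pct=0.05, alpha=0.05, adjust="BH")

    @classmethod
    def timepoint_degs(cls) -> "DEGParams":
        return cls(logfc_threshold=0.25, min_pct=0.05, alpha=0.05, adjust="BH")


def qc_filter(counts: CountMatrix, params: QCParams | None = None) -> CountMatrix:
    """Remove low-quality cells, then rarely detected genes.

    Cells with fewer than ``min_genes_per_cell`` detected genes OR fewer
    than ``min_umis_per_cell`` total UMIs are dropped first; genes detected
    in fewer than ``min_cells_per_gene`` of the *surviving* cells are
    dropped second. The two-pass order is fixed.
    """
    params = params or QCParams()
    v = counts.values
    if v.size == 0:
        return CountMatrix(v.copy(), counts.gene_ids, counts.cell_ids)
    detected_per_cell = (v > 0).sum(axis=0)
    umis_per_cell = v.sum(axis=0)
    keep_cells = (detected_per_cell >= params.min_genes_per_cell) & (
        umis_per_cell >= params.min_umis_per_cell
    )
    v2 = v[:, keep_cells]
    cells = [c for c, k in zip(counts.cell_ids, keep_cells) if k]
    warn: list[str] = []
    if not cells:
        warn.append("qc_filter removed every cell")
        warnings.warn(warn[-1], stacklevel=2)
        out = CountMatrix(np.zeros((0, 0), dtype=v.dtype), [], [])
        out.warnings_ = warn
        return out
    cells_detecting = (v2 > 0).sum(axis=1)
    keep_genes = cells_detecting >= params.min_cells_per_gene
    genes = [g for g, k in zip(counts.gene_ids, keep_genes) if k]
    out = CountMatrix(v2[keep_genes], genes, cells)
    out.warnings_ = warn
    return out


def normalize_log(counts: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and log-transform: log(1 + scale*count/total)."""
    totals = counts.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts (run qc_filter first): "
            f"{[counts.cell_ids[i] for i in zero[:5]]}"
        )
    vals = np.log1p(scale * counts.values / totals)
    return ExpressionMatrix(vals, counts.gene_ids, counts.cell_ids)


def select_hvg(norm: ExpressionMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned normalized dispersion.

    Genes are placed into equal-frequency bins of mean log-normalized
    expression; within each bin the variance is z-scored and genes are
    ranked by that score (descending), ties broken by gene id.
    """
    if n > norm.n_genes:
        raise ValueError(f"requested {n} HVGs but matrix has {norm.n_genes} genes")
    means = norm.values.mean(axis=1)
    variances = norm.values.var(axis=1)
    # need several genes per bin for a meaningful within-bin z-score
    n_bins = max(1, min(n_bins, norm.n_genes // 10))
    # equal-frequency bins on the mean; rank-based to be robust to ties
    order = np.argsort(means, kind="stable")
    bin_of = np.empty(norm.n_genes, dtype=int)
    bin_of[order] = (np.arange(norm.n_genes) * n_bins) // norm.n_genes
    z = np.zeros(norm.n_genes)
    for b in range(n_bins):
        idx = np.flatnonzero(bin_of == b)
        if idx.size == 0:
            continue
        v = variances[idx]
        sd = v.std()
        z[idx] = (v - v.mean()) / sd if sd > 0 else 0.0
    ranking = sorted(range(norm.n_genes), key=lambda i: (-z[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in ranking[:n]]


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the pooled sample is small (n <= 25) and tie-free;
    otherwise the tie-corrected normal approximation.
    """
    n_tot = x.size + y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < n_tot
    method = "exact" if (n_tot <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.pvalue)


def rank_sum_markers(
    norm: ExpressionMatrix,
    group_labels: np.ndarray | list[str],
    params: DEGParams,
    groups: list[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Marker/DEG table for each focal group versus the rest (or a reference).

    Per gene: log2 fold change of pseudocounted means of expm1(normalized)
    expression, detection fractions pct_in / pct_out, and a two-sided
    Wilcoxon rank-sum p for genes passing the |log2fc| and min.pct
    pre-filters. Rows failing the alpha criterion are flagged via the
    ``passed`` column, not dropped.
    """
    labels = np.asarray(group_labels)
    if labels.size != norm.n_cells:
        raise ValueError("group_labels length must match number of cells")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    focal = groups if groups is not None else (uniq if reference is None else
                                               [g for g in uniq if g != reference])
    expr = np.expm1(norm.values)
    rows = []
    for g in focal:
        in_mask = labels == g
        out_mask = (labels == reference) if reference is not None else ~in_mask
        if in_mask.sum() < 2 or out_mask.sum() < 2:
            raise ValueError(f"group {g!r} comparison has a side with <2 cells")
        mean_in = expr[:, in_mask].mean(axis=1)
        mean_out = expr[:, out_mask].mean(axis=1)
        log2fc = np.log2(mean_in + params.pseudocount) - np.log2(
            mean_out + params.pseudocount
        )
        pct_in = (norm.values[:, in_mask] > 0).mean(axis=1)
        pct_out = (norm.values[:, out_mask] > 0).mean(axis=1)
        tested = (np.abs(log2fc) >= params.logfc_threshold) & (
            np.maximum(pct_in, pct_out) >= params.min_pct
        )
        pvals = np.full(norm.n_genes, np.nan)
        for i in np.flatnonzero(tested):
            pvals[i] = _rank_sum_p(norm.values[i, in_mask], norm.values[i, out_mask])
        p_adj = np.full(norm.n_genes, np.nan)
        t_idx = np.flatnonzero(tested)
        if t_idx.size:
            if params.adjust == "BH":
                p_adj[t_idx] = multipletests(pvals[t_idx], method="fdr_bh")[1]
            else:
                p_adj[t_idx] = pvals[t_idx]
        crit = p_adj if params.adjust == "BH" else pvals
        for i in t_idx:
            rows.append(
                dict(gene=norm.gene_ids[i], group=g, log2fc=log2fc[i],
                     pct_in=pct_in[i], pct_out=pct_out[i], p=pvals[i],
                     p_adj=p_adj[i], passed=bool(crit[i] < params.alpha))
            )
    cols = ["gene", "group", "log2fc", "pct_in", "pct_out", "p", "p_adj", "passed"]
    return pd.DataFrame(rows, columns=cols)
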