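"""Signed gene-regulatory-network construction.

The pipeline follows the tree-ensemble importance family (GENIE3 /
GRNBoost2): each gene is regressed on all TF expressions with an
extremely-randomized-trees ensemble (fully grown, sqrt feature sampling)
and the per-TF impurity-reduction importances (normalized to sum to 1 per
target) score candidate TF->target edges. Edges are then filtered to
the top tail of the pooled importance distribution (95th quantile by
default), annotated positive/negative by Pearson correlation with a strict
+/-0.03 rule (anything in between is discarded), and finally restricted to
TFs detected in the retinal-progenitor (RPC) cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.metrics import auc, precision_recall_curve

from mgregen.preprocess import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GRNParams",
    "ImportanceMatrix",
    "infer_importance",
    "filter_importance_quantile",
    "annotate_edge_sign",
    "filter_tf_expressed",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class GRNParams:
    n_trees: int = 100
    min_samples_leaf: int = 1  # fully grown trees, the GENIE3 convention
    candidate_features: str | int = "sqrt"  # "sqrt", "all", or a fixed count
    importance_quantile: float = 0.95
    cor_threshold: float = 0.03
    expression_cluster: str = "progenitor"
    min_expr_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.importance_quantile < 1:
            raise ValueError("importance_quantile must be in (0,1)")
        if self.cor_threshold <= 0:
            raise ValueError("cor_threshold must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ImportanceMatrix:
    """Per (TF, target) importance scores; self-pairs are excluded (NaN)."""

    values: pd.DataFrame  # rows: TFs, columns: targets

    @property
    def tf_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.columns)

    def pooled(self) -> pd.Series:
        """All defined (tf, target) scores as a (tf, target)-indexed series."""
        s = self.values.stack()
        s.index.names = ["tf", "target"]
        return s


def _max_features(spec: str | int, n_tfs: int) -> int | float:
    if spec == "sqrt":
        return max(1, int(np.sqrt(n_tfs)))
    if spec == "all":
        return n_tfs
    return int(spec)


def infer_importance(
    expr: ExpressionMatrix, tf_list: list[str], params: GRNParams | None = None
) -> ImportanceMatrix:
    """Tree-ensemble importance score for every TF->target pair.

    For each target gene, a random-forest regression predicts its expression
    from all TF expressions (excluding the target itself when it is a TF);
    importance is the impurity (variance) reduction attributed to each TF,
    normalized per target to sum to 1. Deterministic given the seed.
    """
    params = params or GRNParams()
    if not tf_list:
        raise ValueError("tf_list is empty")
    if expr.n_cells < 20:
        raise ValueError("need at least 20 cells for importance inference")
    tf_idx = expr.gene_index(list(tf_list))  # raises naming missing TFs
    X_all = expr.values[tf_idx, :].T  # cells x TFs
    tf_set = set(tf_list)
    n_tfs = len(tf_list)
    mf = _max_features(params.candidate_features, n_tfs)
    out = pd.DataFrame(np.nan, index=list(tf_list), columns=list(expr.gene_ids))
    ss = np.random.SeedSequence(params.seed)
    child_seeds = ss.generate_state(expr.n_genes) % (2**31 - 1)
    for gi, gene in enumerate(expr.gene_ids):
        y = expr.values[gi, :]
        if gene in tf_set:
            cols = [j for j, t in enumerate(tf_list) if t != gene]
            if not cols:
                continue
            X = X_all[:, cols]
            names = [tf_list[j] for j in cols]
            mf_g = min(mf, len(cols)) if isinstance(mf, int) else mf
        else:
            X, names, mf_g = X_all, list(tf_list), mf
        model = ExtraTreesRegressor(
            n_estimators=params.n_trees,
            max_features=mf_g,
            min_samples_leaf=params.min_samples_leaf,
            random_state=int(child_seeds[gi]),
            n_jobs=1,
        )
        model.fit(X, y)
        out.loc[names, gene] = model.feature_importances_
    return ImportanceMatrix(out)


def filter_importance_quantile(
    imp: ImportanceMatrix, q: float = 0.95
) -> pd.DataFrame:
    """Keep (tf, target) pairs at or above the pooled importance quantile.

    The quantile is computed over ALL defined pair scores pooled (linear
    interpolation between order statistics); pairs with importance >= the
    quantile are retained.
    """
    pooled = imp.pooled().dropna()
    if pooled.empty:
        raise ValueError("importance matrix is empty")
    threshold = float(np.quantile(pooled.to_numpy(), q, method="linear"))
    kept = pooled[pooled >= threshold]
    df = kept.reset_index()
    df.columns = ["tf", "target", "importance"]
    return df.sort_values("importance", ascending=False, ignore_index=True)


def annotate_edge_sign(
    edges: pd.DataFrame,
    expr: ExpressionMatrix,
    cor_threshold: float = 0.03,
) -> pd.DataFrame:
    """Annotate edges positive/negative by Pearson correlation.

    Strict rule: cor > threshold -> positive, cor < -threshold -> negative,
    anything else (including undefined correlations from zero-variance
    genes) is discarded. Discard counts go to the run log and the returned
    frame's ``attrs``.
    """
    genes = sorted(set(edges["tf"]) | set(edges["target"]))
    gi = {g: i for g, i in zip(genes, expr.gene_index(genes))}
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    cors = np.empty(len(edges))
    for k, (tf, tg) in enumerate(zip(edges["tf"], edges["target"])):
        i, j = gi[tf], gi[tg]
        denom2 = ss[i] * ss[j]
        cors[k] = (
            np.nan if denom2 == 0
            else (centered[i] @ centered[j]) / np.sqrt(denom2)
        )
    out = edges.copy()
    out["cor"] = cors
    sign = np.where(cors > cor_threshold, "positive",
                    np.where(cors < -cor_threshold, "negative", "discard"))
    sign[np.isnan(cors)] = "discard"
    n_undefined = int(np.isnan(cors).sum())
    out["sign"] = sign
    kept = out[out["sign"] != "discard"].reset_index(drop=True)
    n_discarded = len(out) - len(kept)
    logger.info(
        "annotate_edge_sign: kept %d/%d edges (%d discarded, of which %d had "
        "undefined correlation)", len(kept), len(out), n_discarded, n_undefined
    )
    kept.attrs["n_discarded"] = n_discarded
    kept.attrs["n_undefined_cor"] = n_undefined
    return kept


def filter_tf_expressed(
    edges: pd.DataFrame,
    expr: ExpressionMatrix | CountMatrix,
    cluster_labels: np.ndarray | list[str],
    params: GRNParams | None = None,
) -> pd.DataFrame:
    """Drop edges of TFs not expressed in the progenitor (RPC) cluster.

    A TF counts as expressed if detected (value > 0) in at least
    ``min_expr_fraction`` of the cluster's cells.
    """
    params = params or GRNParams()
    labels = np.asarray(cluster_labels)
    mask = labels == params.expression_cluster
    if not mask.any():
        raise ValueError(
            f"cluster {params.expression_cluster!r} absent from labels"
        )
    tfs = sorted(set(edges["tf"]))
    if isinstance(expr, CountMatrix):
        lookup = {g: i for i, g in enumerate(expr.gene_ids)}
        idx = np.array([lookup[t] for t in tfs])
    else:
        idx = expr.gene_index(tfs)
    frac = (np.asarray(expr.values)[idx][:, mask] > 0).mean(axis=1)
    expressed = {t for t, f in zip(tfs, frac) if f >= params.min_expr_fraction}
    kept = edges[edges["tf"].isin(expressed)].reset_index(drop=True)
    logger.info(
        "filter_tf_expressed: %d/%d TFs expressed in %r; kept %d/%d edges",
        len(expressed), len(tfs), params.expression_cluster, len(kept), len(edges),
    )
    kept.attrs = dict(edges.attrs)
    kept.attrs["n_tfs_removed"] = len(tfs) - len(expressed)
    return kept


def evaluate_recovery(imp: ImportanceMatrix, network) -> dict[str, float]:
    """Planted-edge recovery metrics for a synthetic ground-truth network.

    Returns the area under the precision-recall curve over all scored
    TF -> non-TF pairs, the planted-edge density (the AUPR of a random
    ranking), and their ratio.
    """
    truth = network.edge_set()
    pooled = imp.pooled().dropna()
    tf_set = set(imp.tf_ids)
    mask = [tg not in tf_set for _, tg in pooled.index]
    pooled = pooled[mask]
    y = np.array([(tf, tg) in truth for tf, tg in pooled.index], dtype=int)
    prec, rec, _ = precision_recall_curve(y, pooled.to_numpy())
    aupr = float(auc(rec, prec))
    base = float(y.mean())
    return {"aupr": aupr, "baseline": base,
            "fold_over_baseline": aupr / base if base > 0 else np.inf}
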