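"""Progenitor fate-bias tallies and hypergeometric TF specificity scores.

Given condition DEGs in progenitors and marker gene sets for each retinal
cell type, the tally counts how many up- and down-regulated DEGs fall in
each lineage's marker set (which fates the knockout favors or diminishes).
Each TF's cell-type specificity is then the upper-tail hypergeometric
probability that its regulon overlaps a marker set as much as observed:
population N = |gene universe|, successes K = |marker set|, draws
n = |TF target set|, observed overlap k, p = P(X >= k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "LineageMarkerSets",
    "lineage_bias_tally",
    "tf_specificity",
    "hypergeom_upper_tail",
]


@dataclass
class LineageMarkerSets:
    """Cell-type marker gene sets plus the background gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("marker universe is empty")
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"marker set {name!r} is empty")
            if not s <= self.universe:
                raise ValueError(f"marker set {name!r} not contained in universe")

    @classmethod
    def from_marker_table(
        cls, markers: pd.DataFrame, universe: set[str]
    ) -> "LineageMarkerSets":
        """Build sets from a marker table with ``gene`` and ``group`` columns,
        keeping rows flagged ``passed`` with positive log2fc if present."""
        df = markers
        if "passed" in df.columns:
            df = df[df["passed"]]
        if "log2fc" in df.columns:
            df = df[df["log2fc"] > 0]
        sets = {
            g: set(sub["gene"]) & universe
            for g, sub in df.groupby("group")
            if len(set(sub["gene"]) & universe)
        }
        return cls(sets, universe)


def lineage_bias_tally(
    deg_table: pd.DataFrame, markers: LineageMarkerSets
) -> pd.DataFrame:
    """Count significant DEGs overlapping each lineage's markers, by direction.

    ``n_up`` counts DEGs with log2fc > 0 (higher in the knockout/second
    condition, i.e. fates the perturbation favors), ``n_down`` those with
    log2fc < 0. A gene in several marker sets counts in each.
    """
    df = deg_table
    if "passed" in df.columns:
        df = df[df["passed"]]
    up = set(df.loc[df["log2fc"] > 0, "gene"])
    down = set(df.loc[df["log2fc"] < 0, "gene"])
    rows = [
        {
            "cell_type": ct,
            "n_up": len(up & s),
            "n_down": len(down & s),
            "n_markers": len(s),
        }
        for ct, s in markers.sets.items()
    ]
    return pd.DataFrame(rows, columns=["cell_type", "n_up", "n_down", "n_markers"])


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) (the enrichment tail)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def tf_specificity(
    edges: pd.DataFrame,
    markers: LineageMarkerSets,
    adjust: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric specificity p for every (TF, cell type).

    Edge targets outside the marker universe are dropped (count logged). TFs
    left with no targets get p = 1 and ``flagged`` = True. No multiplicity
    adjustment by default; ``adjust=True`` adds BH-adjusted p across all
    (TF, cell type) rows.
    """
    N = len(markers.universe)
    targets_by_tf = {
        tf: set(sub["target"]) for tf, sub in edges.groupby("tf")
    }
    n_outside = sum(
        len(s - markers.universe) for s in targets_by_tf.values()
    )
    if n_outside:
        logger.info("tf_specificity: dropped %d targets outside universe",
                    n_outside)
    rows = []
    for tf, raw in sorted(targets_by_tf.items()):
        targets = raw & markers.universe
        flagged = len(targets) == 0
        for ct, mset in markers.sets.items():
            k = len(targets & mset)
            p = 1.0 if flagged else hypergeom_upper_tail(N, len(mset),
                                                         len(targets), k)
            rows.append(
                dict(tf=tf, cell_type=ct, n_targets=len(targets),
                     n_markers=len(mset), overlap=k, universe_size=N, p=p,
                     flagged=flagged)
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
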