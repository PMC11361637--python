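"""Plain-text readers/writers for the pipeline's tables and matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from mgregen.preprocess import CountMatrix

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_counts_csv",
    "read_counts_csv",
    "write_network_tsv",
    "read_marker_sets_tsv",
    "write_marker_sets_tsv",
]


def write_counts_mtx(counts: CountMatrix, prefix: str | Path) -> None:
    """Write MatrixMarket counts plus gene/cell TSVs (<prefix>.mtx/.genes.tsv/.cells.tsv)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.csr_matrix(counts.values))
    prefix.with_suffix(".genes.tsv").write_text(
        "\n".join(counts.gene_ids) + "\n")
    prefix.with_suffix(".cells.tsv").write_text(
        "\n".join(counts.cell_ids) + "\n")


def read_counts_mtx(prefix: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx")))
    genes = prefix.with_suffix(".genes.tsv").read_text().splitlines()
    cells = prefix.with_suffix(".cells.tsv").read_text().splitlines()
    values = np.asarray(sparse.csr_matrix(mat).todense())
    return CountMatrix(values.astype(np.int64), genes, cells)


def write_counts_csv(counts: CountMatrix, path: str | Path) -> None:
    """Dense gene-by-cell CSV, for small fixtures."""
    counts.to_frame().to_csv(path)


def read_counts_csv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(df.to_numpy().astype(np.int64),
                       list(df.index.astype(str)),
                       list(df.columns.astype(str)))


def write_network_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("tf", "target", "sign", "weight", "importance", "cor")
            if c in edges.columns]
    edges[cols].to_csv(path, sep="\t", index=False)


def write_marker_sets_tsv(sets: dict[str, set[str]], path: str | Path) -> None:
    rows = [(ct, g) for ct, genes in sorted(sets.items()) for g in sorted(genes)]
    pd.DataFrame(rows, columns=["cell_type", "gene"]).to_csv(
        path, sep="\t", index=False)


def read_marker_sets_tsv(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    return {ct: set(sub["gene"]) for ct, sub in df.groupby("cell_type")}
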