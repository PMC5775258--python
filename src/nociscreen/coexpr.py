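"""Threshold-based expression filtering and single-cell coexpression.

Single-cell RNA-seq FPKM matrices are binarized at a positivity threshold
(5 FPKM by default, inclusive) and summarized as per-gene prevalence
(percent of cells positive) and pairwise conditional coexpression fractions
(percent of gene-A-positive cells that are also gene-B-positive; asymmetric
by construction).  A coexpression network connects gene pairs whose mutual
conditional fraction clears an edge threshold.

The module consumes FPKM values as given; normalization from reads is
upstream and out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "DEFAULT_FPKM_THRESHOLD",
    "BinaryExpression",
    "load_matrix",
    "load_triplets",
    "validate_matrix",
    "binarize",
    "prevalence",
    "coexpression_fraction",
    "expressed_gene_set",
    "build_network",
    "write_network",
]

DEFAULT_FPKM_THRESHOLD = 5.0


@dataclass
class BinaryExpression:
    """Boolean positivity per (gene, cell) at a recorded FPKM threshold."""

    calls: pd.DataFrame  # genes x cells, bool
    threshold: float

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def cells(self) -> pd.Index:
        return self.calls.columns

    def positive_cells(self, gene: str) -> pd.Index:
        return self.calls.columns[self.calls.loc[gene].to_numpy()]


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an FPKM matrix: unique ids, no NaN, no negative values."""
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate cell/sample ids")
    if matrix.isna().to_numpy().any():
        raise ValueError("missing values are not allowed; impute upstream")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative FPKM values")
    return matrix


def load_matrix(path: str | Path) -> pd.DataFrame:
    """Load a dense genes-by-cells FPKM TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_matrix(df)


def load_triplets(path: str | Path) -> pd.DataFrame:
    """Load a sparse triplet file (gene, cell, FPKM) into a dense matrix.

    Unlisted (gene, cell) pairs are 0 FPKM.
    """
    trip = pd.read_csv(path, sep="\t", header=0)
    trip.columns = ["gene", "cell", "fpkm"]
    dense = trip.pivot_table(
        index="gene", columns="cell", values="fpkm", aggfunc="sum", fill_value=0.0
    )
    dense.index.name = None
    dense.columns.name = None
    return validate_matrix(dense)


def binarize(
    matrix: pd.DataFrame, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> BinaryExpression:
    """Positivity calls: FPKM >= threshold (inclusive boundary)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    validate_matrix(matrix)
    return BinaryExpression(calls=matrix >= threshold, threshold=threshold)


def prevalence(binary: BinaryExpression, gene: str) -> float:
    """Percent of cells positive for ``gene``."""
    if gene not in binary.genes:
        raise KeyError(f"unknown gene {gene!r}")
    calls = binary.calls.loc[gene].to_numpy()
    return 100.0 * calls.sum() / calls.size


def coexpression_fraction(
    binary: BinaryExpression, gene_a: str, gene_b: str
) -> float:
    """Percent of gene_a-positive cells that are also gene_b-positive.

    Conditional on the gene_a-positive population, hence asymmetric.
    Returns NaN (with a warning) when no cell is positive for gene_a.
    """
    for g in (gene_a, gene_b):
        if g not in binary.genes:
            raise KeyError(f"unknown gene {g!r}")
    a = binary.calls.loc[gene_a].to_numpy()
    b = binary.calls.loc[gene_b].to_numpy()
    n_a = a.sum()
    if n_a == 0:
        warnings.warn(
            f"no {gene_a}-positive cells; coexpression fraction undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return 100.0 * (a & b).sum() / n_a


def expressed_gene_set(
    matrix: pd.DataFrame,
    group_cells: Iterable[str],
    threshold: float = DEFAULT_FPKM_THRESHOLD,
) -> set[str]:
    """Genes whose mean FPKM over ``group_cells`` is >= threshold.

    This is the "highly expressed in the lineage" restriction fed to the
    substrate screen.
    """
    cells = list(group_cells)
    if not cells:
        raise ValueError("empty cell group")
    missing = set(cells) - set(matrix.columns)
    if missing:
        raise KeyError(f"unknown cells: {sorted(missing)}")
    means = matrix[cells].mean(axis=1)
    return set(means.index[means >= threshold])


def build_network(
    binary: BinaryExpression,
    gene_list: Sequence[str],
    edge_threshold: float,
) -> nx.Graph:
    """Coexpression graph over ``gene_list``.

    Edge (a, b) is present iff min(coexpr(a→b), coexpr(b→a)) / 100 >=
    ``edge_threshold``; the edge weight is that minimum on [0, 1].  The
    mutual-minimum rule is symmetric in gene order, and a gene with zero
    positive cells contributes no edges.
    """
    g = nx.Graph()
    g.add_nodes_from(gene_list)
    calls = {gene: binary.calls.loc[gene].to_numpy() for gene in gene_list}
    counts = {gene: calls[gene].sum() for gene in gene_list}
    for i, a in enumerate(gene_list):
        for b in gene_list[i + 1 :]:
            if counts[a] == 0 or counts[b] == 0:
                continue
            joint = (calls[a] & calls[b]).sum()
            mutual = min(joint / counts[a], joint / counts[b])
            if mutual >= edge_threshold:
                g.add_edge(a, b, weight=float(mutual))
    return g


def write_network(graph: nx.Graph, out_prefix: str | Path) -> None:
    """Write the network as edge-list TSV and GraphML."""
    prefix = Path(out_prefix)
    rows = [
        {"gene_a": a, "gene_b": b, "weight": d["weight"]}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        f"{prefix}_edges.tsv", sep="\t", index=False
    )
    nx.write_graphml(graph, f"{prefix}.graphml")
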