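"""Per-dataset Pearson co-expression networks and their consensus.

A co-expression network connects two genes when the absolute Pearson
correlation of their expression profiles reaches a hard threshold (default
0.6). Networks from several datasets are intersected: an edge survives only
if present in every input network, and its consensus weight is the mean of
the per-dataset absolute correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class WeightedGeneNetwork:
    """Undirected gene graph with edge weights in [0, 1].

    Edges are stored under lexicographically ordered gene pairs, so the
    network is symmetric by construction and self-loops are rejected.
    """

    genes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")
            if not (0.0 <= w <= 1.0 + 1e-12):
                raise ValueError(f"edge weight {w} for ({a},{b}) outside [0,1]")
            normalized[_edge_key(a, b)] = min(float(w), 1.0)
        self.edges = normalized
        self.genes = set(self.genes)
        for a, b in self.edges:
            self.genes.add(a)
            self.genes.add(b)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, a: str, b: str) -> float | None:
        return self.edges.get(_edge_key(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return _edge_key(a, b) in self.edges

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def isolated_genes(self) -> set[str]:
        """Genes carried as nodes but incident to no edge."""
        touched = {g for e in self.edges for g in e}
        return self.genes - touched

    def subgraph(self, genes) -> "WeightedGeneNetwork":
        keep = set(genes)
        edges = {e: w for e, w in self.edges.items() if e[0] in keep and e[1] in keep}
        return WeightedGeneNetwork(genes=keep & self.genes, edges=edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.genes))
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.edges.items())
        return g


def correlation_network(
    dataset: ExpressionDataset,
    threshold: float = 0.6,
    min_periods: int = 3,
    signed: bool = False,
) -> WeightedGeneNetwork:
    """Build the hard-thresholded Pearson co-expression network of a dataset.

    Correlations are computed on pairwise-complete observations (missing
    entries excluded per gene pair); pairs with fewer than ``min_periods``
    shared observations get no edge. By default the threshold applies to
    |r| and the edge weight is |r|; with ``signed=True`` only positive
    correlations ``r >= threshold`` form edges (weight still |r| = r).

    Constant (zero-variance) genes stay in the node set but cannot form
    edges; a warning reports them.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    values = dataset.values
    constant = values.index[values.std(axis=1, ddof=1).fillna(0.0) == 0.0]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant gene(s) excluded from edges: "
            f"{sorted(constant)[:5]}..."
        )
    corr = values.T.corr(min_periods=min_periods)
    r = corr.to_numpy(copy=True)
    np.fill_diagonal(r, np.nan)
    score = r if signed else np.abs(r)
    ii, jj = np.where(np.triu(score >= threshold, k=1))
    genes = corr.index
    edges = {
        _edge_key(genes[i], genes[j]): float(abs(r[i, j])) for i, j in zip(ii, jj)
    }
    return WeightedGeneNetwork(genes=set(dataset.genes), edges=edges)


def consensus_network(networks: list[WeightedGeneNetwork]) -> WeightedGeneNetwork:
    """Intersect co-expression networks into one consensus network.

    An edge is kept only if present in every input network; its consensus
    weight is the arithmetic mean of the per-network weights. The node set is
    the union of genes incident to kept edges plus all genes shared by every
    input network (isolated genes are reportable via ``isolated_genes``).
    """
    if not networks:
        raise ValueError("consensus of an empty network list is undefined")
    if len(networks) == 1:
        return networks[0]
    common_edges = set(networks[0].edges)
    for net in networks[1:]:
        common_edges &= set(net.edges)
    edges = {
        e: float(np.mean([net.edges[e] for net in networks])) for e in common_edges
    }
    shared_genes = set.intersection(*(net.genes for net in networks))
    return WeightedGeneNetwork(genes=shared_genes, edges=edges)


def write_edge_list_tsv(network: WeightedGeneNetwork, path) -> None:
    """Write edges as TSV (gene_a, gene_b, weight), lexicographically ordered
    for bit-stable output; isolated genes appear with an empty partner."""
    rows = [
        {"gene_a": a, "gene_b": b, "weight": w}
        for (a, b), w in sorted(network.edges.items())
    ]
    for g in sorted(network.isolated_genes()):
        rows.append({"gene_a": g, "gene_b": "", "weight": np.nan})
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list_tsv(path) -> WeightedGeneNetwork:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    genes: set[str] = set()
    edges: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        a = str(row["gene_a"])
        genes.add(a)
        if pd.notna(row["gene_b"]) and str(row["gene_b"]):
            b = str(row["gene_b"])
            genes.add(b)
            edges[_edge_key(a, b)] = float(row["weight"])
    return WeightedGeneNetwork(genes=genes, edges=edges)
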