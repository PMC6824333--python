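"""Prior-knowledge encoding: pathway membership + interaction-graph topology.

Each gene in the working universe is described by a fixed-length feature
vector: one z-scored binary membership indicator per curated gene set
(hallmark-like and kegg-like collections), followed by three log-scaled
topology features (degree, betweenness centrality, closeness centrality)
computed on the mechanistic/marker subgraph of a typed chemical-gene-disease
interaction graph. At the scale of 50 hallmark sets, 186 kegg-like pathways
and the three topology features this yields 239 dimensions per gene.

The feature matrix is reduced to two principal components and partitioned by
K-means (K=3); a gene's raw prior is its distance to its assigned centroid in
that plane (genes far from the dense core are the ones most enriched with
pathway and interaction annotations). Ranking the raw priors descending and
mapping rank r of n genes to (n - r + 1)/n yields the prior score P in (0, 1]
used for edge re-weighting: the top gene has P = 1 and the bottom approaches
0 as n grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

MECHANISTIC_MARKER = "mechanistic/marker"

NODE_TYPES = ("chemical", "gene", "disease")

TOPOLOGY_FEATURES = ("degree", "betweenness", "closeness")


@dataclass
class GeneSetCollection:
    """Named gene sets tagged by source family ('hallmark' or 'kegg')."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name in self.sets:
            self.families.setdefault(name, "kegg")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self, family: str | None = None) -> list[str]:
        if family is None:
            return list(self.sets)
        return [n for n in self.sets if self.families[n] == family]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


@dataclass
class InteractionGraph:
    """Typed chemical-gene-disease graph with association-class edge labels."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        self.graph.add_node((node_type, node_id), node_type=node_type, name=node_id)

    def add_edge(self, a: str, type_a: str, b: str, type_b: str,
                 association_class: str = MECHANISTIC_MARKER) -> None:
        self.add_node(a, type_a)
        self.add_node(b, type_b)
        self.graph.add_edge((type_a, a), (type_b, b), association_class=association_class)

    def mechanistic_subgraph(self) -> nx.Graph:
        """Subgraph keeping only mechanistic/marker associations (the only
        class relevant for toxicological scoring; 'therapeutic' edges drop)."""
        keep = [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d.get("association_class") == MECHANISTIC_MARKER
        ]
        sub = self.graph.edge_subgraph(keep).copy() if keep else nx.Graph()
        sub.add_nodes_from(
            (n, d) for n, d in self.graph.nodes(data=True) if n not in sub
        )
        return sub

    def gene_nodes(self) -> list[str]:
        return [name for (t, name) in self.graph.nodes if t == "gene"]


@dataclass
class PriorFeatureMatrix:
    """Genes x features matrix: z-scored memberships then log-scaled topology."""

    values: pd.DataFrame
    n_membership: int

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class PriorScoreTable:
    """Per-gene prior score P in (0, 1] and prior rank (1 = top)."""

    table: pd.DataFrame  # index gene, columns rank, score

    def score(self, gene: str) -> float:
        return float(self.table.at[gene, "score"])

    def scores(self) -> pd.Series:
        return self.table["score"]

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


def encode_features(
    collection: GeneSetCollection,
    graph: InteractionGraph,
    gene_universe,
    normalized_betweenness: bool = True,
) -> PriorFeatureMatrix:
    """Encode pathway membership and graph topology into per-gene features.

    Membership indicators (1/0 per gene set) are z-scored per feature across
    the gene universe; a constant membership column cannot be z-scored and is
    set to all-zero with a warning. Degree, betweenness centrality and
    closeness centrality are computed on the mechanistic/marker subgraph and
    transformed as log(1 + x); genes absent from the graph receive the
    transform of zero.
    """
    genes = list(dict.fromkeys(gene_universe))
    if not genes:
        raise ValueError("gene universe is empty")

    blocks: dict[str, np.ndarray] = {}
    constant_cols = []
    for name in collection.names("hallmark") + collection.names("kegg"):
        members = collection.sets[name]
        x = np.array([1.0 if g in members else 0.0 for g in genes])
        sd = x.std(ddof=0)
        if sd == 0.0:
            blocks[name] = np.zeros_like(x)
            constant_cols.append(name)
        else:
            blocks[name] = (x - x.mean()) / sd
    if constant_cols:
        warnings.warn(
            f"{len(constant_cols)} constant membership column(s) zeroed: "
            f"{constant_cols[:5]}..."
        )

    sub = graph.mechanistic_subgraph()
    degree = dict(sub.degree())
    betweenness = nx.betweenness_centrality(sub, normalized=normalized_betweenness)
    closeness = nx.closeness_centrality(sub)

    def topo(metric: dict, g: str) -> float:
        return np.log1p(float(metric.get(("gene", g), 0.0)))

    n_membership = len(blocks)
    blocks["degree"] = np.array([topo(degree, g) for g in genes])
    blocks["betweenness"] = np.array([topo(betweenness, g) for g in genes])
    blocks["closeness"] = np.array([topo(closeness, g) for g in genes])
    features = pd.DataFrame(blocks, index=genes, dtype=float)
    return PriorFeatureMatrix(values=features, n_membership=n_membership)


def prior_scores(
    features: PriorFeatureMatrix,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    standardize_all: bool = False,
) -> PriorScoreTable:
    """Convert the feature matrix to per-gene prior scores in (0, 1].

    The matrix is projected to two principal components; K-means (k clusters,
    ``n_restarts`` seeded restarts, Lloyd iterations to tolerance 1e-6)
    partitions the plane; each gene's raw score is the Euclidean distance to
    its assigned centroid. Genes are ranked by raw score descending (ties
    broken by gene symbol) and the final score is (n - rank + 1)/n, so the
    top-ranked gene scores exactly 1.0 and the bottom 1/n.

    ``standardize_all`` re-standardizes every column (including the already
    log-scaled topology block) before the projection.
    """
    X = features.values.to_numpy(dtype=float, copy=True)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} genes, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if standardize_all:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    n_comp = min(2, X.shape[1], n)
    coords = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, tol=1e-6, random_state=seed,
                algorithm="lloyd").fit(coords)
    raw = np.linalg.norm(coords - km.cluster_centers_[km.labels_], axis=1)

    genes = np.asarray(features.values.index)
    # descending raw score, lexicographic gene symbol as deterministic tie-break
    order = sorted(range(n), key=lambda i: (-raw[i], genes[i]))
    rank = np.empty(n, dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    score = (n - rank + 1) / n
    table = pd.DataFrame({"rank": rank, "score": score}, index=genes)
    return PriorScoreTable(table=table.sort_values("rank"))


# ---------------------------------------------------------------------------
# GMT / TSV I/O
# ---------------------------------------------------------------------------

def read_gmt(path, family: str = "kegg") -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    families: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
            families[parts[0]] = family
    return GeneSetCollection(sets=sets, families=families)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.families[name]}\t{members}\n")


def read_interactions_tsv(path) -> InteractionGraph:
    """Read a typed edge list: node_a, type_a, node_b, type_b, association_class."""
    df = pd.read_csv(path, sep="\t")
    graph = InteractionGraph()
    for row in df.itertuples(index=False):
        graph.add_edge(str(row.node_a), str(row.type_a), str(row.node_b),
                       str(row.type_b), str(row.association_class))
    return graph


def write_interactions_tsv(graph: InteractionGraph, path) -> None:
    rows = [
        {
            "node_a": u[1], "type_a": u[0],
            "node_b": v[1], "type_b": v[0],
            "association_class": d.get("association_class", MECHANISTIC_MARKER),
        }
        for u, v, d in graph.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "type_a", "node_b", "type_b",
                                "association_class"]).to_csv(path, sep="\t", index=False)


def read_prior_table_tsv(path) -> PriorScoreTable:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return PriorScoreTable(table=df[["rank", "score"]])


def write_prior_table_tsv(priors: PriorScoreTable, path) -> None:
    priors.table.to_csv(path, sep="\t", index_label="gene")
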