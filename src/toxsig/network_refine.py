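"""Prior re-weighting of consensus edges and Markov clustering of the result.

Edge re-weighting combines a co-expression weight S(A,B) with the per-gene
prior scores: the default mode multiplies by the mean prior,
S_new = S * (P(A) + P(B)) / 2, and a product mode uses S * P(A) * P(B).
Because S and the priors all lie in (0, 1], re-weighted edges stay in [0, 1].

The Markov Cluster Algorithm (MCL) then partitions the gene graph: the
weighted adjacency matrix (with self-loops) is made column-stochastic and
the process alternates expansion (matrix power, spreading random-walk flow)
with inflation (entrywise power followed by column renormalization,
sharpening flow) until the matrix converges to a doubly idempotent limit
whose attractor structure defines the clusters. The inflation exponent
controls granularity: larger values give more, smaller clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coexpression import WeightedGeneNetwork


@dataclass
class MCLConfig:
    """Markov clustering parameters.

    inflation : granularity exponent, recommended range 1.2-5.0 (default 3.3)
    expansion : matrix-power exponent (default 2)
    prune_threshold : entries below it are zeroed after inflation (1e-5)
    max_iterations : iteration cap (200)
    convergence_tolerance : max entrywise change declaring convergence (1e-8)
    self_loop_weight : explicit loop weight, or None for the standard choice
        of each node's maximum incident edge weight
    """

    inflation: float = 3.3
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tolerance: float = 1e-8
    self_loop_weight: float | None = None

    def __post_init__(self) -> None:
        if not self.inflation > 1.0:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class GeneClustering:
    """A partition of the clustered gene universe into disjoint clusters."""

    clusters: list[frozenset[str]]
    converged: bool = True
    assignment: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.clusters = [frozenset(c) for c in self.clusters]
        if any(not c for c in self.clusters):
            raise ValueError("empty cluster")
        self.assignment = {}
        for idx, cluster in enumerate(self.clusters):
            for gene in cluster:
                if gene in self.assignment:
                    raise ValueError(f"gene {gene!r} in more than one cluster")
                self.assignment[gene] = idx

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def genes(self) -> set[str]:
        return set(self.assignment)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def reweight_edges(
    network: WeightedGeneNetwork,
    priors,
    mode: str = "mean",
) -> WeightedGeneNetwork:
    """Re-weight every edge by the prior scores of its endpoint genes.

    mode='mean'    : S_new(A,B) = S(A,B) * (P(A) + P(B)) / 2
    mode='product' : S_new(A,B) = S(A,B) * P(A) * P(B)

    Every network gene must carry a prior score; priors of 1 everywhere leave
    the network unchanged, and raising any prior never decreases a weight.
    """
    if mode not in ("mean", "product"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = sorted(g for g in network.genes if g not in priors)
    if missing:
        raise ValueError(f"genes without prior scores: {missing[:10]!r}")
    edges = {}
    for (a, b), s in network.edges.items():
        pa, pb = priors.score(a), priors.score(b)
        factor = (pa + pb) / 2.0 if mode == "mean" else pa * pb
        edges[(a, b)] = s * factor
    return WeightedGeneNetwork(genes=set(network.genes), edges=edges)


def _stochastic(m: np.ndarray) -> np.ndarray:
    col = m.sum(axis=0)
    col[col == 0.0] = 1.0
    return m / col


def mcl_cluster(network: WeightedGeneNetwork, config: MCLConfig | None = None) -> GeneClustering:
    """Cluster a weighted gene network with the Markov Cluster Algorithm.

    The transition matrix gets one self-loop per node (weight = the node's
    maximum incident edge weight unless the config fixes it) and is column
    normalized. Each iteration raises the matrix to the expansion power,
    applies the entrywise inflation power with column renormalization, and
    prunes entries below ``prune_threshold`` (never a column's maximum).
    Iteration stops when the maximum entrywise change falls below the
    convergence tolerance or at ``max_iterations`` (then the current matrix
    is interpreted with ``converged=False``).

    Attractors are nodes with positive diagonal mass in the limit; attractor
    systems whose basins overlap are merged, and any gene still attracted by
    several systems goes to the one holding the most of its column mass
    (ties to the lowest cluster index) so the output is always a partition.
    Genes with no edges become singleton clusters.
    """
    config = config or MCLConfig()
    if not network.genes:
        raise ValueError("cannot cluster an empty network")
    isolated = sorted(network.isolated_genes())
    connected = sorted(network.genes - set(isolated))
    clusters: list[frozenset[str]] = []
    converged = True

    if connected:
        index = {g: i for i, g in enumerate(connected)}
        n = len(connected)
        m = np.zeros((n, n))
        for (a, b), w in network.edges.items():
            m[index[a], index[b]] = w
            m[index[b], index[a]] = w
        if config.self_loop_weight is not None:
            loops = np.full(n, float(config.self_loop_weight))
        else:
            loops = m.max(axis=0)  # max incident weight per node
        np.fill_diagonal(m, loops)
        m = _stochastic(m)

        for _ in range(config.max_iterations):
            previous = m
            m = np.linalg.matrix_power(m, config.expansion)
            m = _stochastic(np.power(m, config.inflation))
            keep = m >= config.prune_threshold
            keep[m.argmax(axis=0), np.arange(n)] = True
            m = _stochastic(np.where(keep, m, 0.0))
            if np.abs(m - previous).max() < config.convergence_tolerance:
                break
        else:
            converged = False
            warnings.warn("MCL did not converge within max_iterations")

        clusters.extend(_interpret(m, connected))
    for g in isolated:
        clusters.append(frozenset([g]))
    clusters.sort(key=lambda c: min(c))
    return GeneClustering(clusters=clusters, converged=converged)


def _interpret(m: np.ndarray, genes: list[str]) -> list[frozenset[str]]:
    """Read a partition from the (near-)idempotent MCL limit matrix."""
    n = m.shape[0]
    attractors = np.where(np.diag(m) > 0.0)[0]
    if attractors.size == 0:  # pathological non-converged state
        attractors = np.unique(m.argmax(axis=0))
    # merge attractors whose basins overlap into attractor systems
    system = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while system[x] != x:
            system[x] = system[system[x]]
            x = system[x]
        return x

    for j in range(n):
        rows = [int(a) for a in attractors if m[a, j] > 0.0]
        for a in rows[1:]:
            ra, rb = find(rows[0]), find(a)
            if ra != rb:
                system[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(int(a)) for a in attractors})
    root_index = {r: k for k, r in enumerate(roots)}
    members: dict[int, set[int]] = {k: set() for k in root_index.values()}
    leftovers: list[int] = []
    for j in range(n):
        masses: dict[int, float] = {}
        for a in attractors:
            if m[a, j] > 0.0:
                k = root_index[find(int(a))]
                masses[k] = masses.get(k, 0.0) + m[a, j]
        if masses:
            # largest attractor mass wins; ties go to the lowest cluster index
            best = max(masses.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            members[best].add(j)
        else:  # only reachable on a non-converged interpretation
            leftovers.append(j)
    clusters = [frozenset(genes[j] for j in js) for js in members.values() if js]
    clusters.extend(frozenset([genes[j]]) for j in leftovers)
    return clusters


def clustering_quality(network: WeightedGeneNetwork, clustering: GeneClustering) -> dict:
    """Mass fraction and clustering efficiency of a partition.

    mass_fraction: sum of intra-cluster edge weights over total edge weight
    (1.0 when every edge is internal, 0.0 for all-singleton clusterings).

    efficiency: mean over nodes v of cov(v) * (1 - (|C(v)| - 1)/(n - 1)),
    where cov(v) is the fraction of v's incident edge weight kept inside its
    cluster C(v) (1 for edgeless nodes) and n is the number of clustered
    genes. Coverage rewards clusters that capture each node's connectivity;
    the spread factor penalizes coarse clusterings, so a single all-inclusive
    cluster scores 0 despite full coverage, as does an all-singleton
    clustering of a connected graph.
    """
    uncovered = network.genes - clustering.genes
    if uncovered:
        raise ValueError(f"clustering does not cover genes: {sorted(uncovered)[:5]!r}")
    total = sum(network.edges.values())
    intra = sum(
        w for (a, b), w in network.edges.items()
        if clustering.assignment[a] == clustering.assignment[b]
    )
    mass_fraction = intra / total if total > 0 else 1.0

    n = len(clustering.genes)
    incident: dict[str, float] = {g: 0.0 for g in clustering.genes}
    internal: dict[str, float] = {g: 0.0 for g in clustering.genes}
    for (a, b), w in network.edges.items():
        incident[a] += w
        incident[b] += w
        if clustering.assignment[a] == clustering.assignment[b]:
            internal[a] += w
            internal[b] += w
    eff = 0.0
    for g in clustering.genes:
        cov = internal[g] / incident[g] if incident[g] > 0 else 1.0
        size = len(clustering.clusters[clustering.assignment[g]])
        spread = 1.0 - (size - 1) / (n - 1) if n > 1 else 1.0
        eff += cov * spread
    efficiency = eff / n if n else 1.0
    return {"mass_fraction": mass_fraction, "efficiency": efficiency}


def inflation_scan(
    network: WeightedGeneNetwork,
    inflations,
    config: MCLConfig | None = None,
) -> pd.DataFrame:
    """Run MCL at each inflation value and tabulate clustering summaries.

    Columns: inflation, n_clusters, mass_fraction, efficiency, mean_size
    (= n_genes / n_clusters), min_size, max_size, converged.
    """
    inflations = list(inflations)
    if not inflations:
        raise ValueError("no inflation values given")
    base = config or MCLConfig()
    rows = []
    for inflation in inflations:
        clustering = mcl_cluster(network, replace(base, inflation=float(inflation)))
        quality = clustering_quality(network, clustering)
        sizes = clustering.sizes()
        rows.append({
            "inflation": float(inflation),
            "n_clusters": clustering.n_clusters,
            "mass_fraction": quality["mass_fraction"],
            "efficiency": quality["efficiency"],
            "mean_size": len(clustering.genes) / clustering.n_clusters,
            "min_size": min(sizes),
            "max_size": max(sizes),
            "converged": clustering.converged,
        })
    return pd.DataFrame(rows)


def write_clusters(clustering: GeneClustering, path) -> None:
    """One line per cluster, tab-separated gene symbols."""
    with open(path, "w") as fh:
        for cluster in clustering.clusters:
            fh.write("\t".join(sorted(cluster)) + "\n")


def read_clusters(path) -> GeneClustering:
    clusters = []
    with open(path) as fh:
        for line in fh:
            genes = [g for g in line.rstrip("\n").split("\t") if g]
            if genes:
                clusters.append(frozenset(genes))
    return GeneClustering(clusters=clusters)
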