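"""Classifier-driven gene selection: per-cluster ranking, quota allocation,
signature assembly and global re-ranking.

One random-forest classifier is trained per gene cluster to predict the
binary apical-outcome label from the cluster's genes alone; genes are ranked
within each cluster by mean-decrease-in-Gini importance averaged over
stratified cross-validation folds. The signature budget (e.g. 1000 genes) is
then split across clusters proportionally to cluster-model cross-validation
accuracy — a cluster with accuracy a_c receives total * a_c / sum(a) genes,
integerized by largest remainder and capped at the cluster size, with any
capped excess redistributed among the remaining clusters. The per-cluster
top genes are concatenated and a final random forest over the assembled
signature yields the global ranking; each gene's regulation direction is the
sign of its mean expression difference between dysregulated and
non-dysregulated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .data_model import DYSREGULATED, ExpressionDataset

RF_N_TREES = 500


@dataclass
class ClusterModelReport:
    """Cross-validated random-forest report for one gene cluster."""

    cluster_index: int
    accuracy: float
    importances: pd.Series  # gene -> mean Gini importance over folds
    importance_stability: pd.Series  # gene -> 1/(1+sd of fold importances)
    fold_seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError(f"accuracy {self.accuracy} outside [0,1]")


@dataclass
class RankedSignature:
    """Globally ranked gene signature with provenance."""

    records: pd.DataFrame  # columns: rank, gene, cluster, importance, regulation

    def __post_init__(self) -> None:
        ranks = self.records["rank"].to_numpy()
        if not np.array_equal(np.sort(ranks), np.arange(1, len(ranks) + 1)):
            raise ValueError("ranks must be a permutation of 1..N")
        if self.records["gene"].duplicated().any():
            raise ValueError("duplicate genes in signature")

    @property
    def genes(self) -> list[str]:
        return list(self.records.sort_values("rank")["gene"])

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def __len__(self) -> int:
        return len(self.records)


def _prepare_matrix(dataset: ExpressionDataset, genes: list[str]) -> np.ndarray:
    """Samples x genes design matrix; residual missing values are filled with
    the per-gene mean (random forests need complete input)."""
    x = dataset.values.loc[genes].T
    x = x.fillna(x.mean()).fillna(0.0)
    return x.to_numpy(dtype=float)


def rank_cluster_genes(
    dataset: ExpressionDataset,
    labels: pd.Series,
    cluster_genes,
    cluster_index: int = 0,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = RF_N_TREES,
) -> ClusterModelReport:
    """Rank one cluster's genes by cross-validated random-forest importance.

    A forest (``n_trees`` trees, sqrt(p) features per split) is fit on the
    cluster's genes in each stratified fold; accuracy is the mean fold
    accuracy and importances are Gini importances averaged over folds.
    """
    genes = sorted(set(cluster_genes) & set(dataset.genes))
    if not genes:
        raise ValueError(f"cluster {cluster_index} has no genes in the dataset")
    y = labels.loc[dataset.samples].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present to train a classifier")
    x = _prepare_matrix(dataset, genes)

    n_folds = min(n_folds, int(np.bincount(pd.factorize(y)[0]).min()))
    if n_folds < 2:
        raise ValueError("too few samples in the minority class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accuracies, fold_importances = [], []
    for train, test in skf.split(x, y):
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        ).fit(x[train], y[train])
        accuracies.append(float(rf.score(x[test], y[test])))
        fold_importances.append(rf.feature_importances_)
    imp = np.vstack(fold_importances)
    return ClusterModelReport(
        cluster_index=cluster_index,
        accuracy=float(np.mean(accuracies)),
        importances=pd.Series(imp.mean(axis=0), index=genes),
        importance_stability=pd.Series(1.0 / (1.0 + imp.std(axis=0)), index=genes),
        fold_seed=seed,
    )


def allocate_quota(
    accuracies: dict[int, float],
    cluster_sizes: dict[int, int],
    total: int,
) -> dict[int, int]:
    """Split a gene budget across clusters proportionally to model accuracy.

    Each cluster's ideal share is total * acc_c / sum(acc); shares are
    integerized by largest remainder so quotas sum exactly to the budget.
    A quota never exceeds its cluster's size: capped clusters keep their
    full size and the excess is re-apportioned among the uncapped clusters,
    iterating until the budget is met or every cluster is exhausted. With
    accuracies {A: 0.60, B: 0.55} and a budget of 1000, A gets
    1000*60/115 -> 522 and B 478; if A holds only 520 genes the result is
    {A: 520, B: 480}.

    All-zero accuracies fall back to size-proportional allocation (warned).
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if any(a < 0 for a in accuracies.values()):
        raise ValueError("accuracies must be nonnegative")
    if set(accuracies) != set(cluster_sizes):
        raise ValueError("accuracies and cluster_sizes must cover the same clusters")
    capacity = sum(cluster_sizes.values())
    if capacity <= total:
        return dict(cluster_sizes)

    weights = dict(accuracies)
    if sum(weights.values()) == 0.0:
        warnings.warn("all cluster accuracies are zero; falling back to "
                      "size-proportional allocation")
        weights = {c: float(s) for c, s in cluster_sizes.items()}

    quotas = {c: 0 for c in weights}
    capped: set[int] = set()
    remaining = total
    while remaining > 0:
        active = [c for c in weights if c not in capped]
        if not active:
            break
        wsum = sum(weights[c] for c in active)
        if wsum == 0.0:  # residual zero-accuracy clusters: spread by size
            share = {c: remaining * cluster_sizes[c] / sum(cluster_sizes[c2] for c2 in active)
                     for c in active}
        else:
            share = {c: remaining * weights[c] / wsum for c in active}
        alloc = _largest_remainder(share, remaining)
        newly_capped = False
        for c in active:
            room = cluster_sizes[c] - quotas[c]
            take = min(alloc[c], room)
            quotas[c] += take
            remaining -= take
            if quotas[c] == cluster_sizes[c]:
                capped.add(c)
                newly_capped = True
        if not newly_capped and remaining > 0:
            # rounding left a residue with headroom everywhere: hand out one
            # by one to the largest fractional shares
            order = sorted(active, key=lambda c: (-share[c] % 1, c))
            for c in order:
                if remaining == 0:
                    break
                if quotas[c] < cluster_sizes[c]:
                    quotas[c] += 1
                    remaining -= 1
    return quotas


def _largest_remainder(shares: dict[int, float], total: int) -> dict[int, int]:
    """Integerize fractional shares so they sum exactly to ``total``."""
    floors = {c: int(np.floor(s)) for c, s in shares.items()}
    residue = total - sum(floors.values())
    remainders = sorted(shares, key=lambda c: (-(shares[c] - floors[c]), c))
    for c in remainders[:residue]:
        floors[c] += 1
    return floors


def assemble_signature(
    reports: dict[int, ClusterModelReport],
    quotas: dict[int, int],
) -> list[str]:
    """Take each cluster's top-quota genes by importance and concatenate.

    Ties in importance are broken by cross-validation fold stability (higher
    first), then lexicographically. Clusters are disjoint, so the
    concatenation is already duplicate-free (deduplication is still applied
    defensively).
    """
    selected: list[str] = []
    seen: set[str] = set()
    for cluster_index in sorted(quotas):
        quota = quotas[cluster_index]
        if quota == 0:
            continue
        report = reports[cluster_index]
        if quota > len(report.importances):
            raise RuntimeError(
                f"quota {quota} exceeds cluster {cluster_index} size "
                f"{len(report.importances)}"
            )
        order = sorted(
            report.importances.index,
            key=lambda g: (-report.importances[g], -report.importance_stability[g], g),
        )
        for gene in order[:quota]:
            if gene not in seen:
                selected.append(gene)
                seen.add(gene)
    return selected


def global_ranking(
    dataset: ExpressionDataset,
    labels: pd.Series,
    signature_genes: list[str],
    cluster_of: dict[str, int] | None = None,
    seed: int = 0,
    n_trees: int = RF_N_TREES,
) -> RankedSignature:
    """Rank the assembled signature with one final random forest.

    The forest is fit on all signature genes at once; rank is descending
    Gini importance (ties by symbol). Regulation is 'up' when a gene's mean
    expression in dysregulated samples exceeds its mean in non-dysregulated
    samples, else 'down'.
    """
    if not signature_genes:
        raise ValueError("signature is empty")
    genes = list(signature_genes)
    y = labels.loc[dataset.samples].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present")
    x = _prepare_matrix(dataset, genes)
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    ).fit(x, y)
    importance = pd.Series(rf.feature_importances_, index=genes)

    dys = labels.loc[dataset.samples] == DYSREGULATED
    mean_dys = dataset.values.loc[genes, dys.index[dys]].mean(axis=1)
    mean_non = dataset.values.loc[genes, dys.index[~dys]].mean(axis=1)
    regulation = np.where(mean_dys > mean_non, "up", "down")

    order = sorted(genes, key=lambda g: (-importance[g], g))
    rank = {g: i for i, g in enumerate(order, start=1)}
    records = pd.DataFrame({
        "rank": [rank[g] for g in genes],
        "gene": genes,
        "cluster": [cluster_of.get(g, -1) if cluster_of else -1 for g in genes],
        "importance": importance.values,
        "regulation": regulation,
    }).sort_values("rank").reset_index(drop=True)
    return RankedSignature(records=records)


def select_signature(
    dataset: ExpressionDataset,
    labels: pd.Series,
    clustering,
    signature_size: int = 1000,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = RF_N_TREES,
) -> RankedSignature:
    """Full selection stage: per-cluster ranking, quota allocation, assembly
    and global ranking, producing a signature of ``signature_size`` genes
    (or the whole clustered universe if smaller)."""
    reports: dict[int, ClusterModelReport] = {}
    sizes: dict[int, int] = {}
    rng = np.random.default_rng(seed)
    for idx, cluster in enumerate(clustering.clusters):
        genes = sorted(set(cluster) & set(dataset.genes))
        if not genes:
            continue
        cluster_seed = int(rng.integers(0, 2**31 - 1))
        reports[idx] = rank_cluster_genes(
            dataset, labels, genes, cluster_index=idx, n_folds=n_folds,
            seed=cluster_seed, n_trees=n_trees,
        )
        sizes[idx] = len(genes)
    accuracies = {idx: r.accuracy for idx, r in reports.items()}
    quotas = allocate_quota(accuracies, sizes, signature_size)
    selected = assemble_signature(reports, quotas)
    cluster_of = {g: idx for idx, r in reports.items() for g in r.importances.index}
    return global_ranking(dataset, labels, selected, cluster_of=cluster_of,
                          seed=seed, n_trees=n_trees)


def write_signature_tsv(signature: RankedSignature, path) -> None:
    signature.records.to_csv(path, sep="\t", index=False)


def read_signature_tsv(path) -> RankedSignature:
    return RankedSignature(records=pd.read_csv(path, sep="\t"))
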