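"""Cross-validated apical-outcome prediction and signature benchmarking.

A gene set is scored by training a panel of standard classifiers on the
samples restricted to that gene set and pooling out-of-fold predictions from
stratified cross-validation into a confusion matrix, from which six summary
metrics are computed:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    GMean       = sqrt(sensitivity * specificity)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)
    F0.5        = 1.25 * precision * sensitivity / (0.25 * precision + sensitivity)

with any 0/0 ratio defined as 0. Signatures are compared with a random-set
baseline (many uniformly drawn gene sets of matched size) via a Welch
two-sample t-test per metric on the per-classifier average scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .data_model import DYSREGULATED, ExpressionDataset
from .gene_selection import _prepare_matrix

METRIC_NAMES = ("sensitivity", "specificity", "precision", "gmean", "f1", "f05")

#: Default evaluated panel (the five-classifier panel); KNN is registered too.
DEFAULT_PANEL = ("LDA", "NBC", "QDA", "DT", "RF")


def _make_classifier(name: str, seed: int):
    # LDA/QDA carry shrinkage/ridge regularization so gene sets larger than
    # the sample count do not produce singular class covariances
    registry = {
        "KNN": lambda: KNeighborsClassifier(n_neighbors=3),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "NBC": lambda: GaussianNB(),
        "QDA": lambda: QuadraticDiscriminantAnalysis(solver="eigen", shrinkage="auto"),
        "RF": lambda: RandomForestClassifier(n_estimators=100, random_state=seed,
                                             n_jobs=1),
        "LDA": lambda: LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
    }
    if name not in registry:
        raise ValueError(f"unknown classifier {name!r}; registry: {sorted(registry)}")
    return registry[name]()


CLASSIFIER_REGISTRY = ("KNN", "DT", "NBC", "QDA", "RF", "LDA")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    gmean: float
    f1: float
    f05: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class EvaluationReport:
    """Per-classifier metrics for one gene set plus cross-classifier summary."""

    gene_set_id: str
    per_classifier: dict[str, MetricSet]
    fold_seed: int
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        rows = {name: ms.as_dict() for name, ms in self.per_classifier.items()}
        frame = pd.DataFrame(rows).T
        self.mean = frame.mean().to_dict()
        self.sd = frame.std(ddof=1).fillna(0.0).to_dict()

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(self.per_classifier)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({n: m.as_dict() for n, m in self.per_classifier.items()}).T


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Summary metrics from a confusion matrix; 0/0 ratios are defined as 0."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    return metrics_from_rates(sens, spec, prec)


def metrics_from_rates(sensitivity: float, specificity: float, precision: float) -> MetricSet:
    """Derive GMean/F1/F0.5 from already-computed base rates."""
    gmean = math.sqrt(sensitivity * specificity)
    f1 = _ratio(2.0 * precision * sensitivity, precision + sensitivity)
    f05 = _ratio(1.25 * precision * sensitivity, 0.25 * precision + sensitivity)
    return MetricSet(sensitivity, specificity, precision, gmean, f1, f05)


def counts_from_predictions(y_true, y_pred, positive=DYSREGULATED) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_true = y_true == positive
    pos_pred = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_true & pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
    )


def cross_validate_gene_set(
    dataset: ExpressionDataset,
    labels: pd.Series,
    gene_subset,
    classifiers=DEFAULT_PANEL,
    n_folds: int = 5,
    seed: int = 0,
    gene_set_id: str = "gene_set",
    pool_folds: bool = True,
) -> EvaluationReport:
    """Evaluate one gene set with the classifier panel under stratified CV.

    Out-of-fold predictions are pooled into one confusion matrix per
    classifier before metrics are computed (``pool_folds=False`` instead
    averages per-fold metric values).
    """
    genes = [g for g in gene_subset if g in set(dataset.genes)]
    missing = set(gene_subset) - set(genes)
    if missing:
        raise ValueError(f"genes not in dataset: {sorted(missing)[:5]!r}")
    if not genes:
        raise ValueError("empty gene subset")
    y = labels.loc[dataset.samples].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present")
    x = _prepare_matrix(dataset, genes)
    n_folds = min(n_folds, int(np.bincount(pd.factorize(y)[0]).min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))

    per_classifier: dict[str, MetricSet] = {}
    for name in classifiers:
        if pool_folds:
            y_pred = np.empty_like(y)
            for train, test in splits:
                clf = _make_classifier(name, seed)
                clf.fit(x[train], y[train])
                y_pred[test] = clf.predict(x[test])
            per_classifier[name] = compute_metrics(counts_from_predictions(y, y_pred))
        else:
            fold_metrics = []
            for train, test in splits:
                clf = _make_classifier(name, seed)
                clf.fit(x[train], y[train])
                counts = counts_from_predictions(y[test], clf.predict(x[test]))
                fold_metrics.append(compute_metrics(counts).as_dict())
            mean = pd.DataFrame(fold_metrics).mean()
            per_classifier[name] = MetricSet(**mean.to_dict())
    return EvaluationReport(gene_set_id=gene_set_id, per_classifier=per_classifier,
                            fold_seed=seed)


@dataclass
class BaselineSummary:
    """Distribution of random-gene-set performance.

    ``per_classifier_means`` holds, per classifier, the metric scores
    averaged over all random repeats — the unit of the significance test.
    ``per_repeat`` holds the cross-classifier mean per repeat.
    """

    set_size: int
    n_repeats: int
    panel: tuple[str, ...]
    per_classifier_means: pd.DataFrame  # classifiers x metrics
    per_repeat: pd.DataFrame  # repeats x metrics
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.per_repeat.mean().to_dict()
        self.sd = self.per_repeat.std(ddof=1).fillna(0.0).to_dict()


def random_baseline(
    dataset: ExpressionDataset,
    labels: pd.Series,
    set_size: int,
    n_repeats: int = 500,
    classifiers=DEFAULT_PANEL,
    n_folds: int = 5,
    seed: int = 0,
) -> BaselineSummary:
    """Evaluate ``n_repeats`` uniformly random gene sets of ``set_size``."""
    if set_size > dataset.n_genes:
        raise ValueError("set_size exceeds the gene count")
    rng = np.random.default_rng(seed)
    genes = np.asarray(dataset.genes)
    rows = []
    for rep in range(n_repeats):
        subset = list(rng.choice(genes, size=set_size, replace=False))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        report = cross_validate_gene_set(
            dataset, labels, subset, classifiers=classifiers, n_folds=n_folds,
            seed=rep_seed, gene_set_id=f"random_{rep}",
        )
        rows.append(report.frame())
    stacked = pd.concat(rows, keys=range(n_repeats), names=["repeat", "classifier"])
    per_classifier_means = stacked.groupby(level="classifier").mean().loc[list(classifiers)]
    per_repeat = stacked.groupby(level="repeat").mean()
    return BaselineSummary(
        set_size=set_size, n_repeats=n_repeats, panel=tuple(classifiers),
        per_classifier_means=per_classifier_means, per_repeat=per_repeat,
    )


def compare_to_random(
    report: EvaluationReport,
    baseline: BaselineSummary,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Welch t-test per metric on the per-classifier average scores.

    The two samples are the signature's per-classifier metric values and the
    baseline's per-classifier means over random repeats; both must come from
    the same classifier panel. Returns a table with t statistic, two-sided
    p-value and a significance flag at ``alpha``.
    """
    if tuple(report.panel) != tuple(baseline.panel):
        raise ValueError(
            f"classifier panels differ: {report.panel} vs {baseline.panel}"
        )
    sig_frame = report.frame()
    rows = []
    for metric in METRIC_NAMES:
        a = sig_frame[metric].to_numpy(dtype=float)
        b = baseline.per_classifier_means[metric].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "metric": metric, "t": float(t), "p_value": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows).set_index("metric")


def compare_gene_sets(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Pairwise improvement table between gene-set reports, in percent.

    For each ordered pair (a, b) and metric m: absolute delta = m_a - m_b
    and relative delta = (m_a - m_b) / m_b, both expressed in percentage
    points / percent. A zero reference metric leaves the relative delta
    undefined (NaN).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for a in reports:
        for b in reports:
            if a is b:
                continue
            for metric in METRIC_NAMES:
                ma, mb = a.mean[metric], b.mean[metric]
                rel = (ma - mb) / mb * 100.0 if mb != 0 else float("nan")
                rows.append({
                    "gene_set_a": a.gene_set_id, "gene_set_b": b.gene_set_id,
                    "metric": metric,
                    "absolute_delta_pct": (ma - mb) * 100.0,
                    "relative_delta_pct": rel,
                })
    return pd.DataFrame(rows)


def report_to_json(report: EvaluationReport, path,
                   comparison: pd.DataFrame | None = None) -> None:
    payload = {
        "gene_set_id": report.gene_set_id,
        "fold_seed": report.fold_seed,
        "per_classifier": {n: m.as_dict() for n, m in report.per_classifier.items()},
        "mean": report.mean,
        "sd": report.sd,
    }
    if comparison is not None:
        payload["p_values"] = comparison["p_value"].to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def report_to_csv(report: EvaluationReport, path) -> None:
    """CSV export: one row per classifier plus mean and sd rows."""
    frame = report.frame()
    frame.loc["mean"] = pd.Series(report.mean)
    frame.loc["sd"] = pd.Series(report.sd)
    frame.to_csv(path, index_label="classifier")
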