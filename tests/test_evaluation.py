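import numpy as np
import pandas as pd
import pytest

from conftest import make_labels
from toxsig.data_model import DYSREGULATED, NON_DYSREGULATED, ExpressionDataset
from toxsig.evaluation import (
    BaselineSummary,
    ConfusionCounts,
    EvaluationReport,
    MetricSet,
    compare_gene_sets,
    compare_to_random,
    compute_metrics,
    counts_from_predictions,
    cross_validate_gene_set,
    metrics_from_rates,
    random_baseline,
)

PANEL = ("LDA", "NBC", "QDA", "DT", "RF")


class TestComputeMetrics:
    def test_derived_metrics_from_printed_best_model_rates(self):
        """GMean/F1/F0.5 recomputed from a reported sensitivity 44.78%,
        specificity 68.75%, precision 28.57% round to 55.48/34.88/30.80%."""
        m = metrics_from_rates(0.4478, 0.6875, 0.2857)
        assert m.gmean * 100 == pytest.approx(55.48, abs=0.01)
        assert m.f1 * 100 == pytest.approx(34.88, abs=0.01)
        assert m.f05 * 100 == pytest.approx(30.80, abs=0.01)

    def test_derived_gmean_from_weak_model_rates(self):
        m = metrics_from_rates(0.0448, 0.7208, 0.0429)
        assert m.gmean * 100 == pytest.approx(17.97, abs=0.01)

    def test_degenerate_zero_over_zero_counts(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert m.sensitivity == 0.0
        assert m.precision == 0.0
        assert m.f1 == 0.0
        assert m.specificity == 1.0

    def test_gmean_identity_holds_exactly(self):
        m = compute_metrics(ConfusionCounts(tp=7, fp=3, tn=11, fn=2))
        assert m.gmean**2 == pytest.approx(m.sensitivity * m.specificity, abs=1e-12)

    def test_agrees_with_brute_force_recount_on_random_predictions(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            truth = rng.choice([DYSREGULATED, NON_DYSREGULATED], n)
            pred = rng.choice([DYSREGULATED, NON_DYSREGULATED], n)
            counts = counts_from_predictions(truth, pred)
            tp = sum(t == p == DYSREGULATED for t, p in zip(truth, pred))
            fn = sum(t == DYSREGULATED != p for t, p in zip(truth, pred))
            fp = sum(p == DYSREGULATED != t for t, p in zip(truth, pred))
            tn = n - tp - fn - fp
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
            m = compute_metrics(counts)
            assert 0.0 <= min(m.as_dict().values())
            assert max(m.as_dict().values()) <= 1.0
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))


def _separable_dataset(seed=0, n=80):
    rng = np.random.default_rng(seed)
    flags = rng.random(n) < 0.4
    x = rng.standard_normal((6, n)) * 0.05
    x[0] += 4.0 * flags
    x[1] -= 4.0 * flags
    genes = [f"G{i}" for i in range(6)]
    ds = ExpressionDataset("sep", pd.DataFrame(
        x, index=genes, columns=[f"s{i:03d}" for i in range(n)]))
    return ds, make_labels(ds, flags)


class TestCrossValidateGeneSet:
    def test_perfectly_separable_data_scores_near_one(self):
        ds, labels = _separable_dataset()
        report = cross_validate_gene_set(ds, labels, ds.genes, classifiers=("RF",),
                                         seed=0)
        m = report.per_classifier["RF"]
        assert m.f1 > 0.95
        assert m.gmean > 0.95

    def test_report_means_equal_hand_averaged_rows(self):
        ds, labels = _separable_dataset(seed=1)
        report = cross_validate_gene_set(ds, labels, ds.genes, classifiers=PANEL,
                                         seed=0)
        frame = report.frame()
        for metric in frame.columns:
            assert report.mean[metric] == pytest.approx(frame[metric].mean())
            assert report.sd[metric] == pytest.approx(frame[metric].std(ddof=1))

    def test_unknown_classifier_lists_registry(self):
        ds, labels = _separable_dataset(seed=2)
        with pytest.raises(ValueError, match="registry"):
            cross_validate_gene_set(ds, labels, ds.genes, classifiers=("SVM",))

    def test_label_permutation_falls_in_random_band(self):
        """With permuted labels the signature genes lose their advantage:
        the mean F1 lands inside the random-set null band."""
        rng = np.random.default_rng(7)
        ds, labels = _separable_dataset(seed=7, n=60)
        permuted = pd.Series(rng.permutation(labels.values), index=labels.index)
        report = cross_validate_gene_set(ds, permuted, ds.genes,
                                         classifiers=("NBC", "DT"), seed=0)
        baseline = random_baseline(ds, permuted, set_size=4, n_repeats=15,
                                   classifiers=("NBC", "DT"), seed=1)
        lo = baseline.mean["f1"] - 3 * baseline.sd["f1"] - 0.05
        hi = baseline.mean["f1"] + 3 * baseline.sd["f1"] + 0.05
        assert lo <= report.mean["f1"] <= hi


class TestRandomBaseline:
    def test_single_repeat_reduces_to_one_cross_validation(self):
        ds, labels = _separable_dataset(seed=3)
        baseline = random_baseline(ds, labels, set_size=3, n_repeats=1,
                                   classifiers=("DT",), seed=5)
        rng = np.random.default_rng(5)
        subset = list(rng.choice(np.asarray(ds.genes), size=3, replace=False))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        direct = cross_validate_gene_set(ds, labels, subset, classifiers=("DT",),
                                         seed=rep_seed)
        assert baseline.per_repeat.iloc[0].to_dict() == pytest.approx(direct.mean)

    def test_fixed_seed_reproducible(self):
        ds, labels = _separable_dataset(seed=4)
        a = random_baseline(ds, labels, 3, n_repeats=4, classifiers=("DT",), seed=9)
        b = random_baseline(ds, labels, 3, n_repeats=4, classifiers=("DT",), seed=9)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)

    def test_strong_signature_rarely_beaten_by_random_sets(self):
        ds, labels = _separable_dataset(seed=5)
        signature = cross_validate_gene_set(ds, labels, ["G0", "G1"],
                                            classifiers=("RF",), seed=0)
        baseline = random_baseline(ds, labels, set_size=2, n_repeats=20,
                                   classifiers=("RF",), seed=2)
        beaten = (baseline.per_repeat["f1"] > signature.mean["f1"]).mean()
        assert beaten <= 0.5  # most random pairs include a separating gene too


def _report_from_values(gene_set_id, values_by_classifier):
    per = {
        name: MetricSet(**{m: v for m in
                           ("sensitivity", "specificity", "precision",
                            "gmean", "f1", "f05")})
        for name, v in values_by_classifier.items()
    }
    return EvaluationReport(gene_set_id=gene_set_id, per_classifier=per, fold_seed=0)


def _baseline_from_values(panel, values):
    frame = pd.DataFrame(
        {m: values for m in ("sensitivity", "specificity", "precision",
                             "gmean", "f1", "f05")},
        index=list(panel),
    )
    return BaselineSummary(set_size=10, n_repeats=1, panel=tuple(panel),
                           per_classifier_means=frame,
                           per_repeat=frame.reset_index(drop=True))


class TestCompareToRandom:
    def test_large_shift_is_flagged_significant(self):
        sig = _report_from_values("sig", {c: 0.7 + 0.01 * i
                                          for i, c in enumerate(PANEL)})
        base = _baseline_from_values(PANEL, [0.5 + 0.01 * i
                                             for i in range(len(PANEL))])
        table = compare_to_random(sig, base, alpha=0.1)
        assert table.loc["f1", "significant"]

    def test_alpha_zero_never_significant(self):
        sig = _report_from_values("sig", {c: 0.9 for c in PANEL})
        base = _baseline_from_values(PANEL, [0.1 + 0.01 * i
                                             for i in range(len(PANEL))])
        table = compare_to_random(sig, base, alpha=0.0)
        assert not table["significant"].any()

    def test_mismatched_panels_rejected(self):
        sig = _report_from_values("sig", {"RF": 0.5, "DT": 0.5})
        base = _baseline_from_values(("RF", "NBC"), [0.5, 0.5])
        with pytest.raises(ValueError):
            compare_to_random(sig, base)

    def test_type_one_error_near_nominal_alpha(self):
        """Under the null (both panels drawn from one distribution) the
        alpha=0.1 test flags close to 10% of 1,000 replicates."""
        rng = np.random.default_rng(42)
        flagged = 0
        n_reps = 1000
        for _ in range(n_reps):
            a = rng.normal(0.5, 0.05, len(PANEL))
            b = rng.normal(0.5, 0.05, len(PANEL))
            sig = _report_from_values("sig", dict(zip(PANEL, a)))
            base = _baseline_from_values(PANEL, b)
            table = compare_to_random(sig, base, alpha=0.1)
            flagged += bool(table.loc["f1", "significant"])
        assert flagged / n_reps == pytest.approx(0.1, abs=0.05)


class TestCompareGeneSets:
    def test_relative_improvement_from_reported_f1_values(self):
        a = _report_from_values("T", {c: 0.2458 for c in PANEL})
        b = _report_from_values("L", {c: 0.1927 for c in PANEL})
        table = compare_gene_sets([a, b])
        row = table[(table.gene_set_a == "T") & (table.gene_set_b == "L")
                    & (table.metric == "f1")].iloc[0]
        assert row["relative_delta_pct"] == pytest.approx(27.56, abs=0.01)

    def test_absolute_improvement_from_reported_f1_values(self):
        a = _report_from_values("T", {c: 0.2458 for c in PANEL})
        b = _report_from_values("Lim", {c: 0.2299 for c in PANEL})
        table = compare_gene_sets([a, b])
        row = table[(table.gene_set_a == "T") & (table.gene_set_b == "Lim")
                    & (table.metric == "f1")].iloc[0]
        assert row["absolute_delta_pct"] == pytest.approx(1.59, abs=0.01)

    def test_identical_reports_have_zero_deltas(self):
        a = _report_from_values("A", {c: 0.3 for c in PANEL})
        b = _report_from_values("B", {c: 0.3 for c in PANEL})
        table = compare_gene_sets([a, b])
        assert (table["absolute_delta_pct"] == 0).all()
        assert (table["relative_delta_pct"] == 0).all()

    def test_zero_reference_metric_reported_undefined(self):
        a = _report_from_values("A", {c: 0.3 for c in PANEL})
        b = _report_from_values("B", {c: 0.0 for c in PANEL})
        table = compare_gene_sets([a, b])
        row = table[(table.gene_set_a == "A") & (table.metric == "f1")].iloc[0]
        assert np.isnan(row["relative_delta_pct"])
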