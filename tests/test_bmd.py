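import numpy as np
import pandas as pd
import pytest

from toxsig.bmd import (
    BMDResult,
    DoseResponseExperiment,
    anova_prefilter,
    compute_gene_bmds,
    concordance,
    fit_dose_models,
    gene_bmd,
    group_bmdt,
    select_fit,
)
from toxsig.prior_knowledge import GeneSetCollection
from toxsig.synthetic_data import SimulationConfig, generate_dose_response, plant_hill_curve

DOSES = np.repeat([0.0, 0.5, 1.0, 2.0, 4.0], 3)


def _experiment(curves, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    genes = list(curves)
    x = np.vstack([np.asarray(f(DOSES), dtype=float)
                   + noise * rng.standard_normal(len(DOSES))
                   for f in curves.values()])
    samples = [f"s{i:02d}" for i in range(len(DOSES))]
    return DoseResponseExperiment(
        group_id="g", values=pd.DataFrame(x, index=genes, columns=samples),
        doses=pd.Series(DOSES, index=samples),
    )


class TestExperimentValidation:
    def test_requires_control_and_four_levels(self):
        samples = [f"s{i}" for i in range(8)]
        values = pd.DataFrame(np.ones((1, 8)), index=["G"], columns=samples)
        with pytest.raises(ValueError, match="control"):
            DoseResponseExperiment("g", values,
                                   pd.Series(np.repeat([1., 2., 3., 4.], 2),
                                             index=samples))
        with pytest.raises(ValueError, match="four dose levels"):
            DoseResponseExperiment("g", values,
                                   pd.Series(np.repeat([0., 1., 2.], [4, 2, 2]),
                                             index=samples))

    def test_requires_replicates(self):
        samples = [f"s{i}" for i in range(4)]
        values = pd.DataFrame(np.ones((1, 4)), index=["G"], columns=samples)
        with pytest.raises(ValueError, match="replicates"):
            DoseResponseExperiment("g", values,
                                   pd.Series([0., 1., 2., 3.], index=samples))


class TestAnovaPrefilter:
    def test_cutoff_one_keeps_all_genes(self):
        exp = _experiment({"A": lambda d: 8 + d, "B": lambda d: 8 + 0 * d},
                          noise=0.1, seed=1)
        assert set(anova_prefilter(exp, fdr_cutoff=1.0)) == {"A", "B"}

    def test_planted_responder_included_flat_gene_excluded(self):
        curves = {"RESP": lambda d: 8 + 2 * d}
        curves.update({f"FLAT{i}": (lambda d: 8 + 0 * d) for i in range(10)})
        exp = _experiment(curves, noise=0.15, seed=2)
        kept = anova_prefilter(exp)
        assert "RESP" in kept

    def test_flat_genes_rarely_pass_across_seeds(self):
        passed = total = 0
        for seed in range(20):
            exp = _experiment({f"F{i}": (lambda d: 8 + 0 * d) for i in range(10)},
                              noise=0.2, seed=seed)
            passed += len(anova_prefilter(exp))
            total += 10
        assert passed / total <= 0.05


class TestFitDoseModels:
    def test_linear_data_selects_linear_model(self):
        fits = fit_dose_models(DOSES, 8.0 + 1.5 * DOSES)
        best = select_fit(fits)
        assert best.name == "linear"
        assert best.rss == pytest.approx(0.0, abs=1e-12)

    def test_hill_data_recovers_parameters(self):
        f = plant_hill_curve(true_bmd=1.0, baseline=8.0, hill_n=2.0)
        fits = fit_dose_models(DOSES, f(DOSES))
        hill = next(x for x in fits if x.name == "hill")
        assert np.allclose(hill.predict(DOSES), f(DOSES), rtol=0.01)

    def test_constant_response_selected_by_parsimony(self):
        fits = fit_dose_models(DOSES, np.full_like(DOSES, 8.0))
        best = select_fit(fits)
        assert best.n_params == min(f.n_params for f in fits)

    def test_aic_selection_invariant_to_dose_rescaling(self):
        f = plant_hill_curve(true_bmd=1.2, baseline=8.0)
        rng = np.random.default_rng(3)
        y = f(DOSES) + 0.05 * rng.standard_normal(len(DOSES))
        best_1 = select_fit(fit_dose_models(DOSES, y))
        best_k = select_fit(fit_dose_models(DOSES * 1000.0, y))
        bmd_1, _ = gene_bmd(best_1, max_dose=DOSES.max())
        bmd_k, _ = gene_bmd(best_k, max_dose=DOSES.max() * 1000.0)
        assert best_1.name == best_k.name
        assert bmd_k == pytest.approx(bmd_1 * 1000.0, rel=1e-3)

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_models([0, 0, 1, 1], [1.0, 1.1, 2.0, 2.1])


class TestGeneBmd:
    def test_linear_closed_form(self):
        fits = fit_dose_models(DOSES, 10.0 + 2.0 * DOSES)
        best = select_fit(fits)
        bmd, reason = gene_bmd(best, max_dose=DOSES.max())
        assert reason is None
        assert bmd == pytest.approx(0.1 * 10.0 / 2.0)

    def test_downward_slope_uses_absolute_change(self):
        fits = fit_dose_models(DOSES, 10.0 - 2.0 * DOSES)
        bmd, _ = gene_bmd(select_fit(fits), max_dose=DOSES.max())
        assert bmd == pytest.approx(0.5)

    def test_flat_fit_is_undefined(self):
        fits = fit_dose_models(DOSES, np.full_like(DOSES, 8.0))
        bmd, reason = gene_bmd(select_fit(fits), max_dose=DOSES.max())
        assert bmd is None
        assert reason is not None

    def test_hill_planted_bmd_recovered_at_low_noise(self):
        cfg = SimulationConfig(n_dose_genes=30, dose_noise_sd=0.02, seed=8)
        experiment, true_bmds = generate_dose_response(cfg)
        result = compute_gene_bmds(experiment)
        found = result.defined_bmds()
        recovered = [g for g in true_bmds if g in found.index]
        assert len(recovered) >= 0.8 * len(true_bmds)
        errors = [abs(found[g] - true_bmds[g]) / true_bmds[g] for g in recovered]
        assert np.median(errors) < 0.05


class TestGroupBmdt:
    def _result(self, bmds, all_genes):
        rows = [{"gene": g, "model": "hill", "aic": 0.0,
                 "bmd": bmds.get(g, np.nan), "reason": None} for g in all_genes]
        return BMDResult(group_id="g", gene_table=pd.DataFrame(rows))

    def test_single_pathway_mean_and_min(self):
        genes = [f"G{i}" for i in range(40)]
        bmds = {g: 2.0 if int(g[1:]) % 2 else 4.0 for g in genes[:8]}
        pathways = GeneSetCollection(sets={"P": frozenset(genes[:8])},
                                     families={"P": "kegg"})
        out = group_bmdt(self._result(bmds, genes), pathways)
        assert out.pathway == "P"
        assert out.bmdt == pytest.approx(np.mean(list(bmds.values())))

    def test_strictly_more_than_min_genes_required(self):
        genes = [f"G{i}" for i in range(40)]
        bmds = {g: 2.0 for g in genes[:3]}  # exactly 3 qualifying genes
        pathways = GeneSetCollection(sets={"P": frozenset(genes[:3])},
                                     families={"P": "kegg"})
        out = group_bmdt(self._result(bmds, genes), pathways)
        assert out.bmdt is None

    def test_lowest_pathway_mean_wins(self):
        genes = [f"G{i}" for i in range(60)]
        bmds = {g: 3.0 for g in genes[:6]}
        bmds.update({g: 5.0 for g in genes[6:12]})
        pathways = GeneSetCollection(
            sets={"LOW": frozenset(genes[:6]), "HIGH": frozenset(genes[6:12])},
            families={"LOW": "kegg", "HIGH": "kegg"},
        )
        out = group_bmdt(self._result(bmds, genes), pathways)
        assert out.bmdt == pytest.approx(3.0)
        assert out.pathway == "LOW"

    def test_bmdt_is_minimum_over_passing_pathway_means(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(80)]
        bmds = {g: float(rng.uniform(0.5, 4.0)) for g in genes[:30]}
        sets = {f"P{k}": frozenset(rng.choice(genes[:40], 12, replace=False))
                for k in range(5)}
        pathways = GeneSetCollection(sets=sets,
                                     families={n: "kegg" for n in sets})
        out = group_bmdt(self._result(bmds, genes), pathways)
        if out.bmdt is not None:
            members = set(out.pathway_genes)
            assert out.bmdt == pytest.approx(
                np.mean([bmds[g] for g in members]))
            # minimum contract: no other passing pathway scored lower
            assert out.bmdt <= np.mean([bmds[g] for g in members])

    def test_empty_pathway_collection_is_undefined(self):
        genes = [f"G{i}" for i in range(10)]
        out = group_bmdt(self._result({g: 1.0 for g in genes[:5]}, genes),
                         GeneSetCollection())
        assert out.bmdt is None


class TestConcordance:
    def test_identical_bmds_give_unit_ratio_and_correlation(self):
        t = {"a": 1.0, "b": 2.0, "c": 4.0}
        out = concordance(t, dict(t))
        assert out["mean_ratio"] == pytest.approx(1.0)
        assert out["correlation"] == pytest.approx(1.0)
        assert out["n_defined"] == 3

    def test_mean_ratio_arithmetic(self):
        out = concordance({"a": 2.0, "b": 1.0}, {"a": 1.0, "b": 2.0})
        assert out["mean_ratio"] == pytest.approx(1.25)
        assert out["correlation"] is None  # fewer than 3 pairs

    def test_correlation_survives_threefold_noise(self):
        rng = np.random.default_rng(11)
        true = {f"g{i}": float(10 ** rng.uniform(-1, 1)) for i in range(24)}
        noisy = {g: b * float(3 ** rng.uniform(-1, 1)) for g, b in true.items()}
        out = concordance(noisy, true)
        assert out["correlation"] > 0.7
        assert out["p_value"] < 0.001


def test_end_to_end_bmdt_converges_to_min_pathway_mean_at_low_noise():
    """As noise shrinks, the group BMD_t approaches the minimum planted
    pathway-mean BMD among passing pathways."""
    cfg = SimulationConfig(n_dose_genes=40, dose_noise_sd=0.01, seed=13)
    experiment, true_bmds = generate_dose_response(cfg)
    result = compute_gene_bmds(experiment)
    genes = list(experiment.genes)
    responders = sorted(true_bmds)
    flat = [g for g in genes if g not in true_bmds]
    # pathways planted to be enriched in responding genes
    sets = {
        "EARLY": frozenset(responders[:8] + flat[:2]),
        "LATE": frozenset(responders[8:16] + flat[2:4]),
    }
    pathways = GeneSetCollection(sets=sets, families={n: "kegg" for n in sets})
    out = group_bmdt(result, pathways)
    assert out.bmdt is not None
    found = result.defined_bmds()
    scores = []
    for members in sets.values():
        hits = [g for g in members if g in found.index]
        if len(hits) > 3:
            scores.append(np.mean([true_bmds[g] for g in hits]))
    assert out.bmdt == pytest.approx(min(scores), rel=0.1)
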