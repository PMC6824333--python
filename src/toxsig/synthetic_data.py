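"""Seeded synthetic fixtures with the statistical structure of multi-dataset
toxicogenomic inputs.

The generator emulates, at desk scale, the three ingredients the signature
pipeline consumes:

* a triplet of expression datasets (two "in vitro" with LDH annotations, one
  "in vivo" with histopathology grades) sharing planted co-expression
  modules: genes inside a module load on a common latent factor so their
  expected pairwise correlation equals ``within_module_correlation`` in
  every dataset, background genes are independent, and genes of the first
  ``n_informative_modules`` modules are shifted by ``label_effect_size``
  standard deviations in dysregulated samples. Missing entries are placed
  completely at random at ``missing_rate``. Rat-style datasets carry
  title-case gene symbols so ortholog harmonization is exercised.
* prior-knowledge annotations: gene sets whose membership is biased toward
  informative genes by ``pathway_enrichment_bias`` (an odds multiplier), and
  a typed chemical-gene-disease interaction graph whose gene degrees are
  likewise skewed; a fraction of edges carries a "therapeutic" association
  class to exercise the mechanistic/marker filter.
* a dose-response experiment in which responding genes follow Hill-shaped
  curves planted so that the dose producing a 10% relative change from
  control equals the entry in ``true_bmd_table``, plus Gaussian noise;
  non-responders are flat noise.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DYSREGULATED, NON_DYSREGULATED, ExpressionDataset
from .prior_knowledge import MECHANISTIC_MARKER, GeneSetCollection, InteractionGraph

BASELINE_INTENSITY = 8.0  # log2-like microarray baseline


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle (desk scale by default)."""

    n_genes: int = 600
    n_samples: tuple[int, int, int] = (120, 120, 120)
    module_sizes: tuple[int, ...] = (60,) * 10
    within_module_correlation: float = 0.8
    n_informative_modules: int = 3
    label_effect_size: float = 1.5
    dysregulated_fraction: float = 0.3
    missing_rate: float = 0.10
    n_hallmark_sets: int = 10
    n_kegg_sets: int = 30
    mean_pathway_size: int = 25
    pathway_enrichment_bias: float = 5.0
    n_chemicals: int = 15
    n_diseases: int = 10
    mean_gene_degree: float = 1.0
    therapeutic_edge_fraction: float = 0.2
    dose_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    n_replicates: int = 3
    n_dose_genes: int = 120
    responder_fraction: float = 0.4
    dose_noise_sd: float = 0.1
    true_bmd_table: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene count")
        if not (0.0 < self.within_module_correlation < 1.0):
            raise ValueError("within_module_correlation must be in (0,1)")
        for rate in (self.missing_rate, self.dysregulated_fraction,
                     self.responder_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0,1]")
        if self.pathway_enrichment_bias < 1.0:
            raise ValueError("pathway_enrichment_bias must be >= 1")
        if len(self.dose_levels) < 4 or 0.0 not in self.dose_levels:
            raise ValueError("dose_levels needs >= 4 levels including control 0")
        if self.n_replicates < 2:
            raise ValueError("at least two replicates per dose are required")

    @property
    def n_pathways(self) -> int:
        return self.n_hallmark_sets + self.n_kegg_sets

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"GENE{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def module_assignment(self) -> dict[str, int]:
        """Gene -> module index; background genes map to -1."""
        names = self.gene_names()
        assignment: dict[str, int] = {}
        pos = 0
        for m, size in enumerate(self.module_sizes):
            for g in names[pos:pos + size]:
                assignment[g] = m
            pos += size
        for g in names[pos:]:
            assignment[g] = -1
        return assignment

    def informative_genes(self) -> set[str]:
        assignment = self.module_assignment()
        return {g for g, m in assignment.items()
                if 0 <= m < self.n_informative_modules}


@dataclass
class SyntheticBundle:
    """All generated fixtures plus their ground truth."""

    config: SimulationConfig
    datasets: list[ExpressionDataset]
    labels: list[pd.Series]
    gene_sets: GeneSetCollection
    interactions: InteractionGraph
    experiment: "object"  # DoseResponseExperiment (imported lazily to avoid cycle)
    module_assignment: dict[str, int]
    informative_genes: set[str]
    true_bmds: dict[str, float]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _rat_case(gene: str) -> str:
    return gene[0].upper() + gene[1:].lower()


def generate_expression_triplet(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], list[pd.Series]]:
    """Three expression datasets with planted modules, labels and annotations.

    Dataset 1 emulates human in vitro (uppercase symbols, LDH labels),
    dataset 2 rat in vitro (title-case symbols, LDH labels) and dataset 3
    rat in vivo (title-case symbols, histopathology labels).
    """
    genes = config.gene_names()
    assignment = config.module_assignment()
    informative = config.informative_genes()
    rho = config.within_module_correlation
    datasets, all_labels = [], []
    specs = [
        ("human_invitro", "human", "liver", "ldh", str.upper),
        ("rat_invitro", "rat", "liver", "ldh", _rat_case),
        ("rat_invivo", "rat", "liver", "histopathology", _rat_case),
    ]
    for d, ((ds_id, species, organ, endpoint, caser), n) in enumerate(
            zip(specs, config.n_samples)):
        rng = _rng(config, 10 + d)
        samples = [f"{ds_id}_s{j:03d}" for j in range(1, n + 1)]
        dys = rng.random(n) < config.dysregulated_fraction
        # at least one sample per class so classifiers stay trainable
        if dys.all():
            dys[0] = False
        if not dys.any():
            dys[0] = True

        n_modules = len(config.module_sizes)
        factors = rng.standard_normal((n_modules, n))
        x = np.empty((config.n_genes, n))
        for i, g in enumerate(genes):
            noise = rng.standard_normal(n)
            m = assignment[g]
            if m >= 0:
                x[i] = np.sqrt(rho) * factors[m] + np.sqrt(1.0 - rho) * noise
            else:
                x[i] = noise
            if g in informative:
                x[i] = x[i] + config.label_effect_size * dys
        x += BASELINE_INTENSITY
        if config.missing_rate > 0:
            mask = rng.random(x.shape) < config.missing_rate
            x[mask] = np.nan

        ann = pd.DataFrame(index=samples)
        ann["chemical"] = [f"chem{rng.integers(1, config.n_chemicals + 1):02d}"
                           for _ in samples]
        ann["dose"] = np.round(rng.uniform(0.1, 10.0, n), 3)
        ann["duration"] = "24h"
        ann["organ"] = organ
        ann["species"] = species
        if endpoint == "ldh":
            ldh = np.where(
                dys,
                np.where(rng.random(n) < 0.5,
                         rng.uniform(40.0, 94.9, n), rng.uniform(105.1, 160.0, n)),
                rng.uniform(95.0, 105.0, n),
            )
            ann["ldh_percent"] = np.round(ldh, 2)
            ann["histopathology_grade"] = pd.NA
        else:
            grades_dys = np.array(["moderate", "severe"])
            grades_non = np.array(["present", "minimal", "slight"])
            ann["ldh_percent"] = pd.NA
            ann["histopathology_grade"] = [
                rng.choice(grades_dys) if flag else rng.choice(grades_non)
                for flag in dys
            ]
        values = pd.DataFrame(x, index=[caser(g) for g in genes], columns=samples)
        datasets.append(ExpressionDataset(ds_id, values, ann))
        all_labels.append(pd.Series(
            np.where(dys, DYSREGULATED, NON_DYSREGULATED), index=samples, name="label"
        ))
    return datasets, all_labels


def generate_prior_annotations(
    config: SimulationConfig,
) -> tuple[GeneSetCollection, InteractionGraph]:
    """Gene-set collection and interaction graph biased toward informative genes."""
    genes = config.gene_names()
    informative = config.informative_genes()
    weights = np.array([config.pathway_enrichment_bias if g in informative else 1.0
                        for g in genes])
    probs = weights / weights.sum()

    rng = _rng(config, 20)
    sets: dict[str, frozenset[str]] = {}
    families: dict[str, str] = {}
    for i in range(config.n_pathways):
        family = "hallmark" if i < config.n_hallmark_sets else "kegg"
        size = min(config.n_genes,
                   max(3, int(rng.poisson(config.mean_pathway_size))))
        members = rng.choice(genes, size=size, replace=False, p=probs)
        name = f"{family.upper()}_SET_{i + 1:03d}"
        sets[name] = frozenset(members)
        families[name] = family
    collection = GeneSetCollection(sets=sets, families=families)

    rng = _rng(config, 21)
    graph = InteractionGraph()
    chemicals = [f"chem{i:02d}" for i in range(1, config.n_chemicals + 1)]
    diseases = [f"disease{i:02d}" for i in range(1, config.n_diseases + 1)]
    for c in chemicals:
        graph.add_node(c, "chemical")
    for di in diseases:
        graph.add_node(di, "disease")
    for g, w in zip(genes, weights):
        degree = rng.poisson(config.mean_gene_degree * w)
        for _ in range(degree):
            partner_pool = chemicals if rng.random() < 0.7 else diseases
            partner = partner_pool[rng.integers(len(partner_pool))]
            ptype = "chemical" if partner in chemicals else "disease"
            cls = ("therapeutic"
                   if rng.random() < config.therapeutic_edge_fraction
                   else MECHANISTIC_MARKER)
            graph.add_edge(g, "gene", partner, ptype, cls)
    for _ in range(config.n_chemicals):
        c = chemicals[rng.integers(len(chemicals))]
        di = diseases[rng.integers(len(diseases))]
        graph.add_edge(c, "chemical", di, "disease", MECHANISTIC_MARKER)
    return collection, graph


def plant_hill_curve(true_bmd: float, baseline: float = BASELINE_INTENSITY,
                     amplitude_fraction: float = 0.3, hill_n: float = 2.0,
                     direction: float = 1.0):
    """Hill curve whose 10%-relative-change dose equals ``true_bmd``.

    f(d) = a + s*amp*d^n/(k^n + d^n) with amp = amplitude_fraction*|a| and
    k chosen so |f(B) - a| = 0.1*|a| exactly at B = true_bmd, which requires
    amplitude_fraction > 0.1.
    """
    if amplitude_fraction <= 0.1:
        raise ValueError("amplitude_fraction must exceed the 10% benchmark response")
    amp = amplitude_fraction * abs(baseline)
    k = true_bmd * (amp / (0.1 * abs(baseline)) - 1.0) ** (1.0 / hill_n)

    def f(d):
        d = np.asarray(d, dtype=float)
        return baseline + direction * amp * d ** hill_n / (k ** hill_n + d ** hill_n)

    return f


def generate_dose_response(config: SimulationConfig):
    """Dose-response experiment with Hill-planted responders.

    Responding genes (the first ``responder_fraction`` of ``n_dose_genes``)
    follow Hill curves whose benchmark dose equals the ``true_bmd_table``
    entry (by default log-uniform across the positive dose range, half of
    them down-regulated); the remainder are flat noise. BMDs planted above
    the tested dose range are allowed but warned about.
    """
    from .bmd import DoseResponseExperiment

    rng = _rng(config, 30)
    genes = config.gene_names()[:config.n_dose_genes]
    n_responders = int(round(config.responder_fraction * len(genes)))
    responders = genes[:n_responders]
    max_dose = max(config.dose_levels)
    positive = sorted(d for d in config.dose_levels if d > 0)

    if config.true_bmd_table is not None:
        true_bmds = dict(config.true_bmd_table)
    else:
        lo, hi = np.log10(positive[0] / 2), np.log10(max_dose * 0.8)
        true_bmds = {
            g: float(10 ** rng.uniform(lo, hi)) for g in responders
        }
    outside = [g for g, b in true_bmds.items() if b > max_dose]
    if outside:
        warnings.warn(f"{len(outside)} planted BMD(s) above the tested dose range")

    doses = np.repeat(np.asarray(config.dose_levels, dtype=float), config.n_replicates)
    samples = [f"dr_s{j:03d}" for j in range(1, len(doses) + 1)]
    x = np.empty((len(genes), len(doses)))
    for i, g in enumerate(genes):
        if g in true_bmds:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            f = plant_hill_curve(true_bmds[g], direction=direction)
            x[i] = f(doses)
        else:
            x[i] = BASELINE_INTENSITY
        x[i] = x[i] + config.dose_noise_sd * rng.standard_normal(len(doses))
    values = pd.DataFrame(x, index=genes, columns=samples)
    experiment = DoseResponseExperiment(
        group_id="synthetic_group",
        values=values,
        doses=pd.Series(doses, index=samples),
    )
    return experiment, true_bmds


def generate_bundle(config: SimulationConfig | None = None) -> SyntheticBundle:
    """Generate the full fixture bundle from one config."""
    config = config or SimulationConfig()
    datasets, labels = generate_expression_triplet(config)
    gene_sets, interactions = generate_prior_annotations(config)
    experiment, true_bmds = generate_dose_response(config)
    return SyntheticBundle(
        config=config,
        datasets=datasets,
        labels=labels,
        gene_sets=gene_sets,
        interactions=interactions,
        experiment=experiment,
        module_assignment=config.module_assignment(),
        informative_genes=config.informative_genes(),
        true_bmds=true_bmds,
    )
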