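"""Transcriptomic benchmark-dose (BMD) pipeline.

For each treatment group (chemical x exposure duration) with at least four
dose levels including control, genes are prefiltered by one-way ANOVA across
dose groups with Benjamini-Hochberg FDR control. Each surviving gene's
dose-response curve is fit with a suite of models — exponential (degree
2-5), polynomial (degree 2-3), linear, power, and Hill — and the model with
the lowest AIC (n*ln(RSS/n) + 2k; non-converged fits excluded, near-ties
broken toward fewer parameters) defines the gene-level BMD: the smallest
positive dose at which the fitted response departs from its control level by
the benchmark response (default 10% of the control level, in either
direction, so down-regulated genes are covered).

Gene-level BMDs are aggregated to a treatment-group BMD_t through pathway
enrichment: pathways enriched in BMD-bearing genes (one-sided Fisher exact
test) that contain more than ``min_genes`` such genes and cover more than
``min_coverage`` of their membership are scored by the mean member BMD, and
BMD_t is the lowest pathway score. Concordance with apical benchmark doses
(BMD_a) is summarized by the mean per-group BMD_t/BMD_a ratio and the
Pearson correlation of the log10-transformed pairs.

Model parameterizations (d = dose):

    linear  f(d) = a + b*d
    poly2   f(d) = a + b*d + c*d^2
    poly3   f(d) = a + b*d + c*d^2 + e*d^3
    power   f(d) = a + b*d^p,                 p >= 1
    hill    f(d) = a + b*d^n / (k^n + d^n),   n >= 1, k > 0
    exp2    f(d) = a * exp(b*d)
    exp3    f(d) = a * exp(b*d^p),            p >= 1
    exp4    f(d) = a * (c - (c-1)*exp(-b*d)),          b >= 0
    exp5    f(d) = a * (c - (c-1)*exp(-(b*d)^p)),      b >= 0, p >= 1

The Hill exponent is bounded below by 1 to avoid the super-sensitive
low-dose behaviour of fractional exponents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .prior_knowledge import GeneSetCollection


@dataclass
class DoseResponseExperiment:
    """Dose-annotated expression for one treatment group."""

    group_id: str
    values: pd.DataFrame  # genes x samples
    doses: pd.Series  # sample -> dose

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.doses.index)
        if missing:
            raise ValueError(f"samples without dose annotation: {sorted(missing)[:5]!r}")
        self.doses = self.doses.loc[list(self.values.columns)].astype(float)
        if (self.doses < 0).any():
            raise ValueError("doses must be nonnegative")
        if 0.0 not in set(self.doses):
            raise ValueError("control dose 0 is required")
        if self.doses.nunique() < 4:
            raise ValueError("at least four dose levels (incl. control) are required")
        counts = self.doses.value_counts()
        if (counts < 2).any():
            raise ValueError("at least two replicates per dose level are required")

    @property
    def dose_levels(self) -> np.ndarray:
        return np.sort(self.doses.unique())

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ModelFit:
    name: str
    params: np.ndarray
    n_params: int
    rss: float
    aic: float
    predict: object  # callable d -> response
    converged: bool = True


@dataclass
class BMDResult:
    """Per-gene winning fits and BMDs plus the group-level roll-up."""

    group_id: str
    gene_table: pd.DataFrame  # gene, model, aic, bmd, reason
    bmdt: float | None = None
    pathway: str | None = None
    pathway_genes: tuple[str, ...] = ()
    bmda: float | None = None

    def defined_bmds(self) -> pd.Series:
        t = self.gene_table.dropna(subset=["bmd"])
        return pd.Series(t["bmd"].values, index=t["gene"].values, dtype=float)


# ---------------------------------------------------------------------------
# ANOVA prefilter
# ---------------------------------------------------------------------------

def anova_prefilter(experiment: DoseResponseExperiment,
                    fdr_cutoff: float = 0.05) -> list[str]:
    """Keep genes whose one-way ANOVA across dose groups passes BH-FDR.

    Classic (equal-variance) one-way ANOVA; missing values are dropped per
    gene; genes constant across all groups get p = 1.
    """
    levels = experiment.dose_levels
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two dose groups")
    group_cols = {lv: experiment.doses.index[experiment.doses == lv] for lv in levels}
    pvals = []
    for gene in experiment.genes:
        groups = []
        for lv in levels:
            x = experiment.values.loc[gene, group_cols[lv]].dropna().to_numpy()
            if x.size >= 2:
                groups.append(x)
        if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups) and \
                np.ptp(np.concatenate(groups)) == 0:
            pvals.append(1.0)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.f_oneway(*groups)
        pvals.append(1.0 if not np.isfinite(p) else float(p))
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return [g for g, p in zip(experiment.genes, adjusted) if p <= fdr_cutoff]


# ---------------------------------------------------------------------------
# Model suite
# ---------------------------------------------------------------------------

def _fit_curve(func, d, y, p0, bounds, n_params, name) -> ModelFit | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                func, d, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
            )
        pred = func(d, *popt)
        if not np.all(np.isfinite(pred)):
            return None
    except (RuntimeError, ValueError):
        return None
    rss = float(np.sum((y - pred) ** 2))
    n = len(y)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * n_params
    return ModelFit(name=name, params=np.asarray(popt), n_params=n_params,
                    rss=rss, aic=float(aic),
                    predict=lambda x, f=func, p=popt: f(np.asarray(x, dtype=float), *p))


def _poly_fit(d, y, degree, name) -> ModelFit:
    coeffs = np.polyfit(d, y, degree)
    pred = np.polyval(coeffs, d)
    rss = float(np.sum((y - pred) ** 2))
    n = len(y)
    k = degree + 1
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return ModelFit(name=name, params=coeffs, n_params=k, rss=rss, aic=float(aic),
                    predict=lambda x, c=coeffs: np.polyval(c, np.asarray(x, dtype=float)))


def fit_dose_models(doses, response) -> list[ModelFit]:
    """Fit the full model suite to one gene's dose-response curve.

    Returns the converged fits only; a model that fails to converge is
    excluded from AIC selection rather than penalized.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(y)
    d, y = d[ok], y[ok]
    if np.unique(d).size < 4:
        raise ValueError("at least four dose levels are required for curve fitting")
    dmax = d.max()
    y0 = float(np.mean(y[d == 0])) if np.any(d == 0) else float(y[np.argmin(d)])
    span = float(np.ptp(y)) or 1.0
    big = np.inf

    fits: list[ModelFit | None] = [
        _poly_fit(d, y, 1, "linear"),
        _poly_fit(d, y, 2, "poly2"),
        _poly_fit(d, y, 3, "poly3"),
        _fit_curve(lambda x, a, b, p: a + b * np.power(x, p), d, y,
                   p0=[y0, span / max(dmax, 1e-9), 1.5],
                   bounds=([-big, -big, 1.0], [big, big, 18.0]),
                   n_params=3, name="power"),
        _fit_curve(lambda x, a, b, n, k: a + b * np.power(x, n) /
                   (np.power(k, n) + np.power(x, n)), d, y,
                   p0=[y0, span, 2.0, max(dmax / 2, 1e-6)],
                   bounds=([-big, -big, 1.0, 1e-9], [big, big, 18.0, 100 * max(dmax, 1)]),
                   n_params=4, name="hill"),
        _fit_curve(lambda x, a, b: a * np.exp(b * x), d, y,
                   p0=[y0 if y0 != 0 else 1.0, 0.0],
                   bounds=([-big, -big], [big, big]), n_params=2, name="exp2"),
        _fit_curve(lambda x, a, b, p: a * np.exp(b * np.power(x, p)), d, y,
                   p0=[y0 if y0 != 0 else 1.0, 0.0, 1.5],
                   bounds=([-big, -big, 1.0], [big, big, 18.0]),
                   n_params=3, name="exp3"),
        _fit_curve(lambda x, a, c, b: a * (c - (c - 1) * np.exp(-b * x)), d, y,
                   p0=[y0 if y0 != 0 else 1.0, 1.1, 1.0 / max(dmax, 1e-9)],
                   bounds=([-big, -big, 0.0], [big, big, big]),
                   n_params=3, name="exp4"),
        _fit_curve(lambda x, a, c, b, p: a * (c - (c - 1) * np.exp(-np.power(b * x, p))),
                   d, y,
                   p0=[y0 if y0 != 0 else 1.0, 1.1, 1.0 / max(dmax, 1e-9), 1.5],
                   bounds=([-big, -big, 0.0, 1.0], [big, big, big, 18.0]),
                   n_params=4, name="exp5"),
    ]
    return [f for f in fits if f is not None]


def select_fit(fits: list[ModelFit]) -> ModelFit | None:
    """Lowest-AIC fit; AIC ties within 1e-6 break toward fewer parameters."""
    if not fits:
        return None
    return min(fits, key=lambda f: (round(f.aic / 1e-6) * 1e-6, f.n_params, f.name))


def gene_bmd(fit: ModelFit, max_dose: float, bmr_relative: float = 0.10):
    """Benchmark dose of a fitted curve, or (None, reason).

    BMD is the smallest positive dose d in (0, max_dose] where
    |f(d) - f(0)| = bmr_relative * |f(0)|. Closed forms are used for the
    linear (0.1*|a/b|) and power models; other models are solved by a grid
    scan plus bracketed root-finding. Returns (bmd, None) or (None, reason).
    """
    f0 = float(np.asarray(fit.predict(0.0)))
    if f0 == 0.0:
        return None, "control_level_zero"
    target = bmr_relative * abs(f0)

    if fit.name == "linear":
        b = fit.params[0]  # highest-order polyfit coefficient
        if b == 0:
            return None, "flat_fit"
        bmd = target / abs(b)
        return (float(bmd), None) if bmd <= max_dose else (None, "bmd_above_range")
    if fit.name == "power":
        a, b, p = fit.params
        if b == 0:
            return None, "flat_fit"
        bmd = (target / abs(b)) ** (1.0 / p)
        return (float(bmd), None) if bmd <= max_dose else (None, "bmd_above_range")

    def g(d):
        return np.abs(np.asarray(fit.predict(d), dtype=float) - f0) - target

    grid = np.linspace(0.0, max_dose, 2049)
    vals = g(grid)
    crossing = np.where((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if crossing.size == 0:
        return None, "no_crossing_in_range"
    lo, hi = grid[crossing[0]], grid[crossing[0] + 1]
    if vals[crossing[0] + 1] == 0:
        return float(hi), None
    bmd = optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(bmd), None


# ---------------------------------------------------------------------------
# Group-level aggregation and concordance
# ---------------------------------------------------------------------------

def compute_gene_bmds(experiment: DoseResponseExperiment,
                      fdr_cutoff: float = 0.05,
                      bmr_relative: float = 0.10) -> BMDResult:
    """ANOVA prefilter, model fitting and BMD derivation for every gene."""
    passing = set(anova_prefilter(experiment, fdr_cutoff=fdr_cutoff))
    d = experiment.doses.to_numpy()
    rows = []
    for gene in experiment.genes:
        if gene not in passing:
            rows.append({"gene": gene, "model": None, "aic": np.nan,
                         "bmd": np.nan, "reason": "anova_filtered"})
            continue
        y = experiment.values.loc[gene].to_numpy(dtype=float)
        try:
            fits = fit_dose_models(d, y)
        except ValueError:
            fits = []
        best = select_fit(fits)
        if best is None:
            rows.append({"gene": gene, "model": None, "aic": np.nan,
                         "bmd": np.nan, "reason": "no_converged_fit"})
            continue
        bmd, reason = gene_bmd(best, max_dose=float(d.max()), bmr_relative=bmr_relative)
        rows.append({"gene": gene, "model": best.name, "aic": best.aic,
                     "bmd": bmd if bmd is not None else np.nan, "reason": reason})
    table = pd.DataFrame(rows, columns=["gene", "model", "aic", "bmd", "reason"])
    return BMDResult(group_id=experiment.group_id, gene_table=table)


def group_bmdt(
    result: BMDResult,
    pathways: GeneSetCollection,
    background: set[str] | None = None,
    p_cutoff: float = 0.05,
    min_genes: int = 3,
    min_coverage: float = 0.05,
) -> BMDResult:
    """Aggregate gene BMDs to a treatment-group BMD_t via pathway enrichment.

    Pathways are tested for enrichment of BMD-bearing genes against the
    background of all genes entering the ANOVA filter (one-sided Fisher
    exact, p < p_cutoff), then filtered to those with more than ``min_genes``
    BMD-bearing members and covering more than ``min_coverage`` of their
    in-background membership. Each passing pathway is scored by its mean
    member BMD and BMD_t is the minimum score; with no passing pathway the
    group's BMD_t stays undefined.
    """
    bmds = result.defined_bmds()
    background = set(background) if background is not None else set(result.gene_table["gene"])
    hits = set(bmds.index) & background
    best_score, best_pathway, best_members = None, None, ()
    for name, members in pathways.sets.items():
        in_bg = members & background
        if not in_bg:
            continue
        in_hits = in_bg & hits
        k = len(in_hits)
        table = [
            [k, len(in_bg) - k],
            [len(hits) - k, len(background) - len(in_bg) - (len(hits) - k)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        if p >= p_cutoff:
            continue
        if k <= min_genes:
            continue
        if k / len(in_bg) <= min_coverage:
            continue
        score = float(bmds.loc[sorted(in_hits)].mean())
        if best_score is None or score < best_score:
            best_score, best_pathway, best_members = score, name, tuple(sorted(in_hits))
    return BMDResult(
        group_id=result.group_id, gene_table=result.gene_table,
        bmdt=best_score, pathway=best_pathway, pathway_genes=best_members,
        bmda=result.bmda,
    )


def concordance(bmdts: dict[str, float], bmdas: dict[str, float],
                log_scale: bool = True) -> dict:
    """Concordance of transcriptomic and apical benchmark doses.

    Only treatment groups with both values defined enter. Reports the count
    of such pairs, the mean per-group BMD_t/BMD_a ratio, and the Pearson
    correlation (with two-sided p-value) of the log10-transformed pairs
    (``log_scale=False`` correlates on the linear scale).
    """
    groups = sorted(
        g for g in set(bmdts) & set(bmdas)
        if bmdts[g] is not None and bmdas[g] is not None
        and np.isfinite(bmdts[g]) and np.isfinite(bmdas[g])
    )
    t = np.array([bmdts[g] for g in groups], dtype=float)
    a = np.array([bmdas[g] for g in groups], dtype=float)
    out = {"n_defined": len(groups), "mean_ratio": float(np.mean(t / a)) if len(groups) else None,
           "correlation": None, "p_value": None}
    if len(groups) >= 3:
        x, y = (np.log10(t), np.log10(a)) if log_scale else (t, a)
        r, p = stats.pearsonr(x, y)
        out["correlation"] = float(r)
        out["p_value"] = float(p)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_doses_tsv(path) -> pd.DataFrame:
    """Doses TSV: sample_id, treatment_group, dose."""
    return pd.read_csv(path, sep="\t")


def write_gene_bmds_tsv(result: BMDResult, path) -> None:
    result.gene_table.to_csv(path, sep="\t", index=False)


def write_group_summary_tsv(results: list[BMDResult], path) -> None:
    rows = [{
        "group": r.group_id,
        "bmdt": r.bmdt if r.bmdt is not None else "",
        "pathway": r.pathway or "",
        "n_genes": len(r.pathway_genes),
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_apical_bmds_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["group"].astype(str), df["bmda"].astype(float)))
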