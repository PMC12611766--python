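"""Sperm cell-fraction estimates and disease-burden decomposition.

The fraction of sperm carrying a class of mutations is estimated by summing
duplex VAFs over the class (one mutant molecule at 100x duplex coverage is
one mutant cell in a hundred).  At small values the sum is interpretable as
the percentage of cells; above ~0.1 mean mutations per cell it is reported
as a mean count, since cells then often carry several variants of the
class.  Expected fractions come from the neutral rate model:
``rate(context) x duplex_coverage x age_correction`` summed over the
class's site-alternate universe, with the per-sample age correction taken
from a linear burden-on-age fit normalized by the cohort mean rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .context import BASES
from .coverage import CoverageTrack
from .qc import DataError
from .reference import ReferenceBundle
from .selection import ContextRateModel, site_alt_rates

logger = logging.getLogger(__name__)

#: below this mean count per cell the fraction is reported as a percentage
COUNT_REPORTING_THRESHOLD = 0.1

MAX_DISEASE_INDEL_BP = 21


@dataclass
class CellFractionEstimate:
    sample_id: str
    variant_class: str
    observed_fraction: float
    n_contributing_variants: int
    expected_fraction: float | None = None

    @property
    def reported_as(self) -> str:
        return (
            "percent"
            if self.observed_fraction < COUNT_REPORTING_THRESHOLD
            else "mean_count"
        )


def sum_vaf_fraction(
    variants: pd.DataFrame,
    variant_class: str,
    impact_classes: list[str] | None = None,
    label_col: str | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Observed per-sample cell fraction of a variant class (sum of VAFs).

    The class is selected either by ``impact_classes`` (values of
    ``impact_class``) or by a boolean ``label_col`` (e.g. "likely_disease").
    Samples listed in ``sample_ids`` but carrying no class variants report
    an explicit 0.
    """
    cov = variants["site_duplex_coverage"].to_numpy(dtype=float)
    if (cov <= 0).any():
        raise DataError("variant with zero site coverage")
    sel = pd.Series(True, index=variants.index)
    if impact_classes is not None:
        sel &= variants["impact_class"].isin(impact_classes)
    if label_col is not None:
        sel &= variants[label_col].fillna(False).astype(bool)
    sub = variants.loc[sel].copy()
    sub["vaf"] = sub["mutant_duplex_reads"] / sub["site_duplex_coverage"]
    agg = sub.groupby("sample_id").agg(
        observed_fraction=("vaf", "sum"),
        n_contributing_variants=("vaf", "size"),
    )
    if sample_ids is not None:
        agg = agg.reindex(sample_ids, fill_value=0.0)
        agg["n_contributing_variants"] = agg["n_contributing_variants"].astype(int)
    agg["variant_class"] = variant_class
    return agg.reset_index().rename(columns={"index": "sample_id"})


@dataclass
class AgeCorrection:
    """Per-sample multiplier normalizing the cohort rate model to one age."""

    sample_id: str
    predicted_rate: float
    cohort_mean_rate: float

    @property
    def correction(self) -> float:
        return self.predicted_rate / self.cohort_mean_rate


def compute_age_corrections(
    burdens: pd.DataFrame,
    rate_col: str = "rate_raw",
    age_col: str = "age_years",
) -> pd.DataFrame:
    """Age corrections from an unweighted linear fit of burden vs age.

    correction = (age-predicted rate) / (cohort mean rate); a sample at the
    cohort-average burden therefore has correction 1.
    """
    X = sm.add_constant(burdens[age_col].to_numpy(dtype=float))
    y = burdens[rate_col].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    predicted = fit.predict(X)
    mean_rate = float(y.mean())
    out = burdens[["sample_id"]].copy()
    out["predicted_rate"] = predicted
    out["cohort_mean_rate"] = mean_rate
    out["correction"] = predicted / mean_rate
    if (out["correction"] <= 0).any():
        raise DataError("non-positive age correction; burden fit degenerate")
    return out


def expected_class_fraction(
    model: ContextRateModel,
    ref: ReferenceBundle,
    coverage: CoverageTrack,
    sample_id: str,
    site_alt_universe: pd.DataFrame,
    correction: float = 1.0,
    indel_positions: np.ndarray | None = None,
) -> float:
    """Model-expected cell fraction of a labelled variant class.

    ``site_alt_universe`` lists the class's SNV site-alternates (pos/alt);
    ``indel_positions`` optionally adds per-base indel opportunity (indels
    up to 21 bp, a single genome-wide rate).  The expectation is linear in
    coverage and in the age correction.
    """
    depth = coverage.depths[sample_id].astype(float)
    total = 0.0
    if len(site_alt_universe):
        pos = site_alt_universe["pos"].to_numpy(dtype=np.int64)
        alt = np.array([BASES.index(a) for a in site_alt_universe["alt"]], dtype=np.int64)
        rates = site_alt_rates(model, ref, pos, alt)
        total += float(np.sum(rates * depth[pos - 1]))
    if indel_positions is not None and len(indel_positions):
        total += float(model.indel_rate * depth[np.asarray(indel_positions) - 1].sum())
    return total * correction


def expected_cell_fraction(
    model: ContextRateModel,
    ref: ReferenceBundle,
    coverage: CoverageTrack,
    sample_id: str,
    site_alt_universe: pd.DataFrame,
    correction: float = 1.0,
    indel_positions: np.ndarray | None = None,
) -> float:
    """Model-expected fraction of cells carrying a class variant.

    One duplex molecule interrogates one cell, so the per-duplex-molecule
    rate at a site is the probability that a given cell is mutant there;
    the expected summed VAF of a class is the rate sum over the *covered*
    members of its universe (coverage determines the support, then cancels
    between mutant molecules and depth).  This is the quantity comparable
    to :func:`sum_vaf_fraction`; :func:`expected_class_fraction` gives the
    coverage-weighted expected call count instead.
    """
    depth = coverage.depths[sample_id]
    total = 0.0
    if len(site_alt_universe):
        pos = site_alt_universe["pos"].to_numpy(dtype=np.int64)
        alt = np.array([BASES.index(a) for a in site_alt_universe["alt"]], dtype=np.int64)
        rates = site_alt_rates(model, ref, pos, alt)
        total += float(rates[depth[pos - 1] > 0].sum())
    if indel_positions is not None and len(indel_positions):
        ipos = np.asarray(indel_positions)
        total += float(model.indel_rate * (depth[ipos - 1] > 0).sum())
    return total * correction


@dataclass
class FractionRegression:
    slope: float
    slope_p: float
    predictions: pd.DataFrame  # age, fit, ci_lo, ci_hi
    dispersion: float


def fit_fraction_regression(
    fractions: pd.DataFrame,
    value_col: str = "observed_fraction",
    age_col: str = "age_years",
    predict_ages: tuple[float, ...] = (30.0, 70.0),
) -> FractionRegression:
    """Quasibinomial regression of a cell fraction on age.

    A binomial-family GLM with freely estimated (Pearson) dispersion, the
    standard way to regress overdispersed fractions; point predictions and
    95% CIs are returned at the requested ages.
    """
    y = fractions[value_col].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise DataError("fractions must lie in [0, 1]")
    age = fractions[age_col].to_numpy(dtype=float)
    X = sm.add_constant(age)
    if np.all(y == 0):
        logger.warning("all-zero fractions; degenerate fit reported")
        preds = pd.DataFrame(
            {"age": predict_ages, "fit": 0.0, "ci_lo": 0.0, "ci_hi": 0.0}
        )
        return FractionRegression(0.0, 1.0, preds, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
    Xp = sm.add_constant(np.asarray(predict_ages, dtype=float), has_constant="add")
    pred = fit.get_prediction(Xp).summary_frame(alpha=0.05)
    preds = pd.DataFrame(
        {
            "age": predict_ages,
            "fit": pred["mean"].to_numpy(),
            "ci_lo": pred["mean_ci_lower"].to_numpy(),
            "ci_hi": pred["mean_ci_upper"].to_numpy(),
        }
    )
    return FractionRegression(
        float(fit.params[1]), float(fit.pvalues[1]), preds, float(fit.scale)
    )


@dataclass
class BurdenDecomposition:
    total_disease: float
    expected_neutral: float
    driver_explained: float
    unexplained: float
    per_gene: pd.Series | None = None


def decompose_burden(
    obs_disease: pd.Series,
    exp_disease: pd.Series,
    obs_driver_disease: pd.Series,
    exp_driver_disease: pd.Series,
    per_gene: pd.Series | None = None,
) -> BurdenDecomposition:
    """Split the cohort disease fraction into expected / driver / unexplained.

    All inputs are per-sample series aligned on sample id.  The
    driver-explained portion is the observed sum-of-VAF of variants that
    are both likely-disease and likely-driver minus their neutral
    expectation (floored at zero per sample), so the three components are
    disjoint and sum to the total by construction.
    """
    idx = obs_disease.index
    total = float(obs_disease.mean())
    expected = float(exp_disease.reindex(idx).mean())
    excess = (
        obs_driver_disease.reindex(idx).fillna(0.0)
        - exp_driver_disease.reindex(idx).fillna(0.0)
    ).clip(lower=0.0)
    driver = float(excess.mean())
    return BurdenDecomposition(
        total_disease=total,
        expected_neutral=expected,
        driver_explained=driver,
        unexplained=total - expected - driver,
        per_gene=per_gene,
    )


def per_gene_contributions(
    variants: pd.DataFrame,
    n_samples: int,
    label_cols: tuple[str, ...] = ("likely_disease", "likely_driver"),
) -> pd.Series:
    """Cohort-mean sum-of-VAF of disease/driver variants, per gene, ranked."""
    sel = pd.Series(False, index=variants.index)
    for col in label_cols:
        sel |= variants[col].fillna(False).astype(bool)
    sub = variants.loc[sel & variants["gene_id"].notna()].copy()
    sub["vaf"] = sub["mutant_duplex_reads"] / sub["site_duplex_coverage"]
    contrib = sub.groupby("gene_id")["vaf"].sum() / n_samples
    return contrib.sort_values(ascending=False)


def phenotype_associations(
    outcomes: pd.DataFrame,
    meta: pd.DataFrame,
    predictors: tuple[str, ...] = ("age_years", "bmi", "pack_years", "drink_years"),
) -> pd.DataFrame:
    """Gaussian GLMs of mutation outcomes on phenotype covariates.

    One model per outcome column: outcome ~ age + BMI + pack-years +
    drink-years; coefficient p-values are Benjamini-Hochberg adjusted
    across every (outcome, predictor) test performed.  Constant covariates
    are dropped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    df = outcomes.merge(meta, on="sample_id")
    usable = []
    for p in predictors:
        if df[p].nunique(dropna=True) <= 1:
            logger.warning("predictor %s is constant; dropped", p)
        else:
            usable.append(p)
    rows = []
    for outcome in outcomes.columns.drop("sample_id"):
        sub = df.dropna(subset=[outcome, *usable])
        X = sm.add_constant(sub[list(usable)].astype(float))
        fit = sm.GLM(
            sub[outcome].astype(float), X, family=sm.families.Gaussian()
        ).fit()
        for p in usable:
            rows.append(
                {
                    "outcome": outcome,
                    "predictor": p,
                    "coef": float(fit.params[p]),
                    "p": float(fit.pvalues[p]),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
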