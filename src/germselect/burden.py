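"""Mutation burdens, age regressions and mutational-signature exposures.

Burdens are corrected for the trinucleotide composition of the duplex-covered
territory relative to the full genome, so that datasets targeting different
regions are comparable.  Per-cell burdens use 2,861,326,455 mappable haploid
base pairs (doubled for diploid blood).  Age trends are fitted with a linear
mixed model with a per-individual random slope (maximum likelihood, not
REML), with 95% bands from parametric bootstrap over an age grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm

from .context import channel96, channel96_labels, trinuc32_codes, trinuc32_of_channel, BASES
from .coverage import CoverageTrack
from .qc import DataError
from .reference import ReferenceBundle
from .simulate import HAPLOID_GENOME_BP

logger = logging.getLogger(__name__)

AGE_GRID = np.arange(14, 85)


@dataclass
class BurdenEstimate:
    sample_id: str
    n_snv: int
    n_indel: int
    duplex_bp: int
    rate_raw: float
    rate_corrected: float
    per_cell: float


@dataclass
class RegressionFit:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    model_kind: str
    ages: np.ndarray = field(default_factory=lambda: AGE_GRID.copy())
    prediction: np.ndarray | None = None
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None


def genome_trinuc32_freqs(ref: ReferenceBundle) -> np.ndarray:
    """Pyrimidine-collapsed trinucleotide frequencies of the full genome."""
    codes = trinuc32_codes(ref.trinuc64)
    counts = np.bincount(codes[codes >= 0], minlength=32).astype(float)
    return counts / counts.sum()


def _covered_trinuc32_totals(ref: ReferenceBundle, depth: np.ndarray) -> np.ndarray:
    codes = trinuc32_codes(ref.trinuc64)
    ok = codes >= 0
    return np.bincount(codes[ok], weights=depth[ok], minlength=32)


def composition_corrected_rate(
    n_by_class: np.ndarray, L_by_class: np.ndarray, genome_freqs: np.ndarray
) -> float:
    """sum_c f_c * (n_c / L_c), skipping empty classes and renormalizing f.

    Classes with calls but no covered territory are a data error.
    """
    n = np.asarray(n_by_class, dtype=float)
    L = np.asarray(L_by_class, dtype=float)
    f = np.asarray(genome_freqs, dtype=float)
    if np.any((L == 0) & (n > 0)):
        raise DataError("mutation calls in a trinucleotide class with zero coverage")
    usable = L > 0
    fw = f[usable] / f[usable].sum()
    return float(np.sum(fw * n[usable] / L[usable]))


def corrected_burden(
    variants: pd.DataFrame,
    coverage: CoverageTrack,
    ref: ReferenceBundle,
    sample_id: str,
    tissue: str = "sperm",
    genome_context_freqs: np.ndarray | None = None,
) -> BurdenEstimate:
    """Trinucleotide-composition-corrected burden for one sample.

    rate_corrected = sum_c f_c * (n_c / L_c) over the 32 pyrimidine-strand
    trinucleotide classes, where n_c are SNV calls in class c, L_c the
    duplex-covered bases of class c and f_c the genome frequency of c.
    Classes with no covered territory and no calls are skipped and the
    genome weights renormalized; covered calls without territory are a data
    error.
    """
    f = genome_context_freqs if genome_context_freqs is not None else genome_trinuc32_freqs(ref)
    depth = coverage.depths[sample_id].astype(float)
    L = _covered_trinuc32_totals(ref, depth)

    mine = variants[variants["sample_id"] == sample_id]
    snvs = mine[mine["vartype"] == "snv"]
    codes = trinuc32_codes(ref.trinuc64[snvs["pos"].to_numpy(dtype=int) - 1])
    n = np.bincount(codes[codes >= 0], minlength=32).astype(float)

    rate_corrected = composition_corrected_rate(n, L, f)

    duplex_bp = int(depth.sum())
    n_snv = int(len(snvs))
    rate_raw = n_snv / duplex_bp if duplex_bp else np.nan
    ploidy = 2 if tissue == "blood" else 1
    return BurdenEstimate(
        sample_id=sample_id,
        n_snv=n_snv,
        n_indel=int((mine["vartype"] == "indel").sum()),
        duplex_bp=duplex_bp,
        rate_raw=rate_raw,
        rate_corrected=rate_corrected,
        per_cell=rate_corrected * HAPLOID_GENOME_BP * ploidy,
    )


def cohort_burdens(
    variants: pd.DataFrame,
    coverage: CoverageTrack,
    ref: ReferenceBundle,
    meta: pd.DataFrame,
    genome_context_freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Burden table (one row per sample), joined with donor/age metadata."""
    f = genome_context_freqs if genome_context_freqs is not None else genome_trinuc32_freqs(ref)
    rows = []
    for _, m in meta.iterrows():
        est = corrected_burden(variants, coverage, ref, m["sample_id"], m["tissue"], f)
        rows.append(vars(est))
    out = pd.DataFrame(rows)
    return out.merge(
        meta[["sample_id", "donor_id", "tissue", "age_years"]], on="sample_id"
    )


def singleton_fraction(variants: pd.DataFrame) -> float:
    """Percentage of variants supported by exactly one duplex molecule."""
    if not len(variants):
        return np.nan
    return 100.0 * float((variants["mutant_duplex_reads"] == 1).mean())


def fit_burden_regression(
    data: pd.DataFrame,
    value_col: str = "per_cell",
    age_col: str = "age_years",
    group_col: str = "donor_id",
    n_boot: int = 1000,
    age_grid: np.ndarray = AGE_GRID,
    seed: int = 0,
) -> RegressionFit:
    """Mixed-model age regression of a per-sample burden.

    burden ~ age with a per-individual random slope (no random intercept),
    fitted by maximum likelihood; individuals with multiple time points
    share a slope deviation.  If every individual contributes a single
    sample, or the random-slope variance degenerates, the fit falls back to
    ordinary least squares with a logged note.  95% prediction bands come
    from ``n_boot`` parametric bootstrap replicates over ``age_grid``
    (``n_boot=0`` skips the bands).
    """
    df = data.dropna(subset=[value_col, age_col]).reset_index(drop=True)
    if df[group_col].nunique() < 3:
        raise ValueError("need at least 3 individuals")
    y = df[value_col].to_numpy(dtype=float)
    age = df[age_col].to_numpy(dtype=float)
    X = sm.add_constant(age)

    multi = df.groupby(group_col).size().max() > 1
    mixed = None
    re_scale = float(np.mean(age))  # conditions the variance-component search
    if multi:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                mixed = sm.MixedLM(
                    y, X, groups=df[group_col], exog_re=(age / re_scale)[:, None]
                ).fit(reml=False)
                if (
                    not np.isfinite(mixed.bse[1])
                    or float(np.asarray(mixed.cov_re)[0, 0]) <= 0
                ):
                    mixed = None
            except Exception:  # singular fits on degenerate data
                mixed = None
    if mixed is not None:
        intercept, slope = mixed.params[0], mixed.params[1]
        se = mixed.bse[1]
        kind = "mixed_random_slope"
        var_u = float(np.asarray(mixed.cov_re)[0, 0]) / re_scale**2
        var_e = float(mixed.scale)
    else:
        if multi:
            logger.info("random-slope variance degenerate; falling back to OLS")
        else:
            logger.warning("single-sample donors only; using OLS")
        ols = sm.OLS(y, X).fit()
        intercept, slope = ols.params[0], ols.params[1]
        se = ols.bse[1]
        kind = "gaussian_glm"
        var_u = 0.0
        var_e = float(ols.scale)

    ci = (slope - 1.96 * se, slope + 1.96 * se)
    fit = RegressionFit(float(slope), (float(ci[0]), float(ci[1])), float(intercept), kind)
    fit.ages = np.asarray(age_grid)
    fit.prediction = intercept + slope * fit.ages

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = df[group_col].to_numpy()
        uniq = np.unique(groups)
        preds = np.empty((n_boot, len(fit.ages)))
        for b in range(n_boot):
            u = rng.normal(0.0, np.sqrt(var_u), size=len(uniq))
            u_by = dict(zip(uniq, u))
            y_star = (
                intercept
                + slope * age
                + np.array([u_by[g] for g in groups]) * age
                + rng.normal(0.0, np.sqrt(var_e), size=len(age))
            )
            b_fit = sm.OLS(y_star, X).fit()
            preds[b] = b_fit.params[0] + b_fit.params[1] * fit.ages
        fit.band_lo = np.percentile(preds, 2.5, axis=0)
        fit.band_hi = np.percentile(preds, 97.5, axis=0)
    return fit


def blood_sperm_ratio(burdens: pd.DataFrame) -> pd.Series:
    """Per-donor fold difference of blood vs sperm per-bp-per-year rates.

    Multiple time points within a tissue are averaged first; donors missing
    either tissue are omitted.
    """
    df = burdens.copy()
    df["rate_per_year"] = df["rate_corrected"] / df["age_years"]
    per = df.groupby(["donor_id", "tissue"])["rate_per_year"].mean().unstack()
    if "blood" not in per.columns or "sperm" not in per.columns:
        return pd.Series(dtype=float, name="blood_sperm_ratio")
    ratio = (per["blood"] / per["sperm"]).dropna()
    ratio.name = "blood_sperm_ratio"
    return ratio


def spectrum_96(
    variants: pd.DataFrame,
    ref: ReferenceBundle,
    coverage: CoverageTrack,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """96-channel SNV spectrum, raw and trinucleotide-normalized.

    The normalized channel multiplies the raw count by f_c/g_c, the
    genome-vs-covered-territory abundance ratio of the channel's
    trinucleotide, so spectra from territories with skewed composition are
    comparable with genome-wide expectations.  Raw counts sum exactly to
    the SNV count.
    """
    snvs = variants[variants["vartype"] == "snv"]
    if sample_ids is not None:
        snvs = snvs[snvs["sample_id"].isin(sample_ids)]
    raw = np.zeros(96)
    if len(snvs):
        pos = snvs["pos"].to_numpy(dtype=int)
        tri = ref.trinuc64[pos - 1]
        alt = np.array([BASES.index(a) for a in snvs["alt"]])
        ok = tri >= 0
        ch = channel96(tri[ok], alt[ok])
        raw = np.bincount(ch, minlength=96).astype(float)

    depth = coverage.total(sample_ids)
    g = _covered_trinuc32_totals(ref, depth)
    g = g / g.sum()
    f = genome_trinuc32_freqs(ref)
    t32 = trinuc32_of_channel()
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(g[t32] > 0, f[t32] / g[t32], 0.0)
    return pd.DataFrame(
        {"channel": channel96_labels(), "raw": raw, "normalized": raw * factor}
    )


@dataclass
class SignatureExposure:
    signatures: list[str]
    weights: np.ndarray  # proportions, sum to 1
    counts: np.ndarray  # fitted mutation counts per signature
    residual: float


def load_signature_catalog() -> pd.DataFrame:
    """Packaged synthetic 3-signature catalog (96 channels x signatures).

    The columns are synthetic stand-ins shaped like the ageing germline
    signatures: a CpG-deamination-like signature (SBS1-like), a flat
    clock-like signature (SBS5-like) and a third blood-associated shape
    (SBS19-like).  They are NOT the COSMIC vectors.
    """
    with resources.files("germselect.data").joinpath(
        "synthetic_sbs_catalog.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="channel")


def fit_signature_exposures(
    spectrum: np.ndarray | pd.Series,
    catalog: pd.DataFrame,
) -> SignatureExposure:
    """Non-negative least-squares exposure fit of a 96-channel spectrum."""
    y = np.asarray(spectrum, dtype=float)
    if y.shape[0] != catalog.shape[0]:
        raise ValueError("spectrum and catalog channel counts differ")
    A = catalog.to_numpy(dtype=float)
    colsums = A.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-6):
        raise ValueError("catalog columns must be probability vectors summing to 1")
    w, rnorm = scipy.optimize.nnls(A, y)
    total = w.sum()
    props = w / total if total > 0 else np.zeros_like(w)
    return SignatureExposure(
        signatures=list(catalog.columns),
        weights=props,
        counts=w,
        residual=float(rnorm),
    )
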