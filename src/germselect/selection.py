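"""Context-dependent neutral mutation model and dN/dS selection inference.

The neutral model assigns every possible substitution a rate per duplex
molecule from its strand-specific trinucleotide class (192 classes), with
the eight CpG-transition classes further stratified by the site's
methylation level (two extra multiplicative coefficients per class, 16
parameters, 208 in total).  Rates are maximum-likelihood estimates from
putatively neutral calls (synonymous + noncoding) with the base-pair-level
duplex coverage as exposure: within each stratum the Poisson MLE is simply
calls / summed coverage, which is exactly the log-linear coverage-offset
fit for this saturated parameterization.  An optional pentanucleotide
adjustment multiplies rates by an empirical-Bayes factor per 5-mer stratum,
shrunk toward 1.

Selection is quantified as the ratio omega of observed to model-expected
nonsynonymous mutations: per gene (likelihood-ratio tests per impact class
with a gamma-shrunk per-gene rate nuisance), globally or per gene set
(profile-likelihood CIs), per site (Poisson recurrence tail tests) and per
external-recurrence bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .annotate import (
    IMPACT_NAMES,
    MIS,
    NON,
    SPL,
    SYN,
    annotate_variants,
    coding_site_alt_table,
)
from .context import class192, cpg_transition_mask192
from .coverage import CoverageTrack
from .reference import ReferenceBundle

logger = logging.getLogger(__name__)

CPG_MASK_192 = cpg_transition_mask192()
N_METH_BINS = 3
DEFAULT_METH_EDGES = (1.0 / 3.0, 2.0 / 3.0)

CLASS_COLS = ["syn", "mis", "non", "spl", "ind"]
IMPACT_TO_COL = {SYN: "syn", MIS: "mis", NON: "non", SPL: "spl"}
NAME_TO_COL = {
    "synonymous": "syn",
    "missense": "mis",
    "nonsense": "non",
    "essential_splice": "spl",
    "frameshift_indel": "ind",
    "inframe_indel": "ind",
}


@dataclass
class ContextRateModel:
    """Fitted neutral rates per (trinucleotide class, methylation bin)."""

    rates_by_bin: np.ndarray  # (192, N_METH_BINS) per duplex molecule
    indel_rate: float  # per duplex bp (any indel)
    use_methylation: bool = True
    meth_edges: tuple[float, float] = DEFAULT_METH_EDGES
    penta_factors: np.ndarray | None = None  # (4**5 * 3,) multiplicative
    global_scale: float = 1.0
    n_empty_classes: int = 0

    @property
    def base_rates(self) -> np.ndarray:
        """The 192 per-class rates at the lowest methylation bin."""
        return self.rates_by_bin[:, 0]

    @property
    def methylation_coefficients(self) -> np.ndarray:
        """(8, 2) multiplicative mid/high-bin coefficients for CpG transitions."""
        cpg = np.flatnonzero(CPG_MASK_192)
        base = self.rates_by_bin[cpg, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                base[:, None] > 0, self.rates_by_bin[cpg, 1:] / base[:, None], np.nan
            )

    @property
    def n_parameters(self) -> int:
        extra = 2 * int(CPG_MASK_192.sum()) if self.use_methylation else 0
        return 192 + extra


class ModelError(RuntimeError):
    pass


def _meth_bins(model_edges, meth_values: np.ndarray) -> np.ndarray:
    return np.digitize(meth_values, model_edges)


def _strata(
    ref: ReferenceBundle,
    pos: np.ndarray,
    alt_code: np.ndarray,
    use_methylation: bool,
    meth_edges,
) -> tuple[np.ndarray, np.ndarray]:
    """(class192, meth bin) of each (pos, alt); bin 0 for non-CpG classes."""
    tri = ref.trinuc64[pos - 1]
    ok = tri >= 0
    cls = np.zeros(pos.shape, dtype=np.int64)
    cls[ok] = class192(tri[ok], alt_code[ok])
    cls[~ok] = -1
    bins = np.zeros(pos.shape, dtype=np.int64)
    if use_methylation:
        cpg = ok & CPG_MASK_192[np.clip(cls, 0, None)]
        bins[cpg] = _meth_bins(meth_edges, ref.methylation_by_position[pos[cpg] - 1])
    return cls, bins


def _neutral_universe(ref: ReferenceBundle) -> tuple[np.ndarray, np.ndarray]:
    """(pos, alt_code) of all neutral site-alts: synonymous + noncoding."""
    coding = coding_site_alt_table(ref)
    in_gene = np.zeros(ref.length, dtype=bool)
    if len(coding):
        in_gene[coding["pos"].to_numpy() - 1] = True
    nc_pos = np.flatnonzero(~in_gene) + 1
    nc_pos = nc_pos[(nc_pos > 2) & (nc_pos < ref.length - 1)]  # context resolvable
    tri = ref.trinuc64[nc_pos - 1]
    refb = (tri // 4) % 4
    from .annotate import ALT_TABLE

    nc_alts = ALT_TABLE[refb]  # (n, 3)
    pos = np.concatenate([np.repeat(nc_pos, 3)])
    alt = np.concatenate([nc_alts.reshape(-1)])
    if len(coding):
        syn = coding[coding["impact"] == SYN]
        pos = np.concatenate([pos, syn["pos"].to_numpy()])
        alt = np.concatenate([alt, syn["alt_code"].to_numpy(dtype=np.int64)])
    return pos.astype(np.int64), alt.astype(np.int64)


def noncoding_positions(ref: ReferenceBundle) -> np.ndarray:
    coding = coding_site_alt_table(ref)
    in_gene = np.zeros(ref.length, dtype=bool)
    if len(coding):
        in_gene[coding["pos"].to_numpy() - 1] = True
    return np.flatnonzero(~in_gene) + 1


def fit_context_rate_model(
    variants: pd.DataFrame,
    ref: ReferenceBundle,
    coverage: CoverageTrack,
    sample_ids: list[str] | None = None,
    use_methylation: bool = True,
    use_pentanucleotide: bool = False,
    meth_edges: tuple[float, float] = DEFAULT_METH_EDGES,
    penta_shrinkage: float = 5.0,
) -> ContextRateModel:
    """Fit the duplex-coverage-aware neutral mutation-rate model.

    ``variants`` must carry ``impact_class`` (see
    :func:`germselect.annotate.annotate_variants`); only synonymous and
    noncoding SNV calls inform the substitution rates, and noncoding indels
    inform the single genome-wide indel rate.
    """
    if "impact_class" not in variants.columns:
        variants = annotate_variants(variants, ref)
    cov_total = coverage.total(sample_ids)

    pos_u, alt_u = _neutral_universe(ref)
    cls_u, bin_u = _strata(ref, pos_u, alt_u, use_methylation, meth_edges)
    strat_u = cls_u * N_METH_BINS + bin_u
    exposure = np.bincount(
        strat_u, weights=cov_total[pos_u - 1], minlength=192 * N_METH_BINS
    )

    if sample_ids is not None:
        variants = variants[variants["sample_id"].isin(sample_ids)]
    neutral = variants[
        (variants["vartype"] == "snv")
        & variants["impact_class"].isin(["synonymous", "noncoding"])
    ]
    neutral = neutral[(neutral["pos"] > 2) & (neutral["pos"] < ref.length - 1)]
    pos_n = neutral["pos"].to_numpy(dtype=np.int64)
    alt_n = np.array([_b(a) for a in neutral["alt"]], dtype=np.int64)
    cls_n, bin_n = _strata(ref, pos_n, alt_n, use_methylation, meth_edges)
    counts = np.bincount(
        cls_n * N_METH_BINS + bin_n, minlength=192 * N_METH_BINS
    ).astype(float)

    exposure = exposure.reshape(192, N_METH_BINS)
    counts = counts.reshape(192, N_METH_BINS)

    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(exposure > 0, counts / exposure, np.nan)
    # bins without exposure fall back to the class-pooled rate
    class_exp = exposure.sum(axis=1)
    class_cnt = counts.sum(axis=1)
    pooled = np.where(class_exp > 0, class_cnt / np.maximum(class_exp, 1e-300), 0.0)
    empty = ~np.isfinite(rates)
    rates[empty] = np.broadcast_to(pooled[:, None], rates.shape)[empty]
    n_empty = int((class_exp == 0).sum())
    if n_empty:
        logger.info("%d trinucleotide classes without neutral exposure", n_empty)
    if not use_methylation:
        rates = np.broadcast_to(pooled[:, None], rates.shape).copy()

    # single genome-wide indel rate from noncoding territory
    nc = noncoding_positions(ref)
    nc_cov = cov_total[nc - 1].sum()
    nc_ind = variants[
        (variants["vartype"] == "indel") & (variants["impact_class"] == "noncoding")
    ]
    if nc_cov > 0:
        indel_rate = len(nc_ind) / nc_cov
    else:
        tot = cov_total.sum()
        indel_rate = (variants["vartype"] == "indel").sum() / tot if tot else 0.0
        logger.warning("no noncoding territory; indel rate fitted genome-wide")

    model = ContextRateModel(
        rates_by_bin=rates,
        indel_rate=float(indel_rate),
        use_methylation=use_methylation,
        meth_edges=meth_edges,
        n_empty_classes=n_empty,
    )

    if use_pentanucleotide:
        model.penta_factors = _fit_penta_factors(
            model, ref, cov_total, pos_u, alt_u, pos_n, alt_n, penta_shrinkage
        )
    return model


def _b(base: str) -> int:
    return "ACGT".index(base)


def _fit_penta_factors(
    model, ref, cov_total, pos_u, alt_u, pos_n, alt_n, shrinkage
) -> np.ndarray:
    """Observed/expected per 5-mer stratum, shrunk toward 1."""
    rate_u = site_alt_rates(model, ref, pos_u, alt_u)
    penta_u = ref.penta1024[pos_u - 1]
    refb = (ref.trinuc64[pos_u - 1] // 4) % 4
    rank_u = np.where(alt_u > refb, alt_u - 1, alt_u)
    ok = penta_u >= 0
    strat = penta_u[ok] * 3 + rank_u[ok]
    expected = np.bincount(
        strat, weights=rate_u[ok] * cov_total[pos_u[ok] - 1], minlength=1024 * 3
    )

    penta_n = ref.penta1024[pos_n - 1]
    refb_n = (ref.trinuc64[pos_n - 1] // 4) % 4
    rank_n = np.where(alt_n > refb_n, alt_n - 1, alt_n)
    okn = penta_n >= 0
    observed = np.bincount(
        penta_n[okn] * 3 + rank_n[okn], minlength=1024 * 3
    ).astype(float)

    return (observed + shrinkage) / (expected + shrinkage)


def site_alt_rates(
    model: ContextRateModel,
    ref: ReferenceBundle,
    pos: np.ndarray,
    alt_code: np.ndarray,
) -> np.ndarray:
    """Model rate per duplex molecule for arbitrary (pos, alt) arrays."""
    pos = np.asarray(pos, dtype=np.int64)
    alt_code = np.asarray(alt_code, dtype=np.int64)
    cls, bins = _strata(ref, pos, alt_code, model.use_methylation, model.meth_edges)
    rate = np.zeros(pos.shape, dtype=float)
    ok = cls >= 0
    rate[ok] = model.rates_by_bin[cls[ok], bins[ok]]
    if model.penta_factors is not None:
        penta = ref.penta1024[pos - 1]
        refb = (ref.trinuc64[pos - 1] // 4) % 4
        rank = np.where(alt_code > refb, alt_code - 1, alt_code)
        okp = ok & (penta >= 0)
        rate[okp] *= model.penta_factors[penta[okp] * 3 + rank[okp]]
    return rate * model.global_scale


def expected_gene_counts(
    model: ContextRateModel,
    ref: ReferenceBundle,
    gene,
    cov_total: np.ndarray,
) -> dict[str, float]:
    """Expected mutation count per impact class for one gene.

    For every (site, alt) in the gene's CDS and essential splice sites the
    expectation is rate(context, methylation) x cohort duplex coverage;
    class sums are returned together with the indel expectation
    (indel rate x summed CDS coverage).
    """
    from .annotate import enumerate_gene_site_alts

    tab = enumerate_gene_site_alts(ref, gene)
    rate = site_alt_rates(
        model, ref, tab["pos"].to_numpy(), tab["alt_code"].to_numpy(dtype=np.int64)
    )
    contrib = rate * cov_total[tab["pos"].to_numpy() - 1]
    out = {}
    imp = tab["impact"].to_numpy()
    for code, col in IMPACT_TO_COL.items():
        out[col] = float(contrib[imp == code].sum())
    out["ind"] = float(model.indel_rate * cov_total[gene.cds_positions - 1].sum())
    return out


def expected_counts_by_gene(
    model: ContextRateModel,
    ref: ReferenceBundle,
    coverage: CoverageTrack,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    cov_total = coverage.total(sample_ids)
    rows = []
    for gene in ref.genes:
        e = expected_gene_counts(model, ref, gene, cov_total)
        e["gene_id"] = gene.gene_id
        rows.append(e)
    df = pd.DataFrame(rows).set_index("gene_id")
    return df.rename(columns={c: f"exp_{c}" for c in CLASS_COLS})


def observed_counts_by_gene(
    variants: pd.DataFrame, ref: ReferenceBundle
) -> pd.DataFrame:
    """Observed mutation counts per gene and impact class."""
    if "impact_class" not in variants.columns:
        variants = annotate_variants(variants, ref)
    coding = variants[variants["impact_class"] != "noncoding"].copy()
    coding["col"] = coding["impact_class"].map(NAME_TO_COL)
    counts = (
        coding.groupby(["gene_id", "col"]).size().unstack(fill_value=0)
    )
    out = pd.DataFrame(
        0, index=[g.gene_id for g in ref.genes], columns=[f"n_{c}" for c in CLASS_COLS]
    )
    for col in CLASS_COLS:
        if col in counts.columns:
            out.loc[counts.index, f"n_{col}"] = counts[col]
    out.index.name = "gene_id"
    return out


def selection_tables(
    variants: pd.DataFrame,
    ref: ReferenceBundle,
    model: ContextRateModel,
    coverage: CoverageTrack,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed and expected per-gene count tables for a sample subset.

    Restricting the samples restricts both the calls and the coverage
    exposure, so dN/dS can be computed for e.g. age tertiles.
    """
    sub = variants
    if sample_ids is not None:
        sub = variants[variants["sample_id"].isin(sample_ids)]
    obs = observed_counts_by_gene(sub, ref)
    exp = expected_counts_by_gene(model, ref, coverage, sample_ids)
    return obs, exp


def estimate_theta(n_syn: np.ndarray, exp_syn: np.ndarray) -> float:
    """Negative-binomial overdispersion of synonymous counts across genes.

    Returns ``np.inf`` (the Poisson limit) when the NB fit degenerates,
    with a logged note.
    """
    n = np.asarray(n_syn, dtype=float)
    e = np.asarray(exp_syn, dtype=float)
    ok = e > 0
    n, e = n[ok], e[ok]
    if len(n) < 5 or n.sum() == 0:
        logger.info("too few genes for overdispersion estimation; using Poisson")
        return np.inf

    def nll(params):
        log_s, log_theta = params
        mu = np.exp(log_s) * e
        theta = np.exp(log_theta)
        p = theta / (theta + mu)
        return -scipy.stats.nbinom.logpmf(n, theta, p).sum()

    res = scipy.optimize.minimize(
        nll, x0=[0.0, np.log(10.0)], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    theta = float(np.exp(res.x[1]))
    # keep the NB only if it beats the Poisson limit decisively; otherwise
    # the dispersion is indistinguishable from sampling noise
    s_hat = n.sum() / e.sum()
    ll_pois = float(scipy.stats.poisson.logpmf(n, s_hat * e).sum())
    lrt = 2.0 * (-res.fun - ll_pois)
    if not res.success or theta > 1e4 or lrt < scipy.stats.chi2.ppf(0.95, 1):
        logger.info("NB dispersion fit degenerate (theta=%.3g); using Poisson", theta)
        return np.inf
    return theta


def _pen_loglik_t(n_fixed: float, e_fixed: float, theta: float) -> tuple[float, float]:
    """Profiled gene-rate nuisance t and its penalized log-likelihood part."""
    if np.isinf(theta):
        return 1.0, 0.0
    t = (n_fixed + theta) / (e_fixed + theta)
    return t, theta * (np.log(t) - t)


def _loglik(n: np.ndarray, e: np.ndarray, t: float, omega: np.ndarray) -> float:
    mu = omega * t * e
    ok = mu > 0
    ll = float(np.sum(n[ok] * np.log(mu[ok]) - mu[ok]))
    ll -= float(np.sum(mu[~ok]))  # zero means contribute nothing
    if np.any((n > 0) & ~ok):
        return -np.inf
    return ll


def _lrt(n: np.ndarray, e: np.ndarray, theta: float, free_groups: list[list[int]]):
    """Penalized LRT of free omega groups vs all-neutral, with profiled t."""
    idx_free = [g for g in free_groups if e[g].sum() > 0]
    dof = len(idx_free)
    flat_free = [i for g in idx_free for i in g]
    fixed = [i for i in range(len(n)) if i not in flat_free]

    # alternative: omega free per group (shared within a group), t profiled on
    # the fixed classes; a free group's profiled contribution is
    # ng*log(ng/Eg) - ng + sum_c n_c*log(E_c), independent of t
    if np.isinf(theta):
        t1 = 1.0
        pen1 = 0.0
    else:
        t1 = (n[fixed].sum() + theta) / (e[fixed].sum() + theta)
        pen1 = theta * (np.log(t1) - t1)
    ll1 = _loglik(n[fixed], e[fixed], t1, np.ones(len(fixed))) + pen1
    for g in idx_free:
        ng, eg = n[g].sum(), e[g].sum()
        if ng > 0:
            ll1 += ng * np.log(ng / eg) - ng
            ll1 += float(np.sum(n[g][n[g] > 0] * np.log(e[g][n[g] > 0])))

    if np.isinf(theta):
        t0 = 1.0
        pen0 = 0.0
    else:
        t0 = (n.sum() + theta) / (e.sum() + theta)
        pen0 = theta * (np.log(t0) - t0)
    ll0 = _loglik(n, e, t0, np.ones(len(n))) + pen0

    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(scipy.stats.chi2.sf(stat, dof)) if dof else 1.0
    return stat, p, dof


def gene_dnds_test(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    theta: float | None = None,
) -> pd.DataFrame:
    """Per-gene selection tests.

    ``observed``/``expected`` are the outputs of
    :func:`observed_counts_by_gene` / :func:`expected_counts_by_gene`.
    Gene-to-gene mutation-rate variation is absorbed by a gamma-shrunk
    per-gene rate factor with cohort-estimated dispersion ``theta``
    (estimated from synonymous counts when not given).  Reported tests:
    ``p_gene`` (missense + truncating + indel jointly), ``p_mis``,
    ``p_trunc`` (nonsense + essential splice) and ``p_ind``, each with a
    Benjamini-Hochberg ``q``.
    """
    df = observed.join(expected, how="inner")
    if theta is None:
        theta = estimate_theta(df["n_syn"].to_numpy(), df["exp_syn"].to_numpy())
    if theta is not None and not np.isinf(theta) and theta <= 0:
        raise ModelError("theta must be positive")

    results = []
    for gene_id, row in df.iterrows():
        n = np.array([row[f"n_{c}"] for c in CLASS_COLS], dtype=float)
        e = np.array([row[f"exp_{c}"] for c in CLASS_COLS], dtype=float)
        if e.sum() == 0:
            continue  # gene without coverage is excluded from testing
        bad = (e == 0) & (n > 0)
        if bad.any():
            logger.warning(
                "%s: %d calls in classes without expectation; excluded",
                gene_id, int(n[bad].sum()),
            )
            n[bad] = 0
        t_hat, _ = _pen_loglik_t(n[0], e[0], theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            omegas = np.where(e[1:] > 0, n[1:] / (t_hat * e[1:]), np.nan)
        _, p_gene, _ = _lrt(n, e, theta, [[1], [2, 3], [4]])
        _, p_mis, _ = _lrt(n, e, theta, [[1]])
        _, p_trunc, _ = _lrt(n, e, theta, [[2, 3]])
        _, p_ind, _ = _lrt(n, e, theta, [[4]])
        results.append(
            {
                "gene_id": gene_id,
                **{f"n_{c}": int(row[f"n_{c}"]) for c in CLASS_COLS},
                **{f"exp_{c}": float(row[f"exp_{c}"]) for c in CLASS_COLS},
                "omega_mis": omegas[0],
                "omega_non": omegas[1],
                "omega_spl": omegas[2],
                "omega_ind": omegas[3],
                "p_gene": p_gene,
                "p_mis": p_mis,
                "p_trunc": p_trunc,
                "p_ind": p_ind,
            }
        )
    out = pd.DataFrame(results).set_index("gene_id")
    for col in ["p_gene", "p_mis", "p_trunc", "p_ind"]:
        out[col.replace("p_", "q_")] = multipletests(out[col], method="fdr_bh")[1]
    out.attrs["theta"] = theta
    return out


@dataclass
class GlobalDndsResult:
    omega: float
    ci: tuple[float, float]
    n_obs: float
    n_exp: float
    n_syn: float
    exp_syn: float

    @property
    def excess_fraction(self) -> float:
        """Fraction of observed nonsynonymous mutations attributable to selection."""
        return excess_fraction_from_omega(self.omega)

    @property
    def excess_fraction_ci(self) -> tuple[float, float]:
        return tuple(excess_fraction_from_omega(w) for w in self.ci)

    @property
    def excess_count(self) -> float:
        return self.excess_fraction * self.n_obs


def excess_fraction_from_omega(omega: float) -> float:
    """1 - 1/omega: the driver share of observed nonsynonymous mutations."""
    return 1.0 - 1.0 / omega


def global_dnds_from_counts(
    n_syn: float, exp_syn: float, n_nonsyn: float, exp_nonsyn: float
) -> GlobalDndsResult:
    """Profile-likelihood dN/dS from aggregated counts.

    Model: S ~ Poisson(t E_S), N ~ Poisson(omega t E_N); the synonymous
    rate nuisance t is profiled out.
    """
    if exp_nonsyn <= 0 or exp_syn <= 0:
        raise ModelError("zero expected counts; omega undefined")
    S, N = float(n_syn), float(n_nonsyn)

    def prof_ll(omega):
        t = (S + N) / (exp_syn + omega * exp_nonsyn)
        ll = 0.0
        if S > 0:
            ll += S * np.log(t * exp_syn)
        ll -= t * exp_syn
        if N > 0:
            ll += N * np.log(omega * t * exp_nonsyn)
        ll -= omega * t * exp_nonsyn
        return ll

    if S == 0 or N == 0:
        omega_hat = np.nan if S == 0 else 0.0
        return GlobalDndsResult(omega_hat, (0.0, np.inf), N, exp_nonsyn, S, exp_syn)

    omega_hat = (N / exp_nonsyn) / (S / exp_syn)
    target = prof_ll(omega_hat) - scipy.stats.chi2.ppf(0.95, 1) / 2.0

    def g(w):
        return prof_ll(w) - target

    lo_bound, hi_bound = omega_hat, omega_hat
    step = omega_hat
    while g(max(lo_bound - step, 1e-9)) > 0 and lo_bound > 1e-9:
        lo_bound = max(lo_bound - step, 1e-9)
    while g(hi_bound + step) > 0:
        hi_bound += step
        step *= 2
    lo = (
        scipy.optimize.brentq(g, max(lo_bound - step, 1e-9), omega_hat)
        if lo_bound > 1e-9
        else 0.0
    )
    hi = scipy.optimize.brentq(g, omega_hat, hi_bound + step)
    return GlobalDndsResult(
        float(omega_hat), (float(lo), float(hi)), N, exp_nonsyn, S, exp_syn
    )


NONSYN_COLS = ["mis", "non", "spl"]


def global_dnds(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    genes: list[str] | None = None,
) -> GlobalDndsResult:
    """Cohort-level dN/dS over an optional gene subset (SNV classes only)."""
    df = observed.join(expected, how="inner")
    if genes is not None:
        df = df.loc[df.index.intersection(genes)]
    if not len(df):
        raise ModelError("empty gene scope")
    S = df["n_syn"].sum()
    ES = df["exp_syn"].sum()
    N = sum(df[f"n_{c}"].sum() for c in NONSYN_COLS)
    EN = sum(df[f"exp_{c}"].sum() for c in NONSYN_COLS)
    return global_dnds_from_counts(S, ES, N, EN)


def geneset_dnds(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Global dN/dS restricted to each named gene set."""
    rows = []
    for name, genes in gene_sets.items():
        genes_present = observed.index.intersection(genes)
        if not len(genes_present):
            logger.warning("gene set %s matches no genes; skipped", name)
            continue
        res = global_dnds(observed, expected, list(genes_present))
        rows.append(
            {
                "set": name,
                "n_genes": len(genes_present),
                "omega": res.omega,
                "ci_lo": res.ci[0],
                "ci_hi": res.ci[1],
                "n_obs_nonsyn": res.n_obs,
                "exp_nonsyn": res.n_exp,
            }
        )
    return pd.DataFrame(rows)


def sitewise_hotspot_test(
    variants: pd.DataFrame,
    ref: ReferenceBundle,
    model: ContextRateModel,
    coverage: CoverageTrack,
    sample_ids: list[str] | None = None,
    site_universe: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Poisson recurrence test per (site, alt).

    Recurrence is the number of independent samples carrying the identical
    change.  lambda is the model rate at the site times the summed duplex
    coverage of the cohort (or sample subset).  In exome-wide mode the FDR
    universe is every covered site-alt with observed recurrence >= 1; with
    ``site_universe`` (pos/ref/alt) the tests are restricted to, and
    corrected within, that list.
    """
    snvs = variants[variants["vartype"] == "snv"]
    if sample_ids is not None:
        snvs = snvs[snvs["sample_id"].isin(sample_ids)]
    rec = (
        snvs.groupby(["pos", "ref", "alt"])["sample_id"]
        .nunique()
        .rename("observed")
        .reset_index()
    )
    if site_universe is not None:
        uni = site_universe[["pos", "ref", "alt"]].drop_duplicates()
        rec = uni.merge(rec, on=["pos", "ref", "alt"], how="left").fillna(
            {"observed": 0}
        )
    cov_total = coverage.total(sample_ids)
    pos = rec["pos"].to_numpy(dtype=np.int64)
    alt = np.array([_b(a) for a in rec["alt"]], dtype=np.int64)
    lam = site_alt_rates(model, ref, pos, alt) * cov_total[pos - 1]
    covered = lam > 0
    rec = rec.loc[covered].reset_index(drop=True)
    lam = lam[covered]
    obs = rec["observed"].to_numpy(dtype=int)
    p = scipy.stats.poisson.sf(obs - 1, lam)
    p = np.where(obs == 0, 1.0, p)
    rec["lam"] = lam
    rec["p"] = p
    rec["q"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
    return rec.sort_values("p").reset_index(drop=True)


def recurrence_enrichment(
    variants: pd.DataFrame,
    ref: ReferenceBundle,
    model: ContextRateModel,
    coverage: CoverageTrack,
    recurrence_bins: pd.DataFrame,
    sample_ids: list[str] | None = None,
    default_bin: str = "unobserved",
) -> pd.DataFrame:
    """Observed/expected mutation-rate ratio per external-recurrence bin.

    ``recurrence_bins`` maps site-alts (pos/ref/alt/bin) to bins; every
    other possible coding substitution falls in ``default_bin``.  The ratio
    carries an exact Poisson 95% CI; bins with zero expectation are
    reported with missing ratios.
    """
    coding = coding_site_alt_table(ref)
    cov_total = coverage.total(sample_ids)
    pos = coding["pos"].to_numpy(dtype=np.int64)
    alt = coding["alt_code"].to_numpy(dtype=np.int64)
    lam = site_alt_rates(model, ref, pos, alt) * cov_total[pos - 1]

    from .context import BASES

    key = pd.DataFrame(
        {
            "pos": pos,
            "ref": [BASES[c] for c in coding["ref_code"]],
            "alt": [BASES[c] for c in alt],
            "lam": lam,
        }
    )
    key = key.merge(
        recurrence_bins[["pos", "ref", "alt", "bin"]], on=["pos", "ref", "alt"], how="left"
    )
    key["bin"] = key["bin"].fillna(default_bin)

    snvs = variants[variants["vartype"] == "snv"]
    if sample_ids is not None:
        snvs = snvs[snvs["sample_id"].isin(sample_ids)]
    obs_key = snvs.merge(
        key[["pos", "ref", "alt", "bin"]].drop_duplicates(),
        on=["pos", "ref", "alt"],
        how="inner",
    )

    rows = []
    for bin_name, grp in key.groupby("bin"):
        e = float(grp["lam"].sum())
        o = int((obs_key["bin"] == bin_name).sum())
        if e <= 0:
            rows.append({"bin": bin_name, "observed": o, "expected": e,
                         "ratio": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        lo = scipy.stats.chi2.ppf(0.025, 2 * o) / 2.0 if o > 0 else 0.0
        hi = scipy.stats.chi2.ppf(0.975, 2 * o + 2) / 2.0
        rows.append(
            {
                "bin": bin_name,
                "observed": o,
                "expected": e,
                "ratio": o / e,
                "ci_lo": lo / e,
                "ci_hi": hi / e,
            }
        )
    return pd.DataFrame(rows)


def build_selection_gene_table(
    gene_results: pd.DataFrame,
    q_threshold: float = 0.1,
    lof_p_threshold: float = 0.1,
    min_lof_mutations: int = 2,
    activating_overrides: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Significance and mechanism flags consumed by driver labelling.

    A gene is LOF-enriched when nonsense+splice or indel enrichment is
    nominally significant (p_trunc < 0.1 or p_ind < 0.1) with at least two
    LOF mutations, unless listed as an activating override (genes whose
    truncating variants have a restricted, activating repertoire).
    """
    res = gene_results
    n_lof = res["n_non"] + res["n_spl"] + res["n_ind"]
    lof = (
        ((res["p_trunc"] < lof_p_threshold) | (res["p_ind"] < lof_p_threshold))
        & (n_lof >= min_lof_mutations)
        & ~res.index.isin(activating_overrides)
    )
    return pd.DataFrame(
        {
            "gene_id": res.index,
            "significant": (res["q_gene"] < q_threshold).to_numpy(),
            "lof_enriched": lof.to_numpy(),
        }
    ).reset_index(drop=True)
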