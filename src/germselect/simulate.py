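"""Synthetic sperm-cohort generator.

Emulates the statistical structure of duplex-sequenced bulk sperm under
user-controlled ground truth so that every downstream estimator can be
validated by parameter recovery:

* context-dependent neutral SNV rates with elevated C>T at methylated CpGs,
* linear accumulation of mutations with age (default 1.67 SNVs per year per
  haploid genome, the male-germline rate),
* negative-binomial site-to-site duplex coverage variation,
* positive selection as a multiplicative fold on nonsynonymous rates in
  configured driver genes and hotspot sites,
* indels at a single genome-wide rate with sizes up to 21 bp,
* optional cross-sample DNA contamination for QC tests.

Mutant duplex-molecule counts are Poisson per (site, alternate allele,
sample); clonal lineage structure is not simulated -- at the rates and
depths emulated here essentially every variant is seen in a single molecule,
so counts are sufficient statistics for all downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotate import MIS, NON, SPL, enumerate_gene_site_alts
from .context import (
    BASES,
    SENSE_CODONS,
    class192_decompose,
    cpg_transition_mask192,
    decode,
    COMP_CODE,
    N_CLASSES_192,
)
from .coverage import CoverageTrack
from .reference import ConfigurationError, GeneModel, ReferenceBundle

logger = logging.getLogger(__name__)

#: mappable base pairs of a haploid human cell
HAPLOID_GENOME_BP = 2_861_326_455

#: default neutral SNV rate: 1.67 substitutions per year per haploid genome
DEFAULT_SNV_RATE_PER_BP_YEAR = 1.67 / HAPLOID_GENOME_BP

#: default indel:SNV rate ratio (0.10 vs 1.67 indels/SNVs per year)
DEFAULT_INDEL_FRACTION = 0.10 / 1.67

#: C>T rate multiplier at a fully methylated CpG
DEFAULT_CPG_METH_FACTOR = 6.0

#: strand-symmetric relative rates of the six pyrimidine substitution types,
#: loosely shaped like an ageing germline spectrum (C>T and T>C dominated)
DEFAULT_SUBSTITUTION_WEIGHTS = {
    "C>A": 0.10,
    "C>G": 0.08,
    "C>T": 0.42,
    "T>A": 0.07,
    "T>C": 0.25,
    "T>G": 0.08,
}

MAX_INDEL_SIZE = 21
_FRAMESHIFT_SIZES = np.array([s for s in range(1, MAX_INDEL_SIZE + 1) if s % 3], dtype=np.int64)
_INFRAME_SIZES = np.array([s for s in range(1, MAX_INDEL_SIZE + 1) if s % 3 == 0], dtype=np.int64)


@dataclass
class SelectionConfig:
    """Ground-truth generating parameters of a synthetic cohort."""

    neutral_rate_per_bp_year: float = DEFAULT_SNV_RATE_PER_BP_YEAR
    indel_rate_fraction: float = DEFAULT_INDEL_FRACTION
    driver_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    hotspots: dict[tuple[int, str], float] = field(default_factory=dict)
    cpg_meth_factor: float = DEFAULT_CPG_METH_FACTOR
    substitution_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_WEIGHTS)
    )
    age_offset_years: float = 0.0

    def __post_init__(self):
        if self.neutral_rate_per_bp_year <= 0:
            raise ConfigurationError("neutral rate must be positive")
        if self.indel_rate_fraction < 0:
            raise ConfigurationError("indel fraction must be non-negative")
        if self.cpg_meth_factor < 1:
            raise ConfigurationError("CpG methylation factor must be >= 1")
        for gene, (fm, fl) in self.driver_genes.items():
            if fm < 1 or fl < 1:
                raise ConfigurationError(f"{gene}: selection folds must be >= 1")
        for site, fold in self.hotspots.items():
            if fold < 1:
                raise ConfigurationError(f"hotspot {site}: fold must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hotspots"] = {f"{p}:{a}": f for (p, a), f in self.hotspots.items()}
        return d


def generate_toy_genome(
    n_genes: int,
    exons_per_gene: int,
    exon_len: int,
    seed: int,
    intron_len: int = 100,
    intergenic_len: int = 200,
    chrom: str = "chr_toy",
    total_length: int | None = None,
    meth_high_fraction: float = 0.7,
) -> ReferenceBundle:
    """Generate a deterministic single-chromosome toy genome.

    Genes are laid out left to right, each with ``exons_per_gene`` exons of
    ``exon_len`` bp separated by ``intron_len`` bp introns and flanked by
    ``intergenic_len`` bp of intergenic sequence.  Every CDS is built from
    random sense codons, so it translates without internal stop codons by
    construction.  CpG methylation is drawn from a bimodal Beta mixture
    (most CpGs highly methylated, a minority nearly unmethylated), the shape
    seen in testis whole-genome bisulfite data.
    """
    if n_genes < 1:
        raise ConfigurationError("need at least one gene")
    if exon_len < 30:
        raise ConfigurationError("exon_len must be >= 30")
    if (exons_per_gene * exon_len) % 3 != 0:
        raise ConfigurationError("total CDS length must be divisible by 3")
    if intron_len < 5:
        raise ConfigurationError("introns must be >= 5 bp to host splice sites")

    rng = np.random.default_rng(seed)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    length = intergenic_len + n_genes * (gene_span + intergenic_len)
    if total_length is not None:
        if total_length < length:
            raise ConfigurationError(
                f"genes need {length} bp but chromosome is {total_length} bp"
            )
        length = total_length

    seq = rng.integers(0, 4, size=length, dtype=np.uint8)

    genes = []
    cursor = intergenic_len + 1  # 1-based start of the next gene
    for gi in range(n_genes):
        exons = []
        pos = cursor
        for _ in range(exons_per_gene):
            exons.append((pos, pos + exon_len - 1))
            pos += exon_len + intron_len
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(f"G{gi:04d}", strand, exons)
        n_codons = gene.cds_length // 3
        codons = rng.choice(SENSE_CODONS, size=n_codons)
        cds = np.stack([(codons // 16) % 4, (codons // 4) % 4, codons % 4], axis=1)
        cds = cds.reshape(-1).astype(np.uint8)
        if strand == "-":
            genomic = COMP_CODE[cds][::-1]
        else:
            genomic = cds
        seq[gene.cds_positions - 1] = genomic
        genes.append(gene)
        cursor += gene_span + intergenic_len

    bundle = ReferenceBundle(chrom, seq, genes)
    cpg = bundle.find_cpg_positions()
    high = rng.random(cpg.size) < meth_high_fraction
    meth = np.where(
        high,
        rng.beta(20.0, 2.0, size=cpg.size),
        rng.beta(2.0, 20.0, size=cpg.size),
    )
    return ReferenceBundle(chrom, seq, genes, cpg, meth)


def generate_cohort_metadata(
    n_donors: int,
    seed: int,
    tissue: str = "sperm",
    age_range: tuple[float, float] = (24.0, 75.0),
    time_points: int = 1,
    time_point_gap: float = 12.0,
) -> pd.DataFrame:
    """Sample metadata table for a synthetic cohort (one row per sample)."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_donors):
        donor = f"D{d:03d}"
        age0 = rng.uniform(*age_range)
        for tp in range(time_points):
            age = age0 + tp * time_point_gap
            rows.append(
                {
                    "sample_id": f"{donor}_{tissue}_t{tp}",
                    "donor_id": donor,
                    "tissue": tissue,
                    "age_years": round(float(age), 1),
                    "time_point": tp,
                    "sperm_count_per_ml": float(rng.lognormal(np.log(5e7), 0.6))
                    if tissue == "sperm"
                    else np.nan,
                    "contamination_alpha": float(rng.uniform(0.0, 0.001)),
                    "bmi": round(float(rng.normal(26.0, 3.5)), 1),
                    "pack_years": round(float(max(0.0, rng.exponential(6.0) - 4.0)), 1),
                    "drink_years": round(float(max(0.0, rng.exponential(30.0) - 10.0)), 1),
                    "twin_pair_id": pd.NA,
                }
            )
    return pd.DataFrame(rows)


def simulate_coverage(
    ref: ReferenceBundle,
    meta: pd.DataFrame,
    mean_dx: float,
    dispersion: float = 20.0,
    seed: int = 0,
) -> CoverageTrack:
    """Negative-binomial per-base duplex depth per sample.

    ``dispersion`` is the gamma shape of the gamma-Poisson mixture: the
    site depth has mean ``mean_dx`` and variance ``mean_dx +
    mean_dx**2 / dispersion``.  ``dispersion=np.inf`` gives Poisson depth.
    """
    if mean_dx <= 0:
        raise ConfigurationError("mean_dx must be positive")
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    depths = {}
    for sid in meta["sample_id"]:
        if np.isinf(dispersion):
            lam = np.full(ref.length, float(mean_dx))
        else:
            lam = rng.gamma(dispersion, mean_dx / dispersion, size=ref.length)
        depths[sid] = rng.poisson(lam).astype(np.int32)
    return CoverageTrack(ref.chrom, ref.length, depths)


def _class_weights(cfg: SelectionConfig) -> np.ndarray:
    """Relative rate per 192 class from the substitution-type weights."""
    tri, refb, altb = class192_decompose(np.arange(N_CLASSES_192))
    w = np.zeros(N_CLASSES_192)
    comp = COMP_CODE.astype(np.int64)
    for i in range(N_CLASSES_192):
        r, a = int(refb[i]), int(altb[i])
        if r in (0, 2):  # purine reference: read the pyrimidine strand
            r, a = int(comp[r]), int(comp[a])
        w[i] = cfg.substitution_weights[f"{BASES[r]}>{BASES[a]}"]
    return w


def _site_alt_rates(ref: ReferenceBundle, cfg: SelectionConfig):
    """Per-(site, alt) neutral rates per (duplex molecule x year).

    Returns (rates, cls) where ``rates`` has shape (L, 3) and ``cls`` is the
    192-class index of each cell; edge sites (no trinucleotide) carry rate 0.
    The rates are normalized so that the average per-bp total across the
    chromosome equals ``cfg.neutral_rate_per_bp_year``.
    """
    tri = ref.trinuc64
    valid = tri >= 0
    cls = np.where(valid[:, None], tri[:, None] * 3 + np.arange(3)[None, :], 0)
    w192 = _class_weights(cfg)
    W = np.where(valid[:, None], w192[cls], 0.0)

    cpg_cls = cpg_transition_mask192()
    meth = ref.methylation_by_position
    mult = np.where(
        cpg_cls[cls], 1.0 + (cfg.cpg_meth_factor - 1.0) * meth[:, None], 1.0
    )
    W = W * mult

    mean_total = W.sum() / max(valid.sum(), 1)
    scale = cfg.neutral_rate_per_bp_year / mean_total
    return W * scale, cls


def _fold_matrix(ref: ReferenceBundle, cfg: SelectionConfig) -> np.ndarray:
    """Multiplicative selection fold per (site, alt)."""
    folds = np.ones((ref.length, 3), dtype=np.float64)
    for gene_id, (fold_mis, fold_lof) in cfg.driver_genes.items():
        gene = ref.gene(gene_id)
        tab = enumerate_gene_site_alts(ref, gene)
        sel = tab["impact"].isin([MIS, NON, SPL])
        tab = tab[sel]
        col = np.where(
            tab["alt_code"].to_numpy() > tab["ref_code"].to_numpy(),
            tab["alt_code"].to_numpy() - 1,
            tab["alt_code"].to_numpy(),
        )
        f = np.where(tab["impact"].to_numpy() == MIS, fold_mis, fold_lof)
        folds[tab["pos"].to_numpy() - 1, col] *= f
    for (pos, alt), fold in cfg.hotspots.items():
        refb = int(ref.seq_codes[pos - 1])
        altb = BASES.index(alt)
        if altb == refb:
            raise ConfigurationError(f"hotspot {pos}:{alt} equals the reference base")
        col = altb - 1 if altb > refb else altb
        folds[pos - 1, col] *= fold
    return folds


def simulate_cohort_variants(
    ref: ReferenceBundle,
    coverage: CoverageTrack,
    cfg: SelectionConfig,
    meta: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort variant table under the generating model.

    For every (site, alternate allele, sample) the number of mutant duplex
    molecules is Poisson with mean ``neutral_rate x methylation_effect x
    age x coverage x selection_fold``; rows are emitted for every non-zero
    draw, with ground-truth driver flags retained.
    """
    rng = np.random.default_rng(seed)
    rates, _ = _site_alt_rates(ref, cfg)
    folds = _fold_matrix(ref, cfg)
    R = rates * folds  # (L, 3) per molecule-year

    sample_ids = meta["sample_id"].tolist()
    ages = (meta["age_years"].to_numpy(dtype=float) + cfg.age_offset_years)
    age_by_sample = dict(zip(sample_ids, ages))

    uncovered = int(np.sum(coverage.total(sample_ids) == 0))
    if uncovered:
        logger.info("skipping %d sites with zero cohort coverage", uncovered)

    exposure = coverage.weighted_total(age_by_sample)  # (L,)
    M = R * exposure[:, None]
    records = _draw_snv_events(rng, ref, coverage, meta, M, folds)
    records += _draw_indel_events(rng, ref, coverage, meta, cfg, exposure)

    columns = [
        "sample_id", "chrom", "pos", "ref", "alt", "vartype",
        "mutant_duplex_reads", "site_duplex_coverage", "is_driver_truth",
    ]
    if not records:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(records, columns=columns)
    df = (
        df.groupby(
            ["sample_id", "chrom", "pos", "ref", "alt", "vartype", "is_driver_truth"],
            as_index=False,
        )
        .agg(
            mutant_duplex_reads=("mutant_duplex_reads", "sum"),
            site_duplex_coverage=("site_duplex_coverage", "first"),
        )
    )
    df = df[columns].sort_values(["sample_id", "pos", "alt"]).reset_index(drop=True)
    return df


def _draw_snv_events(rng, ref, coverage, meta, M, folds):
    sample_ids = meta["sample_id"].tolist()
    ages = meta["age_years"].to_numpy(dtype=float)
    m_site = M.sum(axis=1)
    n_events = rng.poisson(m_site)
    sites = np.flatnonzero(n_events)
    records = []
    for s in sites:
        k = int(n_events[s])
        p_alt = M[s] / m_site[s]
        ref_code = int(ref.seq_codes[s])
        alt_bases = [b for b in range(4) if b != ref_code]
        covs = np.array([coverage.depths[sid][s] for sid in sample_ids], dtype=float)
        w = covs * ages
        tot = w.sum()
        if tot <= 0:
            continue
        p_sample = w / tot
        for _ in range(k):
            col = rng.choice(3, p=p_alt)
            si = rng.choice(len(sample_ids), p=p_sample)
            sid = sample_ids[si]
            records.append(
                (
                    sid,
                    ref.chrom,
                    int(s + 1),
                    BASES[ref_code],
                    BASES[alt_bases[col]],
                    "snv",
                    1,
                    int(coverage.depths[sid][s]),
                    bool(folds[s, col] > 1.0),
                )
            )
    return records


def _driver_cds_mask(ref: ReferenceBundle, cfg: SelectionConfig) -> tuple[np.ndarray, np.ndarray]:
    """(is_driver_cds, fold_lof) per position for indel selection."""
    mask = np.zeros(ref.length, dtype=bool)
    fold = np.ones(ref.length, dtype=np.float64)
    for gene_id, (_, fold_lof) in cfg.driver_genes.items():
        gene = ref.gene(gene_id)
        idx = gene.cds_positions - 1
        mask[idx] = True
        fold[idx] = fold_lof
    return mask, fold


def _draw_indel_events(rng, ref, coverage, meta, cfg, exposure):
    if cfg.indel_rate_fraction == 0:
        return []
    sample_ids = meta["sample_id"].tolist()
    ages = meta["age_years"].to_numpy(dtype=float)
    rate_ind = cfg.neutral_rate_per_bp_year * cfg.indel_rate_fraction
    _, fold_lof = _driver_cds_mask(ref, cfg)
    p_fs = len(_FRAMESHIFT_SIZES) / MAX_INDEL_SIZE
    p_if = 1.0 - p_fs
    m_site = rate_ind * exposure * (p_fs * fold_lof + p_if)
    n_events = rng.poisson(m_site)
    sites = np.flatnonzero(n_events)
    records = []
    for s in sites:
        covs = np.array([coverage.depths[sid][s] for sid in sample_ids], dtype=float)
        w = covs * ages
        tot = w.sum()
        if tot <= 0:
            continue
        p_sample = w / tot
        prob_fs = (p_fs * fold_lof[s]) / (p_fs * fold_lof[s] + p_if)
        for _ in range(int(n_events[s])):
            si = rng.choice(len(sample_ids), p=p_sample)
            sid = sample_ids[si]
            frameshift = rng.random() < prob_fs
            size = int(rng.choice(_FRAMESHIFT_SIZES if frameshift else _INFRAME_SIZES))
            pos = int(s + 1)
            anchor = BASES[int(ref.seq_codes[s])]
            if rng.random() < 0.5 and pos + size <= ref.length:  # deletion
                ref_str = anchor + decode(ref.seq_codes[pos : pos + size])
                alt_str = anchor
            else:  # insertion
                ref_str = anchor
                alt_str = anchor + decode(
                    rng.integers(0, 4, size=size, dtype=np.uint8)
                )
            records.append(
                (
                    sid,
                    ref.chrom,
                    pos,
                    ref_str,
                    alt_str,
                    "indel",
                    1,
                    int(coverage.depths[sid][s]),
                    bool(fold_lof[s] > 1.0 and frameshift),
                )
            )
    return records


def simulate_toy_cohort(
    seed: int,
    n_genes: int = 50,
    exons_per_gene: int = 4,
    exon_len: int = 300,
    n_donors: int = 50,
    mean_dx: float = 20_000.0,
    dispersion: float = 20.0,
    cfg: SelectionConfig | None = None,
    tissue: str = "sperm",
    time_points: int = 1,
    total_length: int | None = None,
):
    """Generate a complete toy cohort (reference, metadata, coverage, calls).

    The default geometry (50 genes x 1,200 bp CDS) with deep duplex
    coverage concentrates a study-scale mutation yield onto a desk-scale
    territory: cumulative duplex coverage takes the place of the exome's
    breadth, leaving per-gene mutation counts comparable to a deeply
    sequenced targeted panel.  Returns ``(ref, meta, coverage, variants,
    cfg)``; sub-seeds are derived deterministically from ``seed``.
    """
    cfg = cfg or SelectionConfig()
    ref = generate_toy_genome(
        n_genes, exons_per_gene, exon_len, seed, total_length=total_length
    )
    meta = generate_cohort_metadata(
        n_donors, seed + 1_000_003, tissue=tissue, time_points=time_points
    )
    coverage = simulate_coverage(ref, meta, mean_dx, dispersion, seed + 2_000_003)
    variants = simulate_cohort_variants(ref, coverage, cfg, meta, seed + 3_000_003)
    return ref, meta, coverage, variants, cfg


def inject_contamination(
    variants: pd.DataFrame,
    donor_genotypes: pd.DataFrame,
    alpha: float,
    coverage: CoverageTrack,
    target_samples: list[str],
    seed: int = 0,
    source_sample: str | None = None,
    source_vaf: float = 0.45,
) -> pd.DataFrame:
    """Spike cross-sample germline alleles into a variant table.

    ``donor_genotypes`` has columns pos/ref/alt describing the contaminating
    donor's inherited variants.  Each target sample gains mutant molecules
    Binomial(coverage, alpha) at every germline site, emulating a foreign
    DNA fraction of ``alpha``.  If ``source_sample`` is given, that sample
    (the contaminating donor's own library, present in the same batch) gains
    the germline alleles at heterozygous-like VAF, which is what the
    cohort-wide decontamination step detects.
    """
    if not 0 <= alpha < 0.5:
        raise ConfigurationError("alpha must be in [0, 0.5)")
    if alpha == 0 and source_sample is None:
        return variants.copy()
    rng = np.random.default_rng(seed)
    rows = []

    def _spike(sid: str, frac: float):
        for _, g in donor_genotypes.iterrows():
            cov = int(coverage.depths[sid][int(g["pos"]) - 1])
            if cov == 0:
                continue
            m = int(rng.binomial(cov, frac))
            if m > 0:
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": coverage.chrom,
                        "pos": int(g["pos"]),
                        "ref": g["ref"],
                        "alt": g["alt"],
                        "vartype": "snv" if len(str(g["ref"])) == len(str(g["alt"])) == 1 else "indel",
                        "mutant_duplex_reads": m,
                        "site_duplex_coverage": cov,
                        "is_driver_truth": False,
                    }
                )

    for sid in target_samples:
        if alpha > 0:
            _spike(sid, alpha)
    if source_sample is not None:
        _spike(source_sample, source_vaf)

    if not rows:
        return variants.copy()
    extra = pd.DataFrame(rows)
    out = pd.concat([variants, extra], ignore_index=True)
    return out.sort_values(["sample_id", "pos", "alt"]).reset_index(drop=True)
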