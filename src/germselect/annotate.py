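"""Variant annotation: coding consequences, sequence contexts, disease labels.

Consequence calls are made codon-by-codon against the single-transcript gene
models, with essential splice sites defined as the first and last two bases
of each intron.  Indels are classified by length modulo 3 and are never
assigned SNV classes.  The disease/driver labelling follows a two-criterion
rule set: ClinVar-style pathogenicity (including a guarded
conflicting-classifications rule) or a highly damaging variant in a
monoallelic "absent gene product" developmental-disorder gene; drivers are
highly damaging variants in LOF-enriched positively selected genes or
members of a significant-hotspot list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import (
    BASES,
    CODON_AA,
    COMP_CODE,
    ContextDescriptor,
    decode,
)
from .reference import GeneModel, ReferenceBundle

# integer impact codes used in vectorized site-alt tables (SNVs only)
SYN, MIS, NON, SPL = 0, 1, 2, 3
IMPACT_NAMES = {SYN: "synonymous", MIS: "missense", NON: "nonsense", SPL: "essential_splice"}
SNV_CLASSES = ["synonymous", "missense", "nonsense", "essential_splice"]
ALL_CLASSES = SNV_CLASSES + ["frameshift_indel", "inframe_indel", "noncoding"]

# the three alternates of each reference base, in base order
ALT_TABLE = np.array([[b for b in range(4) if b != r] for r in range(4)], dtype=np.int64)

_CODON_MULT = np.array([16, 4, 1], dtype=np.int64)


class EdgeError(ValueError):
    """Variant too close to a contig edge to resolve its context."""


@dataclass(frozen=True)
class ConsequenceCall:
    impact_class: str
    gene_id: str | None
    aa_change: str | None = None


def enumerate_gene_site_alts(ref: ReferenceBundle, gene: GeneModel) -> pd.DataFrame:
    """All (site, alternate allele) substitutions in a gene's test territory.

    Returns one row per (CDS or essential-splice position, alt) with columns
    ``pos`` (1-based genomic), ``ref_code``, ``alt_code`` (genomic strand)
    and integer ``impact``.
    """
    cds = gene.coding_sequence(ref.seq_codes).astype(np.int64)
    n = cds.shape[0]
    codon_idx = (cds.reshape(-1, 3) * _CODON_MULT).sum(axis=1)
    aa_ref = CODON_AA[codon_idx]

    pos_in_codon = np.arange(n) % 3
    codon_of = np.arange(n) // 3
    # coding-strand alternates, 3 per position
    alts = ALT_TABLE[cds]  # (n, 3)
    delta = (alts - cds[:, None]) * _CODON_MULT[pos_in_codon][:, None]
    new_codon = codon_idx[codon_of][:, None] + delta
    aa_new = CODON_AA[new_codon]

    impact = np.where(
        aa_new == aa_ref[codon_of][:, None],
        SYN,
        np.where(aa_new == "*", NON, MIS),
    ).astype(np.int8)

    # map coding order to genomic coordinates
    if gene.strand == "-":
        pos_g = gene.cds_positions[::-1]
        ref_g = COMP_CODE[cds]
        alt_g = COMP_CODE[alts]
    else:
        pos_g = gene.cds_positions
        ref_g = cds
        alt_g = alts

    rows = {
        "pos": np.repeat(pos_g, 3),
        "ref_code": np.repeat(ref_g, 3).astype(np.int8),
        "alt_code": alt_g.reshape(-1).astype(np.int8),
        "impact": impact.reshape(-1),
    }

    spl = gene.splice_positions
    if spl.size:
        ref_s = ref.seq_codes[spl - 1].astype(np.int64)
        rows = {
            "pos": np.concatenate([rows["pos"], np.repeat(spl, 3)]),
            "ref_code": np.concatenate([rows["ref_code"], np.repeat(ref_s, 3).astype(np.int8)]),
            "alt_code": np.concatenate([rows["alt_code"], ALT_TABLE[ref_s].reshape(-1).astype(np.int8)]),
            "impact": np.concatenate([rows["impact"], np.full(spl.size * 3, SPL, dtype=np.int8)]),
        }

    df = pd.DataFrame(rows)
    df["gene_id"] = gene.gene_id
    return df


def coding_site_alt_table(ref: ReferenceBundle) -> pd.DataFrame:
    """Concatenated site-alt table over all genes (genes do not overlap)."""
    if not ref.genes:
        return pd.DataFrame(columns=["pos", "ref_code", "alt_code", "impact", "gene_id"])
    return pd.concat(
        [enumerate_gene_site_alts(ref, g) for g in ref.genes], ignore_index=True
    )


def classify_consequence(variant: pd.Series | dict, gene: GeneModel, ref: ReferenceBundle) -> ConsequenceCall:
    """Classify a single variant against one gene model."""
    pos = int(variant["pos"])
    if str(variant.get("vartype", "snv")) == "indel":
        size = abs(len(str(variant["alt"])) - len(str(variant["ref"])))
        if _indel_touches(variant, gene):
            cls = "inframe_indel" if size % 3 == 0 else "frameshift_indel"
            return ConsequenceCall(cls, gene.gene_id)
        return ConsequenceCall("noncoding", None)

    if pos in set(gene.splice_positions.tolist()):
        return ConsequenceCall("essential_splice", gene.gene_id)

    cds_pos = gene.cds_positions
    hit = np.searchsorted(cds_pos, pos)
    if hit >= cds_pos.size or cds_pos[hit] != pos:
        return ConsequenceCall("noncoding", None)

    # coding index of the site
    i = hit if gene.strand == "+" else cds_pos.size - 1 - hit
    cds = gene.coding_sequence(ref.seq_codes).astype(np.int64)
    alt_code = np.int64(BASES.index(str(variant["alt"])))
    if gene.strand == "-":
        alt_code = np.int64(COMP_CODE[alt_code])
    codon_start = (i // 3) * 3
    old = cds[codon_start : codon_start + 3].copy()
    new = old.copy()
    new[i % 3] = alt_code
    aa_old = CODON_AA[int((old * _CODON_MULT).sum())]
    aa_new = CODON_AA[int((new * _CODON_MULT).sum())]
    aa_change = f"{aa_old}{i // 3 + 1}{aa_new}"
    if aa_new == aa_old:
        return ConsequenceCall("synonymous", gene.gene_id, aa_change)
    if aa_new == "*":
        return ConsequenceCall("nonsense", gene.gene_id, aa_change)
    return ConsequenceCall("missense", gene.gene_id, aa_change)


def _indel_touches(variant, gene: GeneModel) -> bool:
    pos = int(variant["pos"])
    ref_len = len(str(variant["ref"]))
    territory = gene.cds_positions
    if ref_len > 1:  # deletion: bases pos+1 .. pos+ref_len-1 removed
        span = np.arange(pos + 1, pos + ref_len)
        return bool(np.isin(span, territory).any())
    return bool(np.isin(pos, territory))


def extract_context(ref: ReferenceBundle, pos: int, alt: str) -> ContextDescriptor:
    """Strand-collapsed tri/pentanucleotide context of a substitution.

    The mutated base is always reported as a pyrimidine; variants on a
    purine reference base are reverse-complemented.  Methylation is
    attached only when the site is part of a CpG dinucleotide.
    """
    if pos < 3 or pos > ref.length - 2:
        raise EdgeError(f"position {pos} within 2 bp of the contig edge")
    i = pos - 1
    tri = ref.seq_codes[i - 1 : i + 2].astype(np.int64)
    penta = ref.seq_codes[i - 2 : i + 3].astype(np.int64)
    alt_code = np.int64(BASES.index(alt))
    if alt_code == tri[1]:
        raise ValueError("alt equals reference base")
    is_cpg = bool(
        (tri[1] == 1 and tri[2] == 2) or (tri[1] == 2 and tri[0] == 1)
    )  # central C followed by G, or central G preceded by C
    if tri[1] in (0, 2):  # purine centre: collapse to the pyrimidine strand
        tri = COMP_CODE[tri][::-1].astype(np.int64)
        penta = COMP_CODE[penta][::-1].astype(np.int64)
        alt_code = np.int64(COMP_CODE[alt_code])
    meth = float(ref.methylation_by_position[i]) if is_cpg else None
    return ContextDescriptor(
        trinucleotide=decode(tri.astype(np.uint8)),
        pentanucleotide=decode(penta.astype(np.uint8)),
        alt=BASES[int(alt_code)],
        is_cpg=is_cpg,
        methylation_level=meth,
    )


def annotate_variants(variants: pd.DataFrame, ref: ReferenceBundle) -> pd.DataFrame:
    """Attach ``impact_class`` and ``gene_id`` columns to a variant table.

    SNVs are joined against the exhaustive coding site-alt table; indels are
    classified by CDS overlap and length modulo 3; everything else is
    noncoding.  Each variant receives exactly one class.
    """
    out = variants.copy()
    out["impact_class"] = "noncoding"
    out["gene_id"] = pd.NA

    coding = coding_site_alt_table(ref)
    if len(coding):
        snv = out["vartype"] == "snv"
        key = coding.assign(
            alt=[BASES[c] for c in coding["alt_code"]],
            impact_class=[IMPACT_NAMES[i] for i in coding["impact"]],
        )[["pos", "alt", "impact_class", "gene_id"]]
        merged = out.loc[snv, ["pos", "alt"]].merge(
            key, on=["pos", "alt"], how="left"
        )
        hit = merged["impact_class"].notna().to_numpy()
        idx = out.index[snv]
        out.loc[idx[hit], "impact_class"] = merged.loc[hit, "impact_class"].to_numpy()
        out.loc[idx[hit], "gene_id"] = merged.loc[hit, "gene_id"].to_numpy()

    indel = out.index[out["vartype"] == "indel"]
    for i in indel:
        row = out.loc[i]
        for gene in ref.genes:
            if row["pos"] < gene.start - 25 or row["pos"] > gene.end + 25:
                continue
            call = classify_consequence(row, gene, ref)
            if call.impact_class != "noncoding":
                out.loc[i, "impact_class"] = call.impact_class
                out.loc[i, "gene_id"] = call.gene_id
                break
    return out


MONOALLELIC_REQUIREMENTS = {
    "monoallelic_autosomal",
    "monoallelic_X_hem",
    "monoallelic_X_het",
    "mitochondrial",
}
DD_CONFIDENCE = {"strong", "definitive", "moderate"}
HIGH_IMPACT = {"nonsense", "essential_splice", "frameshift_indel"}
DAMAGING_SCORE_CUTOFF = 30.0


def variant_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["pos"].astype(str) + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str)
    )


def label_disease_and_driver(
    variants: pd.DataFrame,
    clinvar_table: pd.DataFrame | None,
    dd_gene_table: pd.DataFrame | None,
    score_table: pd.DataFrame | None,
    selection_gene_table: pd.DataFrame | None,
    hotspot_list: pd.DataFrame | None,
) -> pd.DataFrame:
    """Apply the likely-disease and likely-driver labelling rules.

    ``variants`` must already carry ``impact_class`` and ``gene_id``.
    Missing annotation tables yield missing (NA) labels, never False.
    """
    out = variants.copy()
    keys = variant_key(out)

    scores = pd.Series(np.nan, index=out.index)
    if score_table is not None and len(score_table):
        lut = score_table.set_index("variant_key")["score"]
        scores = keys.map(lut)
    out["cadd_like_score"] = scores

    damaging = out["impact_class"].isin(HIGH_IMPACT) | (
        (out["impact_class"] == "missense") & (scores > DAMAGING_SCORE_CUTOFF)
    )

    # --- likely disease ---------------------------------------------------
    if clinvar_table is None and dd_gene_table is None:
        out["clinvar_status"] = pd.NA
        out["likely_disease"] = pd.NA
    else:
        clin_patho = pd.Series(False, index=out.index)
        out["clinvar_status"] = pd.NA
        if clinvar_table is not None and len(clinvar_table):
            ct = clinvar_table.set_index("variant_key")
            status = keys.map(ct["clin_sig"])
            out["clinvar_status"] = status
            clin_patho = status.isin(["pathogenic", "likely_pathogenic"])
            if "has_benign_reports" in ct.columns:
                benign = keys.map(ct["has_benign_reports"]).astype("boolean").fillna(True)
                recessive = (
                    keys.map(ct.get("recessive_condition", pd.Series(dtype=bool)))
                    .astype("boolean")
                    .fillna(True)
                )
                conflict_ok = (
                    (status == "conflicting_classifications")
                    & ~benign.astype(bool)
                    & ~recessive.astype(bool)
                )
                clin_patho = clin_patho | conflict_ok
        dd_hit = pd.Series(False, index=out.index)
        if dd_gene_table is not None and len(dd_gene_table):
            dd = dd_gene_table
            mono = dd[
                dd["allelic_requirement"].isin(MONOALLELIC_REQUIREMENTS)
                & dd["confidence"].isin(DD_CONFIDENCE)
                & (dd["mutation_consequence"] == "absent gene product")
            ]["gene_id"]
            dd_hit = out["gene_id"].isin(set(mono)) & damaging
        out["likely_disease"] = (clin_patho.fillna(False) | dd_hit).astype(bool)

    # --- likely driver ----------------------------------------------------
    if selection_gene_table is None and hotspot_list is None:
        out["likely_driver"] = pd.NA
    else:
        drv = pd.Series(False, index=out.index)
        if selection_gene_table is not None and len(selection_gene_table):
            sel = selection_gene_table
            lof_genes = set(
                sel.loc[
                    sel["significant"].astype(bool) & sel["lof_enriched"].astype(bool),
                    "gene_id",
                ]
            )
            drv = out["gene_id"].isin(lof_genes) & damaging
        if hotspot_list is not None and len(hotspot_list):
            hs = set(variant_key(hotspot_list))
            drv = drv | keys.isin(hs)
        out["likely_driver"] = drv.astype(bool)
    return out
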