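"""Sample- and variant-level quality control.

Three gates, mirroring how polyclonal duplex data must be protected from
contamination:

1. sample exclusion: sperm samples need >= 1 million sperm per ml and a
   contamination alpha <= 0.002; blood tolerates alpha up to 0.005.
2. variant-level VAF filtering: in targeted/exome mode true sperm variants
   are essentially private to single molecules, so calls at >= 1% duplex VAF
   are inherited or artefactual and removed.
3. cohort-wide in-silico decontamination: any site carrying a confident
   germline-like call (> 10 duplex molecules and VAF > 0.3) in ANY sample is
   masked in ALL samples, for both calls and coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack

# default thresholds
SPERM_MIN_COUNT_PER_ML = 1e6
ALPHA_SPERM = 0.002
ALPHA_BLOOD = 0.005
VAF_MAX = 0.01
MASK_VAF = 0.3
MASK_READS = 10
MASK_RATIO_MAX = 0.1


@dataclass
class QCThresholds:
    sperm_min_count: float = SPERM_MIN_COUNT_PER_ML
    alpha_sperm: float = ALPHA_SPERM
    alpha_blood: float = ALPHA_BLOOD
    vaf_max: float = VAF_MAX
    mask_vaf: float = MASK_VAF
    mask_reads: int = MASK_READS
    mask_ratio_max: float = MASK_RATIO_MAX
    exclude_indeterminate: bool = True


@dataclass
class QCReport:
    sample_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    masked_passed_ratio: float = 0.0


class DataError(ValueError):
    pass


def filter_samples(
    meta: pd.DataFrame, thresholds: QCThresholds | None = None
) -> list[QCReport]:
    """Apply the sample-level exclusion rules.

    A sample with a missing contamination alpha is flagged indeterminate
    and (by default) not passed.
    """
    thr = thresholds or QCThresholds()
    reports = []
    for _, row in meta.iterrows():
        reasons = []
        tissue = row["tissue"]
        alpha = row.get("contamination_alpha", np.nan)
        if pd.isna(alpha):
            reasons.append("indeterminate_alpha")
            if not thr.exclude_indeterminate:
                reasons = []
        elif tissue == "sperm" and alpha > thr.alpha_sperm:
            reasons.append("high_alpha")
        elif tissue == "blood" and alpha > thr.alpha_blood:
            reasons.append("high_alpha")
        if tissue == "sperm":
            count = row.get("sperm_count_per_ml", np.nan)
            if pd.isna(count):
                if thr.exclude_indeterminate:
                    reasons.append("indeterminate_sperm_count")
            elif count < thr.sperm_min_count:
                reasons.append("low_sperm_count")
        reports.append(QCReport(row["sample_id"], passed=not reasons, reasons=reasons))
    return reports


def qc_report_frame(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "pass": [r.passed for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
            "masked_passed_ratio": [r.masked_passed_ratio for r in reports],
        }
    )


def filter_variants(
    variants: pd.DataFrame,
    vaf_max: float = VAF_MAX,
    masked_sites: np.ndarray | None = None,
) -> pd.DataFrame:
    """Retain variants below the duplex-VAF cap, outside masked sites.

    The VAF cap applies in targeted/exome mode where no matched normal is
    available; a zero-coverage variant row is a data error.
    """
    cov = variants["site_duplex_coverage"].to_numpy(dtype=float)
    if (cov <= 0).any():
        raise DataError("variant row with zero site coverage")
    vaf = variants["mutant_duplex_reads"].to_numpy(dtype=float) / cov
    keep = vaf < vaf_max
    if masked_sites is not None and len(masked_sites):
        keep &= ~variants["pos"].isin(set(np.asarray(masked_sites).tolist())).to_numpy()
    return variants.loc[keep].reset_index(drop=True)


def insilico_decontaminate(
    variants: pd.DataFrame,
    coverage: CoverageTrack,
    mask_reads: int = MASK_READS,
    mask_vaf: float = MASK_VAF,
) -> tuple[np.ndarray, pd.DataFrame, pd.Series, CoverageTrack]:
    """Cohort-wide germline-site masking.

    Any site at which any sample shows more than ``mask_reads`` mutant
    duplex molecules with VAF above ``mask_vaf`` is treated as an inherited
    variant leaking between samples, and is masked across the whole cohort:
    calls at the site are dropped and its coverage is zeroed.

    Returns (masked positions, filtered variants, per-sample masked/passed
    ratio, masked coverage track).  The operation is idempotent.
    """
    cov = variants["site_duplex_coverage"].to_numpy(dtype=float)
    vaf = np.divide(
        variants["mutant_duplex_reads"].to_numpy(dtype=float),
        cov,
        out=np.zeros(len(variants)),
        where=cov > 0,
    )
    germline_like = (variants["mutant_duplex_reads"] > mask_reads) & (vaf > mask_vaf)
    masked_positions = np.unique(variants.loc[germline_like, "pos"].to_numpy())

    masked = variants["pos"].isin(set(masked_positions.tolist()))
    filtered = variants.loc[~masked].reset_index(drop=True)

    n_masked = variants.loc[masked].groupby("sample_id").size()
    n_passed = filtered.groupby("sample_id").size()
    all_samples = variants["sample_id"].unique()
    ratio = (
        n_masked.reindex(all_samples, fill_value=0)
        / n_passed.reindex(all_samples, fill_value=0).replace(0, np.nan)
    ).fillna(np.inf if len(masked_positions) else 0.0)
    ratio.name = "masked_passed_ratio"

    return masked_positions, filtered, ratio, coverage.masked(masked_positions)
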