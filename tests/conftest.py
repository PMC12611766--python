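"""Shared fixtures: small deterministic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import germselect as gs


@pytest.fixture(scope="session")
def small_ref():
    return gs.generate_toy_genome(6, 3, 120, seed=11)


@pytest.fixture(scope="session")
def neutral_cohort():
    """Moderate neutral cohort with the default study-scale rate."""
    ref, meta, cov, variants, cfg = gs.simulate_toy_cohort(
        seed=101, n_genes=20, exons_per_gene=3, exon_len=150,
        n_donors=20, mean_dx=10_000.0,
    )
    annotated = gs.annotate_variants(variants, ref)
    return {"ref": ref, "meta": meta, "coverage": cov,
            "variants": annotated, "cfg": cfg}


@pytest.fixture(scope="session")
def neutral_model(neutral_cohort):
    c = neutral_cohort
    model = gs.fit_context_rate_model(c["variants"], c["ref"], c["coverage"])
    obs = gs.observed_counts_by_gene(c["variants"], c["ref"])
    exp = gs.expected_counts_by_gene(model, c["ref"], c["coverage"])
    return {"model": model, "obs": obs, "exp": exp}


@pytest.fixture(scope="session")
def driver_cohort():
    """Cohort with strong LOF selection in two genes."""
    cfg = gs.SelectionConfig(
        driver_genes={"G0000": (1.0, 20.0), "G0001": (1.0, 20.0)}
    )
    ref, meta, cov, variants, _ = gs.simulate_toy_cohort(
        seed=202, n_genes=12, exons_per_gene=3, exon_len=150,
        n_donors=20, mean_dx=20_000.0, cfg=cfg,
    )
    annotated = gs.annotate_variants(variants, ref)
    return {"ref": ref, "meta": meta, "coverage": cov,
            "variants": annotated, "cfg": cfg}


def make_variant_table(rows: list[dict]) -> pd.DataFrame:
    base = {
        "sample_id": "S1",
        "chrom": "chr_toy",
        "pos": 100,
        "ref": "A",
        "alt": "T",
        "vartype": "snv",
        "mutant_duplex_reads": 1,
        "site_duplex_coverage": 100,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


@pytest.fixture
def flat_coverage():
    def _make(ref, depth, sample_ids=("S1",)):
        return gs.CoverageTrack(
            ref.chrom, ref.length,
            {sid: np.full(ref.length, depth, dtype=np.int32) for sid in sample_ids},
        )

    return _make
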