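"""Sum-of-VAF cell fractions, expected fractions and burden decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import germselect as gs
from germselect.disease import expected_cell_fraction, expected_class_fraction
from germselect.qc import DataError
from germselect.selection import ContextRateModel, N_METH_BINS

from conftest import make_variant_table


def labelled_table(rows):
    df = make_variant_table(rows)
    if "impact_class" not in df.columns:
        df["impact_class"] = [r.get("impact_class", "synonymous") for r in rows]
    return df


class TestSumVaf:
    def test_three_singletons_at_coverage_100(self):
        """Three mutations, one molecule each at 100x: fraction 0.03 and
        reported as a percentage (3% of cells)."""
        rows = [{"pos": 10 + i, "impact_class": "synonymous"} for i in range(3)]
        out = gs.sum_vaf_fraction(labelled_table(rows), "synonymous",
                                  impact_classes=["synonymous"])
        assert out.loc[0, "observed_fraction"] == pytest.approx(0.03, abs=0)
        assert out.loc[0, "n_contributing_variants"] == 3
        est = gs.CellFractionEstimate("S1", "synonymous", 0.03, 3)
        assert est.reported_as == "percent"
        assert gs.CellFractionEstimate("S1", "x", 1.2, 9).reported_as == "mean_count"

    def test_empty_class_reports_zero(self):
        rows = [{"pos": 10, "impact_class": "synonymous"}]
        out = gs.sum_vaf_fraction(labelled_table(rows), "missense",
                                  impact_classes=["missense"], sample_ids=["S1"])
        assert out.loc[0, "observed_fraction"] == 0.0

    def test_matches_rowwise_recomputation(self):
        rng = np.random.default_rng(5)
        rows = [
            {
                "sample_id": f"S{rng.integers(3)}",
                "pos": int(10 + i),
                "impact_class": "missense",
                "mutant_duplex_reads": int(rng.integers(1, 4)),
                "site_duplex_coverage": int(rng.integers(50, 500)),
            }
            for i in range(40)
        ]
        df = labelled_table(rows)
        out = gs.sum_vaf_fraction(df, "missense", impact_classes=["missense"])
        for _, r in out.iterrows():
            manual = sum(
                row["mutant_duplex_reads"] / row["site_duplex_coverage"]
                for row in rows
                if row["sample_id"] == r["sample_id"]
            )
            assert r["observed_fraction"] == pytest.approx(manual)

    def test_zero_coverage_errors(self):
        df = labelled_table([{"pos": 10, "site_duplex_coverage": 0}])
        with pytest.raises(DataError):
            gs.sum_vaf_fraction(df, "all")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["synonymous", "missense", "nonsense"]),
                    min_size=1, max_size=25))
    def test_additive_over_class_partition(self, classes):
        rows = [{"pos": 10 + i, "impact_class": c} for i, c in enumerate(classes)]
        df = labelled_table(rows)
        total = gs.sum_vaf_fraction(df, "all")["observed_fraction"].sum()
        parts = sum(
            gs.sum_vaf_fraction(df, c, impact_classes=[c])["observed_fraction"].sum()
            for c in ("synonymous", "missense", "nonsense")
        )
        assert parts == pytest.approx(total, rel=1e-12)


class TestAgeCorrection:
    def test_sample_at_cohort_mean_has_unit_correction(self):
        ages = np.array([30.0, 40.0, 50.0, 60.0, 70.0])
        rates = 1e-9 * ages
        df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(5)],
                           "age_years": ages, "rate_raw": rates})
        out = gs.compute_age_corrections(df)
        mid = out.set_index("sample_id").loc["S2", "correction"]
        assert mid == pytest.approx(1.0)
        assert (out["correction"] > 0).all()
        # linear fit: corrections scale with age around the mean
        assert out["correction"].iloc[-1] > out["correction"].iloc[0]


class TestExpectedFraction:
    def _setup(self, depth=100):
        ref = gs.generate_toy_genome(1, 1, 30, seed=5, total_length=500)
        cov = gs.CoverageTrack(ref.chrom, ref.length,
                               {"S1": np.full(ref.length, depth, dtype=np.int32)})
        model = ContextRateModel(
            rates_by_bin=np.full((192, N_METH_BINS), 1e-3),
            indel_rate=0.0, use_methylation=False,
        )
        universe = pd.DataFrame(
            {"pos": np.arange(10, 20),
             "alt": ["A" if ref.sequence[p - 1] != "A" else "C"
                     for p in range(10, 20)]}
        )
        return ref, cov, model, universe

    def test_hand_product_sum_with_max_age_correction(self):
        """10 site-alts x 1e-3 x coverage 100 x correction 1.42 = 1.42."""
        ref, cov, model, universe = self._setup()
        got = expected_class_fraction(model, ref, cov, "S1", universe,
                                      correction=1.42)
        assert got == pytest.approx(1.42, rel=1e-12)

    def test_linear_in_coverage_and_correction(self):
        ref, cov, model, universe = self._setup()
        base = expected_class_fraction(model, ref, cov, "S1", universe)
        ref2, cov2, _, _ = self._setup(depth=200)
        assert expected_class_fraction(model, ref2, cov2, "S1", universe) == \
            pytest.approx(2 * base, rel=1e-12)
        assert expected_class_fraction(model, ref, cov, "S1", universe,
                                       correction=3.0) == \
            pytest.approx(3 * base, rel=1e-12)

    def test_indel_opportunity_uses_single_rate(self):
        ref, cov, model, universe = self._setup()
        model.indel_rate = 1e-4
        got = expected_class_fraction(model, ref, cov, "S1",
                                      universe.head(0),
                                      indel_positions=np.arange(10, 20))
        assert got == pytest.approx(10 * 1e-4 * 100, rel=1e-12)


class TestFractionRegression:
    def test_constant_fraction_flat_fit(self):
        df = pd.DataFrame({"observed_fraction": [0.02] * 12,
                           "age_years": np.linspace(25, 70, 12)})
        fit = gs.fit_fraction_regression(df)
        assert abs(fit.slope) < 1e-6
        assert np.allclose(fit.predictions["fit"], 0.02, atol=1e-9)

    def test_logistic_generating_curve_recovered(self):
        rng = np.random.default_rng(8)
        ages = np.linspace(25, 75, 60)
        true = 1 / (1 + np.exp(-(-5.0 + 0.04 * ages)))
        obs = rng.binomial(800, true) / 800
        fit = gs.fit_fraction_regression(
            pd.DataFrame({"observed_fraction": obs, "age_years": ages}),
            predict_ages=(30.0, 70.0),
        )
        for age, want in [(30.0, 1 / (1 + np.exp(5.0 - 0.04 * 30))),
                          (70.0, 1 / (1 + np.exp(5.0 - 0.04 * 70)))]:
            row = fit.predictions.set_index("age").loc[age]
            assert row["ci_lo"] <= want <= row["ci_hi"]

    def test_all_zero_degenerate(self):
        df = pd.DataFrame({"observed_fraction": [0.0] * 5,
                           "age_years": [30, 40, 50, 60, 70]})
        fit = gs.fit_fraction_regression(df)
        assert fit.slope == 0.0

    def test_out_of_range_fractions_rejected(self):
        df = pd.DataFrame({"observed_fraction": [0.5, 1.2],
                           "age_years": [30, 40]})
        with pytest.raises(DataError):
            gs.fit_fraction_regression(df)


class TestDecomposition:
    def test_published_style_arithmetic(self):
        idx = ["S1"]
        d = gs.decompose_burden(
            pd.Series([3.3], index=idx), pd.Series([1.2], index=idx),
            pd.Series([1.5], index=idx), pd.Series([0.4], index=idx),
        )
        assert d.driver_explained == pytest.approx(1.1)
        assert d.unexplained == pytest.approx(1.0)

    def test_null_cohort_fully_explained(self):
        idx = [f"S{i}" for i in range(4)]
        obs = pd.Series([0.01, 0.02, 0.03, 0.04], index=idx)
        d = gs.decompose_burden(obs, obs.copy(),
                                pd.Series(0.0, index=idx),
                                pd.Series(0.0, index=idx))
        assert d.unexplained == pytest.approx(0.0, abs=1e-15)
        assert d.driver_explained == 0.0

    def test_components_sum_to_total_exactly(self):
        rng = np.random.default_rng(2)
        idx = [f"S{i}" for i in range(50)]
        obs = pd.Series(rng.uniform(0, 0.05, 50), index=idx)
        exp = pd.Series(rng.uniform(0, 0.02, 50), index=idx)
        od = pd.Series(rng.uniform(0, 0.03, 50), index=idx)
        ed = pd.Series(rng.uniform(0, 0.01, 50), index=idx)
        d = gs.decompose_burden(obs, exp, od, ed)
        total = d.expected_neutral + d.driver_explained + d.unexplained
        assert total == pytest.approx(d.total_disease, abs=1e-12)

    def test_driver_excess_attributed_on_simulation(self, driver_cohort):
        """>=80% of the injected LOF excess lands in driver_explained."""
        c = driver_cohort
        model = gs.fit_context_rate_model(c["variants"], c["ref"], c["coverage"])
        obs, exp = gs.selection_tables(c["variants"], c["ref"], model, c["coverage"])
        res = gs.gene_dnds_test(obs, exp)
        sel = gs.build_selection_gene_table(res)
        dd = pd.DataFrame(
            {"gene_id": ["G0000", "G0001"],
             "allelic_requirement": "monoallelic_autosomal",
             "confidence": "definitive",
             "mutation_consequence": "absent gene product"}
        )
        lab = gs.label_disease_and_driver(c["variants"], None, dd, None, sel,
                                          pd.DataFrame(columns=["pos", "ref", "alt"]))
        samples = sorted(c["meta"]["sample_id"])
        obs_dis = gs.sum_vaf_fraction(lab, "dis", label_col="likely_disease",
                                      sample_ids=samples).set_index("sample_id")
        both = lab.copy()
        both["both"] = (both["likely_disease"].fillna(False).astype(bool)
                        & both["likely_driver"].fillna(False).astype(bool))
        obs_drv = gs.sum_vaf_fraction(both, "drv", label_col="both",
                                      sample_ids=samples).set_index("sample_id")

        burdens = gs.cohort_burdens(c["variants"], c["coverage"], c["ref"], c["meta"])
        corr = gs.compute_age_corrections(burdens).set_index("sample_id")
        universe = gs.annotate.coding_site_alt_table(c["ref"])
        damaging = universe[(universe["impact"].isin([2, 3]))
                            & universe["gene_id"].isin(["G0000", "G0001"])]
        uni = pd.DataFrame({"pos": damaging["pos"].to_numpy(),
                            "alt": [gs.context.BASES[b]
                                    for b in damaging["alt_code"]]})
        fs_pos = np.concatenate([c["ref"].gene(g).cds_positions
                                 for g in ("G0000", "G0001")])
        exp_dis = pd.Series(
            {s: expected_cell_fraction(model, c["ref"], c["coverage"], s, uni,
                                       corr.loc[s, "correction"],
                                       indel_positions=fs_pos)
             for s in samples}
        )
        d = gs.decompose_burden(
            obs_dis["observed_fraction"], exp_dis,
            obs_drv["observed_fraction"], exp_dis,
        )
        injected_excess = d.total_disease - d.expected_neutral
        assert injected_excess > 0
        assert d.driver_explained >= 0.8 * injected_excess


class TestPhenotypeAssociations:
    def _meta(self, n, seed=0):
        meta = gs.generate_cohort_metadata(n, seed)
        return meta

    def test_null_outcomes_survive_fdr(self):
        """17 outcomes x 4 predictors = 68 null tests: ~5% raw p < 0.05 and
        (in most seeded replicates) nothing survives BH."""
        raw_frac = []
        clean = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            meta = self._meta(40, seed=seed)
            outcomes = pd.DataFrame({"sample_id": meta["sample_id"]})
            for i in range(17):
                outcomes[f"o{i}"] = rng.normal(size=len(meta))
            res = gs.phenotype_associations(outcomes, meta)
            assert len(res) == 68
            raw_frac.append((res["p"] < 0.05).mean())
            clean += int((res["q"] < 0.05).sum() == 0)
        assert clean >= 4
        assert abs(np.mean(raw_frac) - 0.05) < 0.05

    def test_true_effect_detected_after_adjustment(self):
        rng = np.random.default_rng(2)
        meta = self._meta(60, seed=3)
        outcomes = pd.DataFrame({"sample_id": meta["sample_id"]})
        outcomes["hit"] = 2.0 * meta["pack_years"] + rng.normal(0, 1.0, len(meta))
        for i in range(10):
            outcomes[f"null{i}"] = rng.normal(size=len(meta))
        res = gs.phenotype_associations(outcomes, meta).set_index(
            ["outcome", "predictor"]
        )
        assert res.loc[("hit", "pack_years"), "q"] < 0.05

    def test_constant_predictor_dropped(self):
        meta = self._meta(10)
        meta["bmi"] = 25.0
        outcomes = pd.DataFrame({"sample_id": meta["sample_id"],
                                 "o": np.arange(10.0)})
        res = gs.phenotype_associations(outcomes, meta)
        assert "bmi" not in set(res["predictor"])
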