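"""Type-II ANOVA effect sizes and cross-species correlation analyses."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

import phyloexpress as px


def _meta(species, treatments, reps):
    rows = []
    for sp in species:
        for tr in treatments:
            for k in range(reps):
                rows.append((f"{sp}_{tr}_{k}", sp, tr, 0))
    return px.SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "species_id", "treatment",
                                    "fibrosis_score"])
    )


class TestOgAnova:
    def test_hand_partitioned_2x2x2(self):
        """Cell means (0, 0, 0, 4), 2 reps each: the partition done by hand.

        Grand mean 1. Marginal treatment means 0 vs 2 -> SS_treat = 4+4 = 8;
        marginal species means 0 vs 2 -> SS_species = 8; cell SS = 24, so
        SS_interaction = 24 - 8 - 8 = 8; residual 0; SS_total = 6*1 + 2*9 = 24.
        On a balanced design Type II equals this classical partition.
        """
        meta = _meta(["A", "B"], ["PBS", "alum"], 2)
        vals = {
            "A_PBS_0": 0.0, "A_PBS_1": 0.0, "A_alum_0": 0.0, "A_alum_1": 0.0,
            "B_PBS_0": 0.0, "B_PBS_1": 0.0, "B_alum_0": 4.0, "B_alum_1": 4.0,
        }
        y = pd.Series(vals, name="OG1")
        row = px.fit_og_anova(y, meta)
        assert row["eta2_treatment"] == pytest.approx(8 / 24, abs=1e-12)
        assert row["eta2_species"] == pytest.approx(8 / 24, abs=1e-12)
        assert row["eta2_interaction"] == pytest.approx(8 / 24, abs=1e-12)
        assert row["eta2_residual"] == pytest.approx(0.0, abs=1e-12)
        assert row["df_resid"] == 4

    def test_matches_statsmodels_type2_unbalanced(self):
        """Dual route: vectorized QR model comparison equals anova_lm(typ=2)."""
        rng = np.random.default_rng(0)
        meta_rows = []
        for sp in ["A", "B", "C"]:
            for tr in ["PBS", "alum"]:
                for k in range(int(rng.integers(3, 7))):  # unbalanced
                    meta_rows.append((f"{sp}_{tr}_{k}", sp, tr, 0))
        meta = px.SampleMetadata(
            pd.DataFrame(meta_rows, columns=["sample_id", "species_id",
                                             "treatment", "fibrosis_score"])
        )
        samples = meta.table["sample_id"]
        Y = pd.DataFrame(
            rng.normal(10, 3, (4, len(samples))), columns=samples,
            index=[f"OG{i}" for i in range(4)],
        )
        mine = px.og_anova(Y, meta)
        df = meta.table.set_index("sample_id")
        for og in Y.index:
            df["y"] = Y.loc[og, df.index]
            fit = smf.ols("y ~ C(treatment) * C(species_id)", data=df).fit()
            tab = anova_lm(fit, typ=2)
            assert mine.loc[og, "F_treatment"] == pytest.approx(
                tab.loc["C(treatment)", "F"], rel=1e-8
            )
            assert mine.loc[og, "F_species"] == pytest.approx(
                tab.loc["C(species_id)", "F"], rel=1e-8
            )
            assert mine.loc[og, "F_interaction"] == pytest.approx(
                tab.loc["C(treatment):C(species_id)", "F"], rel=1e-8
            )
            assert mine.loc[og, "p_interaction"] == pytest.approx(
                tab.loc["C(treatment):C(species_id)", "PR(>F)"], rel=1e-8
            )

    def test_eta2_sums_to_one_on_balanced_design(self):
        rng = np.random.default_rng(1)
        meta = _meta(list("ABCDE"), ["PBS", "alum"], 4)
        Y = pd.DataFrame(
            rng.normal(5, 2, (30, 40)), columns=meta.table["sample_id"],
            index=[f"OG{i}" for i in range(30)],
        )
        out = px.og_anova(Y, meta)
        total = (
            out["eta2_treatment"] + out["eta2_species"] + out["eta2_interaction"]
            + out["eta2_residual"]
        )
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_residual_df_matches_study_design(self):
        # 14 species x 2 treatments, 158 samples -> df_resid = 158 - 28 = 130
        cfg = px.SimulationConfig(n_orthogroups=3, seed=0)
        ds = px.simulate_dataset(cfg, px.simulate_tree(14, seed=0))
        vals = pd.DataFrame(
            np.random.default_rng(0).normal(
                10, 1, (3, len(ds.metadata.table))
            ),
            columns=ds.metadata.table["sample_id"],
            index=["a", "b", "c"],
        )
        out = px.og_anova(vals, ds.metadata)
        assert (out["df_resid"] == 130).all()

    def test_affine_invariance_of_eta2(self):
        rng = np.random.default_rng(2)
        meta = _meta(["A", "B", "C"], ["PBS", "alum"], 3)
        Y = pd.DataFrame(
            rng.normal(0, 1, (5, 18)), columns=meta.table["sample_id"],
            index=[f"OG{i}" for i in range(5)],
        )
        a = px.og_anova(Y, meta)
        b = px.og_anova(Y * 7.0 + 100.0, meta)
        for col in ["eta2_treatment", "eta2_species", "eta2_interaction"]:
            assert np.allclose(a[col], b[col], atol=1e-10)

    def test_constant_response_flagged(self):
        meta = _meta(["A", "B"], ["PBS", "alum"], 3)
        Y = pd.DataFrame(
            np.full((1, 12), 3.5), columns=meta.table["sample_id"], index=["OG1"]
        )
        out = px.og_anova(Y, meta)
        assert out["status"].iloc[0] == "constant"
        assert out["eta2_treatment"].iloc[0] == 0.0
        assert np.isnan(out["F_treatment"].iloc[0])

    def test_missing_cell_flags_rank_deficiency(self):
        meta_rows = [
            ("a1", "A", "PBS", 0), ("a2", "A", "PBS", 0),
            ("a3", "A", "alum", 0), ("a4", "A", "alum", 0),
            ("b1", "B", "PBS", 0), ("b2", "B", "PBS", 0),  # B has no alum
        ]
        meta = px.SampleMetadata(
            pd.DataFrame(meta_rows, columns=["sample_id", "species_id",
                                             "treatment", "fibrosis_score"])
        )
        Y = pd.DataFrame(
            np.arange(6.0).reshape(1, 6), columns=[r[0] for r in meta_rows],
            index=["OG1"],
        )
        out = px.og_anova(Y, meta)
        assert (out["status"] == "rank_deficient").all()


class TestEffectSizeSummary:
    def test_all_above_line(self):
        rows = pd.DataFrame(
            {
                "eta2_treatment": [0.5, 0.4],
                "eta2_interaction": [0.1, 0.2],
                "p_treatment": [0.01, 0.2],
                "p_species": [0.5, 0.5],
                "p_interaction": [0.9, 0.9],
                "status": ["ok", "ok"],
            }
        )
        s = px.effect_size_scatter(rows)
        assert s["fraction_treatment_above_interaction"] == 1.0
        assert s["fraction_treatment_significant"] == 0.5

    def test_empty_after_flags(self):
        rows = pd.DataFrame({"status": ["constant"], "eta2_treatment": [0.0],
                             "eta2_interaction": [0.0], "p_treatment": [np.nan],
                             "p_species": [np.nan], "p_interaction": [np.nan]})
        assert px.effect_size_scatter(rows) == {"n": 0}

    def test_regimes_separate(self):
        """Interaction-dominated generator vs treatment-dominated generator."""
        common = dict(
            n_species=6, n_orthogroups=150, samples_per_species_per_treatment=4,
            species_effect_sd=0.3, seed=21,
        )
        for tt, ti, expect_above in [(0.8, 0.05, True), (0.05, 0.8, False)]:
            cfg = px.SimulationConfig(
                treatment_lfc_sd=tt, interaction_sd=ti, **common
            )
            ds = px.simulate_dataset(cfg)
            sfs = {sp: px.compute_size_factors(c) for sp, c in ds.counts.items()}
            norm = {sp: px.normalize(ds.counts[sp], sfs[sp]) for sp in ds.counts}
            core = px.restrict_to_core(
                px.aggregate_to_orthogroups(norm, ds.og_map)
            )
            out = px.og_anova(core.values, ds.metadata)
            s = px.effect_size_scatter(out)
            above = s["fraction_treatment_above_interaction"] > 0.5
            assert above == expect_above


class TestPairwiseCorrelations:
    def test_self_pair_audit(self, og_de_tables):
        sp = "sp01"
        mat = pd.DataFrame({"a": og_de_tables[sp]["wald"],
                            "b": og_de_tables[sp]["wald"]})
        pairs = px.pairwise_wald_correlations({"a": og_de_tables[sp],
                                               "b": og_de_tables[sp]})
        assert pairs["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_responses_near_zero(self):
        rng = np.random.default_rng(3)
        tables = {
            f"sp{i}": pd.DataFrame(
                {"wald": rng.normal(0, 1, 400)},
                index=[f"OG{k}" for k in range(400)],
            )
            for i in range(6)
        }
        pairs = px.pairwise_wald_correlations(tables)
        se = pairs["r"].std(ddof=1) / np.sqrt(len(pairs))
        assert abs(pairs["r"].mean()) < 3 * se + 0.01

    def test_shared_signal_gives_positive_mean(self):
        rng = np.random.default_rng(4)
        shared = rng.normal(0, 2, 300)
        tables = {
            f"sp{i}": pd.DataFrame(
                {"wald": shared + rng.normal(0, 1, 300)},
                index=[f"OG{k}" for k in range(300)],
            )
            for i in range(5)
        }
        pairs = px.pairwise_wald_correlations(tables)
        assert (pairs["r"] > 0).all()
        mean_r, t, p = px.correlation_distribution_test(pairs)
        assert mean_r > 0.5 and p < 1e-6

    def test_too_few_shared_flagged(self):
        a = pd.DataFrame({"wald": [1.0, 2.0]}, index=["OG1", "OG2"])
        b = pd.DataFrame({"wald": [1.0, 2.0]}, index=["OG3", "OG4"])
        pairs = px.pairwise_wald_correlations({"a": a, "b": b})
        assert pairs["status"].iloc[0] == "too_few_shared"
        assert np.isnan(pairs["r"].iloc[0])


class TestDistributionTest:
    def test_closed_form_t(self):
        # r = (0.1, 0.2, 0.3): t = mean / (sd/sqrt(3)) = 0.2/(0.1/1.732) = 3.464
        mean_r, t, p = px.correlation_distribution_test(np.array([0.1, 0.2, 0.3]))
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            px.correlation_distribution_test(np.array([0.2, 0.2, 0.2]))


class TestCopyNumberCorrelation:
    def test_constant_copy_number_is_na(self):
        og_map = px.OrthogroupMap(
            ["sp1"], {f"OG{i}": {"sp1": (f"t{i}",)} for i in range(5)}
        )
        tab = pd.DataFrame(
            {"lfc": [0.5, -1.0, 2.0, 0.1, -0.2]},
            index=[f"OG{i}" for i in range(5)],
        )
        out = px.copy_number_lfc_correlation({"sp1": tab}, og_map)
        assert out["reason"] == "constant_input"

    def test_perfect_linear_relation(self):
        og_map = px.OrthogroupMap(
            ["sp1"],
            {f"OG{i}": {"sp1": tuple(f"t{i}_{j}" for j in range(i + 1))}
             for i in range(5)},
        )
        tab = pd.DataFrame(
            {"lfc": [10.0 - 2 * (i + 1) for i in range(5)]},
            index=[f"OG{i}" for i in range(5)],
        )
        out = px.copy_number_lfc_correlation({"sp1": tab}, og_map)
        assert out["r"] == pytest.approx(-1.0)

    def test_null_generator_near_zero(self, og_de_tables, small_dataset):
        out = px.copy_number_lfc_correlation(og_de_tables, small_dataset.og_map)
        assert abs(out["r"]) < 0.15
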