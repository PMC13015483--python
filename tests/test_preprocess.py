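"""Filtering, imputation, normalization and residualization rules."""

import numpy as np
import pandas as pd
import pytest

from exermap.preprocess import (clean_metabolites,
                                conditional_median_mad_normalize,
                                filter_low_expression,
                                filter_proteomics_quantified,
                                flag_pc_outliers, regress_technical,
                                resolve_platform_redundancy, tmm_log_cpm)


def _matrix(vals, prefix="f", cols=None):
    vals = np.asarray(vals, dtype=float)
    cols = cols or [f"s{i}" for i in range(vals.shape[1])]
    return pd.DataFrame(vals, index=[f"{prefix}{i}" for i in
                                     range(vals.shape[0])], columns=cols)


class TestCleanMetabolites:
    def test_feature_over_20pct_missing_removed(self):
        rng = np.random.default_rng(61)
        vals = rng.uniform(1, 10, (20, 100))
        vals[0, :21] = np.nan          # 21% missing -> removed
        vals[1, :20] = np.nan          # 20% missing -> kept (not "> 20%")
        out, report = clean_metabolites(_matrix(vals))
        assert "f0" not in out.index
        assert "f1" in out.index
        step = [s for s in report.steps if s["step"] == "missingness_filter"][0]
        assert step["n_removed"] == 1

    def test_small_matrix_takes_half_minimum_path(self):
        rng = np.random.default_rng(62)
        vals = rng.uniform(2, 10, (10, 8))
        vals[3, 0] = np.nan
        out, report = clean_metabolites(_matrix(vals))
        assert report.flags["imputation_method"] == "half_minimum"
        expect = np.log2(np.nanmin(vals[3]) / 2.0 + 1.0)
        assert abs(out.loc["f3", "s0"] - expect) < 1e-10

    def test_large_matrix_takes_knn_path(self):
        rng = np.random.default_rng(63)
        vals = rng.uniform(2, 10, (30, 12))
        vals[5, 2] = np.nan
        _, report = clean_metabolites(_matrix(vals))
        assert report.flags["imputation_method"] == "knn"

    def test_nonpositive_values_become_missing_before_filter(self):
        vals = np.full((5, 10), 4.0)
        vals[0, :3] = -3.0             # 30% nonpositive -> removed
        out, report = clean_metabolites(_matrix(vals))
        assert "f0" not in out.index
        conv = [s for s in report.steps
                if s["step"] == "nonpositive_to_missing"][0]
        assert conv["n_values_converted"] == 3

    def test_complete_matrix_only_log_transformed(self):
        rng = np.random.default_rng(64)
        vals = rng.uniform(1, 100, (8, 6))
        out, report = clean_metabolites(_matrix(vals))
        np.testing.assert_allclose(out.to_numpy(), np.log2(vals + 1.0))
        assert all(s["n_removed"] == 0 for s in report.steps)

    def test_duplicate_ids_averaged(self):
        m = pd.DataFrame([[2.0, 4.0], [4.0, 8.0]], index=["a", "a"],
                         columns=["s0", "s1"])
        out, _ = clean_metabolites(m)
        np.testing.assert_allclose(out.loc["a"], np.log2([3.0, 6.0]) +
                                   np.log2(1 + 1 / np.array([3.0, 6.0])))

    def test_all_removed_raises(self):
        vals = np.full((3, 10), np.nan)
        vals[:, 0] = 1.0
        with pytest.raises(ValueError, match="all features removed"):
            clean_metabolites(_matrix(vals))

    def test_conservation_across_steps(self):
        rng = np.random.default_rng(65)
        vals = rng.uniform(1, 10, (25, 20))
        vals[rng.random((25, 20)) < 0.1] = np.nan
        _, report = clean_metabolites(_matrix(vals))
        for s in report.steps:
            assert s["n_in"] == s["n_out"] + s["n_removed"]

    def test_idempotent_on_clean_output(self):
        rng = np.random.default_rng(66)
        vals = rng.uniform(1, 10, (15, 10))
        vals[2, 0] = np.nan
        out1, _ = clean_metabolites(_matrix(vals))
        # the filters pass through an already-clean matrix unchanged
        raw_again = 2.0**out1 - 1.0
        out2, _ = clean_metabolites(raw_again)
        pd.testing.assert_frame_equal(out1, out2)


class TestConditionalNormalize:
    @staticmethod
    def _design(samples, sexes, groups):
        return pd.DataFrame(dict(sample_id=samples, sex=sexes, group=groups),
                            index=samples)

    def test_independent_medians_normalized_to_zero(self):
        rng = np.random.default_rng(67)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        vals = rng.normal(5, 1, (50, n)) + rng.normal(0, 2, n)[None, :]
        m = _matrix(vals, cols=samples)
        d = self._design(samples, ["F", "M"] * (n // 2),
                         ["EE", "RE", "CON", "EE"] * (n // 4))
        out, report = conditional_median_mad_normalize(m, d)
        assert report.flags["normalized"]
        np.testing.assert_allclose(np.median(out.to_numpy(), axis=0), 0.0,
                                   atol=1e-10)

    def test_sex_associated_medians_block_normalization(self):
        rng = np.random.default_rng(68)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        sexes = ["F"] * (n // 2) + ["M"] * (n // 2)
        vals = rng.normal(5, 0.2, (50, n))
        vals[:, n // 2:] += 4.0        # male samples shifted
        m = _matrix(vals, cols=samples)
        d = self._design(samples, sexes, ["EE", "CON"] * (n // 2))
        out, report = conditional_median_mad_normalize(m, d)
        assert not report.flags["normalized"]
        pd.testing.assert_frame_equal(out, m)
        assert min(report.flags["gate_p_values"].values()) < 0.01

    def test_zero_mad_sample_centered_at_unit_scale(self):
        n = 12
        samples = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(69)
        vals = rng.normal(3, 1, (30, n))
        vals[:, 0] = 7.0               # constant sample: MAD = 0
        m = _matrix(vals, cols=samples)
        d = self._design(samples, ["F", "M"] * (n // 2),
                         ["EE", "RE", "CON"] * (n // 3))
        out, report = conditional_median_mad_normalize(m, d)
        if report.flags["normalized"]:
            np.testing.assert_allclose(out["s0"], 0.0, atol=1e-12)


class TestPCOutliers:
    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(70)
        vals = rng.normal(0, 1, (30, 50))
        vals[:, 0] += 10.0 * rng.standard_normal(30)  # gross outlier sample
        flagged = flag_pc_outliers(_matrix(vals))
        assert "s0" in flagged

    def test_spherical_gaussian_rarely_flagged(self):
        rng = np.random.default_rng(71)
        flagged = flag_pc_outliers(_matrix(rng.normal(0, 1, (40, 100))))
        assert len(flagged) == 0

    def test_zero_multiplier_flags_outside_iqr_box(self):
        rng = np.random.default_rng(72)
        m = _matrix(rng.normal(0, 1, (20, 30)))
        flagged = flag_pc_outliers(m, iqr_mult=0.0)
        assert len(flagged) >= 15   # everything outside [Q1, Q3] on any PC

    def test_too_few_samples_warns_empty(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = flag_pc_outliers(_matrix(np.random.rand(5, 2)))
        assert out == []


class TestPlatformRedundancy:
    def test_lowest_cv_platform_kept(self):
        features = pd.DataFrame(dict(refmet_id=["X", "X"],
                                     platform=["A", "B"]))
        cv = pd.DataFrame(dict(platform=["A", "A", "B", "B"],
                               standard=["s1", "s2", "s1", "s2"],
                               cv=[0.07, 0.09, 0.14, 0.16]))
        out = resolve_platform_redundancy(features, cv)
        assert out[out["platform"] == "A"]["keep"].all()
        assert not out[out["platform"] == "B"]["keep"].any()

    def test_single_platform_kept_unchanged(self):
        features = pd.DataFrame(dict(refmet_id=["Y"], platform=["A"]))
        cv = pd.DataFrame(dict(platform=["A"], standard=["s"], cv=[0.5]))
        out = resolve_platform_redundancy(features, cv)
        assert out["keep"].all()
        assert out["reason"].iloc[0] == "single_platform"

    def test_tie_resolves_lexicographically(self):
        features = pd.DataFrame(dict(refmet_id=["Z", "Z"],
                                     platform=["B", "A"]))
        cv = pd.DataFrame(dict(platform=["A", "B"], standard=["s", "s"],
                               cv=[0.1, 0.1]))
        out = resolve_platform_redundancy(features, cv)
        kept = out[out["keep"]]
        assert list(kept["platform"]) == ["A"]
        assert (kept["reason"] == "tie_lexicographic").all()

    def test_missing_cv_falls_back_with_warning(self):
        features = pd.DataFrame(dict(refmet_id=["W", "W"],
                                     platform=["B", "A"]))
        cv = pd.DataFrame(dict(platform=["A"], standard=["s"], cv=[0.1]))
        with pytest.warns(UserWarning, match="missing"):
            out = resolve_platform_redundancy(features, cv)
        assert list(out[out["keep"]]["platform"]) == ["A"]


class TestExpressionFilters:
    def test_literal_rule_boundary(self):
        # 10 samples with equal library sizes of 2e6: count 1 = 0.5 CPM
        vals = np.full((3, 10), 10_000.0)
        vals[0, 0] = 1.0               # CPM 0.5 in exactly 10% -> removed
        vals[1, :] = 10_000.0          # always above -> kept
        vals[2, 1] = 1.2               # CPM 0.6 > 0.5 everywhere -> kept
        m = _matrix(vals)
        m.loc["pad"] = 2e6 - m.sum(axis=0)  # library size exactly 2e6
        lib = m.sum(axis=0)
        cpm0 = m.loc["f0"] / lib * 1e6
        assert (cpm0 <= 0.5).mean() == 0.10
        out = filter_low_expression(m, rule="literal")
        assert "f0" not in out.index
        assert {"f1", "f2"} <= set(out.index)

    def test_conventional_rule_keeps_mostly_expressed(self):
        vals = np.full((2, 10), 1000.0)
        vals[0, :8] = 0.0              # expressed in only 20% of samples
        m = _matrix(vals)
        out = filter_low_expression(m, rule="conventional")
        assert "f0" in out.index       # 20% >= 10% of samples above 0.5 CPM

    def test_zero_library_rejected(self):
        m = _matrix([[0.0, 5.0], [0.0, 5.0]])
        with pytest.raises(ValueError, match="library"):
            filter_low_expression(m)

    @pytest.mark.parametrize("n_obs,kept", [(29, False), (30, True),
                                            (100, True)])
    def test_proteomics_quantified_boundary(self, n_obs, kept):
        vals = np.full((1, 100), np.nan)
        vals[0, :n_obs] = 1.0
        out = filter_proteomics_quantified(_matrix(vals))
        assert ("f0" in out.index) is kept

    def test_tmm_equal_libraries_unit_factors(self):
        rng = np.random.default_rng(73)
        base = rng.uniform(100, 1000, 200)
        vals = np.tile(base[:, None], (1, 6))
        out = tmm_log_cpm(_matrix(vals))
        # identical samples: every sample gets the same log-CPM column
        assert np.allclose(out.to_numpy().std(axis=1), 0.0, atol=1e-8)


class TestRegressTechnical:
    def test_orthogonal_batch_effect_removed(self):
        rng = np.random.default_rng(74)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        group = pd.Series(["EE", "CON"] * (n // 2), index=samples)
        batch = pd.Series((["b1"] * 2 + ["b2"] * 2) * (n // 4), index=samples)
        clean = rng.normal(0, 1, (30, n))
        # make the clean signal exactly orthogonal to batch so the batch
        # coefficient is identified without noise
        b2 = (batch == "b2").to_numpy(float)
        b2c = b2 - b2.mean()
        proj = (clean @ b2c) / (b2c @ b2c)
        clean = clean - proj[:, None] * b2c[None, :]
        m = _matrix(clean + b2[None, :], cols=samples)
        out = regress_technical(m, technical=batch.to_frame("batch"),
                                protected=group.to_frame("group"))
        resid = out.to_numpy() - clean
        # batch contribution gone up to a per-feature constant
        assert np.abs(resid - resid.mean(axis=1, keepdims=True)).max() < 1e-8

    def test_no_technical_covariates_is_identity(self):
        rng = np.random.default_rng(75)
        m = _matrix(rng.normal(0, 1, (5, 10)))
        out = regress_technical(m, technical=pd.DataFrame(index=m.columns),
                                protected=pd.DataFrame(
                                    dict(g=["a", "b"] * 5), index=m.columns))
        pd.testing.assert_frame_equal(out, m)

    def test_batch_confounded_with_group_skipped(self):
        rng = np.random.default_rng(76)
        n = 20
        samples = [f"s{i}" for i in range(n)]
        group = pd.Series(["EE"] * 10 + ["CON"] * 10, index=samples)
        batch = pd.Series(["b1"] * 10 + ["b2"] * 10, index=samples)
        m = _matrix(rng.normal(0, 1, (8, n)), cols=samples)
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_technical(m, technical=batch.to_frame("batch"),
                                    protected=group.to_frame("group"))
        pd.testing.assert_frame_equal(out, m)

    def test_protected_effects_survive(self):
        rng = np.random.default_rng(77)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        group = pd.Series(["EE", "CON"] * (n // 2), index=samples)
        batch = pd.Series((["b1"] * 2 + ["b2"] * 2) * (n // 4), index=samples)
        g_eff = np.where(group == "EE", 2.0, 0.0)
        b_eff = np.where(batch == "b2", 1.0, 0.0)
        m = _matrix(rng.normal(0, 0.5, (20, n)) + g_eff + b_eff,
                    cols=samples)
        out = regress_technical(m, technical=batch.to_frame("batch"),
                                protected=group.to_frame("group"))
        diff = (out.loc[:, group == "EE"].mean(axis=1)
                - out.loc[:, group == "CON"].mean(axis=1))
        assert abs(diff.mean() - 2.0) < 0.2
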