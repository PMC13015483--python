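"""Differential analysis: contrasts, filtering, FDR, z-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exermap.differential import (adjust_stratified, build_zscore_matrix,
                                  contrast, estimate_precision_weights,
                                  fit_feature, min_pairs_filter,
                                  run_differential, sex_difference)
from exermap.simulate import EffectSpec, generate_cohort, generate_omics


class TestContrasts:
    def test_balanced_delta_delta_equals_raw_arithmetic(self, middle_cohort):
        """On complete balanced data the mixed-model dd estimate equals the
        plain difference of raw group mean changes."""
        rng = np.random.default_rng(1)
        d = middle_cohort
        y = rng.normal(0, 1, len(d))
        ff = fit_feature(y, d, covariates=())
        row = contrast(ff, "difference_in_changes", "EE", "4hr")
        ys = pd.Series(y, index=d["sample_id"])

        def mean_change(grp):
            sub = d[d["group"] == grp]
            pre = ys[sub[sub["timepoint"] == "pre"]["sample_id"]].mean()
            post = ys[sub[sub["timepoint"] == "4hr"]["sample_id"]].mean()
            return post - pre

        oracle = mean_change("EE") - mean_change("CON")
        assert abs(row["estimate"] - oracle) < 1e-8

    def test_planted_dd_effect_recovered(self, planted_omics):
        matrix, truth, spec = planted_omics
        res = run_differential(matrix, _design_for(matrix), covariates=(),
                               families=("difference_in_changes",
                                         "group_specific"), ome="protein")
        dd = res[(res["family"] == "difference_in_changes")
                 & (res["group"] == "EE")].set_index("feature_id")
        affected = truth[truth["is_dd_affected"]]
        est = dd.loc[affected["feature_id"], "estimate"].to_numpy()
        signed = affected["dd_signed_effect"].to_numpy()
        assert abs(np.mean(est - signed)) < 0.15
        con = res[(res["family"] == "group_specific")
                  & (res["group"] == "CON")]
        assert abs(con["estimate"].mean()) < 0.1

    def test_global_time_shift_hits_group_specific_only(self, middle_cohort):
        """A circadian-like shift affecting every group's post samples is
        detected by group-specific contrasts but nulled by delta-delta."""
        rng = np.random.default_rng(2)
        d = middle_cohort
        n_feat = 200
        part = d["participant_id"].astype("category").cat.codes.to_numpy()
        shift = (d["timepoint"] != "pre").to_numpy(float) * 1.0
        vals = (rng.normal(0, 1, (n_feat, len(d)))
                + rng.normal(0, 1, (n_feat, part.max() + 1))[:, part]
                + shift[None, :])
        m = pd.DataFrame(vals, index=[f"F{i}" for i in range(n_feat)],
                         columns=d["sample_id"])
        res = run_differential(m, d, covariates=(),
                               families=("difference_in_changes",
                                         "group_specific"))
        gs = res[(res["family"] == "group_specific")]
        dd = res[res["family"] == "difference_in_changes"]
        assert gs["significant"].mean() > 0.5
        assert (dd["p"] < 0.05).mean() < 0.10

    def test_modality_contrast_centered_under_symmetric_effects(
            self, middle_cohort):
        rng = np.random.default_rng(3)
        d = middle_cohort
        ex_post = (d["group"].isin(["EE", "RE"])
                   & (d["timepoint"] != "pre")).to_numpy(float)
        part = d["participant_id"].astype("category").cat.codes.to_numpy()
        vals = (rng.normal(0, 1, (100, len(d)))
                + rng.normal(0, 1, (100, part.max() + 1))[:, part]
                + 1.5 * ex_post[None, :])
        m = pd.DataFrame(vals, index=[f"F{i}" for i in range(100)],
                         columns=d["sample_id"])
        res = run_differential(m, d, covariates=(), families=("modality",))
        assert abs(res["estimate"].mean()) < 0.1
        assert (res["p"] < 0.05).mean() < 0.12


def _design_for(matrix):
    # conftest matrices carry sample ids of the middle cohort
    from exermap.simulate import generate_cohort
    return generate_cohort(dict(EE=20, RE=20, CON=20),
                           profile_weights=(0.0, 1.0, 0.0), seed=12)


class TestVarianceModeration:
    def test_moderation_preserves_estimates_and_calibration(self):
        from exermap.simulate import EffectSpec, generate_cohort, generate_omics
        design = generate_cohort({"EE": 10, "RE": 10, "CON": 10},
                                 profile_weights=(0, 1, 0), seed=1)
        spec = EffectSpec(n_features_per_ome=150, frac_dd_affected=0.1,
                          dd_effect=1.0, trajectory_shapes=False,
                          n_modules=0, module_size=1, omes=("protein",),
                          seed=2)
        mats, truth = generate_omics(design, spec)
        r0 = run_differential(mats["protein"], design, covariates=(),
                              families=("difference_in_changes",))
        r1 = run_differential(mats["protein"], design, covariates=(),
                              families=("difference_in_changes",),
                              moderate_var=True)
        np.testing.assert_allclose(r0["estimate"], r1["estimate"])
        assert (r1["df"] > r0["df"]).all()   # borrowed strength adds df
        null = ~r1["feature_id"].isin(
            truth[truth["is_dd_affected"]]["feature_id"])
        assert abs((r1[null]["p"] < 0.05).mean() - 0.05) < 0.03


class TestMinPairsFilter:
    @pytest.mark.parametrize("n_pairs,expect", [(2, False), (3, True)])
    def test_boundary_at_three_pairs(self, middle_cohort, n_pairs, expect):
        d = middle_cohort
        missing = pd.DataFrame(
            False, index=["f1"], columns=list(d["sample_id"]))
        ee = d[d["group"] == "EE"].drop_duplicates("participant_id")
        # knock out EE pairs beyond n_pairs by removing their post sample
        for pid in ee["participant_id"].iloc[n_pairs:]:
            sid = d[(d["participant_id"] == pid)
                    & (d["timepoint"] == "4hr")]["sample_id"]
            missing.loc["f1", sid] = True
        mask = min_pairs_filter(d, missing)
        assert bool(mask.loc["f1", "difference_in_changes:EE:4hr"]) is expect

    def test_complete_data_all_testable(self, middle_cohort):
        missing = pd.DataFrame(False, index=["a", "b"],
                               columns=list(middle_cohort["sample_id"]))
        mask = min_pairs_filter(middle_cohort, missing)
        assert mask.all().all()


class TestStratifiedFDR:
    def test_hand_computed_bh(self):
        res = pd.DataFrame(dict(
            feature_id=list("abcd"), family="difference_in_changes",
            group="EE", timepoint="4hr", p=[0.01, 0.02, 0.03, 0.04],
            estimate=1.0))
        adj = adjust_stratified(res)
        np.testing.assert_allclose(adj["adj_p"], [0.04, 0.04, 0.04, 0.04])

    def test_single_feature_unchanged(self):
        res = pd.DataFrame(dict(feature_id=["a"], family="f", group="g",
                                timepoint="t", p=[0.2], estimate=[1.0]))
        assert adjust_stratified(res)["adj_p"].iloc[0] == 0.2

    def test_strata_are_independent(self):
        rows = []
        for tp in ("45min", "4hr"):
            rows.append(dict(feature_id="hit", family="f", group="EE",
                             timepoint=tp, p=0.0004, estimate=1.0))
            for i in range(99):
                rows.append(dict(feature_id=f"n{i}", family="f", group="EE",
                                 timepoint=tp, p=0.9, estimate=0.0))
        adj = adjust_stratified(pd.DataFrame(rows))
        hits = adj[adj["feature_id"] == "hit"]
        # BH uses the within-stratum count (100), not the pooled 200:
        # adjusted = 0.0004 * 100 in each stratum
        np.testing.assert_allclose(hits["adj_p"], 0.04)


class TestSexDifference:
    def test_sign_convention_male_positive(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(40)]
        sex = pd.Series(["M"] * 20 + ["F"] * 20, index=samples)
        vals = rng.normal(0, 1, (5, 40))
        vals[:, :20] += 2.0
        m = pd.DataFrame(vals, index=[f"f{i}" for i in range(5)],
                         columns=samples)
        res = sex_difference(m, sex)
        assert (res["estimate"] > 0).all()
        assert res["significant"].all()

    def test_null_calibration_under_permutation(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(60)]
        sex = pd.Series(rng.permutation(["M"] * 30 + ["F"] * 30),
                        index=samples)
        m = pd.DataFrame(rng.normal(0, 1, (1000, 60)),
                         index=[f"f{i}" for i in range(1000)],
                         columns=samples)
        res = sex_difference(m, sex)
        assert abs((res["p"] < 0.05).mean() - 0.05) < 0.02

    def test_single_sex_rejected(self):
        m = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="both sexes"):
            sex_difference(m, pd.Series(["M"] * 4, index=list("abcd")))


class TestPrecisionWeights:
    def test_homoscedastic_surrogate_gives_flat_weights(self, middle_cohort):
        rng = np.random.default_rng(7)
        d = middle_cohort
        # constant variance on the log2 scale => flat mean-variance trend
        mu = rng.uniform(6.0, 10.0, size=200)
        vals = 2.0 ** (mu[:, None] + rng.normal(0, 0.3, (200, len(d))))
        m = pd.DataFrame(np.round(vals),
                         index=[f"g{i}" for i in range(200)],
                         columns=d["sample_id"])
        w = estimate_precision_weights(m, d, covariates=())
        assert w.to_numpy().std() / w.to_numpy().mean() < 0.10

    def test_overdispersed_counts_downweight_low_counts(self, middle_cohort):
        rng = np.random.default_rng(8)
        d = middle_cohort
        mu = np.exp(rng.uniform(np.log(5), np.log(2000), 300))
        disp = 0.5
        r = 1 / disp
        vals = rng.negative_binomial(r, r / (r + mu[:, None]),
                                     size=(300, len(d))).astype(float)
        m = pd.DataFrame(vals, index=[f"g{i}" for i in range(300)],
                         columns=d["sample_id"])
        w = estimate_precision_weights(m, d, covariates=())
        lo = mu < np.quantile(mu, 0.2)
        hi = mu > np.quantile(mu, 0.8)
        assert w.to_numpy()[lo].mean() < w.to_numpy()[hi].mean()

    def test_single_sample_rejected(self, middle_cohort):
        m = pd.DataFrame(np.ones((20, 1)),
                         columns=[middle_cohort["sample_id"].iloc[0]])
        with pytest.raises(ValueError, match="at least 2"):
            estimate_precision_weights(m, middle_cohort)


class TestZScoreMatrix:
    @staticmethod
    def _row(fid, p, est, contrast_name="difference_in_changes:EE:4hr"):
        return dict(feature_id=fid, contrast=contrast_name, p=p,
                    estimate=est, family="difference_in_changes",
                    group="EE", timepoint="4hr")

    def test_most_extreme_z_per_gene(self):
        res = pd.DataFrame([
            self._row("f1", 2 * stats.norm.sf(1.2), +1.0),
            self._row("f2", 2 * stats.norm.sf(2.5), -1.0),
        ])
        zm = build_zscore_matrix(res, mapping={"f1": "G", "f2": "G"})
        assert zm.shape == (1, 1)
        assert abs(zm.iloc[0, 0] - (-2.5)) < 1e-6

    def test_phospho_sites_expanded_with_identical_rows(self):
        res = pd.DataFrame([self._row("p1", 2 * stats.norm.sf(3.0), 1.0)])
        zm = build_zscore_matrix(res, mapping={"p1": "PROT_S1;S2"},
                                 phospho_expand=True)
        assert sorted(zm.index) == ["PROT_S1", "PROT_S2"]
        assert np.allclose(zm.to_numpy(), 3.0, atol=1e-6)

    def test_p_of_one_gives_zero_and_underflow_capped(self):
        res = pd.DataFrame([self._row("a", 1.0, 1.0),
                            self._row("b", 0.0, -1.0)])
        zm = build_zscore_matrix(res)
        assert zm.loc["a"].iloc[0] == 0.0
        assert zm.loc["b"].iloc[0] == -38.0

    def test_unmapped_features_dropped(self):
        res = pd.DataFrame([self._row("a", 0.5, 1.0),
                            self._row("b", 0.5, 1.0)])
        zm = build_zscore_matrix(res, mapping={"a": "G1"})
        assert list(zm.index) == ["G1"]
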