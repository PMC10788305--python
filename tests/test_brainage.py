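"""Cohort statistics and brain-age model: recovery, calibration, FDR."""

import numpy as np
import pandas as pd
import pytest

from psgkit import (
    clean_outliers, fit_age_associations, select_features, fit_brain_age,
    gap_group_analysis, group_difference_models, profile_similarity,
    simulate_cohort,
)
from psgkit.synth import CohortParams


def linear_curves(n_features=40, seed=0):
    rng = np.random.default_rng(seed)
    curves = {}
    for j in range(n_features):
        a = rng.uniform(0.8, 1.2) * (-1 if j % 2 else 1)
        b = rng.uniform(-5, 5)
        curves[f"feat{j:02d}"] = (lambda a, b: (lambda age: a * age + b))(a, b)
    return curves


@pytest.fixture(scope="module")
def cohort():
    params = CohortParams(n=600, age_range=(2.5, 17.5),
                          curves=linear_curves(), offset_sd=1.0,
                          feature_noise_sd=2.0,
                          groups={"delayed": {"n": 50, "offset": -2.0}})
    return simulate_cohort(params, seed=11)


class TestCleanOutliers:
    def test_gross_outlier_masked_in_first_round(self):
        df = pd.DataFrame({"f": [0.0] * 99 + [100.0]})
        out = clean_outliers(df)
        assert out["f"].isna().sum() == 1
        assert np.isnan(out["f"].iloc[-1])

    def test_normal_tail_mass_masked(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"f": rng.standard_normal(10000)})
        out = clean_outliers(df, rounds=1)
        frac = out["f"].isna().mean()
        assert 0.001 < frac < 0.006  # ~0.27 % for a 3-SD rule

    def test_constant_feature_untouched(self):
        df = pd.DataFrame({"f": np.full(50, 7.0)})
        assert clean_outliers(df)["f"].notna().all()

    def test_second_round_recomputes_statistics(self):
        df = pd.DataFrame({"f": [0.0] * 50 + [10.0] * 2 + [1000.0]})
        out = clean_outliers(df, rounds=2)
        assert out["f"].isna().sum() >= 1


class TestAgeAssociations:
    def test_linear_effect_recovered(self, cohort):
        features, subjects, _ = cohort
        pool = subjects["group"] == "non-NDD"
        res = fit_age_associations(features[pool], subjects[pool])
        f0 = res.set_index("feature").loc["feat00"]
        assert f0["beta"] == pytest.approx(1.0, abs=0.25)
        assert f0["fdr_q"] < 0.05
        assert f0["fdr_q"] >= f0["p"]

    def test_quadratic_trajectory_flagged_by_bic(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(2.5, 17.5, 400)
        quad = (age - 10.0) ** 2 + rng.normal(0, 1.0, 400)
        lin = 2.0 * age + rng.normal(0, 1.0, 400)
        subjects = pd.DataFrame({
            "age": age,
            "sex": rng.choice(["F", "M"], 400),
            "race": rng.choice(["white", "black"], 400)})
        features = pd.DataFrame({"quad": quad, "lin": lin})
        res = fit_age_associations(features, subjects).set_index("feature")
        assert res.loc["quad", "delta_bic"] < 0      # quadratic wins
        assert res.loc["lin", "delta_bic"] > 0       # linear suffices

    def test_null_features_control_false_positives(self):
        rng = np.random.default_rng(2)
        n = 300
        subjects = pd.DataFrame({
            "age": rng.uniform(2.5, 17.5, n),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["white", "black", "other"], n)})
        features = pd.DataFrame(rng.standard_normal((n, 100)),
                                columns=[f"null{j}" for j in range(100)])
        res = fit_age_associations(features, subjects)
        assert (res["fdr_q"] < 0.05).mean() < 0.05

    def test_bh_qvalues_monotone_in_p(self, cohort):
        features, subjects, _ = cohort
        res = fit_age_associations(features, subjects).sort_values("p")
        assert (np.diff(res["fdr_q"]) >= -1e-12).all()


class TestSelectFeatures:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        df = pd.DataFrame({"a": a, "b": a.copy(),
                           "c": rng.standard_normal(100)})
        assert select_features(df) == ["a", "c"]

    def test_highly_correlated_pair_pruned(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(500)
        df = pd.DataFrame({"a": a, "b": a + 0.2 * rng.standard_normal(500)})
        assert select_features(df) == ["a"]

    def test_independent_features_all_retained(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((200, 30)),
                          columns=[f"f{j}" for j in range(30)])
        assert len(select_features(df)) == 30


class TestBrainAge:
    def test_heldout_error_matches_latent_noise(self, cohort):
        """Residual developmental noise of 1 yr implies held-out
        MAE near SD*sqrt(2/pi) ~ 0.8 and unbiased mean error."""
        features, subjects, _ = cohort
        idx = subjects.index[subjects["group"] == "non-NDD"]
        perm = np.random.default_rng(1).permutation(len(idx))
        tr, te = idx[perm[:420]], idx[perm[420:]]
        model = fit_brain_age(features.loc[tr], subjects.loc[tr],
                              feature_list=select_features(features.loc[tr]),
                              seed=0)
        held = model.predict(features.loc[te], subjects.loc[te])
        assert held.mae == pytest.approx(0.84, abs=0.12)
        assert abs(held.me) < 0.2
        assert held.mae >= abs(held.me)
        assert model.cv_r2[0] > 0.85

    def test_pure_noise_features_have_no_skill(self):
        rng = np.random.default_rng(3)
        n = 300
        subjects = pd.DataFrame({
            "age": rng.uniform(2.5, 17.5, n),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["white", "black"], n)})
        features = pd.DataFrame(rng.standard_normal((n, 20)),
                                columns=[f"f{j}" for j in range(20)])
        model = fit_brain_age(features, subjects, seed=0)
        assert model.cv_r2[0] <= 0.05

    def test_prediction_invariant_to_feature_rescaling(self, cohort):
        features, subjects, _ = cohort
        idx = subjects.index[subjects["group"] == "non-NDD"]
        m1 = fit_brain_age(features.loc[idx], subjects.loc[idx], n_folds=0)
        scaled = features.copy()
        scaled["feat00"] = scaled["feat00"] * 100.0 + 5.0
        m2 = fit_brain_age(scaled.loc[idx], subjects.loc[idx], n_folds=0)
        p1 = m1.predict(features.loc[idx], subjects.loc[idx])
        p2 = m2.predict(scaled.loc[idx], subjects.loc[idx])
        np.testing.assert_allclose(p1.predictions["predicted"],
                                   p2.predictions["predicted"], atol=1e-8)

    def test_missing_feature_raises(self, cohort):
        features, subjects, _ = cohort
        model = fit_brain_age(features, subjects, n_folds=0)
        with pytest.raises(ValueError, match="absent"):
            model.predict(features.drop(columns=["feat00"]), subjects)

    def test_delayed_group_shows_negative_gap(self, cohort):
        features, subjects, _ = cohort
        idx = subjects.index[subjects["group"] == "non-NDD"]
        model = fit_brain_age(features.loc[idx], subjects.loc[idx], n_folds=0)
        d = subjects["group"] == "delayed"
        res = model.predict(features[d], subjects[d])
        assert res.me == pytest.approx(-1.9, abs=0.45)


class TestGapAnalysis:
    def test_delayed_group_detected_with_resampling(self, cohort):
        features, subjects, _ = cohort
        res = gap_group_analysis(features, subjects, n_rounds=20, seed=3)
        row = res.set_index("group").loc["delayed"]
        assert row["me_mean"] == pytest.approx(-1.9, abs=0.45)
        assert row["median_p_me"] < 0.01
        assert row["me_min"] <= row["me_mean"] <= row["me_max"]

    def test_single_round_min_equals_max(self, cohort):
        features, subjects, _ = cohort
        res = gap_group_analysis(features, subjects, n_rounds=1, seed=0)
        row = res.set_index("group").loc["delayed"]
        assert row["me_min"] == row["me_max"] == row["me_mean"]

    def test_null_group_not_systematically_flagged(self):
        params = CohortParams(n=400, age_range=(2.5, 17.5),
                              curves=linear_curves(20), offset_sd=1.0,
                              feature_noise_sd=2.0,
                              groups={"null": {"n": 50, "offset": 0.0}})
        features, subjects, _ = simulate_cohort(params, seed=5)
        res = gap_group_analysis(features, subjects, n_rounds=10, seed=1)
        row = res.set_index("group").loc["null"]
        assert abs(row["me_mean"]) < 0.5


class TestGroupDifferences:
    def test_implanted_group_effect_recovered(self):
        rng = np.random.default_rng(4)
        n, g = 400, 80
        age = rng.uniform(2.5, 17.5, n + g)
        group = np.array(["non-NDD"] * n + ["dd"] * g)
        y = age * 0.5 + rng.normal(0, 1, n + g)
        sd = y.std()
        y[n:] -= 1.0 * sd  # -1 SD shift in the group
        subjects = pd.DataFrame({
            "age": age, "group": group,
            "sex": rng.choice(["F", "M"], n + g),
            "race": rng.choice(["white", "black"], n + g),
            "ahi": rng.lognormal(0, 0.5, n + g),
            "medication": rng.random(n + g) < 0.2})
        features = pd.DataFrame({"ss_density": y})
        res = group_difference_models(features, subjects, "dd")
        row = res.set_index("feature").loc["ss_density"]
        assert row["beta_group"] == pytest.approx(-1.0, abs=0.3)
        assert row["q_group"] < 0.05

    def test_opposite_age_slopes_detected_as_interaction(self):
        rng = np.random.default_rng(5)
        n, g = 400, 80
        age = rng.uniform(2.5, 17.5, n + g)
        group = np.array(["non-NDD"] * n + ["dd"] * g)
        slope = np.where(group == "dd", -0.5, 0.5)
        y = slope * age + rng.normal(0, 1, n + g)
        subjects = pd.DataFrame({
            "age": age, "group": group,
            "sex": rng.choice(["F", "M"], n + g),
            "race": rng.choice(["white", "black"], n + g)})
        features = pd.DataFrame({"overlap": y})
        res = group_difference_models(features, subjects, "dd",
                                      covariates=("sex", "race"))
        row = res.set_index("feature").loc["overlap"]
        assert row["beta_interaction"] < 0
        assert row["q_interaction"] < 0.05

    def test_empty_group_raises(self, cohort):
        features, subjects, _ = cohort
        with pytest.raises(ValueError, match="empty group"):
            group_difference_models(features, subjects, "nonexistent")


class TestProfileSimilarity:
    def test_delayed_group_most_similar_to_younger_bin(self):
        params = CohortParams(n=800, age_range=(2.0, 22.0),
                              curves=linear_curves(20), offset_sd=0.5,
                              feature_noise_sd=1.0,
                              groups={"delayed": {"n": 60, "offset": -2.0,
                                                  "age_range": (7.0, 9.0)}})
        features, subjects, _ = simulate_cohort(params, seed=6)
        pool = subjects["group"] == "non-NDD"
        d = subjects["group"] == "delayed"
        prof = profile_similarity(features[d], features[pool],
                                  subjects.loc[pool, "age"])
        best = prof.loc[prof["mean_abs_diff"].idxmin(), "bin_center"]
        # group mean age 8, delayed by 2 -> nearest 2-y bin center to 6
        assert best in (5, 7)

    def test_self_subset_minimized_at_own_age_bin(self):
        params = CohortParams(n=800, age_range=(2.0, 22.0),
                              curves=linear_curves(10), offset_sd=0.5,
                              feature_noise_sd=1.0)
        features, subjects, _ = simulate_cohort(params, seed=7)
        m = (subjects["age"] >= 10) & (subjects["age"] < 12)
        prof = profile_similarity(features[m], features, subjects["age"])
        best = prof.loc[prof["mean_abs_diff"].idxmin(), "bin_center"]
        assert best == 11

    def test_single_constant_feature_gives_exact_curve(self):
        rng = np.random.default_rng(8)
        ages = pd.Series(rng.uniform(2, 14, 300))
        comp = pd.DataFrame({"f": ages * 1.0})
        grp = pd.DataFrame({"f": np.full(20, 5.0)})
        prof = profile_similarity(grp, comp, ages)
        mu, sd = comp["f"].mean(), comp["f"].std()
        for _, row in prof.iterrows():
            m = (ages >= row["bin_center"] - 1) & (ages < row["bin_center"] + 1)
            expect = abs(comp["f"][m.to_numpy()].mean() - 5.0) / sd
            assert row["mean_abs_diff"] == pytest.approx(expect, rel=1e-9)

    def test_small_bins_omitted(self):
        rng = np.random.default_rng(9)
        ages = pd.Series(rng.uniform(2, 10, 100))
        comp = pd.DataFrame({"f": rng.standard_normal(100)})
        grp = pd.DataFrame({"f": rng.standard_normal(10)})
        prof = profile_similarity(grp, comp, ages)
        assert (prof["bin_center"] <= 13).all()
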