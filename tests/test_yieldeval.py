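"""Yield evaluation: unit conversion, grouped CV, rank overlap, cross-correlation."""

import numpy as np
import pandas as pd
import pytest

from phenocae.training import pearson
from phenocae.yieldeval import (BU_AC_TO_T_HA, convert_yield, experiment1,
                                experiment2, experiment3,
                                feature_cross_correlation, fit_predict,
                                grouped_kfold_split, r_squared, rmse,
                                top_fraction_overlap)


class TestConvertYield:
    def test_zero(self):
        assert convert_yield(0.0) == 0.0

    def test_hundred_bushels(self):
        # 100 bu/ac * 56 lb/bu * 0.45359237 kg/lb / 4046.8564 m2/ac * 10
        assert convert_yield(100.0) == pytest.approx(6.2765, abs=5e-3)
        assert convert_yield(100.0) == pytest.approx(100 * BU_AC_TO_T_HA, rel=1e-12)

    def test_linearity(self, rng):
        x = rng.uniform(0, 300)
        assert convert_yield(2 * x) == pytest.approx(2 * convert_yield(x))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            convert_yield(-1.0)


class TestGroupedKFold:
    def test_84_genotypes_5_folds(self):
        genos = [f"G{i:03d}" for i in range(84)]
        folds = grouped_kfold_split(genos, k=5, seed=0)
        sizes = sorted(pd.Series(folds).value_counts().tolist())
        assert sizes == [16, 17, 17, 17, 17]

    def test_every_genotype_in_exactly_one_fold(self):
        genos = [f"G{i}" for i in range(23)]
        folds = grouped_kfold_split(genos, k=4, seed=3)
        assert set(folds) == set(genos)
        assert set(folds.values()) == {0, 1, 2, 3}

    def test_seeded_repeatability_and_variation(self):
        genos = [f"G{i}" for i in range(30)]
        assert grouped_kfold_split(genos, seed=1) == grouped_kfold_split(genos, seed=1)
        assert grouped_kfold_split(genos, seed=1) != grouped_kfold_split(genos, seed=2)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            grouped_kfold_split(["a", "b", "c"], k=1)
        with pytest.raises(ValueError):
            grouped_kfold_split(["a", "b", "c"], k=4)


class TestScores:
    def test_perfect_predictions(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0

    def test_mean_prediction_gives_zero_r2(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        y, pred = np.array([0.0, 2.0]), np.array([1.0, 1.0])
        assert rmse(y, pred) == 1.0
        assert r_squared(y, pred) == pytest.approx(0.0)

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.zeros(5))


class TestFitPredict:
    def test_memorizes_toy_set(self, rng):
        x = rng.normal(size=(30, 3))
        y = x @ np.array([1.0, -2.0, 0.5])
        idx = np.arange(30)
        pred = fit_predict(x, y, idx[:20], idx[20:], seed=0,
                           regressor_params={"max_depth": 6, "n_estimators": 500})
        assert np.isfinite(pred).all() and pred.shape == (10,)

    def test_constant_target(self, rng):
        x = rng.normal(size=(20, 2))
        y = np.full(20, 3.0)
        pred = fit_predict(x, y, np.arange(15), np.arange(15, 20), seed=0)
        np.testing.assert_allclose(pred, 3.0, atol=1e-3)

    def test_seeded_repeatability(self, rng):
        x = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        a = fit_predict(x, y, np.arange(30), np.arange(30, 40), seed=5)
        b = fit_predict(x, y, np.arange(30), np.arange(30, 40), seed=5)
        np.testing.assert_array_equal(a, b)

    def test_overlap_and_empty_train_rejected(self, rng):
        x, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        with pytest.raises(ValueError):
            fit_predict(x, y, np.arange(6), np.arange(5, 10))
        with pytest.raises(ValueError):
            fit_predict(x, y, np.array([], dtype=int), np.arange(5))


class TestTopFractionOverlap:
    def test_perfect_predictions_full_overlap(self, rng):
        y = pd.Series(rng.normal(size=12), index=[f"G{i}" for i in range(12)])
        for fraction in (0.25, 0.5):
            assert top_fraction_overlap(y, y, fraction) == 100.0

    def test_reversed_ranking_half_fraction(self):
        y = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert top_fraction_overlap(y, -y, 0.5) == 0.0

    def test_nine_genotype_top_set(self):
        # 36 genotypes, fraction 0.25 -> top set of 9; build predictions
        # agreeing on exactly 5 of them: overlap 100 * 5 / 9 = 55.55%
        genos = [f"G{i:02d}" for i in range(36)]
        y_true = pd.Series(np.arange(36, dtype=float), index=genos)
        y_pred = y_true.copy()
        # demote 4 of the true top-9 far down, promote 4 outsiders
        for g in genos[-4:]:
            y_pred[g] = -1.0
        assert top_fraction_overlap(y_true, y_pred, 0.25) == pytest.approx(
            100 * 5 / 9, abs=0.01)

    def test_mismatched_keys_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError):
            top_fraction_overlap(a, b, 0.5)
        with pytest.raises(ValueError):
            top_fraction_overlap(a, a, 1.5)

    def test_random_permutation_calibration(self, rng):
        """Monte-Carlo mean overlap of random rankings is ~ fraction * 100."""
        n_genos, fraction, n_draws = 40, 0.25, 1000
        genos = [f"G{i}" for i in range(n_genos)]
        y_true = pd.Series(np.arange(n_genos, dtype=float), index=genos)
        overlaps = []
        for _ in range(n_draws):
            perm = pd.Series(rng.permutation(n_genos).astype(float), index=genos)
            overlaps.append(top_fraction_overlap(y_true, perm, fraction))
        mean = np.mean(overlaps)
        mc_sd = np.std(overlaps, ddof=1) / np.sqrt(n_draws)
        assert abs(mean - fraction * 100) <= 3 * mc_sd + 1e-9


def _toy_tables(rng, n_genos=12, n_env=3, n_rep=2, informative=True):
    rows, feats = [], []
    g_eff = rng.normal(scale=10, size=n_genos)
    e_eff = rng.normal(scale=10, size=n_env)
    for g in range(n_genos):
        for e in range(n_env):
            for r in range(n_rep):
                pid = f"G{g:02d}_E{e}_R{r}"
                y = 150 + g_eff[g] + e_eff[e] + rng.normal(scale=1.0)
                rows.append(dict(plot_id=pid, genotype_id=f"G{g:02d}",
                                 environment_id=f"E{e}", replicate_id=r + 1,
                                 timepoint="TP1", yield_bu_ac=y))
                feat = [g_eff[g] + rng.normal(scale=0.1),
                        e_eff[e] + rng.normal(scale=0.1)] if informative \
                    else list(rng.normal(size=2))
                feats.append(dict(plot_id=pid, f1=feat[0], f2=feat[1]))
    df = pd.DataFrame(rows)
    meta = df[["plot_id", "genotype_id", "environment_id", "replicate_id", "timepoint"]]
    yields = df[["plot_id", "yield_bu_ac"]]
    return pd.DataFrame(feats), yields, meta


class TestExperiment1:
    def test_fold_count_and_units(self, rng):
        feats, yields, meta = _toy_tables(rng)
        res = experiment1({"toy": feats}, yields, meta, k=5, seed=0)
        assert len(res) == 1 and len(res[0].r2) == 5
        # RMSE reported in t/ha: far below the bu/ac spread
        assert res[0].mean_rmse < 5.0

    def test_identical_features_identical_results(self, rng):
        feats, yields, meta = _toy_tables(rng)
        res = experiment1({"a": feats, "b": feats.copy()}, yields, meta, seed=0)
        assert res[0].r2 == res[1].r2
        assert res[0].rmse == res[1].rmse

    def test_noise_features_do_not_inflate_r2(self, rng):
        feats, yields, meta = _toy_tables(rng)
        noisy = feats.copy()
        for i in range(3):
            noisy[f"noise{i}"] = rng.normal(size=len(feats))
        res = experiment1({"plain": feats, "noisy": noisy}, yields, meta, seed=0)
        assert res[1].mean_r2 <= res[0].mean_r2 + 0.05

    def test_missing_feature_set_rejected(self, rng):
        _, yields, meta = _toy_tables(rng)
        with pytest.raises(ValueError):
            experiment1({}, yields, meta)


class TestExperiment2:
    def test_informative_features_beat_chance(self, rng):
        feats, yields, meta = _toy_tables(rng, n_genos=16)
        res = experiment2(feats, yields, meta, fraction=0.5, seed=0)
        assert len(res) == 3
        assert np.mean([r.overlap_pct for r in res]) > 50.0
        for r in res:
            assert 0.0 <= r.overlap_pct <= 100.0

    def test_single_location_rejected(self, rng):
        feats, yields, meta = _toy_tables(rng, n_env=1)
        with pytest.raises(ValueError):
            experiment2(feats, yields, meta)


class TestExperiment3:
    def test_heldout_environment_rmse(self, rng):
        feats, yields, meta = _toy_tables(rng)
        out = experiment3(feats, yields, meta, heldout_environment="E2", seed=0)
        assert out["unit"] == "bu/ac"
        assert np.isfinite(out["rmse"]) and out["rmse"] >= 0
        assert out["n_test"] == (meta["environment_id"] == "E2").sum()

    def test_unknown_environment_rejected(self, rng):
        feats, yields, meta = _toy_tables(rng)
        with pytest.raises(ValueError):
            experiment3(feats, yields, meta, heldout_environment="E9")


class TestFeatureCrossCorrelation:
    def test_self_correlation_diagonal(self, rng):
        a = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x", "y", "z"])
        mat = feature_cross_correlation(a, a)
        np.testing.assert_allclose(np.diag(mat.to_numpy(float)), 1.0, atol=1e-12)

    def test_duplicated_column_gives_unit_entry(self, rng):
        a = pd.DataFrame({"u": rng.normal(size=20)})
        b = pd.DataFrame({"v": a["u"].to_numpy()})
        assert feature_cross_correlation(a, b).loc["u", "v"] == pytest.approx(1.0)

    def test_matches_pairwise_oracle(self, rng):
        a = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a1", "a2"])
        b = pd.DataFrame(rng.normal(size=(25, 3)), columns=["b1", "b2", "b3"])
        mat = feature_cross_correlation(a, b)
        for ca in a.columns:
            for cb in b.columns:
                assert mat.loc[ca, cb] == pytest.approx(
                    pearson(a[ca].to_numpy(), b[cb].to_numpy()), abs=1e-12)

    def test_misaligned_rows_rejected(self, rng):
        a = pd.DataFrame({"x": rng.normal(size=5)})
        b = pd.DataFrame({"y": rng.normal(size=6)})
        with pytest.raises(ValueError):
            feature_cross_correlation(a, b)
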