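"""Random-forest stage regression, Welch/BH differential testing."""

import numpy as np
import pandas as pd
import pytest

from teametab.binning import FeatureMatrix
from teametab.errors import DegenerateTestError, InvalidDesignError
from teametab.forest import fit_forest
from teametab.selection import (
    RFConfig,
    bh_adjust,
    differential_features,
    encode_stage_response,
    permutation_model_test,
    select_features,
    welch_test,
)
from teametab.synthetic import (
    BLACK_STAGES,
    GREEN_STAGES,
    black_config,
    green_config,
    simulate_design,
    simulate_feature_matrix,
)


def matrix_from_array(X, sample_ids):
    """samples x features array -> FeatureMatrix (features x samples)."""
    fids = [f"n{100 + i}.00" for i in range(X.shape[1])]
    values = pd.DataFrame(X.T, index=fids, columns=sample_ids)
    info = pd.DataFrame(
        {"polarity": "negative", "bin_mz": np.arange(X.shape[1]) + 100.0,
         "accurate_mz": np.arange(X.shape[1]) + 100.0},
        index=fids,
    )
    return FeatureMatrix(values, info, {})


class TestEncodeResponse:
    def test_green_ordinal(self):
        design = simulate_design(green_config(1, n_features=10, n_informative=0))
        resp = encode_stage_response(design, list(GREEN_STAGES))
        assert resp["picking_r1"] == 0
        assert resp["roasting_r3"] == 5
        assert len(resp) == 18  # QCs excluded

    def test_arm_filter_excludes_other_arm(self):
        design = simulate_design(black_config(1, n_features=10, n_informative=0))
        resp = encode_stage_response(design, list(BLACK_STAGES), arm="4h")
        assert "oxidation-4h_r1" in resp.index
        assert "oxidation-overnight_r1" not in resp.index
        assert "picking_r1" in resp.index  # shared stages kept

    def test_label_based_not_positional(self):
        design = simulate_design(green_config(1, n_features=10, n_informative=0))
        shuffled = design.sample(frac=1.0, random_state=0)
        a = encode_stage_response(design, list(GREEN_STAGES))
        b = encode_stage_response(shuffled, list(GREEN_STAGES))
        assert a.sort_index().equals(b.sort_index())

    def test_unknown_stage_error(self):
        design = simulate_design(green_config(1, n_features=10, n_informative=0))
        with pytest.raises(InvalidDesignError):
            encode_stage_response(design, ["picking", "rolling"])


class TestForest:
    y8 = np.repeat(np.arange(8), 3).astype(float)

    def test_duplicated_response_high_r2(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 1, (24, 30))
        X[:, 7] = self.y8
        fit = fit_forest(X, self.y8, n_trees=1000, max_features=30, seed=3)
        assert fit.oob_r2 > 0.9
        assert int(np.argmax(fit.inc_mse)) == 7

    def test_pure_noise_r2_near_or_below_zero(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(0, 1, (18, 200))
        y = np.repeat(np.arange(6), 3).astype(float)
        fit = fit_forest(X, y, n_trees=500, max_features="third", seed=5)
        assert fit.oob_r2 < 0.15

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(0, 1, (18, 50))
        y = np.repeat(np.arange(6), 3).astype(float)
        a = fit_forest(X, y, n_trees=100, seed=9)
        b = fit_forest(X, y, n_trees=100, seed=9)
        assert a.oob_r2 == b.oob_r2
        assert np.array_equal(a.inc_mse, b.inc_mse)

    def test_constant_feature_zero_importance(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(0, 1, (18, 20))
        X[:, 4] = 1.0
        y = np.repeat(np.arange(6), 3).astype(float)
        fit = fit_forest(X, y, n_trees=300, seed=1)
        assert fit.inc_mse[4] == 0.0

    def test_constant_response_error(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError):
            fit_forest(X, np.ones(10), n_trees=10, seed=0)

    def test_oob_r2_close_to_sklearn(self):
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(4)
        logX = rng.normal(0, 0.2, (18, 300))
        logX[:, :20] += np.linspace(0, 0.6, 6).repeat(3)[:, None]
        X = np.exp(logX)
        y = np.repeat(np.arange(6), 3).astype(float)
        ours = fit_forest(X, y, n_trees=800, max_features="sqrt", seed=0)
        ref = RandomForestRegressor(
            n_estimators=800, max_features="sqrt", oob_score=True, random_state=0
        ).fit(X, y)
        assert ours.oob_r2 == pytest.approx(ref.oob_score_, abs=0.12)


class TestPermutationTests:
    def setup_matrix(self, seed=0, informative=True):
        sim = green_config(
            seed + 300,
            n_features=120,
            n_informative=20 if informative else 0,
            n_trend_clusters=1,
            noise_sigma=0.15,
            trend_amplitude=1.0,
            n_compounds=20,
            weight_effect=False,
            mapped_fraction=0.0,
        )
        design = simulate_design(sim)
        matrix, truth = simulate_feature_matrix(sim, design)
        response = encode_stage_response(design, list(sim.stages))
        return matrix, response, truth

    def test_minimum_p_floor(self):
        matrix, response, _ = self.setup_matrix()
        cfg = RFConfig(seed=1, n_trees=150, n_trees_null=150, n_permutations=10)
        p, null = permutation_model_test(matrix, response, cfg)
        assert p >= 1 / 11
        assert len(null) == 10

    def test_planted_trend_significant(self):
        matrix, response, _ = self.setup_matrix()
        cfg = RFConfig(seed=1, n_trees=300, n_trees_null=200, n_permutations=99)
        res = select_features(matrix, response, cfg)
        assert res.model_p < 0.05
        assert res.model_r2 > 0.3

    def test_planted_features_rank_high(self):
        matrix, response, truth = self.setup_matrix()
        cfg = RFConfig(seed=2, n_trees=500, n_trees_null=300, n_permutations=99)
        res = select_features(matrix, response, cfg)
        top = set(res.importance.sort_values("inc_mse").index[-20:])
        planted = set(truth.informative_feature_ids)
        assert len(top & planted) >= 15

    def test_pvalues_never_zero(self):
        matrix, response, _ = self.setup_matrix()
        cfg = RFConfig(seed=3, n_trees=150, n_trees_null=150, n_permutations=20)
        res = select_features(matrix, response, cfg)
        assert (res.importance["p_value"] > 0).all()
        assert res.model_p > 0


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_textbook_example(self):
        res = welch_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.t == pytest.approx(-1.0954, abs=1e-4)
        assert res.df == pytest.approx(6.0, abs=1e-6)
        assert res.p == pytest.approx(0.315, abs=1e-3)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0], [4.0, 4.5, 6.0]
        fwd, rev = welch_test(a, b), welch_test(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_zero_variance_equal_means(self):
        res = welch_test([2, 2, 2], [2, 2])
        assert res.p == 1.0

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(DegenerateTestError):
            welch_test([2, 2, 2], [3, 3, 3])

    def test_group_size_guard(self):
        with pytest.raises(DegenerateTestError):
            welch_test([1], [2, 3])


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_capped(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestDifferential:
    def build(self, seed, fold, sigma=0.05):
        sim = black_config(
            seed,
            n_features=150,
            n_informative=30,
            n_trend_clusters=1,
            noise_sigma=sigma,
            ppm_jitter=0.0,
            n_compounds=20,
            weight_effect=False,
            mapped_fraction=0.0,
            arm_fold_change=fold,
            n_arm_diff=20,
        )
        design = simulate_design(sim)
        matrix, truth = simulate_feature_matrix(sim, design)
        return matrix, design, truth

    def test_planted_fold_changes_detected(self):
        matrix, design, truth = self.build(50, fold=2.0)
        diff = differential_features(matrix, design, "oxidation", "4h", "overnight")
        planted = set(truth.arm_diff_feature_ids)
        sig = set(diff.index[diff["significant"]])
        assert len(sig & planted) / len(planted) >= 0.8
        assert (diff.loc[sorted(sig & planted), "direction"] == "increased").all()

    def test_direction_partition(self):
        matrix, design, _ = self.build(51, fold=2.0)
        diff = differential_features(matrix, design, "roasting", "4h", "overnight")
        sig = diff[diff["significant"]]
        inc = set(sig.index[sig["direction"] == "increased"])
        dec = set(sig.index[sig["direction"] == "decreased"])
        assert inc | dec == set(sig.index)
        assert not (inc & dec)

    def test_null_p_roughly_uniform(self):
        matrix, design, _ = self.build(52, fold=1.0)
        diff = differential_features(matrix, design, "oxidation", "4h", "overnight")
        p = diff["p"].dropna().to_numpy()
        from scipy import stats

        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_missing_stage_error(self):
        matrix, design, _ = self.build(53, fold=1.0)
        with pytest.raises(InvalidDesignError):
            differential_features(matrix, design, "fixation", "4h", "overnight")
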