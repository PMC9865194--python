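"""Boosted screening, backward elimination, origin assignment, CV R^2."""

import numpy as np
import pandas as pd
import pytest

from chromorigin import (
    BoostParams,
    ChromatinMatrix,
    assign_origin,
    backward_eliminate,
    cv_variance_explained,
    rank_features,
    repeat_predictions,
    screen_importance,
)
from chromorigin.ranking import _fit_gain, _argmin_feature, select_top_k
from chromorigin._seeds import derive_seed
from conftest import make_matrix, make_meta, make_profile


def planted_matrix(n=500, n_noise=30, seed=0):
    """y equals one column exactly; the rest are independent noise."""
    rng = np.random.default_rng(seed)
    driver = rng.poisson(5.0, n).astype(float)
    cols = {"driver": driver}
    for j in range(n_noise):
        cols[f"noise{j:02d}"] = rng.poisson(5.0, n).astype(float)
    return make_matrix(cols), make_profile(driver.astype(int), "s")


class TestBoostParams:
    def test_off_grid_values_rejected(self):
        with pytest.raises(ValueError, match="learning_rate"):
            BoostParams(learning_rate=0.37)
        with pytest.raises(ValueError, match="max_depth"):
            BoostParams(max_depth=4)

    def test_override_flag_accepts_any(self):
        p = BoostParams(learning_rate=0.37, allow_any=True)
        assert p.learning_rate == 0.37


class TestScreenImportance:
    def test_exact_driver_gets_top_importance(self):
        X, y = planted_matrix()
        imp = screen_importance(y, X, BoostParams(seed=1))
        assert imp.scores.idxmax() == "driver"
        # the single-feature model explains nearly all variance
        X_driver = ChromatinMatrix(X.values[["driver", "noise00"]])
        assert cv_variance_explained(y, X_driver, BoostParams(seed=1)) > 0.9

    def test_constant_target_gives_zero_importances(self):
        X, _ = planted_matrix(n=100, n_noise=5)
        y = make_profile([3] * 100)
        imp = screen_importance(y, X, BoostParams(seed=1))
        assert (imp.scores == 0).all()

    def test_same_seed_bit_identical(self):
        X, y = planted_matrix(n=200, n_noise=8)
        a = screen_importance(y, X, BoostParams(seed=7))
        b = screen_importance(y, X, BoostParams(seed=7))
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_single_feature_matrix_rejected(self):
        X, y = planted_matrix(n=50, n_noise=0)
        with pytest.raises(ValueError, match="2 features"):
            screen_importance(y, X, BoostParams(seed=0))

    def test_unused_features_present_with_zero_score(self):
        X, y = planted_matrix(n=400, n_noise=25)
        imp = screen_importance(y, X, BoostParams(seed=3))
        assert set(imp.scores.index) == set(X.feature_ids)
        assert (imp.scores >= 0).all()


class TestBackwardEliminate:
    def test_single_feature_is_rank_one(self):
        X, y = planted_matrix(n=50, n_noise=0)
        r = backward_eliminate(y, X, BoostParams(seed=0))
        assert r.ranked_features == ["driver"] and r.step_importances == []

    def test_exact_driver_beats_noise_two_features(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(6.0, 300).astype(float)
        X = make_matrix({"a_driver": a, "b_noise": rng.poisson(6.0, 300)})
        y = make_profile(a.astype(int))
        r = backward_eliminate(y, X, BoostParams(seed=4))
        assert r.rank1 == "a_driver"
        # at the 2-feature fit the driver's importance dominates
        step = r.step_importances[0]
        assert step["a_driver"] > step["b_noise"]

    def test_each_removal_is_argmin_of_refit_importance(self):
        """Per-step oracle: re-extract the fitted model's importances
        independently and confirm the eliminated feature is their argmin."""
        rng = np.random.default_rng(2)
        cols = {f"f{j}": rng.poisson(4.0, 250).astype(float) for j in range(5)}
        X = make_matrix(cols)
        y = make_profile(
            (cols["f2"] + rng.poisson(2.0, 250)).astype(int)
        )
        params = BoostParams(seed=9)
        r = backward_eliminate(y, X, params)
        surviving = list(X.feature_ids)
        Xv = X.values.to_numpy(dtype=np.float32)
        col_of = {f: i for i, f in enumerate(X.feature_ids)}
        for step, removed in enumerate(r.elimination_order[:-1]):
            gains, _ = _fit_gain(
                Xv[:, [col_of[f] for f in surviving]],
                y.counts.astype(float),
                surviving,
                params,
                derive_seed(params.seed, "eliminate", step),
            )
            assert _argmin_feature(gains) == removed
            surviving.remove(removed)

    def test_zero_importance_ties_eliminated_by_ascending_id(self):
        scores = pd.Series({"c": 0.0, "a": 0.0, "b": 2.0})
        assert _argmin_feature(scores) == "a"

    def test_empty_feature_set_rejected(self):
        X = ChromatinMatrix(pd.DataFrame(index=range(10)))
        with pytest.raises(ValueError, match="empty"):
            backward_eliminate(make_profile([1] * 10), X, BoostParams(seed=0))


class TestRankFeatures:
    def test_planted_driver_rank_one_among_25(self):
        X, y = planted_matrix(n=500, n_noise=24)
        r = rank_features(y, X, BoostParams(seed=5))
        assert r.rank1 == "driver"
        assert len(r.ranked_features) == 20

    def test_small_feature_count_path(self):
        X, y = planted_matrix(n=120, n_noise=2)
        r = rank_features(y, X, BoostParams(seed=5))
        assert len(r.ranked_features) == 3
        assert set(r.ranked_features) == set(X.feature_ids)

    def test_output_is_permutation_of_screened_top20(self):
        X, y = planted_matrix(n=300, n_noise=30, seed=3)
        for seed in (0, 1):
            r = rank_features(y, X, BoostParams(seed=seed))
            top = select_top_k(r.screen_importances, 20)
            assert sorted(r.ranked_features) == sorted(top)

    def test_rank1_equals_last_surviving(self):
        X, y = planted_matrix(n=300, n_noise=10, seed=4)
        r = rank_features(y, X, BoostParams(seed=2))
        assert r.elimination_order[-1] == r.rank1


class TestAssignOrigin:
    def test_lookup_and_match_flags(self):
        X, y = planted_matrix(n=120, n_noise=2)
        meta = make_meta(
            {"driver": "liver", "noise00": "colon", "noise01": "brain"}
        )
        r = rank_features(y, X, BoostParams(seed=0))
        pred = assign_origin(r, meta, "s", expected_type="liver")
        assert pred.predicted_type == "liver" and pred.match is True
        pred2 = assign_origin(r, meta, "s", expected_type="colon")
        assert pred2.match is False
        pred3 = assign_origin(r, meta, "s")
        assert pred3.match is None

    def test_missing_metadata_rejected(self):
        X, y = planted_matrix(n=120, n_noise=2)
        meta = make_meta({"noise00": "colon", "noise01": "brain"})
        r = rank_features(y, X, BoostParams(seed=0))
        with pytest.raises(KeyError, match="driver"):
            assign_origin(r, meta, "s")


class TestRepeatPredictions:
    def test_exact_driver_always_recovered(self):
        X, y = planted_matrix(n=300, n_noise=5)
        meta = make_meta(
            {f: ("liver" if f == "driver" else "other") for f in X.feature_ids}
        )
        rep = repeat_predictions(
            y, X, meta, BoostParams(seed=0), n_repeats=5, base_seed=10,
            expected_type="liver",
        )
        assert rep.accuracy == 1.0 and rep.reproducible

    def test_single_repeat_accuracy_is_binary(self):
        X, y = planted_matrix(n=120, n_noise=2)
        meta = make_meta({f: "t" for f in X.feature_ids})
        rep = repeat_predictions(
            y, X, meta, BoostParams(seed=0), 1, 3, expected_type="absent"
        )
        assert rep.accuracy in (0.0, 1.0)

    def test_expected_type_absent_gives_zero_accuracy(self):
        X, y = planted_matrix(n=120, n_noise=2)
        meta = make_meta({f: "t" for f in X.feature_ids})
        rep = repeat_predictions(
            y, X, meta, BoostParams(seed=0), 3, 0, expected_type="nowhere"
        )
        assert rep.accuracy == 0.0 and rep.reproducible


class TestCvVarianceExplained:
    def test_noise_target_near_zero(self):
        rng = np.random.default_rng(0)
        r2s = []
        for seed in range(5):
            X = make_matrix(
                {f"f{j}": rng.poisson(5.0, 2000) for j in range(5)}
            )
            y = make_profile(rng.poisson(5.0, 2000))
            r2s.append(cv_variance_explained(y, X, BoostParams(seed=seed)))
        assert np.mean(r2s) <= 0.1

    def test_zero_variance_target_rejected(self):
        X, _ = planted_matrix(n=60, n_noise=2)
        with pytest.raises(ValueError, match="variance"):
            cv_variance_explained(make_profile([2] * 60), X, BoostParams(seed=0))

    def test_location_invariance(self):
        X, y = planted_matrix(n=400, n_noise=4, seed=6)
        r2 = cv_variance_explained(y, X, BoostParams(seed=1))
        y_shift = make_profile(y.counts + 7)
        r2_shift = cv_variance_explained(y_shift, X, BoostParams(seed=1))
        assert r2_shift == pytest.approx(r2, abs=0.05)
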