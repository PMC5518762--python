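import numpy as np
import pandas as pd
import pytest

from hybridrange import (
    BinaryMap,
    DomainError,
    SuitabilityMap,
    TrainingSet,
    build_family_ensembles,
    consensus_binary,
    ensemble_weighted_mean,
    fit_full,
    maxtss_threshold,
    project,
    split_sample_eval,
    tss,
)
from hybridrange.grids import cells_of
from hybridrange.sdm import FitResult

from conftest import make_flat_stack


def brute_force_maxtss(probs, labels, weights):
    """Double loop over every candidate threshold; smallest argmax wins."""
    best_t = best_s = None
    for t in np.unique(probs):
        pred = probs >= t
        a = weights[pred & (labels == 1)].sum()
        b = weights[pred & (labels == 0)].sum()
        c = weights[~pred & (labels == 1)].sum()
        d = weights[~pred & (labels == 0)].sum()
        s = a / (a + c) + d / (b + d) - 1.0
        if best_s is None or s > best_s + 1e-12:
            best_t, best_s = t, s
    return float(best_t), float(best_s)


def separable_training(n=100, seed=0, gap=10.0):
    """Linearly separable presences (warm) vs absences (cold)."""
    rng = np.random.default_rng(seed)
    temp = np.concatenate([rng.normal(25, 1, n), rng.normal(25 - gap, 1, n)])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    return TrainingSet(pd.DataFrame({"TEMP": temp}), y, np.ones(2 * n), "sep")


class TestTSS:
    @pytest.mark.parametrize(
        "conf,expected",
        [
            ((50, 0, 0, 50), 1.0),
            ((0, 50, 50, 0), -1.0),
            ((40, 10, 20, 30), 40 / 60 + 30 / 40 - 1.0),
        ],
    )
    def test_known_confusions(self, conf, expected):
        assert tss(*conf) == pytest.approx(expected, abs=1e-9)

    def test_bounded_on_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 200, 4)
            if a + c == 0 or b + d == 0:
                continue
            assert -1.0 <= tss(a, b, c, d) <= 1.0

    def test_empty_margin_is_an_error_not_nan(self):
        with pytest.raises(DomainError):
            tss(0, 10, 0, 10)
        with pytest.raises(DomainError):
            tss(10, 0, 10, 0)


class TestMaxTSSThreshold:
    def test_perfectly_ranked(self):
        thr, score = maxtss_threshold(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])
        )
        assert thr == pytest.approx(0.8)
        assert score == pytest.approx(1.0)

    def test_inverted_two_points_smallest_argmax(self):
        thr, score = maxtss_threshold(np.array([0.6, 0.4]), np.array([0, 1]))
        assert thr == pytest.approx(0.4)
        assert score <= 0.0

    def test_rank_invariance_under_constant_shift(self):
        rng = np.random.default_rng(1)
        probs = rng.uniform(0.1, 0.8, 50)
        labels = (rng.random(50) < 0.5).astype(float)
        eps = 1e-4
        t1, s1 = maxtss_threshold(probs, labels)
        t2, s2 = maxtss_threshold(probs + eps, labels)
        assert s2 == pytest.approx(s1)
        assert t2 == pytest.approx(t1 + eps)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 51)
            probs = np.round(rng.random(n), 3)
            labels = np.zeros(n)
            labels[rng.choice(n, max(1, int(n * rng.uniform(0.2, 0.8))), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            weights = rng.uniform(0.5, 2.0, n)
            got = maxtss_threshold(probs, labels, weights)
            want = brute_force_maxtss(probs, labels, weights)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            maxtss_threshold(np.array([0.5, 0.6]), np.array([1, 1]))


class TestSplitSampleEval:
    def test_separable_glm_scores_one(self):
        scores = split_sample_eval(separable_training(), "GLM", seed=3)
        assert len(scores) == 3
        assert all(s == pytest.approx(1.0) for s in scores)

    def test_deterministic_given_seed(self):
        train = separable_training(gap=2.0)
        assert split_sample_eval(train, "GLM", seed=5) == split_sample_eval(
            train, "GLM", seed=5
        )

    def test_uninformative_predictors_score_near_zero(self):
        rng = np.random.default_rng(8)
        n = 4000
        X = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
        y = (rng.random(n) < 0.5).astype(float)
        train = TrainingSet(X, y, np.ones(n), "null")
        scores = split_sample_eval(train, "GLM", seed=2)
        # maxTSS optimisation on held-out data biases scores slightly upward
        assert abs(float(np.mean(scores))) < 0.2


class TestFitAndProject:
    def test_separable_presences_predicted_present(self):
        train = separable_training()
        fit = fit_full(train, "GLM", eval_tss=[1.0, 1.0, 1.0])
        probs = fit.model.predict(train.X[train.y == 1])
        assert (probs >= 0.5).all()

    def test_tree_models_ace_separable_fixture(self):
        train = separable_training(n=150, seed=4)
        for algo in ("BRT", "RF"):
            scores = split_sample_eval(train, algo, seed=6)
            assert np.mean(scores) >= 0.9, algo

    def test_single_class_training_rejected(self):
        with pytest.raises(DomainError):
            TrainingSet(pd.DataFrame({"T": [1.0, 2.0]}), np.ones(2), np.ones(2))

    def _gradient_stack(self, n=20):
        grid = np.tile(np.linspace(0, 30, n), (n, 1))
        return make_flat_stack(n, resolution=0.5, layers={"TEMP": grid})

    def test_projection_consistent_with_pointwise_prediction(self):
        stack = self._gradient_stack()
        rng = np.random.default_rng(0)
        lon = rng.uniform(0, 10, 80)
        lat = rng.uniform(0.01, 10, 80)
        rows, cols = cells_of(lon, lat, stack)
        temp = stack.layers["TEMP"][rows, cols]
        y = (temp > 15).astype(float)
        train = TrainingSet(pd.DataFrame({"TEMP": temp}), y, np.ones(80), "sp")
        fit = fit_full(train, "GLM", eval_tss=[1.0])
        smap = project(fit, stack)
        assert np.nanmin(smap.values) >= 0 and np.nanmax(smap.values) <= 1
        np.testing.assert_allclose(
            smap.values[rows, cols],
            np.clip(fit.model.predict(train.X), 0, 1),
            atol=1e-12,
        )

    def test_warming_does_not_reduce_suitability_for_warm_adapted_glm(self):
        # positive-slope logistic response: a uniform +2 shift can only raise
        # per-cell probabilities (checked numerically on the projected grids)
        stack = self._gradient_stack()
        rng = np.random.default_rng(1)
        lon = rng.uniform(0, 10, 120)
        lat = rng.uniform(0.01, 10, 120)
        rows, cols = cells_of(lon, lat, stack)
        temp = stack.layers["TEMP"][rows, cols]
        prob = 1 / (1 + np.exp(-(temp - 15)))
        y = (rng.random(120) < prob).astype(float)
        if y.sum() in (0, len(y)):
            pytest.skip("degenerate draw")
        train = TrainingSet(pd.DataFrame({"TEMP": temp}), y, np.ones(120), "sp")
        fit = fit_full(train, "GLM", eval_tss=[1.0])
        base = project(fit, stack)
        warmed_stack = make_flat_stack(
            20, resolution=0.5, layers={"TEMP": stack.layers["TEMP"] + 2.0}
        )
        warmed = project(fit, warmed_stack)
        land = ~np.isnan(base.values)
        assert (warmed.values[land] >= base.values[land] - 1e-9).all()


class _ConstModel:
    def __init__(self, value: float):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def const_fit(algorithm, value, score, replicate_id=0):
    train = TrainingSet(
        pd.DataFrame({"T": [0.0, 1.0, 2.0, 3.0]}),
        np.array([0.0, 0.0, 1.0, 1.0]),
        np.ones(4),
        "dummy",
    )
    return FitResult(
        algorithm=algorithm,
        species_id="dummy",
        replicate_id=replicate_id,
        model=_ConstModel(value),
        train=train,
        eval_tss=[score],
    )


class TestEnsembles:
    def _maps(self, values):
        return [SuitabilityMap(np.array([[v, v], [v, np.nan]])) for v in values]

    def test_equal_weights_give_arithmetic_mean(self):
        out = ensemble_weighted_mean(self._maps([0.2, 0.6]), [0.5, 0.5])
        assert out.values[0, 0] == pytest.approx(0.4)

    def test_weighted_mean_hand_example(self):
        out = ensemble_weighted_mean(self._maps([0.2, 0.8]), [0.25, 0.75])
        assert out.values[0, 0] == pytest.approx(0.65)

    def test_single_map_identity(self):
        maps = self._maps([0.37])
        out = ensemble_weighted_mean(maps, [0.9])
        np.testing.assert_allclose(out.values, maps[0].values)

    def test_nonpositive_members_dropped(self):
        with pytest.warns(UserWarning):
            out = ensemble_weighted_mean(self._maps([0.2, 0.8]), [0.5, -0.1])
        assert out.values[0, 0] == pytest.approx(0.2)
        with pytest.raises(DomainError):
            ensemble_weighted_mean(self._maps([0.2]), [0.0])

    def test_family_membership_counts(self):
        stack = make_flat_stack(4, layers={"T": np.zeros((4, 4))})
        fits = [const_fit("GLM", 0.6, 0.8), const_fit("GAM", 0.6, 0.8)]
        for rep in range(1, 11):
            fits.append(const_fit("BRT", 0.4, 0.7, rep))
            fits.append(const_fit("RF", 0.4, 0.7, rep))
        ens = build_family_ensembles(
            fits, stack, thresholds={"regression": 0.5, "machine_learning": 0.5}
        )
        assert len(ens["regression"].member_algorithms) == 2
        assert len(ens["machine_learning"].member_algorithms) == 20
        # identical members -> ensemble equals any member
        assert np.nanmax(np.abs(ens["regression"].suitability.values - 0.6)) < 1e-12
        assert float(np.nansum(ens["regression"].binary.values)) == 16
        assert float(np.nansum(ens["machine_learning"].binary.values)) == 0

    def test_zero_weight_member_does_not_change_map(self):
        stack = make_flat_stack(4, layers={"T": np.zeros((4, 4))})
        base = [const_fit("GLM", 0.7, 0.8), const_fit("GAM", 0.3, 0.4)]
        padded = base + [const_fit("GLM", 0.99, 0.0)]
        thr = {"regression": 0.5}
        with pytest.warns(UserWarning):
            with_pad = build_family_ensembles(padded, stack, thr)["regression"]
        without = build_family_ensembles(base, stack, thr)["regression"]
        np.testing.assert_allclose(
            with_pad.suitability.values, without.suitability.values
        )


class TestConsensus:
    def _bmap(self, vals):
        return BinaryMap(np.asarray(vals, dtype=float))

    def test_truth_table(self):
        out = consensus_binary(self._bmap([[1, 1, 0, 0]]), self._bmap([[1, 0, 1, 0]]))
        np.testing.assert_array_equal(out.values, [[1, 0, 0, 0]])

    def test_subset_of_each_input_and_commutative(self):
        rng = np.random.default_rng(2)
        a = self._bmap(rng.integers(0, 2, (6, 6)).astype(float))
        b = self._bmap(rng.integers(0, 2, (6, 6)).astype(float))
        ab = consensus_binary(a, b)
        ba = consensus_binary(b, a)
        np.testing.assert_array_equal(ab.values, ba.values)
        assert not ((ab.values == 1) & (a.values == 0)).any()
        assert not ((ab.values == 1) & (b.values == 0)).any()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DomainError):
            consensus_binary(self._bmap([[1, 0]]), self._bmap([[1], [0]]))
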