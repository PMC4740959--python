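"""Reservoir dynamics, readout training, and classification protocols."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridesn._exceptions import ConfigurationError, InputError, ShapeError
from hybridesn.esn import (
    ESNClassifier,
    ESNState,
    StateMatrix,
    classify_threshold,
    classify_wta,
    harvest,
    harvest_batch,
    normalized_abs,
    predict,
    step,
    threshold_accuracy,
    train_readout,
    wta_accuracy,
)
from hybridesn.synth import gen_eeg_like, train_test_split

from conftest import make_weights


def lstsq_oracle(x, y, ridge=0.0):
    """Brute-force normal equations by explicit inversion."""
    gram = x @ x.T + ridge * np.eye(x.shape[0])
    return (y @ x.T) @ np.linalg.inv(gram)


class TestStep:
    def test_zero_state_zero_input_is_fixed_point(self):
        w = make_weights("hybrid", n=10)
        s = step(ESNState.zero(10), np.zeros(1), w)
        assert np.all(s.x == 0.0) and s.xc == 0.0 and s.t == 1

    def test_single_active_neuron_hand_evaluation(self):
        # isolate one neuron: w_in = 1, all recurrent/hub weights zero
        w = make_weights("hybrid", n=2)
        w.w_in[:] = 1.0
        w.w_ring[:] = w.w_up[:] = w.w_down[:] = 0.0
        s = step(ESNState.zero(2), np.array([0.1]), w, alpha=1.0)
        assert s.x == pytest.approx(np.tanh(0.1))

    def test_unit_ring_identity_activation_rotates_state(self):
        w = make_weights("one_way_ring", n=5)
        w.w_in[:] = 0.0
        w.w_ring[:] = 1.0
        state = ESNState(x=np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        s = step(state, np.zeros(1), w, alpha=1.0, activation=lambda v: v)
        assert np.allclose(s.x, [5.0, 1.0, 2.0, 3.0, 4.0])

    def test_dimension_mismatch_names_operands(self):
        w = make_weights("hybrid", n=4, k=2)
        with pytest.raises(ShapeError, match="channels"):
            step(ESNState.zero(4), np.zeros(3), w)

    def test_alpha_out_of_range_rejected(self):
        w = make_weights("hybrid", n=4)
        with pytest.raises(ConfigurationError):
            step(ESNState.zero(4), np.zeros(1), w, alpha=0.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_state_bounded_under_small_weights(self, seed):
        """Echo-state-style stability: tanh and small weights keep the
        state in [-1, 1] for arbitrary bounded input."""
        w = make_weights("hybrid", n=8, seed=3, weight_scale=0.3)
        rng = np.random.default_rng(seed)
        state = ESNState.zero(8)
        for _ in range(30):
            state = step(state, rng.uniform(-1, 1, 1), w, alpha=0.7)
            assert np.all(np.abs(state.x) <= 1.0)


class TestHarvest:
    def test_column_count_preserved_without_washout(self):
        w = make_weights("hybrid", n=6)
        sm = harvest(np.ones((1, 10)), w)
        assert sm.x_all.shape == (6, 10)

    def test_washout_discards_leading_columns(self):
        w = make_weights("hybrid", n=6)
        sm = harvest(np.ones((1, 10)), w, washout=4)
        assert sm.x_all.shape == (6, 6)

    def test_constant_input_converges_to_fixed_point(self):
        w = make_weights("hybrid", n=10, weight_scale=0.2)
        sm = harvest(np.ones((1, 300)), w, alpha=1.0)
        step_dist = np.linalg.norm(np.diff(sm.x_all[:, -50:], axis=1), axis=0)
        assert step_dist[-1] < 1e-10

    def test_empty_signal_rejected(self):
        w = make_weights("hybrid", n=4)
        with pytest.raises(InputError):
            harvest(np.empty((1, 0)), w)

    @pytest.mark.parametrize("kind", ["one_way_ring", "two_way_ring", "hybrid", "random"])
    def test_batch_harvest_matches_sequential(self, kind, rng):
        w = make_weights(kind, n=7, k=2, seed=4)
        signals = rng.normal(size=(3, 2, 20))
        batched = harvest_batch(signals, w, alpha=0.6)
        for b in range(3):
            sm = harvest(signals[b], w, alpha=0.6)
            assert np.allclose(batched[b], sm.x_all, atol=1e-12)


class TestReadout:
    def test_exact_recovery_square_system(self, rng):
        x = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        w_true = rng.normal(size=(2, 6))
        ro = train_readout(StateMatrix(x, w_true @ x), ridge=0.0)
        assert np.allclose(ro.w_out, w_true, atol=1e-9)

    def test_zero_targets_give_zero_weights(self, rng):
        x = rng.normal(size=(4, 30))
        ro = train_readout(StateMatrix(x, np.zeros((2, 30))), ridge=0.0)
        assert np.allclose(ro.w_out, 0.0, atol=1e-12)

    def test_matches_bruteforce_normal_equation_oracle(self, rng):
        x = rng.normal(size=(5, 40))
        y = rng.normal(size=(2, 40))
        ro = train_readout(StateMatrix(x, y), ridge=0.0)
        assert np.allclose(ro.w_out, lstsq_oracle(x, y), atol=1e-10)

    def test_ridge_matches_oracle_and_conditions_solution(self, rng):
        x = rng.normal(size=(5, 40))
        y = rng.normal(size=(2, 40))
        ro = train_readout(StateMatrix(x, y), ridge=0.5)
        assert np.allclose(ro.w_out, lstsq_oracle(x, y, 0.5), atol=1e-10)

    def test_oracle_agreement_on_well_conditioned_random_systems(self, rng):
        """Property: ridge=0 equals the explicit pseudo-inverse solution
        whenever the Gram matrix is well-conditioned."""
        for _ in range(20):
            x = rng.normal(size=(6, 50))
            if np.linalg.cond(x @ x.T) > 1e8:
                continue
            y = rng.normal(size=(3, 50))
            ro = train_readout(StateMatrix(x, y), ridge=0.0)
            rel = np.abs(ro.w_out - lstsq_oracle(x, y)).max() / np.abs(ro.w_out).max()
            assert rel < 1e-8

    def test_singular_gram_with_zero_ridge_advises_ridge(self):
        x = np.zeros((4, 10))
        x[0] = 1.0  # rank-1 states
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            train_readout(StateMatrix(x, np.ones((1, 10))), ridge=0.0)

    def test_predict_identity_readout_returns_states(self, rng):
        x = rng.normal(size=(4, 9))
        out = predict(train_readout(StateMatrix(np.eye(4), np.eye(4)), ridge=0.0),
                      StateMatrix(x))
        assert np.allclose(out, x, atol=1e-10)

    def test_row_of_ones_readout_sums_states(self, rng):
        from hybridesn.esn import ReadoutWeights

        x = rng.normal(size=(5, 7))
        out = predict(ReadoutWeights(np.ones((1, 5))), StateMatrix(x))
        assert np.allclose(out, x.sum(axis=0))

    def test_train_then_predict_recomposes_targets(self, rng):
        x = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        y = rng.normal(size=(2, 6))
        ro = train_readout(StateMatrix(x, y), ridge=0.0)
        assert np.allclose(predict(ro, StateMatrix(x)), y, atol=1e-8)


class TestClassification:
    def test_threshold_on_reference_targets_is_perfect(self):
        ref = np.array([0, 1, 1, 0, 1])
        assert threshold_accuracy(ref.astype(float), ref) == 1.0

    def test_constant_zero_output_vs_ones_reference_scores_zero(self):
        assert threshold_accuracy(np.zeros(6), np.ones(6, dtype=int)) == 0.0

    def test_hand_counted_threshold_accuracy(self):
        y = np.array([0.2, 0.7, 0.4, 0.9])
        assert threshold_accuracy(y, np.array([0, 1, 1, 1])) == pytest.approx(0.75)

    def test_threshold_labels_use_geq_convention(self):
        assert classify_threshold(np.array([0.5]), 0.5).tolist() == [1]

    def test_wta_recovers_one_hot_segments(self):
        y = np.zeros((3, 30))
        truth = [2, 0, 1]
        bounds = [(0, 10), (10, 20), (20, 30)]
        for (a, b), c in zip(bounds, truth):
            y[c, a:b] = 1.0
        assert classify_wta(y, bounds).tolist() == truth
        assert wta_accuracy(y, bounds, truth) == 1.0

    def test_wta_tie_breaks_toward_lowest_index(self):
        y = np.ones((2, 4))
        assert classify_wta(y, [(0, 4)]).tolist() == [0]

    def test_wta_hand_built_averages(self):
        y = np.array([
            [0.1, 0.1, 0.9, 0.9, 0.2, 0.2],
            [0.0, 0.0, 0.1, 0.1, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.0, 0.1, 0.1],
        ])
        labels = classify_wta(y, [(0, 2), (2, 4), (4, 6)])
        assert labels.tolist() == [2, 0, 1]

    def test_empty_segment_rejected(self):
        with pytest.raises(InputError):
            classify_wta(np.ones((2, 4)), [(2, 2)])


def test_normalized_abs_scales_by_training_maximum():
    x = np.array([[-4.0, 2.0, 1.0]])
    scaled, scale = normalized_abs(x)
    assert scale == 4.0
    assert np.allclose(scaled, [[1.0, 0.5, 0.25]])


class TestESNClassifier:
    def test_sklearn_param_round_trip(self):
        clf = ESNClassifier(n_reservoir=42, alpha=0.3)
        params = clf.get_params()
        assert params["n_reservoir"] == 42
        clone = ESNClassifier(**params)
        assert clone.get_params() == params

    def test_end_to_end_separable_stream_reaches_95_percent(self):
        """Parameter-recovery gate: a hybrid N=100 reservoir separates an
        easy synthetic two-class stream at >= 95% per-time-step accuracy."""
        ds = gen_eeg_like(n_per_class=24, duration_s=6.0, fs=100.0, seed=11)
        train, test = train_test_split(ds, 18, 6, seed=1)
        x_train, scale = normalized_abs(train.as_array())
        x_test = np.abs(test.as_array()) / scale
        clf = ESNClassifier(
            topology="hybrid", n_reservoir=100, decision="threshold", random_state=2
        )
        clf.fit(x_train, train.labels)
        assert clf.timestep_score(x_test, test.labels) >= 0.95

    def test_multiclass_wta_predicts_labels_from_classes(self):
        rng = np.random.default_rng(0)
        # three classes with distinct channel energies
        segs, labels = [], []
        for c in range(3):
            for _ in range(8):
                seg = 0.05 * rng.normal(size=(3, 60))
                seg[c] += 1.0
                segs.append(seg)
                labels.append(f"class{c}")
        x = np.stack(segs)
        y = np.array(labels)
        clf = ESNClassifier(n_reservoir=30, random_state=1).fit(x, y)
        assert set(clf.predict(x)) <= set(y)
        assert clf.score(x, y) == 1.0

    def test_digital_mode_runs_and_is_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, size=(8, 1, 40))
        y = np.repeat([0, 1], 4)
        clf = ESNClassifier(n_reservoir=12, mode="digital", random_state=0)
        a = clf.fit(x, y).decision_function(x)
        b = ESNClassifier(n_reservoir=12, mode="digital", random_state=0).fit(
            x, y
        ).decision_function(x)
        assert np.array_equal(a, b)

    def test_threshold_decision_requires_binary_labels(self):
        x = np.zeros((6, 1, 10))
        y = np.array([0, 1, 2, 0, 1, 2])
        clf = ESNClassifier(decision="threshold", n_reservoir=5)
        with pytest.raises(ConfigurationError):
            clf.fit(x, y)
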