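"""Propagation, loss and random-search fitting of the cell-cycle model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclefit import (
    FitConfig,
    MarkovCellCycleModel,
    PhaseCountSeries,
    TransitionMatrix,
    fit_transition_matrix,
    random_matrix,
    rmsre,
    step,
    trajectory,
)
from cyclefit.matrices import REPLICATION_MATRIX
from cyclefit.model import ZeroObservedCountError


def step_oracle(state, matrix):
    """Brute-force per-flux propagation: sum_i S[i] * P[i,j] * RM[i,j]."""
    out = np.zeros(4)
    for i in range(4):
        for j in range(4):
            out[j] += state[i] * matrix[i, j] * REPLICATION_MATRIX[i, j]
    return out


class TestStep:
    def test_all_homotypic_leaves_state_unchanged(self):
        s = np.array([10.0, 20.0, 30.0, 40.0])
        assert np.array_equal(step(s, TransitionMatrix.identity()), s)

    def test_forced_division_doubles_m_cells(self):
        # all M cells divide: 100 mothers -> 200 G1 daughters
        p = TransitionMatrix.from_rates(0.0, 0.0, 1.0, 0.0)
        out = step(np.array([0.0, 0.0, 100.0, 0.0]), p)
        assert np.array_equal(out, [200.0, 0.0, 0.0, 0.0])

    def test_matches_per_flux_oracle_on_random_instances(self, rng):
        s = np.array([50.0, 30.0, 20.0, 0.0])
        for _ in range(25):
            p = random_matrix(rng)
            assert np.allclose(step(s, p), step_oracle(s, p.values), rtol=1e-14)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            step(np.array([-1.0, 0, 0, 0]), TransitionMatrix.identity())

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_with_growth(self, seed):
        """Total count grows by exactly S[M] * P[M,G1] each step."""
        r = np.random.default_rng(seed)
        p = random_matrix(r)
        s = r.uniform(0, 100, size=4)
        out = step(s, p)
        assert out.sum() == pytest.approx(s.sum() + s[2] * p["M", "G1"], rel=1e-12)


class TestTrajectory:
    def test_zero_hours_returns_initial_state_only(self):
        t = trajectory([1.0, 2, 3, 4], TransitionMatrix.identity(), 0)
        assert len(t) == 1
        assert np.array_equal(t.counts[0], [1, 2, 3, 4])

    def test_all_homotypic_is_constant_over_72_hours(self):
        t = trajectory([5.0, 6, 7, 8], TransitionMatrix.identity(), 72)
        assert len(t) == 73
        assert np.all(t.counts == t.counts[0])

    def test_multinucleated_count_non_decreasing(self, rng):
        for _ in range(10):
            p = random_matrix(rng)
            t = trajectory([50.0, 30, 20, 5], p, 48)
            assert np.all(np.diff(t.counts[:, 3]) >= -1e-12)

    def test_iterated_step_equivalence(self, control_matrix):
        t = trajectory([100.0, 50, 10, 2], control_matrix, 5)
        s = np.array([100.0, 50, 10, 2])
        for k in range(1, 6):
            s = step(s, control_matrix)
            assert np.allclose(t.counts[k], s, rtol=1e-15)


class TestRmsre:
    def test_zero_for_identical_series(self, control_matrix):
        t = trajectory([100.0, 50, 10, 2], control_matrix, 24)
        assert rmsre(t, t) == 0.0

    def test_constant_relative_error_is_that_error(self):
        obs = np.array([[4.0, 8, 2, 6], [10, 2, 4, 8], [6, 6, 6, 6], [2, 4, 8, 10]])
        pred = obs * 1.5  # pred - obs = obs/2 everywhere
        assert rmsre(pred, obs) == pytest.approx(0.5)

    def test_matches_direct_formula_on_random_instance(self, rng):
        obs = rng.uniform(1, 10, size=(6, 4))
        pred = obs + rng.normal(0, 1, size=(6, 4))
        per_phase = [
            np.sqrt(np.mean((pred[:, j] - obs[:, j]) ** 2 / obs[:, j] ** 2))
            for j in range(4)
        ]
        assert rmsre(pred, obs) == pytest.approx(np.mean(per_phase), rel=1e-12)

    def test_zero_observed_count_raises_naming_phase(self):
        obs = np.array([[1.0, 1, 0, 1]])
        with pytest.raises(ZeroObservedCountError, match="M"):
            rmsre(obs + 1, obs)
        # stabilizer makes it computable
        assert np.isfinite(rmsre(obs + 1, obs, eps=1e-6))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_non_negative_and_zero_on_self(self, seed):
        r = np.random.default_rng(seed)
        obs = r.uniform(0.1, 10, size=(5, 4))
        pred = r.uniform(0.1, 10, size=(5, 4))
        assert rmsre(pred, obs) >= 0
        assert rmsre(obs, obs) == 0


class TestFit:
    def test_constant_series_fits_to_near_identity(self):
        obs = PhaseCountSeries.from_counts(
            np.arange(25.0), np.tile([100.0, 80, 20, 10], (25, 1))
        )
        result = fit_transition_matrix(obs, FitConfig(seed=0))
        assert np.allclose(result.best_matrix.homotypic_rates, 1.0, atol=1e-6)
        assert result.rmsre < 1e-6

    def test_error_trace_non_increasing(self, control_matrix, control_initial):
        obs = trajectory(control_initial, control_matrix, 72)
        result = fit_transition_matrix(obs, FitConfig(seed=3))
        assert np.all(np.diff(result.error_trace) <= 1e-15)

    def test_recovers_known_rates_on_noiseless_series(self, control_matrix, control_initial):
        obs = trajectory(control_initial, control_matrix, 72)
        result = fit_transition_matrix(obs, FitConfig(seed=1))
        err = np.abs(
            result.best_matrix.homotypic_rates - control_matrix.homotypic_rates
        )
        assert np.median(err) <= 0.02
        assert result.rmsre < 1e-2

    def test_bit_reproducible_given_seed(self, control_matrix, control_initial):
        obs = trajectory(control_initial, control_matrix, 36)
        a = fit_transition_matrix(obs, FitConfig(seed=11))
        b = fit_transition_matrix(obs, FitConfig(seed=11))
        assert np.array_equal(a.best_matrix.values, b.best_matrix.values)
        assert np.array_equal(a.error_trace, b.error_trace)

    def test_learning_rate_schedule_halves_every_two_epochs(self):
        cfg = FitConfig()
        lrs = [cfg.learning_rate(e) for e in range(1, 7)]
        assert lrs == [0.1, 0.1, 0.05, 0.05, 0.025, 0.025]

    def test_degenerate_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_transition_matrix(
                PhaseCountSeries.from_counts(np.arange(3.0), np.zeros((3, 4))),
                FitConfig(seed=0),
            )

    def test_zero_count_in_series_raises_without_eps(self):
        counts = np.tile([10.0, 5, 2, 0], (10, 1))
        obs = PhaseCountSeries.from_counts(np.arange(10.0), counts)
        with pytest.raises(ZeroObservedCountError):
            fit_transition_matrix(obs, FitConfig(seed=0))


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        model = MarkovCellCycleModel(epochs=4, random_state=9)
        params = model.get_params()
        assert params["epochs"] == 4
        clone = MarkovCellCycleModel(**params)
        assert clone.get_params() == params

    def test_fit_predict_reconstructs_observations(self, control_matrix, control_initial):
        obs = trajectory(control_initial, control_matrix, 72)
        model = MarkovCellCycleModel(random_state=2).fit(obs)
        pred = model.predict()
        norm = obs.normalize()
        assert rmsre(pred.counts, norm.counts) == pytest.approx(model.rmsre_)
        assert -model.score(obs) == pytest.approx(model.rmsre_)

    def test_accepts_plain_arrays(self, control_matrix):
        obs = trajectory([100.0, 50, 10, 5], control_matrix, 24)
        model = MarkovCellCycleModel(epochs=3, candidates_per_epoch=200, random_state=0)
        model.fit(obs.counts)
        assert hasattr(model, "transition_matrix_")
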