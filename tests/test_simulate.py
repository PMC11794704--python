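"""Synthetic population and agent-level generators."""

import numpy as np
import pandas as pd
import pytest

from cyclefit import (
    PHASES,
    SimulationConfig,
    TransitionMatrix,
    random_study_matrix,
    simulate_agents,
    simulate_population,
    step,
    trajectory,
)
from cyclefit.calling import call_phases


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_hours=1),
            dict(frames_per_hour=0),
            dict(initial_counts=[0, 0, 0, 0]),
            dict(initial_counts=[-1, 10, 0, 0]),
            dict(count_noise_model="gamma"),
            dict(intensity_noise_sd=-0.1),
        ],
    )
    def test_invalid_configs_rejected(self, control_matrix, kwargs):
        base = dict(true_matrix=control_matrix, n_hours=12)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimulationConfig(**base)


class TestSimulatePopulation:
    def test_all_homotypic_rates_one_keeps_counts_constant(self):
        cfg = SimulationConfig(
            true_matrix=TransitionMatrix.identity(),
            initial_counts=[10, 20, 30, 40],
            n_hours=12,
        )
        series = simulate_population(cfg)
        assert np.all(series.counts == series.counts[0])

    def test_forced_division_doubles_population(self):
        cfg = SimulationConfig(
            true_matrix=TransitionMatrix.from_rates(0.0, 0.0, 1.0, 0.0),
            initial_counts=[0, 0, 100, 0],
            n_hours=2,
        )
        series = simulate_population(cfg)
        assert np.array_equal(series.counts[1], [200, 0, 0, 0])
        assert series.totals[1] == 200.0

    def test_noiseless_equals_trajectory_exactly(self, control_matrix, control_initial):
        cfg = SimulationConfig(
            true_matrix=control_matrix, initial_counts=control_initial, n_hours=24
        )
        series = simulate_population(cfg)
        ref = trajectory(control_initial, control_matrix, 24)
        assert np.array_equal(series.counts, ref.counts)

    def test_matches_stepwise_hand_propagation(self, rng):
        m = random_study_matrix(rng)
        cfg = SimulationConfig(true_matrix=m, initial_counts=[50, 30, 20, 5], n_hours=5)
        series = simulate_population(cfg)
        s = np.array([50.0, 30, 20, 5])
        for k in range(1, 6):
            s = step(s, m)
            assert np.allclose(series.counts[k], s, rtol=1e-15)

    def test_total_growth_equals_division_flux(self, control_matrix, control_initial):
        cfg = SimulationConfig(
            true_matrix=control_matrix, initial_counts=control_initial, n_hours=24
        )
        series = simulate_population(cfg)
        growth = np.diff(series.totals)
        expected = series.counts[:-1, 2] * control_matrix["M", "G1"]
        assert np.allclose(growth, expected, rtol=1e-12)

    @pytest.mark.parametrize("noise", ["poisson", "lognormal"])
    def test_observation_noise_is_seeded_and_unbiased(self, control_matrix, noise):
        cfg = dict(
            true_matrix=control_matrix,
            initial_counts=[1000, 500, 120, 40],
            n_hours=12,
            count_noise_model=noise,
            seed=5,
        )
        a = simulate_population(SimulationConfig(**cfg))
        b = simulate_population(SimulationConfig(**cfg))
        assert np.array_equal(a.counts, b.counts)  # same substream
        clean = simulate_population(
            SimulationConfig(**{**cfg, "count_noise_model": "none"})
        )
        rel = np.abs(a.counts - clean.counts) / clean.counts
        assert 0 < rel.mean() < 0.5


class TestSimulateAgents:
    def test_no_mitotic_failure_means_no_multinucleated_agents(self):
        m = TransitionMatrix.from_dwell_times(4.0, 8.0, 2.0, 1.0)  # MSR = 1
        cfg = SimulationConfig(
            true_matrix=m, initial_counts=[300, 150, 50, 0], n_hours=20,
            frames_per_hour=1, seed=1,
        )
        rec = simulate_agents(cfg, emit_features=False)
        assert not (rec["true_phase"] == "Multinucleated").any()

    def test_multinucleated_agents_never_revert(self, small_sim_config):
        rec = simulate_agents(small_sim_config, emit_features=False)
        order = {p: i for i, p in enumerate(PHASES)}
        for _, grp in rec.groupby("cell_id"):
            phases = grp.sort_values("time_h")["true_phase"].map(order).to_numpy()
            multi = phases == 3
            if multi.any():
                assert multi[multi.argmax():].all()

    def test_frame_times_strictly_increasing_per_cell(self, small_sim_config):
        rec = simulate_agents(small_sim_config, emit_features=False)
        assert (
            rec.sort_values(["cell_id", "time_h"]).groupby("cell_id")["time_h"]
            .diff().dropna() > 0
        ).all()

    def test_geometric_dwell_time_mean(self):
        """Mean G1 dwell with homotypic rate 0.5 is 1/(1-0.5) = 2 h."""
        m = TransitionMatrix.from_rates(0.5, 0.5, 0.4, 0.1)
        cfg = SimulationConfig(
            true_matrix=m, initial_counts=[20_000, 0, 0, 0], n_hours=40,
            frames_per_hour=1, seed=3,
        )
        rec = simulate_agents(cfg, emit_features=False)
        founders = rec[rec["cell_id"] < 20_000]
        exits = (
            founders[founders["true_phase"] != "G1"].groupby("cell_id")["time_h"].min()
        )
        assert exits.mean() == pytest.approx(2.0, abs=0.05)

    def test_noiseless_features_round_trip_through_phase_caller(self, small_sim_config):
        rec = simulate_agents(small_sim_config)
        labels = call_phases(rec)
        assert (labels.to_numpy() == rec["true_phase"].to_numpy()).all()

    def test_reproducible_for_fixed_seed(self, small_sim_config):
        a = simulate_agents(small_sim_config)
        b = simulate_agents(small_sim_config)
        pd.testing.assert_frame_equal(a, b)

    def test_population_fractions_converge_to_expectation(self, control_matrix):
        """Law of large numbers: hourly agent fractions approach the
        deterministic population fractions as the population grows."""
        init = np.array([3000, 1500, 380, 120])
        cfg = SimulationConfig(
            true_matrix=control_matrix, initial_counts=init, n_hours=12,
            frames_per_hour=1, seed=21,
        )
        rec = simulate_agents(cfg, emit_features=False)
        tally = (
            rec.groupby(["time_h", "true_phase"]).size().unstack(fill_value=0)
            .reindex(columns=list(PHASES), fill_value=0)
        )
        agent_frac = tally.div(tally.sum(axis=1), axis=0).loc[np.arange(13.0)]
        pop = trajectory(init, control_matrix, 12)
        assert np.abs(agent_frac.to_numpy() - pop.fractions()).max() < 0.02


class TestStudyMatrices:
    def test_random_study_matrix_is_valid_and_in_regime(self, rng):
        for _ in range(50):
            m = random_study_matrix(rng)
            diag = m.homotypic_rates
            assert np.all(diag[:3] >= 1 - 1 / 3.5)
            assert diag[3] == 1.0
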