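"""Decomposition: cost function, fixed-N fitting, knee selection."""

import numpy as np
import pytest

from submovekit.decompose import (
    DecompositionConfig,
    decompose_fixed_n,
    decompose_reach,
    reconstruction_cost,
    select_optimal_n,
)
from submovekit.io import ReachTrial, differentiate
from submovekit.minjerk import Submovement, TimeGrid, position_trajectory, superpose


def trial_from_subs(subs, t_end=2.0, target_from_subs=True):
    grid = TimeGrid.regular(t_end)
    start = np.zeros(3)
    p = position_trajectory(subs, start, grid)
    target = p[-1] if target_from_subs else np.array([40.0, 0, 0])
    tr = ReachTrial("synthetic", grid, p, start, target)
    tr.v = superpose(subs, grid)
    tr.a = np.gradient(tr.v, grid.dt, axis=0)
    return tr


CFG = DecompositionConfig(n_restarts=2, seed=0)


class TestCost:
    def test_perfect_fit_costs_zero(self):
        subs = [Submovement(0.1, 0.6, np.array([30.0, 5.0, -2.0]))]
        trial = trial_from_subs(subs)
        signal = np.sum(trial.v**2) * trial.t.dt
        assert reconstruction_cost(subs, trial, CFG) <= 1e-8 * signal

    def test_empty_set_costs_signal_power(self):
        subs = [Submovement(0.1, 0.6, np.array([30.0, 0, 0]))]
        trial = trial_from_subs(subs)
        expected = np.sum(trial.v**2) * trial.t.dt
        assert reconstruction_cost([], trial, CFG) == pytest.approx(expected)

    def test_opposing_overlap_penalized(self):
        """Two coincident opposite submovements reconstruct zero velocity
        (zero error against a null trial) but pay the overlap penalty,
        equal by quadrature to twice the integrated |v| of one pulse."""
        a = Submovement(0.5, 0.6, np.array([10.0, 0, 0]))
        b = Submovement(0.5, 0.6, np.array([-10.0, 0, 0]))
        null_trial = trial_from_subs([a, b])  # velocities cancel exactly
        assert np.allclose(null_trial.v, 0)
        # give the trial nonzero RMS so the penalty scale is nonzero
        probe = Submovement(0.1, 0.3, np.array([5.0, 0, 0]))
        trial = trial_from_subs([probe])
        cost_clean = reconstruction_cost([probe], trial, CFG)
        cost_opposing = reconstruction_cost([probe, a, b], trial, CFG)
        from submovekit.decompose import _lambda_effective, _velocities
        lam = _lambda_effective(trial, CFG)
        v_one = _velocities(np.array(a.as_tuple()), trial.t)[0]
        expected_penalty = lam * 2.0 * np.sum(np.abs(v_one)) * trial.t.dt
        assert cost_opposing - cost_clean == pytest.approx(expected_penalty, rel=1e-6)


class TestFixedN:
    def test_single_submovement_recovery(self):
        true = Submovement(0.0, 0.6, np.array([30.0, 0, 0]))
        trial = trial_from_subs([true], t_end=1.2)
        subs, cost = decompose_fixed_n(trial, 1, CFG)
        assert subs[0].t0 == pytest.approx(true.t0, abs=0.02)
        assert subs[0].D == pytest.approx(true.D, abs=0.05)
        assert subs[0].A == pytest.approx(true.A, abs=0.5)

    def test_two_separated_submovements_recovered(self):
        true = [
            Submovement(0.0, 0.5, np.array([25.0, 5.0, 0])),
            Submovement(0.8, 0.4, np.array([8.0, -2.0, 3.0])),
        ]
        trial = trial_from_subs(true, t_end=1.6)
        subs, _ = decompose_fixed_n(trial, 2, CFG)
        for fit, t in zip(subs, true):
            assert fit.t0 == pytest.approx(t.t0, abs=0.02)
            assert fit.D == pytest.approx(t.D, abs=0.05)
            assert fit.A == pytest.approx(t.A, abs=0.5)

    def test_overparameterized_fit_no_worse(self):
        true = Submovement(0.1, 0.6, np.array([30.0, 0, 0]))
        trial = trial_from_subs([true], t_end=1.3)
        cfg = DecompositionConfig(n_range=(1, 2, 3), n_restarts=2, seed=0)
        res = decompose_reach(trial, cfg)
        assert res.cost_curve[1] <= res.cost_curve[0] + cfg.tol

    def test_matches_grid_search_oracle(self):
        """Brute-force search over (t0, D) with per-(t0,D) linear-optimal
        amplitudes agrees with the gradient-based fit within the grid step."""
        true = Submovement(0.15, 0.5, np.array([20.0, -6.0, 4.0]))
        trial = trial_from_subs([true], t_end=1.0)
        g = 30.0
        best = (np.inf, None)
        for t0 in np.arange(0.0, 0.5, 0.025):
            for D in np.arange(0.1, 1.0, 0.025):
                tau = np.clip((trial.t.samples - t0) / D, 0, 1)
                mask = ((trial.t.samples - t0) >= 0) & ((trial.t.samples - t0) <= D)
                shape = g * tau**2 * (1 - tau) ** 2 * mask / D
                denom = shape @ shape
                if denom == 0:
                    continue
                A = trial.v.T @ shape / denom
                sse = np.sum((np.outer(shape, A) - trial.v) ** 2)
                if sse < best[0]:
                    best = (sse, (t0, D, A))
        t0_g, D_g, A_g = best[1]
        subs, _ = decompose_fixed_n(trial, 1, CFG)
        assert subs[0].t0 == pytest.approx(t0_g, abs=0.025)
        assert subs[0].D == pytest.approx(D_g, abs=0.025)
        assert subs[0].A == pytest.approx(A_g, abs=0.5)


class TestKneeSelection:
    def test_spec_elbow_curve(self):
        # normalized distances below the diagonal peak at N=2
        assert select_optimal_n([1.0, 0.2, 0.1, 0.05], (1, 2, 3, 4)) == 2

    def test_ideal_elbow(self):
        assert select_optimal_n([1.0, 0.0, 0.0, 0.0], (1, 2, 3, 4)) == 2

    def test_linear_curve_degenerates_to_smallest(self):
        assert select_optimal_n([4.0, 3.0, 2.0, 1.0], (1, 2, 3, 4)) == 1

    def test_constant_curve_warns_and_returns_smallest(self):
        with pytest.warns(UserWarning):
            assert select_optimal_n([1.0, 1.0, 1.0], (1, 2, 3)) == 1


class TestDecomposeReach:
    def test_noiseless_single_submovement(self):
        trial = trial_from_subs([Submovement(0.0, 0.6, np.array([30.0, 0, 0]))], t_end=1.2)
        cfg = DecompositionConfig(n_range=tuple(range(1, 6)), n_restarts=2, seed=0)
        res = decompose_reach(trial, cfg)
        assert res.n_star in (1, 2)
        assert res.recon_vaf >= 99.9

    def test_cost_curve_monotone_on_corpus(self, decomposed_corpus):
        _, _, decomps, (gen, dcfg) = decomposed_corpus
        for d in decomps.values():
            assert np.all(np.diff(d.cost_curve) <= dcfg.tol + 1e-9)

    def test_fitted_durations_respect_bounds(self, decomposed_corpus):
        _, _, decomps, (gen, dcfg) = decomposed_corpus
        for d in decomps.values():
            for s in d.submovements:
                assert dcfg.d_min - 1e-9 <= s.D <= dcfg.d_max + 1e-9

    def test_deterministic_given_seed(self):
        trial = trial_from_subs(
            [Submovement(0.0, 0.5, np.array([20.0, 4.0, 0])), Submovement(0.6, 0.4, np.array([6.0, 0, 2.0]))],
            t_end=1.5,
        )
        cfg = DecompositionConfig(n_range=(1, 2, 3), n_restarts=2, seed=3)
        a = decompose_reach(trial, cfg)
        b = decompose_reach(trial, cfg)
        assert np.array_equal(a.cost_curve, b.cost_curve)
        assert a.n_star == b.n_star
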