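"""Closed-loop simulator: stub policies, stopping rules, determinism."""

import numpy as np
import pytest

from submovekit.closed_loop import SimulationConfig, simulate_reach
from submovekit.features import dttaps


class PerfectPolicy:
    """Amplitude = exact remaining vector, duration 0.5 s, never corrects."""

    def trigger_prob(self, ctx):
        return 0.0

    def amplitude(self, ctx, k):
        done = sum((s.A for s in ctx.initiated), np.zeros(3))
        return ctx.target - ctx.start - done

    def duration(self, ctx, k):
        return 0.5


class AlwaysTriggerPolicy(PerfectPolicy):
    def trigger_prob(self, ctx):
        return 1.0

    def amplitude(self, ctx, k):
        return np.array([0.1, 0.0, 0.0])


class ZeroAmplitudePolicy(PerfectPolicy):
    def amplitude(self, ctx, k):
        return np.zeros(3)


START = np.zeros(3)
TARGET = np.array([30.0, 10.0, 20.0])


class TestStoppingRules:
    def test_perfect_policy_hits_with_one_submovement(self):
        res = simulate_reach(PerfectPolicy(), START, TARGET)
        assert res.success
        assert res.n_submovements == 1
        assert res.end_distance == pytest.approx(0.0, abs=1e-9)
        # dwell clock starts when the fingertip enters the 1.27 cm radius,
        # slightly before the 0.5 s submovement completes
        assert 1.3 < res.times[-1] <= 1.5

    def test_always_trigger_fails_at_submovement_cap(self):
        res = simulate_reach(AlwaysTriggerPolicy(), START, TARGET)
        assert not res.success
        assert res.failure_reason == "submovement_cap"
        assert res.n_submovements == 30

    def test_zero_amplitude_fails_at_timeout(self):
        res = simulate_reach(ZeroAmplitudePolicy(), START, TARGET)
        assert not res.success
        assert res.failure_reason == "timeout"
        assert res.times[-1] == pytest.approx(3.0)
        assert res.end_distance == pytest.approx(np.linalg.norm(TARGET - START))

    def test_success_requires_full_dwell(self):
        cfg = SimulationConfig(dwell=2.0, timeout=2.2)
        res = simulate_reach(PerfectPolicy(), START, TARGET, cfg)
        # arrival at 0.5 s leaves only 1.7 s < 2.0 s dwell
        assert not res.success
        assert res.failure_reason == "timeout"


class TestTrajectoryProperties:
    def test_deterministic(self):
        a = simulate_reach(PerfectPolicy(), START, TARGET)
        b = simulate_reach(PerfectPolicy(), START, TARGET)
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_causal_prefix_equivalence(self):
        """Truncating the simulation horizon leaves the common prefix
        unchanged: no step depends on later predictions."""

        class CountdownPolicy(PerfectPolicy):
            def trigger_prob(self, ctx):
                return 0.9 if abs(ctx.t_now - 0.25) < 1e-9 else 0.0

            def amplitude(self, ctx, k):
                return 0.5 * super().amplitude(ctx, k)

        full = simulate_reach(CountdownPolicy(), START, TARGET, SimulationConfig(timeout=3.0))
        short = simulate_reach(CountdownPolicy(), START, TARGET, SimulationConfig(timeout=1.0))
        n = len(short.trajectory)
        assert np.array_equal(full.trajectory[:n], short.trajectory[:n])

    def test_corrective_loop_converges(self):
        """A policy covering 80% of the remaining vector per submovement
        converges into the target within a few corrections."""

        class GeometricPolicy(PerfectPolicy):
            def trigger_prob(self, ctx):
                # correct 0.35 s after the last onset if not on target
                planned = ctx.start + sum((s.A for s in ctx.initiated), np.zeros(3))
                late = ctx.t_now - ctx.initiated[-1].t0 >= 0.35
                return 1.0 if late and np.linalg.norm(planned - ctx.target) > 1.0 else 0.0

            def amplitude(self, ctx, k):
                return 0.8 * super().amplitude(ctx, k)

        res = simulate_reach(GeometricPolicy(), START, TARGET)
        assert res.success
        assert 2 <= res.n_submovements <= 6
        assert res.end_distance < 1.27

    def test_dttaps_seen_by_policy_matches_definition(self):
        seen = {}

        class RecordingPolicy(PerfectPolicy):
            def amplitude(self, ctx, k):
                seen[k] = dttaps(ctx, k)
                return super().amplitude(ctx, k)

        simulate_reach(RecordingPolicy(), START, TARGET)
        assert seen[1] == pytest.approx(np.linalg.norm(TARGET - START))
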