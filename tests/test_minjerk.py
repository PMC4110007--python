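"""Closed-form minimum-jerk basis: shape, support, conservation, linearity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from submovekit.minjerk import (
    InvalidSubmovementError,
    Submovement,
    TimeGrid,
    minjerk_acceleration,
    minjerk_velocity,
    position_trajectory,
    superpose,
)

GRID = TimeGrid.regular(2.0)


def idx(t):
    return int(round(t / GRID.dt))


class TestVelocity:
    def test_peak_value_is_15_over_8_A_over_D(self):
        sub = Submovement(0.0, 1.0, np.array([10.0, 0.0, 0.0]))
        v = minjerk_velocity(sub, GRID)
        assert v[idx(0.5)] == pytest.approx([18.75, 0.0, 0.0])

    def test_integral_recovers_amplitude(self):
        sub = Submovement(0.0, 1.0, np.array([10.0, -4.0, 2.5]))
        v = minjerk_velocity(sub, GRID)
        disp = np.trapezoid(v, dx=GRID.dt, axis=0)
        assert disp == pytest.approx(sub.A, abs=1e-4)

    def test_compact_support(self):
        sub = Submovement(0.5, 0.8, np.array([10.0, 3.0, -1.0]))
        v = minjerk_velocity(sub, GRID)
        assert np.all(v[GRID.samples < 0.5 - 1e-12] == 0)
        assert np.all(v[GRID.samples > 1.3 + 1e-12] == 0)
        # polynomial vanishes at the boundaries themselves
        assert v[idx(0.5)] == pytest.approx([0, 0, 0])
        assert v[idx(1.3)] == pytest.approx([0, 0, 0])

    def test_single_positive_component_gives_nonnegative_speed(self):
        sub = Submovement(0.2, 0.6, np.array([7.0, 0.0, 0.0]))
        v = minjerk_velocity(sub, GRID)
        assert np.all(v[:, 0] >= 0)
        assert np.all(v[:, 1:] == 0)

    def test_too_short_duration_rejected(self):
        with pytest.raises(InvalidSubmovementError):
            Submovement(0.0, 0.05, np.zeros(3))

    def test_non_finite_amplitude_rejected(self):
        with pytest.raises(InvalidSubmovementError):
            Submovement(0.0, 0.5, np.array([np.nan, 0, 0]))


class TestSuperposition:
    def test_empty_set_is_zero(self):
        assert np.all(superpose([], GRID) == 0)

    def test_singleton_equals_single_velocity(self):
        sub = Submovement(0.1, 0.5, np.array([5.0, 1.0, 0.0]))
        assert np.array_equal(superpose([sub], GRID), minjerk_velocity(sub, GRID))

    def test_duplicated_submovement_doubles_velocity(self):
        sub = Submovement(0.1, 0.5, np.array([5.0, 1.0, 0.0]))
        assert np.allclose(superpose([sub, sub], GRID), 2 * minjerk_velocity(sub, GRID))


class TestPosition:
    def test_no_submovements_stays_at_start(self):
        start = np.array([1.0, 2.0, 3.0])
        pos = position_trajectory([], start, GRID)
        assert np.all(pos == start)

    def test_midpoint_displacement_is_half(self):
        sub = Submovement(0.0, 1.0, np.array([10.0, 0.0, 0.0]))
        pos = position_trajectory([sub], np.zeros(3), GRID)
        assert pos[idx(0.5)] == pytest.approx([5.0, 0.0, 0.0])

    def test_reaches_target_when_amplitudes_telescope(self):
        start = np.array([0.0, 0.0, 0.0])
        target = np.array([30.0, 0.0, 40.0])
        subs = [
            Submovement(0.0, 0.6, 0.7 * target),
            Submovement(0.4, 0.4, 0.3 * target),
        ]
        pos = position_trajectory(subs, start, GRID)
        assert pos[-1] == pytest.approx(target, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.floats(0.0, 1.0),          # t0
            st.floats(0.1, 0.8),          # D
            st.floats(-30.0, 30.0),       # Ax
            st.floats(-30.0, 30.0),       # Ay
            st.floats(-30.0, 30.0),       # Az
        ),
        min_size=0,
        max_size=5,
    )
)
def test_displacement_conservation(data):
    """Final position - start equals the amplitude sum: exact in closed form,
    O(dt^2) via trapezoidal integration of the superposed velocity."""
    subs = [Submovement(t0, D, np.array([ax, ay, az])) for t0, D, ax, ay, az in data]
    start = np.array([3.0, -2.0, 1.0])
    pos = position_trajectory(subs, start, GRID)
    total = sum((s.A for s in subs), np.zeros(3))
    assert pos[-1] - start == pytest.approx(total, abs=1e-6)
    v = superpose(subs, GRID)
    # trapezoid error is O((dt/D)^2) per submovement
    bound = 1e-9 + sum(np.abs(s.A).sum() * (GRID.dt / s.D) ** 2 for s in subs)
    assert np.abs(np.trapezoid(v, dx=GRID.dt, axis=0) - total).max() <= bound


def test_closed_form_position_matches_integrated_velocity():
    subs = [
        Submovement(0.0, 0.7, np.array([20.0, -5.0, 10.0])),
        Submovement(0.3, 0.5, np.array([-4.0, 8.0, 1.0])),
    ]
    pos = position_trajectory(subs, np.zeros(3), GRID)
    v = superpose(subs, GRID)
    integrated = np.concatenate(
        [np.zeros((1, 3)), np.cumsum((v[1:] + v[:-1]) / 2 * GRID.dt, axis=0)]
    )
    assert np.abs(pos - integrated).max() < 5e-3  # O(dt^2)


def test_velocity_is_smooth_at_boundaries():
    """The pulse's first derivative vanishes at both ends, so acceleration
    is continuous (zero) across the support boundary."""
    sub = Submovement(0.5, 1.0, np.array([10.0, 0.0, 0.0]))
    a = minjerk_acceleration(sub, GRID)
    assert a[idx(0.5)] == pytest.approx([0, 0, 0])
    assert a[idx(1.5)] == pytest.approx([0, 0, 0])
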