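"""Receptor sensing, overlap geometry, steering and movement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sggrad.cells import (
    CellAgent,
    MotilityParams,
    OccupancyWindow,
    local_gradient,
    move,
    overlapped_points,
    propose_heading,
    receptor_occupancy,
    wrap_angle,
)
from sggrad.field import AttractantField


def brute_force_overlap(position, field, radius):
    """Independent enumeration of all lattice nodes within the radius."""
    ny, nx = field.shape
    out = set()
    for r in range(ny):
        for c in range(nx):
            x, y = c * field.spacing, r * field.spacing
            if (x - position[0]) ** 2 + (y - position[1]) ** 2 <= radius**2 + 1e-9:
                out.add((r, c))
    return out


class TestReceptorOccupancy:
    @pytest.mark.parametrize(
        "c,kd,expected",
        [(0.0, 12.0, 0.0), (12.0, 12.0, 0.5), (108.0, 12.0, 0.9)],
    )
    def test_binding_isotherm(self, c, kd, expected):
        assert receptor_occupancy(c, kd) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            receptor_occupancy(-1.0, 12.0)

    @given(st.floats(0.0, 1e9), st.floats(1e-3, 1e6))
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_saturating(self, c, kd):
        y = receptor_occupancy(c, kd)
        assert 0.0 <= y < 1.0
        assert receptor_occupancy(c * 2 + 1, kd) > y or c > 1e18


class TestOverlappedPoints:
    def test_nine_points_on_node(self):
        # dx = 4, radius 6: centre node, 4 at distance 4, 4 at sqrt(32)
        f = AttractantField.uniform((11, 11), 1.0, 4.0, 150.0)
        pts = overlapped_points((20.0, 20.0), f, 6.0)
        assert len(pts) == 9
        assert pts == brute_force_overlap((20.0, 20.0), f, 6.0)

    def test_small_radius_single_point(self):
        f = AttractantField.uniform((11, 11), 1.0, 4.0, 150.0)
        pts = overlapped_points((20.0, 20.0), f, 1.5)
        assert pts == {(5, 5)}

    def test_translation_by_one_spacing(self):
        f = AttractantField.uniform((11, 11), 1.0, 4.0, 150.0)
        a = overlapped_points((16.0, 20.0), f, 6.0)
        b = overlapped_points((20.0, 20.0), f, 6.0)
        assert {(r, c + 1) for r, c in a} == b

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_at_random_positions(self, seed):
        rng = np.random.default_rng(seed)
        f = AttractantField.uniform((13, 13), 1.0, 4.0, 150.0)
        pos = rng.uniform(8.0, 40.0, size=2)
        assert overlapped_points(pos, f, 6.0) == brute_force_overlap(pos, f, 6.0)


class TestLocalGradient:
    def test_uniform_field_zero_vector(self):
        f = AttractantField.uniform((11, 11), 50.0, 4.0, 150.0)
        g = local_gradient((20.0, 20.0), f, 6.0)
        assert np.allclose(g, 0.0)

    def test_exact_on_linear_field(self):
        f = AttractantField.uniform((11, 11), 0.0, 4.0, 150.0)
        slope = 2.5
        f.concentrations[:] = 7.0 + slope * np.arange(11)[None, :] * 4.0
        g = local_gradient((20.0, 20.0), f, 6.0)
        assert abs(g[0] - slope) < 1e-10
        assert abs(g[1]) < 1e-10

    def test_quadratic_field_within_spacing_error(self):
        dx = 4.0
        f = AttractantField.uniform((21, 21), 0.0, dx, 150.0)
        xs = np.arange(21) * dx
        f.concentrations[:] = 0.01 * xs[None, :] ** 2
        # analytic gradient at x0: 0.02 * x0
        g = local_gradient((40.0, 40.0), f, 6.0)
        assert abs(g[0] - 0.02 * 40.0) < 0.01 * 2 * dx
        assert abs(g[1]) < 1e-10

    def test_single_point_degenerate_zero(self):
        f = AttractantField.uniform((11, 11), 1.0, 4.0, 150.0)
        f.concentrations[5, 5] = 99.0
        g = local_gradient((20.0, 20.0), f, 1.5)
        assert np.allclose(g, 0.0)


class TestProposeHeading:
    def test_no_bias_tiny_sigma_keeps_heading(self, rng):
        p = MotilityParams(wrapped_normal_sigma=1e-9, bias_strength=0.0)
        h = propose_heading(0.7, np.zeros(2), p, rng, 12.0)
        assert h == pytest.approx(0.7, abs=1e-6)

    def test_zero_gradient_circular_mean_is_current_heading(self, rng):
        p = MotilityParams(wrapped_normal_sigma=0.6, bias_strength=2.0)
        n = 100_000
        h = propose_heading(
            np.full(n, 1.0), np.zeros((n, 2)), p, rng, 12.0
        )
        mean = np.angle(np.exp(1j * h).mean())
        r = np.abs(np.exp(1j * h).mean())
        circ_se = np.sqrt((1 - r**2) / n) / r
        assert abs(wrap_angle(mean - 1.0)) < 3 * circ_se

    def test_strong_bias_aligns_with_gradient(self, rng):
        p = MotilityParams(wrapped_normal_sigma=0.6, bias_strength=50.0)
        n = 100_000
        grad = np.tile([1.0, 0.0], (n, 1))  # huge contrast: saturated bias
        h = propose_heading(rng.uniform(-np.pi, np.pi, n), grad, p, rng, 12.0)
        mean = np.angle(np.exp(1j * h).mean())
        r = np.abs(np.exp(1j * h).mean())
        circ_se = np.sqrt((1 - r**2) / n) / r
        assert abs(mean) < 3 * circ_se

    def test_subthreshold_contrast_gives_no_bias(self, rng):
        p = MotilityParams(bias_strength=5.0, contrast_threshold=1e-3)
        # contrast = |grad| * sense_length = 5e-5 * 12 < 1e-3
        n = 50_000
        h = propose_heading(
            np.full(n, 2.0), np.tile([5e-5 / 12, 0.0], (n, 1)) * 12, p, rng, 12.0
        )
        mean = np.angle(np.exp(1j * np.asarray(h)).mean())
        assert abs(wrap_angle(mean - 2.0)) < 0.05

    def test_chemotactic_index_increases_with_bias(self, rng):
        sense = 12.0
        grad = np.array([[2e-4, 0.0]])  # mid-range contrast
        cis = []
        for b in [0.0, 1.0, 4.0]:
            p = MotilityParams(bias_strength=b)
            n = 20_000
            h = propose_heading(
                rng.uniform(-np.pi, np.pi, n), np.tile(grad[0], (n, 1)), p, rng, sense
            )
            cis.append(np.cos(h).mean())
        assert cis[0] < cis[1] < cis[2]


class TestMove:
    def test_exact_step_length(self):
        pos, th = move(np.array([0.0, 10.0]), 0.0, 10.0, 60.0, (1000.0, 1000.0))
        assert pos[0] == pytest.approx(10.0)
        assert pos[1] == pytest.approx(10.0)
        assert th == 0.0

    def test_zero_dt_no_motion(self):
        pos, th = move(np.array([5.0, 5.0]), 1.0, 10.0, 0.0, (100.0, 100.0))
        assert np.allclose(pos, [5.0, 5.0])

    def test_reflection_keeps_cell_inside(self):
        pos, th = move(np.array([1.0, 50.0]), np.pi, 60.0, 60.0, (100.0, 100.0))
        assert 0.0 <= pos[0] <= 100.0
        # displacement magnitude bounded by speed * dt
        assert np.hypot(pos[0] - 1.0, pos[1] - 50.0) <= 60.0 + 1e-9

    def test_reflection_inverts_normal_heading(self):
        pos, th = move(np.array([2.0, 50.0]), np.pi, 10.0, 60.0, (100.0, 100.0))
        assert pos[0] == pytest.approx(8.0)
        assert th == pytest.approx(0.0)


class TestOccupancyWindow:
    def test_constant_input_converges_to_constant(self):
        w = OccupancyWindow(3, window_s=60.0, dt_s=1.0)
        for _ in range(61):
            w.push(np.full(3, 0.7))
        assert np.allclose(w.average, 0.7)

    def test_step_input_reaches_half_at_half_window(self):
        w = OccupancyWindow(1, window_s=60.0, dt_s=1.0)
        for _ in range(60):
            w.push(np.zeros(1))
        for _ in range(30):
            w.push(np.ones(1))
        assert w.average[0] == pytest.approx(0.5)

    def test_average_stays_within_window_contents(self):
        rng = np.random.default_rng(0)
        w = OccupancyWindow(1, window_s=10.0, dt_s=1.0)
        for _ in range(100):
            w.push(rng.uniform(0.2, 0.9, size=1))
            assert 0.0 <= w.average[0] <= 0.9

    def test_reset_and_grow(self):
        w = OccupancyWindow(2, window_s=5.0, dt_s=1.0)
        for _ in range(5):
            w.push(np.ones(2))
        w.reset(0)
        assert w.average[0] == 0.0
        assert w.average[1] == 1.0
        w.grow(1)
        assert w.average.shape == (3,)
        assert w.average[2] == 0.0

    def test_out_of_range_sample_rejected(self):
        w = OccupancyWindow(1)
        with pytest.raises(ValueError):
            w.push(np.array([1.2]))


class TestPersistentWalkStatistics:
    def test_heading_autocorrelation_matches_wrapped_normal(self, rng):
        # one reorientation: E[cos(dtheta)] = exp(-sigma^2 / 2)
        sigma = 0.6
        p = MotilityParams(wrapped_normal_sigma=sigma, bias_strength=0.0)
        n = 200_000
        h0 = rng.uniform(-np.pi, np.pi, n)
        h1 = propose_heading(h0, np.zeros((n, 2)), p, rng, 12.0)
        est = np.cos(h1 - h0).mean()
        expected = np.exp(-(sigma**2) / 2.0)
        assert est == pytest.approx(expected, abs=3.0 / np.sqrt(n))

    def test_msd_crossover_matches_persistence_theory(self, rng):
        # unbiased persistent walk: for t >> tau, MSD ~ 2 v^2 tau t with
        # tau = -dt_reorient / ln(exp(-sigma^2/2))
        sigma, dt_re, speed = 0.8, 5.0, 10.0
        p = MotilityParams(wrapped_normal_sigma=sigma, bias_strength=0.0)
        v = speed / 60.0
        tau = dt_re / (sigma**2 / 2.0)
        n = 4000
        heads = rng.uniform(-np.pi, np.pi, n)
        pos = np.zeros((n, 2))
        t_end = 2400.0
        steps = int(t_end / dt_re)
        for _ in range(steps):
            heads = propose_heading(heads, np.zeros((n, 2)), p, rng, 12.0)
            pos[:, 0] += v * dt_re * np.cos(heads)
            pos[:, 1] += v * dt_re * np.sin(heads)
        msd = (pos**2).sum(axis=1).mean()
        expected = 2.0 * v**2 * tau * (t_end - tau)
        assert msd == pytest.approx(expected, rel=0.2)


class TestCellAgent:
    def test_sense_and_reorient_on_ramp(self, rng):
        f = AttractantField.uniform((11, 26), 0.0, 4.0, 150.0)
        f.concentrations[:] = np.arange(26)[None, :] * 2.0  # 0.5 nM/um ramp
        agent = CellAgent(position=np.array([48.0, 20.0]), heading=np.pi)
        c_local, y, grad = agent.sense(f)
        assert c_local == pytest.approx(24.0, rel=0.2)
        assert 0.0 < y < 1.0
        assert grad[0] > 0
        agent.motility = MotilityParams(
            wrapped_normal_sigma=0.1, bias_strength=100.0
        )
        agent.reorient(grad, rng)
        assert abs(agent.heading) < 0.5  # steered up-gradient

    def test_move_respects_bounds(self):
        agent = CellAgent(position=np.array([1.0, 1.0]), heading=-3.0)
        agent.move(120.0, (100.0, 40.0))
        x, y = agent.position
        assert 0.0 <= x <= 100.0 and 0.0 <= y <= 40.0
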