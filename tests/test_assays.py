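"""Scenario builders and scoring statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from sggrad.assays import (
    build_bridge,
    build_disc_well,
    build_population_scan,
    build_two_spot,
    leading_distance,
    radial_leading_distance,
    score_response,
    score_two_spot,
    time_to_pass,
    total_vmax,
    two_spot_counts,
)
from sggrad.engine import run


def synthetic_trajectory(positions_by_time, y=10.0):
    """Tidy trajectory table from {time: [x positions]} (fixed cell count)."""
    rows = []
    for t, xs in sorted(positions_by_time.items()):
        for cid, x in enumerate(xs):
            rows.append((float(t), cid, float(x), y, 0.0, 0.0, 0.0, "none"))
    return pd.DataFrame(
        rows,
        columns=[
            "time_s", "cell_id", "x_um", "y_um",
            "heading_rad", "occupancy", "occupancy_avg", "event",
        ],
    )


class TestBuilders:
    def test_imposed_bridge_pins_strips_and_forms_expected_slope(self):
        # 0-300 nM over 1 mm: steady-state interior gradient 0.3 nM/um
        spec = build_bridge(300.0, mode="imposed", cells=0, duration_s=1800.0)
        res = run(spec)
        c = res.field.concentrations
        nx = c.shape[1]
        ramp = 300.0 * np.arange(nx) / (nx - 1)
        assert np.abs(c - ramp[None, :]).max() < 0.02 * 300.0
        slope = (c[2, -1] - c[2, 0]) / spec.geometry.length_um
        assert slope == pytest.approx(0.3, rel=0.01)

    def test_uniform_bridge_has_no_fixed_points(self):
        from sggrad.engine import build_field

        spec = build_bridge(300.0, mode="self_generated", cells=10, duration_s=0.0)
        f = build_field(spec)
        assert np.all(f.concentrations == 300.0)
        assert not f.fixed_mask.any()

    def test_long_imposed_bridge_slope(self):
        # 6 mm, 0-10 uM: slope 10/6 nM/um encoded by the geometry
        spec = build_bridge(10000.0, mode="imposed", length_um=6000.0, cells=0,
                            duration_s=0.0)
        assert spec.field_init.c_high_nM / spec.geometry.length_um == pytest.approx(
            10.0 / 6.0, rel=1e-9
        )

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            build_bridge(300.0, mode="sideways")

    def test_population_scan_specs_differ_only_in_count_and_seed(self):
        specs = build_population_scan(10000.0, [50, 100, 200, 400])
        assert [s.cell_init.count for s in specs] == [50, 100, 200, 400]
        assert len({s.seed for s in specs}) == 4
        dumps = []
        for s in specs:
            d = s.model_dump()
            d["cell_init"].pop("count")
            d.pop("seed")
            dumps.append(d)
        assert all(d == dumps[0] for d in dumps)

    def test_population_scan_total_vmax_derived(self):
        (spec,) = build_population_scan(10000.0, [200])
        assert total_vmax(spec) == 200 * spec.cell_init.cell.vmax

    def test_empty_population_list_rejected(self):
        with pytest.raises(ValueError):
            build_population_scan(10000.0, [])

    def test_two_spot_geometry_constraint(self):
        with pytest.raises(Exception):
            build_two_spot(1000.0, spot_radius_um=300.0, separation_um=250.0)


class TestScoreResponse:
    def test_all_or_none_fractions(self):
        traj = synthetic_trajectory({0: [0.0] * 5, 3600: [500.0] * 5})
        assert score_response(traj, 400.0, 3600.0) == 1.0
        traj = synthetic_trajectory({0: [0.0] * 5, 3600: [100.0] * 5})
        assert score_response(traj, 400.0, 3600.0) == 0.0

    def test_partial_fraction(self):
        xs0 = [0.0] * 10
        xs1 = [500.0] * 3 + [100.0] * 7
        traj = synthetic_trajectory({0: xs0, 3600: xs1})
        assert score_response(traj, 400.0, 3600.0) == pytest.approx(0.3)

    def test_time_beyond_run_rejected(self):
        traj = synthetic_trajectory({0: [0.0], 60: [1.0]})
        with pytest.raises(ValueError, match="ends"):
            score_response(traj, 400.0, 3600.0)

    @given(st.lists(st.floats(0.0, 1000.0), min_size=3, max_size=30))
    @settings(deadline=None, max_examples=40)
    def test_monotone_nonincreasing_in_threshold(self, finals):
        traj = synthetic_trajectory({0: [0.0] * len(finals), 60: finals})
        scores = [score_response(traj, d, 60.0) for d in (100.0, 400.0, 800.0)]
        assert scores[0] >= scores[1] >= scores[2]


class TestTimeToPass:
    def test_ballistic_cell_passes_at_speed_times_time(self):
        # 10 um/min from x=0: passes 1 mm just after 100 min
        times = {t: [10.0 / 60.0 * t] for t in range(0, 6301, 60)}
        traj = synthetic_trajectory(times)
        res = time_to_pass(traj, n=1, distance_um=1000.0)
        assert not res.censored
        assert res.time_s == pytest.approx(6000.0, abs=61.0)

    def test_censored_when_population_too_small(self):
        traj = synthetic_trajectory({0: [0.0] * 5, 60: [2000.0] * 5})
        res = time_to_pass(traj, n=100, distance_um=1000.0)
        assert res.censored
        assert res.time_s == float("inf")

    def test_counts_distinct_cells(self):
        traj = synthetic_trajectory({0: [0, 0, 0], 60: [1500, 100, 100],
                                     120: [1500, 1500, 100]})
        assert time_to_pass(traj, n=2, distance_um=1000.0).time_s == 120.0


class TestLeadingDistance:
    def test_k_equals_population_mean_of_all(self):
        traj = synthetic_trajectory({0: [0.0] * 10, 60: list(range(100, 1100, 100))})
        assert leading_distance(traj, k=10, t_s=60.0) == pytest.approx(550.0)

    def test_k_one_is_maximum(self):
        traj = synthetic_trajectory({0: [0.0] * 10, 60: list(range(100, 1100, 100))})
        assert leading_distance(traj, k=1, t_s=60.0) == 1000.0

    def test_top_two_of_ladder(self):
        traj = synthetic_trajectory({0: [0.0] * 10, 60: list(range(100, 1100, 100))})
        assert leading_distance(traj, k=2, t_s=60.0) == pytest.approx(950.0)

    def test_too_few_cells_rejected(self):
        traj = synthetic_trajectory({0: [0.0] * 3, 60: [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="alive"):
            leading_distance(traj, k=10, t_s=60.0)

    def test_radial_variant_uses_radial_displacement(self):
        traj = synthetic_trajectory({0: [500.0], 60: [800.0]}, y=500.0)
        assert radial_leading_distance(traj, 1, 60.0, (500.0, 500.0)) == pytest.approx(
            300.0
        )


class TestTwoSpotScore:
    def test_exact_double_counts_positive(self):
        pos = np.array([[1.0, 0.0]] * 10 + [[-1.0, 0.0]] * 5)
        assert score_two_spot(pos, (0.0, 0.0), (1.0, 0.0)) is True

    def test_just_below_double_negative(self):
        pos = np.array([[1.0, 0.0]] * 9 + [[-1.0, 0.0]] * 5)
        assert score_two_spot(pos, (0.0, 0.0), (1.0, 0.0)) is False

    def test_rotation_invariance(self, rng):
        pos = rng.normal(size=(40, 2)) * 50.0 + 10.0
        center = np.array([10.0, 10.0])
        axis = np.array([1.0, 0.0])
        base = two_spot_counts(pos, center, axis)
        for phi in (0.3, 1.2, 2.9):
            rot = np.array(
                [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
            )
            assert (
                two_spot_counts((pos - center) @ rot.T + center, center, rot @ axis)
                == base
            )

    def test_uniform_random_placement_matches_binomial_tail(self, rng):
        # 15 cells placed uniformly, no simulation: P(front >= 2*back)
        # equals the exact binomial tail P(F >= 10)
        n, trials = 15, 20000
        expected = 1.0 - binom.cdf(9, n, 0.5)
        hits = 0
        for _ in range(trials):
            r = 100.0 * np.sqrt(rng.uniform(size=n))
            phi = rng.uniform(-np.pi, np.pi, n)
            pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
            hits += score_two_spot(pos, (0.0, 0.0), (1.0, 0.0))
        freq = hits / trials
        se = np.sqrt(expected * (1 - expected) / trials)
        assert freq == pytest.approx(expected, abs=4 * se)


class TestScoringPurity:
    def test_same_trajectory_same_score(self):
        spec = build_bridge(300.0, cells=10, duration_s=300.0, length_um=400.0,
                            reservoir_length_um=200.0)
        res = run(spec)
        s1 = score_response(res.trajectory, 100.0, 300.0)
        s2 = score_response(res.trajectory.copy(), 100.0, 300.0)
        assert s1 == s2
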