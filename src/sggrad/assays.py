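"""Builders and scoring statistics for the four simulated assays.

* **bridge** — cells cross a channel between two reservoirs, either up an
  imposed gradient held between pinned source/sink strips or through an
  initially uniform attractant they degrade into a self-generated wave.
  Scored by the *response score* (fraction of the starting cells whose
  displacement along the channel exceeds a threshold within a time window),
  the *time to pass* (first time n cells have covered a given distance) and
  the *leading distance* (mean displacement of the k front-most cells).
* **population scan** — the bridge at a fixed background, varying the
  number of seeded cells.
* **disc well** — cells start in a central disc in a uniform background and
  migrate radially outward; scored by the radial leading distance.
* **two spot** — a drop of cells next to an equal drop of attractant on an
  open field; scored positive when, splitting all cells by the line through
  the original drop centre perpendicular to the spot-spot axis, at least
  twice as many sit in the attractant-facing half as in the far half.

Builders return fully resolved :class:`~sggrad.scenario.ScenarioSpec`
objects; scoring functions are pure functions of a trajectory table.

The builder defaults for the disc-well and two-spot arenas are
scaled-down re-creations of the bench-scale layouts (the same geometry at
a fraction of the linear size) so that a full concentration ladder with
replicates runs in minutes; pass explicit dimensions for full-size runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .engine import RunResult, run
from .scenario import (
    BridgeGeometry,
    CellInit,
    CellModel,
    DiscWellGeometry,
    ImposedGradientInit,
    LogicSpec,
    MotilityModel,
    NumericsSpec,
    ScenarioSpec,
    TwoSpotGeometry,
    UniformInit,
)

__all__ = [
    "ScoreResult",
    "TimeToPass",
    "build_bridge",
    "build_population_scan",
    "build_disc_well",
    "build_two_spot",
    "score_response",
    "time_to_pass",
    "leading_distance",
    "radial_leading_distance",
    "score_two_spot",
    "two_spot_counts",
    "score_run",
    "run_scenario",
    "total_vmax",
]

# Assay-scale numerics shared by all builders (coarser than the library
# defaults; accuracy checked against the unit oracles at this setting).
_ASSAY_NUMERICS = dict(
    dx_um=5.0,
    field_dt_s=0.1,
    agent_dt_s=1.0,
    diffusion_um2_s=300.0,
)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------
@dataclass
class TimeToPass:
    time_s: float
    censored: bool


@dataclass
class ScoreResult:
    """Assay-level statistics of one run (fields unused by an assay = None)."""

    response_score: float | None = None
    time_to_pass_s: float | None = None
    time_to_pass_censored: bool | None = None
    leading_distances_um: list = dc_field(default_factory=list)
    two_spot_positive: bool | None = None
    front_count: int | None = None
    back_count: int | None = None

    def to_dict(self) -> dict:
        return {
            "response_score": self.response_score,
            "time_to_pass_s": self.time_to_pass_s,
            "time_to_pass_censored": self.time_to_pass_censored,
            "leading_distances_um": list(self.leading_distances_um),
            "two_spot_positive": self.two_spot_positive,
            "front_count": self.front_count,
            "back_count": self.back_count,
        }


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------
def build_bridge(
    concentration_nM: float,
    mode: str = "self_generated",
    length_um: float = 1000.0,
    width_um: float = 50.0,
    reservoir_length_um: float = 500.0,
    cells: int = 100,
    duration_s: float = 3600.0,
    seed: int = 0,
    degradation: str | None = None,
    mitogen: bool = False,
    record_every_s: float = 60.0,
    cell_overrides: dict | None = None,
    motility_overrides: dict | None = None,
) -> ScenarioSpec:
    """Bridge assay scenario.

    ``mode='imposed'`` pins a sink strip (at the cells' end) at 0 nM and a
    source strip at ``concentration_nM`` across the bare channel, with no
    degradation; the gradient forms dynamically between the strips.
    ``mode='self_generated'`` fills channel and reservoirs uniformly at
    ``concentration_nM`` with degradation on (``always_on`` unless
    overridden).
    """
    if mode not in ("self_generated", "imposed"):
        raise ValueError(f"unknown bridge mode: {mode!r}")
    if mode == "imposed":
        geometry = BridgeGeometry(
            length_um=length_um, width_um=width_um, reservoir_length_um=0.0
        )
        field_init = ImposedGradientInit(c_low_nM=0.0, c_high_nM=concentration_nM)
        if degradation is None:
            degradation = "none"
    else:
        geometry = BridgeGeometry(
            length_um=length_um,
            width_um=width_um,
            reservoir_length_um=reservoir_length_um,
        )
        field_init = UniformInit(concentration_nM=concentration_nM)
        if degradation is None:
            degradation = "always_on"
    return ScenarioSpec(
        geometry=geometry,
        field_init=field_init,
        cell_init=CellInit(
            count=cells,
            cell=CellModel(**(cell_overrides or {})),
            motility=MotilityModel(**(motility_overrides or {})),
        ),
        logic=LogicSpec(degradation=degradation, mitogen=mitogen),
        numerics=NumericsSpec(**_ASSAY_NUMERICS),
        duration_s=duration_s,
        seed=seed,
        record_every_s=record_every_s,
    )


def build_population_scan(
    background_nM: float,
    populations: list[int],
    base_seed: int = 0,
    **bridge_kwargs,
) -> list[ScenarioSpec]:
    """One self-generated bridge spec per population, seeds varied in step."""
    if not populations:
        raise ValueError("populations must be non-empty")
    return [
        build_bridge(
            background_nM,
            mode="self_generated",
            cells=int(n),
            seed=base_seed + i,
            **bridge_kwargs,
        )
        for i, n in enumerate(populations)
    ]


def build_disc_well(
    background_nM: float,
    well_radius_um: float = 250.0,
    arena_um: float = 1400.0,
    cells: int = 120,
    duration_s: float = 5400.0,
    seed: int = 0,
    degradation: str = "always_on",
    mitogen: bool = False,
    record_every_s: float = 60.0,
) -> ScenarioSpec:
    """Radial (one-spot) assay: cells seeded in a central disc."""
    return ScenarioSpec(
        geometry=DiscWellGeometry(well_radius_um=well_radius_um, arena_um=arena_um),
        field_init=UniformInit(concentration_nM=background_nM),
        cell_init=CellInit(count=cells),
        logic=LogicSpec(degradation=degradation, mitogen=mitogen),
        numerics=NumericsSpec(**_ASSAY_NUMERICS),
        duration_s=duration_s,
        seed=seed,
        record_every_s=record_every_s,
    )


def build_two_spot(
    spot_concentration_nM: float,
    degradation: str = "none",
    spot_radius_um: float = 125.0,
    separation_um: float = 250.0,
    pad_um: float = 300.0,
    cells: int = 200,
    duration_s: float = 3600.0,
    seed: int = 0,
    record_every_s: float = 60.0,
    diffusion_um2_s: float = 75.0,
    field_dt_s: float = 0.25,
    cell_overrides: dict | None = None,
    motility_overrides: dict | None = None,
) -> ScenarioSpec:
    """Two-spot assay: cell drop beside an equal attractant drop.

    The default geometry is a quarter-scale model of the bench layout
    (500 um drops spaced 1 mm centre-to-centre); the attractant diffusion
    coefficient is scaled by the same linear factor, which preserves the
    ratio of the arena flooding time to the cell crossing time.  The arena
    border drains to zero (open boundary), standing in for the much larger
    agar field around the drops.

    The default cell kinetics differ from the bridge assays: the two-spot
    system is a cyclic-AMP / phosphodiesterase pairing, modelled with a
    sharper enzyme (Km = 100 nM) and a higher sensory detection threshold
    than the folate system used on the bridges.
    """
    numerics = dict(_ASSAY_NUMERICS)
    numerics["diffusion_um2_s"] = diffusion_um2_s
    numerics["field_dt_s"] = field_dt_s
    cell_kw = {"km_nM": 100.0}
    cell_kw.update(cell_overrides or {})
    mot_kw = {"contrast_threshold": 2.0e-3}
    mot_kw.update(motility_overrides or {})
    return ScenarioSpec(
        geometry=TwoSpotGeometry(
            spot_radius_um=spot_radius_um,
            separation_um=separation_um,
            pad_um=pad_um,
        ),
        field_init=UniformInit(concentration_nM=spot_concentration_nM),
        cell_init=CellInit(
            count=cells,
            cell=CellModel(**cell_kw),
            motility=MotilityModel(**mot_kw),
        ),
        logic=LogicSpec(degradation=degradation),
        numerics=NumericsSpec(**numerics),
        duration_s=duration_s,
        seed=seed,
        record_every_s=record_every_s,
    )


def total_vmax(spec: ScenarioSpec) -> float:
    """Population degradation capacity: cell count x per-cell Vmax."""
    return spec.cell_init.count * spec.cell_init.cell.vmax


# ----------------------------------------------------------------------
# trajectory helpers
# ----------------------------------------------------------------------
def _record_times(traj: pd.DataFrame) -> np.ndarray:
    return np.sort(traj.loc[traj["event"] == "none", "time_s"].unique())


def _positions_at(traj: pd.DataFrame, t: float) -> pd.DataFrame:
    """Rows of the regular record nearest to time ``t`` (error if uncovered)."""
    times = _record_times(traj)
    if times.size == 0:
        raise ValueError("trajectory contains no records")
    if t > times[-1] + 1e-9:
        raise ValueError(f"trajectory ends at {times[-1]} s, before t={t} s")
    idx = int(np.argmin(np.abs(times - t)))
    t_sel = times[idx]
    return traj[(traj["event"] == "none") & (traj["time_s"] == t_sel)]


def _displacements(traj: pd.DataFrame, t: float, radial_center=None) -> pd.Series:
    """Per-cell displacement at time ``t``: along x, or radial if a centre
    is given; measured from each cell's own first recorded position."""
    rows = _positions_at(traj, t)
    first = traj.loc[traj.groupby("cell_id")["time_s"].idxmin()]
    first = first.set_index("cell_id")
    rows = rows.set_index("cell_id")
    if radial_center is None:
        return rows["x_um"] - first.loc[rows.index, "x_um"]
    cx, cy = radial_center
    r_now = np.hypot(rows["x_um"] - cx, rows["y_um"] - cy)
    r_then = np.hypot(
        first.loc[rows.index, "x_um"] - cx, first.loc[rows.index, "y_um"] - cy
    )
    return r_now - r_then.values


# ----------------------------------------------------------------------
# scores
# ----------------------------------------------------------------------
def score_response(
    traj: pd.DataFrame, distance_um: float = 400.0, t_s: float = 3600.0
) -> float:
    """Fraction of the initially seeded cells displaced beyond
    ``distance_um`` along the channel axis at time ``t_s``."""
    initial_ids = set(
        traj.loc[
            (traj["time_s"] == traj["time_s"].min()) & (traj["event"] == "none"),
            "cell_id",
        ]
    )
    disp = _displacements(traj, t_s)
    disp = disp[disp.index.isin(initial_ids)]
    if len(initial_ids) == 0:
        raise ValueError("no initially seeded cells in trajectory")
    return float((disp > distance_um).sum()) / len(initial_ids)


def time_to_pass(
    traj: pd.DataFrame, n: int = 100, distance_um: float = 1000.0
) -> TimeToPass:
    """First record time at which >= n distinct cells have covered
    ``distance_um`` along the axis; censored if that never happens."""
    times = _record_times(traj)
    first = traj.loc[traj.groupby("cell_id")["time_s"].idxmin()].set_index("cell_id")
    reg = traj[traj["event"] == "none"]
    disp = reg["x_um"].values - first.loc[reg["cell_id"], "x_um"].values
    passed = reg.loc[disp > distance_um, ["time_s", "cell_id"]]
    if passed.empty:
        return TimeToPass(float("inf"), True)
    first_pass = passed.groupby("cell_id")["time_s"].min().sort_values()
    if len(first_pass) < n:
        return TimeToPass(float("inf"), True)
    return TimeToPass(float(first_pass.iloc[n - 1]), False)


def leading_distance(traj: pd.DataFrame, k: int = 10, t_s: float = 3600.0) -> float:
    """Mean axis displacement of the k front-most cells at time ``t_s``."""
    disp = _displacements(traj, t_s)
    if len(disp) < k:
        raise ValueError(f"only {len(disp)} cells alive at t={t_s}, need {k}")
    return float(np.sort(disp.values)[-k:].mean())


def radial_leading_distance(
    traj: pd.DataFrame, k: int, t_s: float, center
) -> float:
    """Mean radial displacement of the k outermost cells at time ``t_s``."""
    disp = _displacements(traj, t_s, radial_center=center)
    if len(disp) < k:
        raise ValueError(f"only {len(disp)} cells alive at t={t_s}, need {k}")
    return float(np.sort(disp.values)[-k:].mean())


def two_spot_counts(positions: np.ndarray, center, axis_direction) -> tuple[int, int]:
    """(front, back) cell counts split by the diameter of the original cell
    drop perpendicular to the spot-spot axis."""
    pos = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    axis = np.asarray(axis_direction, dtype=np.float64)
    norm = np.hypot(axis[0], axis[1])
    if norm == 0:
        raise ValueError("axis_direction must be non-zero")
    axis = axis / norm
    proj = (pos[:, 0] - center[0]) * axis[0] + (pos[:, 1] - center[1]) * axis[1]
    front = int((proj > 0).sum())
    back = int((proj < 0).sum())
    return front, back


def score_two_spot(positions: np.ndarray, center, axis_direction) -> bool:
    """Positive when the attractant-facing half holds at least twice as many
    cells as the far half."""
    front, back = two_spot_counts(positions, center, axis_direction)
    return front >= 2 * back


# ----------------------------------------------------------------------
# run + score
# ----------------------------------------------------------------------
def score_run(result: RunResult) -> ScoreResult:
    """Compute the scenario's standard statistics from a finished run."""
    spec = result.spec
    traj = result.trajectory
    g = spec.geometry
    end = float(traj["time_s"].max()) if len(traj) else 0.0
    score = ScoreResult()
    if g.kind == "bridge":
        t_score = min(3600.0, end)
        score.response_score = score_response(traj, 400.0, t_score)
        ttp = time_to_pass(traj, n=min(100, result.n_initial), distance_um=g.length_um)
        score.time_to_pass_s = ttp.time_s
        score.time_to_pass_censored = ttp.censored
        k = min(10, result.n_initial)
        if k:
            disp = _displacements(traj, end)
            score.leading_distances_um = sorted(
                np.sort(disp.values)[-k:].tolist(), reverse=True
            )
    elif g.kind == "disc_well":
        lx = g.arena_um
        k = min(10, result.n_initial)
        disp = _displacements(traj, end, radial_center=(lx / 2, lx / 2))
        score.leading_distances_um = sorted(
            np.sort(disp.values)[-k:].tolist(), reverse=True
        )
    else:  # two_spot
        rows = _positions_at(traj, end)
        center = (g.pad_um + g.spot_radius_um, g.pad_um + g.spot_radius_um)
        front, back = two_spot_counts(
            rows[["x_um", "y_um"]].values, center, (1.0, 0.0)
        )
        score.front_count = front
        score.back_count = back
        score.two_spot_positive = front >= 2 * back
    return score


def run_scenario(spec: ScenarioSpec, **run_kwargs) -> tuple[RunResult, ScoreResult]:
    """Run a scenario and compute its standard scores."""
    result = run(spec, **run_kwargs)
    return result, score_run(result)
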