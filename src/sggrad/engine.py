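"""Coupled field-agent simulation loop.

One agent tick (default 1 s) advances the world in a fixed order:

1. field diffusion sub-steps covering the tick,
2. per cell: sense (overlapped points, mean concentration, instantaneous
   occupancy, running-average update), degrade (if enabled), reorient (at
   the reorientation interval), move, maybe divide (if the attractant is a
   mitogen),
3. record.

Cells are processed as arrays in stable id order and all randomness flows
through one seeded generator, so a run is bit-reproducible from its
scenario and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cells import (
    CellParams,
    CellPopulation,
    MotilityParams,
    OverlapStencil,
    _plane_fit_gradient,
    propose_heading,
    receptor_occupancy,
    wrap_angle,
)
from .field import AttractantField
from .reactions import InductionParams, MitogenParams, degrade_step, maybe_divide
from .scenario import ScenarioSpec

__all__ = ["SimulationState", "RunResult", "build_field", "build_cells", "step", "run"]

TRAJECTORY_COLUMNS = [
    "time_s",
    "cell_id",
    "x_um",
    "y_um",
    "heading_rad",
    "occupancy",
    "occupancy_avg",
    "event",
]


# ----------------------------------------------------------------------
# initialisation from a scenario
# ----------------------------------------------------------------------
def _grid_shape(lx: float, ly: float, dx: float) -> tuple[int, int]:
    return (int(round(ly / dx)) + 1, int(round(lx / dx)) + 1)


def domain_size(spec: ScenarioSpec) -> tuple[float, float]:
    """Walkable domain (x_max, y_max) in um for a scenario."""
    g = spec.geometry
    if g.kind == "bridge":
        return (g.length_um + 2 * g.reservoir_length_um, g.width_um)
    if g.kind == "disc_well":
        return (g.arena_um, g.arena_um)
    lx = 2 * g.pad_um + 2 * g.spot_radius_um + g.separation_um
    ly = 2 * (g.pad_um + g.spot_radius_um)
    return (lx, ly)


def build_field(spec: ScenarioSpec) -> AttractantField:
    """Initial attractant field for a scenario."""
    lx, ly = domain_size(spec)
    num = spec.numerics
    shape = _grid_shape(lx, ly, num.dx_um)
    init = spec.field_init
    if init.kind == "uniform":
        conc = np.full(shape, float(init.concentration_nM))
        mask = None
        if spec.geometry.kind == "two_spot":
            # attractant only inside the attractant drop
            g = spec.geometry
            cx = g.pad_um + g.spot_radius_um + g.separation_um
            cy = ly / 2.0
            yy, xx = np.meshgrid(
                np.arange(shape[0]) * num.dx_um,
                np.arange(shape[1]) * num.dx_um,
                indexing="ij",
            )
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= g.spot_radius_um**2
            conc = np.where(inside, float(init.concentration_nM), 0.0)
            if g.open_boundary:
                mask = np.zeros(shape, dtype=bool)
                mask[0, :] = mask[-1, :] = True
                mask[:, 0] = mask[:, -1] = True
                conc[mask] = 0.0
    else:  # imposed gradient between pinned strips
        conc = np.full(shape, float(init.c_low_nM))
        conc[:, -1] = float(init.c_high_nM)
        mask = np.zeros(shape, dtype=bool)
        mask[:, 0] = True  # sink at the cell end
        mask[:, -1] = True  # reservoir at the far end
    return AttractantField(conc, num.dx_um, num.diffusion_um2_s, fixed_mask=mask)


def build_cells(spec: ScenarioSpec, rng) -> CellPopulation:
    """Seed the initial population in the scenario's placement region."""
    lx, ly = domain_size(spec)
    g = spec.geometry
    n = spec.cell_init.count
    if g.kind == "bridge":
        x0 = g.reservoir_length_um
        xs = rng.uniform(x0, x0 + spec.cell_init.band_um, size=n)
        ys = rng.uniform(0.0, ly, size=n)
    elif g.kind == "disc_well":
        r = g.well_radius_um * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        phi = rng.uniform(-np.pi, np.pi, size=n)
        xs = lx / 2.0 + r * np.cos(phi)
        ys = ly / 2.0 + r * np.sin(phi)
    else:  # two_spot: cells in the left drop
        r = g.spot_radius_um * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        phi = rng.uniform(-np.pi, np.pi, size=n)
        xs = g.pad_um + g.spot_radius_um + r * np.cos(phi)
        ys = ly / 2.0 + r * np.sin(phi)
    headings = rng.uniform(-np.pi, np.pi, size=n)
    cm = spec.cell_init.cell
    mm = spec.cell_init.motility
    params = CellParams(
        speed_um_min=cm.speed_um_min,
        overlap_radius_um=cm.overlap_radius_um,
        kd_nM=cm.kd_nM,
        vmax=cm.vmax,
        km_nM=cm.km_nM,
    )
    motility = MotilityParams(
        wrapped_normal_sigma=mm.wrapped_normal_sigma,
        bias_strength=mm.bias_strength,
        reorientation_interval_s=mm.reorientation_interval_s,
        contrast_saturation=mm.contrast_saturation,
        contrast_threshold=mm.contrast_threshold,
    )
    pos = np.column_stack([xs, ys]) if n else np.empty((0, 2))
    return CellPopulation(
        pos,
        headings,
        params,
        motility,
        window_s=spec.numerics.occupancy_window_s,
        dt_s=spec.numerics.agent_dt_s,
    )


# ----------------------------------------------------------------------
# state
# ----------------------------------------------------------------------
@dataclass
class SimulationState:
    """Mutable state of a running simulation."""

    spec: ScenarioSpec
    field: AttractantField
    cells: CellPopulation
    rng: np.random.Generator
    time_s: float = 0.0
    tick: int = 0
    stencil: OverlapStencil | None = None
    induction: InductionParams | None = None
    mitogen: MitogenParams | None = None
    divisions: list = dc_field(default_factory=list)
    _records: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stencil is None:
            self.stencil = OverlapStencil(
                self.cells.params.overlap_radius_um
                if self.cells.n
                else self.spec.cell_init.cell.overlap_radius_um,
                self.spec.numerics.dx_um,
            )
        logic = self.spec.logic
        if self.induction is None:
            self.induction = InductionParams(
                enabled=(logic.degradation == "induced"),
                vb=logic.induction.vb,
                ki=logic.induction.ki,
                h=logic.induction.h,
            )
        if self.mitogen is None:
            self.mitogen = MitogenParams(
                enabled=logic.mitogen,
                occupancy_floor=logic.mitogen_params.occupancy_floor,
                min_division_time_min=logic.mitogen_params.min_division_time_min,
            )

    # -- recording -----------------------------------------------------
    def record(self, event: str = "none", index=None) -> None:
        cells = self.cells
        if index is None:
            index = slice(None)
        ids = cells.ids[index]
        n = np.size(ids)
        if n == 0:
            return
        self._records.append(
            (
                np.full(n, self.time_s),
                np.atleast_1d(ids).copy(),
                np.atleast_2d(cells.positions[index]).copy(),
                np.atleast_1d(cells.headings[index]).copy(),
                np.atleast_1d(cells.occupancy[index]).copy(),
                np.atleast_1d(cells.occupancy_average[index]).copy(),
                event,
            )
        )

    def trajectory(self) -> pd.DataFrame:
        if not self._records:
            dtypes = [float, np.int64, float, float, float, float, float, str]
            return pd.DataFrame(
                {c: pd.Series(dtype=t) for c, t in zip(TRAJECTORY_COLUMNS, dtypes)}
            )
        times = np.concatenate([r[0] for r in self._records])
        ids = np.concatenate([r[1] for r in self._records])
        pos = np.vstack([r[2] for r in self._records])
        heads = np.concatenate([r[3] for r in self._records])
        occ = np.concatenate([r[4] for r in self._records])
        occ_avg = np.concatenate([r[5] for r in self._records])
        events = np.concatenate(
            [np.full(r[0].shape[0], r[6], dtype=object) for r in self._records]
        )
        return pd.DataFrame(
            {
                "time_s": times,
                "cell_id": ids,
                "x_um": pos[:, 0],
                "y_um": pos[:, 1],
                "heading_rad": heads,
                "occupancy": occ,
                "occupancy_avg": occ_avg,
                "event": events,
            }
        )


def step(state: SimulationState) -> None:
    """Advance the simulation by one agent tick."""
    spec = state.spec
    num = spec.numerics
    dt = num.agent_dt_s
    n_sub = max(1, int(round(dt / num.field_dt_s)))
    for _ in range(n_sub):
        state.field.diffusion_step(dt / n_sub)

    cells = state.cells
    if cells.n:
        rows, cols, inside, rel = state.stencil.query(
            cells.positions, state.field.shape
        )
        conc = state.field.concentrations[rows, cols]
        w = inside.astype(np.float64)
        npts = np.maximum(w.sum(axis=1), 1.0)
        c_local = (w * conc).sum(axis=1) / npts
        y_now = receptor_occupancy(c_local, cells.params.kd_nM)
        cells.occupancy = np.atleast_1d(y_now)
        cells.window.push(cells.occupancy)

        if spec.logic.degradation != "none":
            degrade_step(
                cells,
                state.field,
                state.induction,
                dt,
                state.stencil,
                c_local=c_local,
                overlap=(rows, cols, inside, rel),
            )

        reorient_every = max(1, int(round(cells.motility.reorientation_interval_s / dt)))
        if state.tick % reorient_every == 0:
            occ_vals = conc / (conc + cells.params.kd_nM)
            grads = _plane_fit_gradient(occ_vals, rel, inside)
            cells.headings = propose_heading(
                cells.headings,
                grads,
                cells.motility,
                state.rng,
                2.0 * cells.params.overlap_radius_um,
            )

        bounds = domain_size(spec)
        step_len = cells.params.speed_um_min / 60.0 * dt
        cells.positions[:, 0] += step_len * np.cos(cells.headings)
        cells.positions[:, 1] += step_len * np.sin(cells.headings)
        for axis, hi in ((0, bounds[0]), (1, bounds[1])):
            p = cells.positions[:, axis]
            lo_hit = p < 0.0
            hi_hit = p > hi
            if np.any(lo_hit):
                p[lo_hit] = -p[lo_hit]
                cells.headings[lo_hit] = wrap_angle(
                    np.pi - cells.headings[lo_hit] if axis == 0 else -cells.headings[lo_hit]
                )
            if np.any(hi_hit):
                p[hi_hit] = 2.0 * hi - p[hi_hit]
                cells.headings[hi_hit] = wrap_angle(
                    np.pi - cells.headings[hi_hit] if axis == 0 else -cells.headings[hi_hit]
                )
            np.clip(p, 0.0, hi, out=p)

        if state.mitogen.enabled:
            n_before = cells.n
            daughters = maybe_divide(
                cells, state.mitogen, dt, state.rng, max_cells=spec.logic.max_cells
            )
            if daughters.size:
                new_slice = np.arange(n_before, cells.n)
                event_time = state.time_s + dt
                for j in new_slice:
                    state.divisions.append(
                        (event_time, int(cells.mothers[j]), int(cells.ids[j]))
                    )
                # log the event rows at event time
                t_save = state.time_s
                state.time_s = event_time
                mother_rows = np.isin(cells.ids, cells.mothers[new_slice])
                state.record("division", index=np.flatnonzero(mother_rows))
                state.record("birth", index=new_slice)
                state.time_s = t_save

    state.time_s += dt
    state.tick += 1


# ----------------------------------------------------------------------
# full run
# ----------------------------------------------------------------------
@dataclass
class RunResult:
    """Everything a finished run produced."""

    spec: ScenarioSpec
    trajectory: pd.DataFrame
    field: AttractantField
    snapshots: list
    divisions: list
    n_initial: int
    initial_mass: float

    @property
    def origins(self) -> pd.DataFrame:
        """First recorded state of every cell (its own start)."""
        t = self.trajectory
        first = t.loc[t.groupby("cell_id")["time_s"].idxmin()]
        return first.set_index("cell_id")[["time_s", "x_um", "y_um"]]

    def mass_balance(self) -> dict:
        f = self.field
        return {
            "initial_mass": self.initial_mass,
            "final_mass": f.total_mass(),
            "cumulative_degraded": f.cumulative_degraded,
            "cumulative_clamped": f.cumulative_clamped,
        }


def run(
    spec: ScenarioSpec,
    snapshot_every_s: float | None = None,
    progress: bool = False,
) -> RunResult:
    """Initialise a scenario, iterate to its duration, collect outputs."""
    rng = np.random.default_rng(spec.seed)
    fld = build_field(spec)
    cells = build_cells(spec, rng)
    state = SimulationState(spec=spec, field=fld, cells=cells, rng=rng)
    initial_mass = fld.total_mass()
    snapshots = [(0.0, fld.snapshot())]
    state.record()

    n_ticks = int(round(spec.duration_s / spec.numerics.agent_dt_s))
    rec_every = max(1, int(round(spec.record_every_s / spec.numerics.agent_dt_s)))
    snap_every = (
        max(1, int(round(snapshot_every_s / spec.numerics.agent_dt_s)))
        if snapshot_every_s
        else None
    )
    for k in range(1, n_ticks + 1):
        step(state)
        if k % rec_every == 0 or k == n_ticks:
            state.record()
        if snap_every and (k % snap_every == 0 or k == n_ticks):
            snapshots.append((state.time_s, fld.snapshot()))
        if progress and k % 600 == 0:
            print(
                f"t={state.time_s:8.0f} s  cells={state.cells.n:5d}  "
                f"mass={fld.total_mass():.4g}"
            )
    if n_ticks > 0 and snapshots[-1][0] != state.time_s:
        snapshots.append((state.time_s, fld.snapshot()))

    traj = state.trajectory()
    # drop duplicate final record if the tick loop recorded it twice
    traj = traj.drop_duplicates(
        subset=["time_s", "cell_id", "event"], keep="first"
    ).reset_index(drop=True)
    return RunResult(
        spec=spec,
        trajectory=traj,
        field=fld,
        snapshots=snapshots,
        divisions=state.divisions,
        n_initial=spec.cell_init.count,
        initial_mass=initial_mass,
    )
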