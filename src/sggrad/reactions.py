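"""Attractant degradation and attractant-driven mitosis.

Degradation: each cell removes attractant from the grid points it overlaps
at a Michaelis-Menten rate ``r = Vmax * c / (c + Km)`` where ``c`` is the
mean concentration over the overlapped points.  The removed mass is split
evenly across those points and each point is clamped at zero; the mass
actually removed is added to the field's ``cumulative_degraded`` ledger.
When degradation is *induced*, Vmax is multiplied by a Hill function of the
trailing-minute average receptor occupancy,
``vb + (1 - vb) * y^h / (ki^h + y^h)``, so enzyme activity switches on only
once receptors have been busy for a while.

Mitosis: the attractant doubles as a mitogen.  The division *rate* rises
linearly from zero at a minimum average occupancy (0.35) to one division
per ``min_division_time`` (1 min) at full occupancy, which makes the
expected waiting time exactly infinite at the floor and exactly the
minimum at saturation.  Division is a Poisson event; after it fires, the
occupancy windows of both mother and daughter are zeroed, giving a brief
refractory period while the windows refill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import CellPopulation
from .field import AttractantField

__all__ = [
    "InductionParams",
    "MitogenParams",
    "mm_rate",
    "induction_factor",
    "degrade_step",
    "division_rate",
    "maybe_divide",
]


@dataclass
class InductionParams:
    """Hill induction of the degradation machinery by receptor occupancy."""

    enabled: bool = False
    vb: float = 0.05  # basal activity fraction
    ki: float = 0.4  # occupancy of half-activity
    h: float = 2.0  # Hill coefficient

    def __post_init__(self) -> None:
        if not (0.0 <= self.vb <= 1.0):
            raise ValueError("vb must lie in [0, 1]")
        if not (0.0 < self.ki < 1.0):
            raise ValueError("ki must lie in (0, 1)")
        if self.h < 1.0:
            raise ValueError("h must be >= 1")


@dataclass
class MitogenParams:
    """Attractant-driven division: rate interpolation parameters."""

    enabled: bool = False
    occupancy_floor: float = 0.35
    min_division_time_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.occupancy_floor < 1.0):
            raise ValueError("occupancy_floor must lie in (0, 1)")
        if self.min_division_time_min <= 0:
            raise ValueError("min_division_time_min must be positive")


def mm_rate(c, vmax, km):
    """Michaelis-Menten rate ``vmax * c / (c + km)``."""
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(np.asarray(km) <= 0):
        raise ValueError("km must be positive")
    if np.any(np.asarray(vmax) < 0):
        raise ValueError("vmax must be non-negative")
    out = vmax * c / (c + km)
    return float(out) if out.ndim == 0 else out


def induction_factor(y_avg, params: InductionParams):
    """Induced activity fraction ``vb + (1 - vb) * y^h / (ki^h + y^h)``.

    Monotone increasing in the average occupancy; equals ``vb`` at zero
    occupancy and approaches (but never reaches) 1 at full occupancy.
    """
    y = np.asarray(y_avg, dtype=np.float64)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("average occupancy must lie in [0, 1]")
    yh = y**params.h
    out = params.vb + (1.0 - params.vb) * yh / (params.ki**params.h + yh)
    return float(out) if out.ndim == 0 else out


def degrade_step(
    population: CellPopulation,
    field: AttractantField,
    induction: InductionParams,
    dt: float,
    stencil,
    c_local: np.ndarray | None = None,
    overlap=None,
) -> float:
    """Remove attractant around every cell for one tick of ``dt`` seconds.

    Each cell's rate uses the mean concentration over its overlapped
    points; the removed mass ``r * dt`` is split evenly across them
    (per-point concentration decrement ``r * dt / (n_points * dx^2)``).
    Overlapping removals that would drive a point negative are clamped at
    zero, with only the mass actually removed entering the ledger.
    Returns the total mass removed (nM um^2).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if overlap is None:
        rows, cols, inside, _ = stencil.query(population.positions, field.shape)
    else:
        rows, cols, inside, _ = overlap
    conc = field.concentrations[rows, cols]
    w = inside.astype(np.float64)
    npts = w.sum(axis=1)
    if c_local is None:
        with np.errstate(invalid="ignore"):
            c_local = (w * conc).sum(axis=1) / np.maximum(npts, 1.0)
    vmax_eff = population.params.vmax
    if induction.enabled:
        vmax_eff = vmax_eff * induction_factor(
            population.occupancy_average, induction
        )
    rate = mm_rate(c_local, vmax_eff, population.params.km_nM)  # mass/min
    dx2 = field.spacing**2
    # per-point concentration decrement for this tick
    dec_per_point = rate * (dt / 60.0) / np.maximum(npts, 1.0) / dx2
    requested = np.zeros(field.shape)
    np.add.at(
        requested,
        (rows.ravel(), cols.ravel()),
        (w * dec_per_point[:, None]).ravel(),
    )
    return field.remove_mass(requested)


def division_rate(y_avg, params: MitogenParams):
    """Division rate per minute, linear in average occupancy above the floor.

    ``lambda(y) = max(0, (y - floor) / (1 - floor)) / min_division_time`` —
    zero (infinite expected waiting time) at the occupancy floor, one
    division per ``min_division_time`` at full occupancy.
    """
    y = np.asarray(y_avg, dtype=np.float64)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("average occupancy must lie in [0, 1]")
    lam = np.maximum(0.0, (y - params.occupancy_floor) / (1.0 - params.occupancy_floor))
    out = lam / params.min_division_time_min
    return float(out) if out.ndim == 0 else out


def maybe_divide(
    population: CellPopulation,
    params: MitogenParams,
    dt: float,
    rng,
    max_cells: int | None = None,
) -> np.ndarray:
    """Fire Poisson division events for one tick; returns daughter ids.

    Each cell divides with probability ``1 - exp(-lambda * dt)`` in the
    tick.  Daughters appear at the mother's position with a fresh random
    heading; both mother and daughter have their running-average occupancy
    reset to zero (refractory until the window refills above the floor).
    ``max_cells`` caps runaway growth in saturating attractant.
    """
    if not params.enabled:
        return np.empty(0, dtype=np.int64)
    lam = division_rate(population.occupancy_average, params)  # per min
    p = -np.expm1(-lam * dt / 60.0)
    draws = rng.random(population.n)
    divide = np.flatnonzero(draws < p)
    if max_cells is not None:
        room = max(0, max_cells - population.n)
        divide = divide[:room]
    return population.spawn(divide, rng)
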