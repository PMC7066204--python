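"""Motile cell agents: receptor sensing and persistent biased random walk.

Cells are point agents with a heading and constant speed.  Each agent
senses the attractant through saturable receptors (single-site binding,
occupancy ``y = c / (c + Kd)``) at the grid points it overlaps (all nodes
within ``overlap_radius`` of its centroid).  Steering combines a persistent
random component — a new heading drawn from a wrapped normal centred on the
current heading — with a bias vector along the local *occupancy* gradient.
Saturable receptors perceive occupancy differences, not raw concentration
differences, so the bias magnitude scales with the occupancy contrast
across the cell body and vanishes both in very dilute and in saturating
attractant.

The module is array-oriented: operations accept an (N, ...) stack of agent
state so a whole population advances in one call.  ``CellAgent`` is a
single-agent convenience wrapper over the same functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import AttractantField

__all__ = [
    "CellParams",
    "MotilityParams",
    "CellAgent",
    "CellPopulation",
    "OccupancyWindow",
    "receptor_occupancy",
    "overlapped_points",
    "local_gradient",
    "propose_heading",
    "move",
    "wrap_angle",
]


# ----------------------------------------------------------------------
# parameters
# ----------------------------------------------------------------------
@dataclass
class CellParams:
    """Kinetic and geometric parameters shared by a cell population.

    speed_um_min : constant migration speed, um/min.
    overlap_radius_um : radius defining the overlapped grid points, um.
    kd_nM : receptor dissociation constant, nM.
    vmax : maximal degradation rate per cell, nM um^2 / min (field-mass
        units per minute).
    km_nM : Michaelis constant of the degrading activity, nM.
    """

    speed_um_min: float = 13.0
    overlap_radius_um: float = 6.0
    kd_nM: float = 12.0
    vmax: float = 1.2e6
    km_nM: float = 500.0

    def __post_init__(self) -> None:
        for name in ("speed_um_min", "overlap_radius_um", "kd_nM", "vmax", "km_nM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MotilityParams:
    """Steering parameters of the persistent biased random walk.

    wrapped_normal_sigma : dispersion of the heading proposal, rad.
    bias_strength : length of the bias vector (relative to the unit
        persistence vector) when the sensed occupancy contrast saturates.
    reorientation_interval_s : time between direction updates, s.
    contrast_saturation : occupancy difference across the cell body at
        which the bias magnitude saturates (dimensionless occupancy units).
    contrast_threshold : smallest occupancy difference across the cell
        body the receptors can resolve; weaker contrasts contribute no
        bias.  A deterministic stand-in for receptor-count shot noise,
        which otherwise lets arbitrarily faint gradients steer cells over
        long times.
    """

    wrapped_normal_sigma: float = 0.6
    bias_strength: float = 2.5
    reorientation_interval_s: float = 5.0
    contrast_saturation: float = 0.005
    contrast_threshold: float = 4.0e-4

    def __post_init__(self) -> None:
        if self.wrapped_normal_sigma <= 0:
            raise ValueError("wrapped_normal_sigma must be positive")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be non-negative")
        if self.reorientation_interval_s <= 0:
            raise ValueError("reorientation_interval_s must be positive")
        if self.contrast_saturation <= 0:
            raise ValueError("contrast_saturation must be positive")
        if self.contrast_threshold < 0:
            raise ValueError("contrast_threshold must be non-negative")


# ----------------------------------------------------------------------
# pure operations
# ----------------------------------------------------------------------
def receptor_occupancy(c, kd):
    """Fraction of receptors bound at concentration ``c``: c / (c + Kd)."""
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("kd must be positive")
    out = c / (c + kd)
    return float(out) if out.ndim == 0 else out


def wrap_angle(theta):
    """Map angles to (-pi, pi]."""
    theta = np.asarray(theta, dtype=np.float64)
    out = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out) if out.ndim == 0 else out


class OverlapStencil:
    """Candidate-node stencil for a given overlap radius and grid spacing.

    Pre-computes the square window of lattice offsets that can possibly lie
    within ``radius`` of an arbitrary position whose nearest node is the
    window centre.
    """

    def __init__(self, radius: float, spacing: float) -> None:
        if radius <= 0 or spacing <= 0:
            raise ValueError("radius and spacing must be positive")
        self.radius = float(radius)
        self.spacing = float(spacing)
        reach = int(np.ceil((radius + spacing / 2.0) / spacing))
        k = np.arange(-reach, reach + 1)
        dr, dc = np.meshgrid(k, k, indexing="ij")
        self.offsets_r = dr.ravel()
        self.offsets_c = dc.ravel()

    def query(self, positions: np.ndarray, shape: tuple[int, int]):
        """Overlapped nodes for each position.

        Parameters
        ----------
        positions : (N, 2) array of (x, y) um.
        shape : grid shape (ny, nx).

        Returns
        -------
        rows, cols : (N, K) int arrays, clipped to the grid.
        inside : (N, K) bool, True where the node exists and its centre is
            within ``radius`` (Euclidean, <=) of the position.
        rel : (N, K, 2) node position minus cell position, um.
        """
        ny, nx = shape
        dx = self.spacing
        pos = np.asarray(positions, dtype=np.float64)
        near_r = np.round(pos[:, 1] / dx).astype(np.int64)
        near_c = np.round(pos[:, 0] / dx).astype(np.int64)
        rows = near_r[:, None] + self.offsets_r[None, :]
        cols = near_c[:, None] + self.offsets_c[None, :]
        in_grid = (rows >= 0) & (rows < ny) & (cols >= 0) & (cols < nx)
        rows_cl = np.clip(rows, 0, ny - 1)
        cols_cl = np.clip(cols, 0, nx - 1)
        rel_x = cols * dx - pos[:, 0][:, None]
        rel_y = rows * dx - pos[:, 1][:, None]
        dist2 = rel_x**2 + rel_y**2
        inside = in_grid & (dist2 <= self.radius**2 + 1e-9)
        rel = np.stack([rel_x, rel_y], axis=-1)
        return rows_cl, cols_cl, inside, rel


def overlapped_points(position, field: AttractantField, radius: float):
    """Set of (row, col) grid nodes within ``radius`` of ``position``.

    Never empty: falls back to the nearest node if the radius excludes
    every node centre.
    """
    stencil = OverlapStencil(radius, field.spacing)
    rows, cols, inside, _ = stencil.query(
        np.asarray([position], dtype=np.float64), field.shape
    )
    pts = {
        (int(r), int(c))
        for r, c, ok in zip(rows[0], cols[0], inside[0])
        if ok
    }
    if not pts:
        pts = {field.nearest_node(position)}
    return pts


def _plane_fit_gradient(values, rel, weights):
    """Weighted least-squares plane gradient, batched.

    values : (N, K), rel : (N, K, 2) positions relative to centroid,
    weights : (N, K) 0/1 mask.  Returns (N, 2) gradients; degenerate fits
    (fewer than 3 points or collinear support) give the zero vector.
    """
    w = weights.astype(np.float64)
    s0 = w.sum(axis=1)
    sx = (w * rel[..., 0]).sum(axis=1)
    sy = (w * rel[..., 1]).sum(axis=1)
    sv = (w * values).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(s0 > 0, sx / np.maximum(s0, 1e-300), 0.0)
        my = np.where(s0 > 0, sy / np.maximum(s0, 1e-300), 0.0)
        mv = np.where(s0 > 0, sv / np.maximum(s0, 1e-300), 0.0)
    cx = rel[..., 0] - mx[:, None]
    cy = rel[..., 1] - my[:, None]
    cv = values - mv[:, None]
    sxx = (w * cx * cx).sum(axis=1)
    sxy = (w * cx * cy).sum(axis=1)
    syy = (w * cy * cy).sum(axis=1)
    sxv = (w * cx * cv).sum(axis=1)
    syv = (w * cy * cv).sum(axis=1)
    det = sxx * syy - sxy * sxy
    scale = np.maximum(sxx + syy, 1e-300)
    ok = (s0 >= 3) & (det > 1e-12 * scale**2)
    det_safe = np.where(ok, det, 1.0)
    gx = np.where(ok, (syy * sxv - sxy * syv) / det_safe, 0.0)
    gy = np.where(ok, (sxx * syv - sxy * sxv) / det_safe, 0.0)
    return np.stack([gx, gy], axis=-1)


def local_gradient(position, field: AttractantField, radius: float, kd=None):
    """Gradient at a cell position from the overlapped grid points.

    Least-squares plane fit of node values against node positions over the
    overlapped set.  With ``kd`` given the fit is done on receptor
    occupancy (what a saturable receptor actually perceives); otherwise on
    raw concentration.  Degenerate sets return the zero vector.
    """
    stencil = OverlapStencil(radius, field.spacing)
    rows, cols, inside, rel = stencil.query(
        np.asarray([position], dtype=np.float64), field.shape
    )
    vals = field.concentrations[rows, cols]
    if kd is not None:
        vals = vals / (vals + kd)
    return _plane_fit_gradient(vals, rel, inside)[0]


def propose_heading(heading, gradient, params: MotilityParams, rng, sense_length):
    """New heading: wrapped-normal persistence plus occupancy-gradient bias.

    A persistence angle is drawn from a wrapped normal centred on the
    current heading.  The unit persistence vector is added to a bias vector
    along the (normalized) gradient whose length is
    ``bias_strength * min(|grad| * sense_length / contrast_saturation, 1)``
    — i.e. proportional to the occupancy difference the cell can resolve
    across its body, saturating at ``bias_strength``.  The returned heading
    is the angle of the summed vector; with a zero gradient it is the
    persistence draw itself.

    Accepts scalars or (N,) arrays (gradient then (N, 2)).
    """
    scalar_in = np.ndim(heading) == 0
    heading = np.atleast_1d(np.asarray(heading, dtype=np.float64))
    grad = np.atleast_2d(np.asarray(gradient, dtype=np.float64))
    n = heading.shape[0]
    theta_p = heading + rng.normal(0.0, params.wrapped_normal_sigma, size=n)
    gmag = np.hypot(grad[:, 0], grad[:, 1])
    contrast = gmag * sense_length
    b = params.bias_strength * np.minimum(
        contrast / params.contrast_saturation, 1.0
    )
    b = np.where(contrast >= params.contrast_threshold, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ghat_x = np.where(gmag > 0, grad[:, 0] / np.maximum(gmag, 1e-300), 0.0)
        ghat_y = np.where(gmag > 0, grad[:, 1] / np.maximum(gmag, 1e-300), 0.0)
    vx = np.cos(theta_p) + b * ghat_x
    vy = np.sin(theta_p) + b * ghat_y
    # Zero resultant (exactly opposed vectors) falls back to persistence.
    degenerate = (vx == 0.0) & (vy == 0.0)
    out = np.where(degenerate, wrap_angle(theta_p), np.arctan2(vy, vx))
    return float(out[0]) if scalar_in else out


def move(position, heading, speed_um_min, dt, bounds):
    """Advance positions at constant speed along heading, reflecting walls.

    bounds : (x_max, y_max) of the walkable rectangle (lower-left origin).
    Returns (new_position, new_heading); the heading component normal to a
    wall is inverted on reflection.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=np.float64)).copy()
    th = np.atleast_1d(np.asarray(heading, dtype=np.float64)).copy()
    step = speed_um_min / 60.0 * dt
    pos[:, 0] += step * np.cos(th)
    pos[:, 1] += step * np.sin(th)
    xmax, ymax = bounds
    for axis, hi in ((0, xmax), (1, ymax)):
        lo_hit = pos[:, axis] < 0.0
        hi_hit = pos[:, axis] > hi
        pos[lo_hit, axis] = -pos[lo_hit, axis]
        pos[hi_hit, axis] = 2.0 * hi - pos[hi_hit, axis]
        flip = lo_hit | hi_hit
        if np.any(flip):
            if axis == 0:
                th[flip] = wrap_angle(np.pi - th[flip])
            else:
                th[flip] = wrap_angle(-th[flip])
        # Steps are < spacing in practice; clip guards pathological dt.
        np.clip(pos[:, axis], 0.0, hi, out=pos[:, axis])
    if np.asarray(position).ndim == 1:
        return pos[0], float(th[0])
    return pos, th


# ----------------------------------------------------------------------
# running-average occupancy
# ----------------------------------------------------------------------
class OccupancyWindow:
    """Exact sliding-window mean of instantaneous receptor occupancy.

    A fixed-length circular buffer of per-tick samples spanning the
    averaging window (60 s by default).  The buffer starts at zero: a
    freshly initialised (or freshly divided) cell reports a zero average
    until real samples accumulate, which is what creates the brief
    post-division refractory period.
    """

    def __init__(self, n_cells: int, window_s: float = 60.0, dt_s: float = 1.0) -> None:
        self.n_samples = max(1, int(round(window_s / dt_s)))
        self.buffer = np.zeros((n_cells, self.n_samples))
        self._sum = np.zeros(n_cells)
        self._ptr = 0

    def push(self, y_now: np.ndarray) -> None:
        y = np.asarray(y_now, dtype=np.float64)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("occupancy samples must lie in [0, 1]")
        self._sum += y - self.buffer[:, self._ptr]
        self.buffer[:, self._ptr] = y
        self._ptr = (self._ptr + 1) % self.n_samples

    @property
    def average(self) -> np.ndarray:
        avg = self._sum / self.n_samples
        # Guard running-sum drift at the boundaries.
        return np.clip(avg, 0.0, 1.0)

    def reset(self, index) -> None:
        """Zero the window of selected cells (post-division refractory)."""
        self.buffer[index, :] = 0.0
        self._sum[index] = 0.0

    def grow(self, n_new: int) -> None:
        """Append ``n_new`` cells with empty (zero) windows."""
        self.buffer = np.vstack(
            [self.buffer, np.zeros((n_new, self.n_samples))]
        )
        self._sum = np.concatenate([self._sum, np.zeros(n_new)])


# ----------------------------------------------------------------------
# population container
# ----------------------------------------------------------------------
class CellPopulation:
    """Structure-of-arrays container for a population of identical agents."""

    def __init__(
        self,
        positions: np.ndarray,
        headings: np.ndarray,
        params: CellParams,
        motility: MotilityParams,
        window_s: float = 60.0,
        dt_s: float = 1.0,
    ) -> None:
        self.positions = np.atleast_2d(np.asarray(positions, dtype=np.float64)).copy()
        self.headings = np.atleast_1d(np.asarray(headings, dtype=np.float64)).copy()
        if self.positions.shape[0] != self.headings.shape[0]:
            raise ValueError("positions and headings must have matching length")
        n = self.positions.shape[0]
        self.ids = np.arange(n, dtype=np.int64)
        self._next_id = n
        self.params = params
        self.motility = motility
        self.window = OccupancyWindow(n, window_s, dt_s)
        self.occupancy = np.zeros(n)  # last instantaneous occupancy
        self.mothers = np.full(n, -1, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def occupancy_average(self) -> np.ndarray:
        return self.window.average

    def spawn(self, mother_index: np.ndarray, rng) -> np.ndarray:
        """Create daughters at their mothers' positions.

        Daughters get an independently drawn uniform heading and an empty
        occupancy window; the mothers' windows are reset as well (both are
        refractory until their windows refill).  Returns daughter ids.
        """
        mother_index = np.atleast_1d(mother_index)
        k = mother_index.shape[0]
        if k == 0:
            return np.empty(0, dtype=np.int64)
        new_pos = self.positions[mother_index].copy()
        new_head = rng.uniform(-np.pi, np.pi, size=k)
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.positions = np.vstack([self.positions, new_pos])
        self.headings = np.concatenate([self.headings, new_head])
        self.ids = np.concatenate([self.ids, new_ids])
        self.mothers = np.concatenate(
            [self.mothers, self.ids[mother_index]]
        )
        self.occupancy = np.concatenate([self.occupancy, np.zeros(k)])
        self.window.grow(k)
        self.window.reset(mother_index)
        return new_ids


@dataclass
class CellAgent:
    """Single-agent view used in examples and unit-level reasoning.

    The simulation itself advances a :class:`CellPopulation`; this wrapper
    exposes the same operations for one cell.
    """

    position: np.ndarray
    heading: float
    params: CellParams = dc_field(default_factory=CellParams)
    motility: MotilityParams = dc_field(default_factory=MotilityParams)
    occupancy_average: float = 0.0
    refractory: bool = False

    def sense(self, field: AttractantField):
        """(local mean concentration, occupancy, occupancy gradient)."""
        pts = overlapped_points(self.position, field, self.params.overlap_radius_um)
        rows = np.array([p[0] for p in pts])
        cols = np.array([p[1] for p in pts])
        c_local = float(field.concentrations[rows, cols].mean())
        y = receptor_occupancy(c_local, self.params.kd_nM)
        grad = local_gradient(
            self.position, field, self.params.overlap_radius_um, kd=self.params.kd_nM
        )
        return c_local, y, grad

    def reorient(self, gradient, rng) -> None:
        self.heading = float(
            propose_heading(
                self.heading,
                np.asarray(gradient, dtype=np.float64),
                self.motility,
                rng,
                2.0 * self.params.overlap_radius_um,
            )
        )

    def move(self, dt: float, bounds) -> None:
        if dt < 0:
            raise ValueError("dt must be non-negative")
        self.position, self.heading = move(
            self.position, self.heading, self.params.speed_um_min, dt, bounds
        )
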