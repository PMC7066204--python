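"""2D attractant concentration lattice with finite-difference diffusion.

The environment is a uniform square grid storing attractant concentration
(nM).  Diffusion follows the heat equation ``dc/dt = D * laplacian(c)`` and
is advanced with the DuFort-Frankel leapfrog scheme, an unconditionally
stable explicit method that keeps two time levels.  Grid points may be
pinned to their initial concentration ("fixed points"), which turns them
into infinite reservoirs or sinks between which imposed gradients form.

Units: lengths in um, time in s, concentration in nM.  "Mass" means the
depth-integrated quantity ``concentration * dx**2`` (nM um^2); a nominal
unit depth is absorbed into the cells' Vmax.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AttractantField"]

# FTCS is only conditionally stable; the bootstrap step that seeds the
# second time level is sub-cycled so its diffusion number stays below this.
_FTCS_NU_MAX = 0.25


def _neighbor_sum(c: np.ndarray) -> np.ndarray:
    """Sum of the four lattice neighbors with edge replication (no-flux)."""
    s = np.empty_like(c)
    s[1:, :] = c[:-1, :]
    s[0, :] = c[0, :]
    s[:-1, :] += c[1:, :]
    s[-1, :] += c[-1, :]
    s[:, 1:] += c[:, :-1]
    s[:, 0] += c[:, 0]
    s[:, :-1] += c[:, 1:]
    s[:, -1] += c[:, -1]
    return s


class AttractantField:
    """Attractant concentration on a 2D grid, indexed (row, col) = (y, x).

    Parameters
    ----------
    concentrations
        Initial concentration lattice, nM, shape (ny, nx).
    spacing
        Grid spacing dx in um (uniform, square cells).
    diffusion_coefficient
        D in um^2/s.
    fixed_mask
        Optional boolean lattice; where True the concentration is held at
        its initial value after every update (reservoir/sink points).
    """

    def __init__(
        self,
        concentrations: np.ndarray,
        spacing: float,
        diffusion_coefficient: float,
        fixed_mask: np.ndarray | None = None,
    ) -> None:
        conc = np.asarray(concentrations, dtype=np.float64)
        if conc.ndim != 2:
            raise ValueError("concentrations must be a 2D lattice")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        if diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be non-negative")
        self.concentrations = conc.copy()
        self.previous_concentrations = conc.copy()
        self.spacing = float(spacing)
        self.diffusion_coefficient = float(diffusion_coefficient)
        if fixed_mask is None:
            fixed_mask = np.zeros(conc.shape, dtype=bool)
        fixed_mask = np.asarray(fixed_mask, dtype=bool)
        if fixed_mask.shape != conc.shape:
            raise ValueError(
                f"fixed_mask shape {fixed_mask.shape} does not match "
                f"concentrations shape {conc.shape}"
            )
        self.fixed_mask = fixed_mask.copy()
        self.fixed_values = conc[fixed_mask].copy()
        self.cumulative_degraded = 0.0
        # Mass created by clamping scheme undershoots at zero (audited so
        # the global mass ledger can close exactly).
        self.cumulative_clamped = 0.0
        self._bootstrapped = False
        self._last_dt: float | None = None

    # ------------------------------------------------------------------
    # constructors / basic geometry
    # ------------------------------------------------------------------
    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int],
        concentration: float,
        spacing: float,
        diffusion_coefficient: float,
    ) -> "AttractantField":
        return cls(
            np.full(shape, float(concentration)),
            spacing,
            diffusion_coefficient,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.concentrations.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the node bounding box in um: (x_max, y_max)."""
        ny, nx = self.shape
        return ((nx - 1) * self.spacing, (ny - 1) * self.spacing)

    def node_position(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) in um of a grid node; origin at the lower-left node."""
        return (col * self.spacing, row * self.spacing)

    def total_mass(self) -> float:
        """Total attractant mass, nM um^2."""
        return float(self.concentrations.sum()) * self.spacing**2

    # ------------------------------------------------------------------
    # updates
    # ------------------------------------------------------------------
    def apply_fixed_points(self) -> None:
        """Re-pin fixed-mask points to their stored concentrations."""
        if self.fixed_values.size:
            self.concentrations[self.fixed_mask] = self.fixed_values

    def diffusion_step(self, dt: float) -> None:
        """Advance the field one step of the heat equation.

        The first call (or a call after ``dt`` changed) seeds the second
        time level with sub-cycled forward-Euler steps; subsequent calls
        use the two-level DuFort-Frankel update.  No-flux boundaries on the
        outer border; fixed points re-pinned afterwards.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self._last_dt is not None and dt != self._last_dt:
            self._bootstrapped = False
        self._last_dt = dt

        d = self.diffusion_coefficient
        if d == 0.0:
            self.apply_fixed_points()
            return
        nu = d * dt / self.spacing**2

        if not self._bootstrapped:
            # Sub-cycled FTCS seeds the second time level.  The leapfrog
            # stencil evolves two interleaved space-time parity classes
            # that never exchange mass afterwards, and its checkerboard
            # mode is neutral (root -1), so any parity imbalance in the
            # starting pair would persist as a permanent checkerboard.  An
            # FTCS substep with diffusion number exactly 1/8 annihilates
            # the checkerboard mode (amplification 1 - 8*nu = 0), so both
            # starting levels are taken after such a substep whenever the
            # step size allows one.
            kill = 1.0 / 8.0
            if nu >= kill:
                rest = nu - kill
                m = int(np.ceil(rest / kill))
                subs = [kill] + ([rest / m] * m if m else [])
            else:
                subs = [nu / 2.0] * 2
            c = self.concentrations
            prev = None
            for i, nu_sub in enumerate(subs):
                c = (1.0 - 4.0 * nu_sub) * c + nu_sub * _neighbor_sum(c)
                if i == 0:
                    prev = c.copy()
            np.maximum(c, 0.0, out=c)
            np.maximum(prev, 0.0, out=prev)
            self.previous_concentrations = prev
            self.concentrations = c
            self._bootstrapped = True
        else:
            s = _neighbor_sum(self.concentrations)
            new = (
                (1.0 - 4.0 * nu) * self.previous_concentrations + 2.0 * nu * s
            ) / (1.0 + 4.0 * nu)
            neg = new < 0.0
            if np.any(neg):
                # clamp undershoots symmetrically on both time levels so
                # the injected mass is exactly what the ledger records
                deficit = -new[neg]
                self.cumulative_clamped += float(deficit.sum()) * self.spacing**2
                new[neg] = 0.0
                self.concentrations[neg] += deficit
            self.previous_concentrations = self.concentrations
            self.concentrations = new
        self.apply_fixed_points()

    def advance(self, total_time: float, dt: float) -> None:
        """Run ``diffusion_step`` repeatedly to cover ``total_time``."""
        n = int(round(total_time / dt))
        for _ in range(n):
            self.diffusion_step(dt)

    def remove_mass(self, decrement: np.ndarray) -> float:
        """Remove a per-node concentration decrement, clamping at zero.

        Both time levels are decremented so the leapfrog scheme sees a
        consistent sink (removing from one level only would let the scheme's
        level-averaging double-count part of the removal).  Returns the mass
        actually removed (nM um^2) and adds it to ``cumulative_degraded``.
        """
        # clamp to what BOTH levels can absorb: removing unequal amounts
        # from the two levels would let the leapfrog's level-averaging
        # re-create part of the mass, breaking the ledger
        actual = np.minimum(
            decrement,
            np.minimum(self.concentrations, self.previous_concentrations),
        )
        np.maximum(actual, 0.0, out=actual)
        self.concentrations -= actual
        self.previous_concentrations -= actual
        self.apply_fixed_points()
        removed = float(actual.sum()) * self.spacing**2
        self.cumulative_degraded += removed
        return removed

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def nearest_node(self, position) -> tuple[int, int]:
        """(row, col) of the grid node nearest an (x, y) position in um."""
        x, y = float(position[0]), float(position[1])
        w, h = self.extent
        if not (0.0 <= x <= w and 0.0 <= y <= h):
            raise ValueError(f"position ({x}, {y}) outside domain {w} x {h} um")
        return (int(round(y / self.spacing)), int(round(x / self.spacing)))

    def sample_concentration(self, position) -> float:
        """Concentration (nM) at the grid node nearest ``position``.

        Agents interact with discrete grid points, so the lookup is
        nearest-node rather than interpolating.
        """
        r, c = self.nearest_node(position)
        return float(self.concentrations[r, c])

    def snapshot(self) -> np.ndarray:
        return self.concentrations.copy()
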