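"""Declarative scenario description: geometry, field, cells, logic, numerics.

A :class:`ScenarioSpec` is a complete, validated description of one
simulated experiment.  Specs are plain data (pydantic models), round-trip
through YAML, reject unknown keys, and carry every default explicitly once
resolved, so a saved spec re-runs bit-identically.
"""

from __future__ import annotations

from typing import Literal, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BridgeGeometry",
    "DiscWellGeometry",
    "TwoSpotGeometry",
    "UniformInit",
    "ImposedGradientInit",
    "CellModel",
    "MotilityModel",
    "InductionModel",
    "MitogenModel",
    "LogicSpec",
    "CellInit",
    "NumericsSpec",
    "ScenarioSpec",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------
class BridgeGeometry(_Model):
    """Channel of ``length_um`` between two reservoirs of the same width."""

    kind: Literal["bridge"] = "bridge"
    length_um: float = Field(1000.0, gt=0)
    width_um: float = Field(50.0, gt=0)
    reservoir_length_um: float = Field(500.0, ge=0)


class DiscWellGeometry(_Model):
    """Central circular well of cells inside a square arena."""

    kind: Literal["disc_well"] = "disc_well"
    well_radius_um: float = Field(1000.0, gt=0)
    arena_um: float = Field(4000.0, gt=0)

    @model_validator(mode="after")
    def _well_fits(self):
        if 2 * self.well_radius_um >= self.arena_um:
            raise ValueError("arena_um must exceed the well diameter")
        return self


class TwoSpotGeometry(_Model):
    """Cell drop and attractant drop of equal radius on an open field."""

    kind: Literal["two_spot"] = "two_spot"
    spot_radius_um: float = Field(500.0, gt=0)
    separation_um: float = Field(1000.0, gt=0)  # centre to centre
    pad_um: float = Field(250.0, ge=0)
    # The bench assay sits on an agar field much larger than the two drops;
    # pinning the arena border at zero lets attractant drain away as it
    # would into that surround, instead of accumulating in a closed box.
    open_boundary: bool = True

    @model_validator(mode="after")
    def _spots_ok(self):
        if self.spot_radius_um >= self.separation_um:
            raise ValueError("spot_radius_um must be smaller than separation_um")
        return self


Geometry = Union[BridgeGeometry, DiscWellGeometry, TwoSpotGeometry]


# ----------------------------------------------------------------------
# field initialisation
# ----------------------------------------------------------------------
class UniformInit(_Model):
    """Uniform attractant everywhere (self-generated-gradient mode)."""

    kind: Literal["uniform"] = "uniform"
    concentration_nM: float = Field(..., ge=0)


class ImposedGradientInit(_Model):
    """Fixed source/sink strips; the gradient forms dynamically between them."""

    kind: Literal["imposed_gradient"] = "imposed_gradient"
    c_low_nM: float = Field(0.0, ge=0)
    c_high_nM: float = Field(..., ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.c_high_nM < self.c_low_nM:
            raise ValueError("c_high_nM must be >= c_low_nM")
        return self


FieldInit = Union[UniformInit, ImposedGradientInit]


# ----------------------------------------------------------------------
# cells and logic
# ----------------------------------------------------------------------
class CellModel(_Model):
    speed_um_min: float = Field(13.0, gt=0)
    overlap_radius_um: float = Field(6.0, gt=0)
    kd_nM: float = Field(12.0, gt=0)
    vmax: float = Field(1.2e6, gt=0)  # nM um^2 / min per cell
    km_nM: float = Field(500.0, gt=0)


class MotilityModel(_Model):
    wrapped_normal_sigma: float = Field(0.6, gt=0)
    bias_strength: float = Field(2.5, ge=0)
    reorientation_interval_s: float = Field(5.0, gt=0)
    contrast_saturation: float = Field(0.005, gt=0)
    contrast_threshold: float = Field(4.0e-4, ge=0)


class InductionModel(_Model):
    vb: float = Field(0.05, ge=0, le=1)
    ki: float = Field(0.4, gt=0, lt=1)
    h: float = Field(2.0, ge=1)


class MitogenModel(_Model):
    occupancy_floor: float = Field(0.35, gt=0, lt=1)
    min_division_time_min: float = Field(1.0, gt=0)


class LogicSpec(_Model):
    degradation: Literal["none", "always_on", "induced"] = "none"
    mitogen: bool = False
    induction: InductionModel = InductionModel()
    mitogen_params: MitogenModel = MitogenModel()
    max_cells: int = Field(4000, gt=0)


class CellInit(_Model):
    count: int = Field(..., ge=0)
    band_um: float = Field(40.0, gt=0)  # seeding band depth (bridge)
    cell: CellModel = CellModel()
    motility: MotilityModel = MotilityModel()


# ----------------------------------------------------------------------
# numerics
# ----------------------------------------------------------------------
class NumericsSpec(_Model):
    dx_um: float = Field(4.0, gt=0)
    field_dt_s: float = Field(0.05, gt=0)
    agent_dt_s: float = Field(1.0, gt=0)
    diffusion_um2_s: float = Field(150.0, gt=0)
    occupancy_window_s: float = Field(60.0, gt=0)


# ----------------------------------------------------------------------
# the scenario
# ----------------------------------------------------------------------
class ScenarioSpec(_Model):
    """Complete declarative description of one simulated assay."""

    geometry: Geometry = Field(..., discriminator="kind")
    field_init: FieldInit = Field(..., discriminator="kind")
    cell_init: CellInit
    logic: LogicSpec = LogicSpec()
    numerics: NumericsSpec = NumericsSpec()
    duration_s: float = Field(..., ge=0)
    seed: int = Field(0, ge=0)
    record_every_s: float = Field(60.0, gt=0)

    @model_validator(mode="after")
    def _consistent(self):
        if (
            self.geometry.kind != "bridge"
            and self.field_init.kind == "imposed_gradient"
        ):
            raise ValueError(
                "imposed_gradient field_init is only defined for bridge geometry"
            )
        return self
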