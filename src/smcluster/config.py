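"""Validated simulation configurations.

Every generator run is fully determined by one :class:`SimulationConfig`.
Scenario-specific parameters live in a tagged sub-model so a JSON config
file validates strictly (unknown keys rejected, invalid values named).

Default parameter values are the study conditions of the experiments the
generators emulate: hole saturation width ``a_max ~ 200 um`` with rate
``C ~ 2e-3 1/s``, rounding capillary velocity ``gamma/eta ~ 1e-8 m/s``,
fusion capillary velocity ``2.9e-9 m/s`` with cluster diameters
``~200 um``, and count dynamics ``p1 = 50 /day``, ``p2 = 1.5 /day``,
``t_s = 8 day``.  Frames are 300 s apart for the fast hole-opening
movies and 1200 s apart for cluster movies; the pixel scale is
0.65 um/px.  Measurement-noise magnitudes (axis SD 2 um, width SD 5 um,
Poisson counts) are fixture choices: the underlying experiments do not
quote them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Union

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SimulationConfig",
    "HoleParams",
    "RoundingParams",
    "FusionParams",
    "CountParams",
    "OrientationParams",
    "SpeckleParams",
    "load_config",
]


class _Strict(BaseModel):
    model_config = {"extra": "forbid", "validate_assignment": True}


class HoleParams(_Strict):
    """Exponential hole-width saturation a(t) = a_max (1 - exp(-C t))."""

    scenario: Literal["hole"] = "hole"
    a_max_um: float = Field(200.0, gt=0)
    C_per_s: float = Field(2e-3, gt=0)
    n_frames: int = Field(60, ge=2)
    width_noise_um: float = Field(0.0, ge=0)
    tip_A_sqrt_m: float | None = Field(None, gt=0, description="parabola coefficient for tip-profile points (m^1/2)")


class RoundingParams(_Strict):
    """Anisotropy decay of a volume-conserving prolate spheroid."""

    scenario: Literal["rounding"] = "rounding"
    eps0: float = Field(-0.25, description="initial anisotropy (c-a)/(c+a); negative for prolate")
    gamma_over_eta_m_s: float = Field(1e-8, gt=0)
    r0_um: float = Field(100.0, gt=0)
    n_frames: int = Field(72, ge=2)
    n_tracks: int = Field(1, ge=1)
    axis_noise_um: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check_eps(self) -> "RoundingParams":
        if not abs(self.eps0) < 1:
            raise ValueError("eps0 must satisfy |eps0| < 1 (spheroid degenerates at +-1)")
        return self


class FusionParams(_Strict):
    """Frenkel viscous-sintering neck growth between two discs."""

    scenario: Literal["fusion"] = "fusion"
    R1_um: float = Field(100.0, gt=0)
    R2_um: float = Field(100.0, gt=0)
    gamma_over_eta_m_s: float = Field(2.9e-9, gt=0)
    n_frames: int = Field(48, ge=2)
    rho_noise_um: float = Field(0.0, ge=0)
    rho_max_um: float | None = Field(None, gt=0, description="plateau; defaults to min(R1, R2)")


class CountParams(_Strict):
    """Cluster-count dynamics dN/dt = p1 - min(t/t_s, 1) p2 N."""

    scenario: Literal["counts"] = "counts"
    p1_per_day: float = Field(50.0, gt=0)
    p2_per_day: float = Field(1.5, gt=0)
    ts_day: float = Field(8.0, gt=0)
    horizon_day: float = Field(14.0, gt=0)
    noise: Literal["none", "poisson", "gaussian"] = "none"
    gaussian_sd: float = Field(3.0, ge=0)
    onset_delay_day: float = Field(0.0, ge=0, description="zero-padded pre-onset span (seeding-density delay)")
    condition: str = "synthetic"


class OrientationParams(_Strict):
    """Nematic angles with von-Mises-concentrated doubled angles."""

    scenario: Literal["orientation"] = "orientation"
    kappa: float = Field(2.0, ge=0)
    mu_rad: float = Field(0.0, description="mean fiber direction, radians mod pi")
    n_angles: int = Field(1000, ge=1)


class SpeckleParams(_Strict):
    """Random speckle texture pair related by a displacement field."""

    scenario: Literal["speckle"] = "speckle"
    n_speckles: int = Field(3000, ge=1)
    speckle_sigma_px: float = Field(1.5, gt=0)
    shift_px: tuple[float, float] = (0.0, 0.0)


ScenarioParams = Union[
    HoleParams, RoundingParams, FusionParams, CountParams, OrientationParams, SpeckleParams
]


class SimulationConfig(_Strict):
    """Master configuration: seed, imaging geometry, and scenario parameters.

    The seed fully determines the output: two runs with an equal config
    are bit-identical.
    """

    seed: int = Field(..., ge=0)
    pixel_size_um: float = Field(0.65, gt=0)
    frame_interval_s: float | None = Field(None, gt=0)
    image_shape: tuple[int, int] = (512, 512)
    render_masks: bool = False
    params: ScenarioParams = Field(..., discriminator="scenario")

    @model_validator(mode="after")
    def _default_frame_interval(self) -> "SimulationConfig":
        if self.frame_interval_s is None:
            # fast acquisition for hole-opening movies, slow for cluster movies
            fast = isinstance(self.params, (HoleParams, SpeckleParams))
            object.__setattr__(self, "frame_interval_s", 300.0 if fast else 1200.0)
        if min(self.image_shape) < 8:
            raise ValueError("image_shape must be at least 8x8 pixels")
        return self

    @property
    def scenario(self) -> str:
        return self.params.scenario


_SCENARIO_MODELS = {
    "hole": HoleParams,
    "rounding": RoundingParams,
    "fusion": FusionParams,
    "counts": CountParams,
    "orientation": OrientationParams,
    "speckle": SpeckleParams,
}


def config_from_dict(doc: dict) -> SimulationConfig:
    """Build a config from a flat JSON document.

    The document carries top-level keys (``seed``, ``pixel_size_um``,
    ``frame_interval_s``, ``image_shape``, ``render_masks``) plus a
    ``scenario`` tag; every remaining key belongs to that scenario's
    parameter model.  Unknown keys raise with the offending key named.
    """
    doc = dict(doc)
    scenario = doc.pop("scenario", None)
    if scenario not in _SCENARIO_MODELS:
        raise ValueError(
            f"scenario must be one of {sorted(_SCENARIO_MODELS)}, got {scenario!r}"
        )
    top = {k: doc.pop(k) for k in ("seed", "pixel_size_um", "frame_interval_s", "image_shape", "render_masks") if k in doc}
    params = _SCENARIO_MODELS[scenario](**doc)
    return SimulationConfig(params=params, **top)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a JSON config file."""
    with open(path) as fh:
        doc = json.load(fh)
    return config_from_dict(doc)


def dump_config(cfg: SimulationConfig) -> dict:
    """Flat JSON-ready dict; ``config_from_dict`` round-trips it."""
    doc = cfg.model_dump(exclude={"params"})
    doc.update(cfg.params.model_dump())
    doc["image_shape"] = list(doc["image_shape"])
    if "shift_px" in doc:
        doc["shift_px"] = list(doc["shift_px"])
    return doc
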