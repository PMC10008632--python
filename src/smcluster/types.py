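"""Core time-series containers and their CSV dialects.

All image-derived quantities are stored in micrometres and seconds,
matching the on-disk CSV schemas (unit-suffixed column names).  Fits
convert to SI internally where a constant is conventionally quoted in
metres per second (the capillary velocity gamma/eta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ShapeTrack",
    "HoleSeries",
    "FusionSeries",
    "CountSeries",
    "FitResult",
    "tracks_to_frame",
    "tracks_from_frame",
]


def _as1d(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


@dataclass
class ShapeTrack:
    """Per-cluster morphometric time series.

    Attributes
    ----------
    object_id : label of the tracked connected component.
    t_s : frame times (s).
    area_um2, perimeter_um : projected area and contour perimeter.
    major_um, minor_um : ellipse semi-axes from second central moments,
        ``major_um >= minor_um``.
    cx_um, cy_um : centroid.

    Derived properties follow the prolate-spheroid convention with the
    major semi-axis ``a`` and minor semi-axis ``c``: the anisotropy
    ``eps = (c - a)/(c + a)`` is non-positive, the mean radius is
    ``r = (2a + c)/3``, and circularity is ``4*pi*A/P**2``.
    """

    object_id: int
    t_s: np.ndarray
    area_um2: np.ndarray
    perimeter_um: np.ndarray
    major_um: np.ndarray
    minor_um: np.ndarray
    cx_um: np.ndarray
    cy_um: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t_s", "area_um2", "perimeter_um", "major_um", "minor_um", "cx_um", "cy_um"):
            setattr(self, name, _as1d(getattr(self, name)))
        n = self.t_s.size
        for name in ("area_um2", "perimeter_um", "major_um", "minor_um", "cx_um", "cy_um"):
            if getattr(self, name).size != n:
                raise ValueError(f"ShapeTrack field {name!r} length mismatch")

    @property
    def eps(self) -> np.ndarray:
        a, c = self.major_um, self.minor_um
        return (c - a) / (c + a)

    @property
    def r_um(self) -> np.ndarray:
        return (2.0 * self.major_um + self.minor_um) / 3.0

    @property
    def circularity(self) -> np.ndarray:
        circ = 4.0 * np.pi * self.area_um2 / self.perimeter_um**2
        # digitization can push a perfect disc marginally above 1
        out = np.where((circ > 1.0) & (circ <= 1.02), 1.0, circ)
        return out

    def __len__(self) -> int:
        return self.t_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.object_id,
                "t_s": self.t_s,
                "area_um2": self.area_um2,
                "perimeter_um": self.perimeter_um,
                "circ": self.circularity,
                "major_um": self.major_um,
                "minor_um": self.minor_um,
                "eps": self.eps,
                "r_um": self.r_um,
                "cx_um": self.cx_um,
                "cy_um": self.cy_um,
            }
        )


def tracks_to_frame(tracks: list[ShapeTrack]) -> pd.DataFrame:
    """Concatenate tracks into one long-format table."""
    if not tracks:
        return pd.DataFrame(
            columns=["track_id", "t_s", "area_um2", "perimeter_um", "circ",
                     "major_um", "minor_um", "eps", "r_um", "cx_um", "cy_um"]
        )
    return pd.concat([t.to_frame() for t in tracks], ignore_index=True)


def tracks_from_frame(df: pd.DataFrame) -> list[ShapeTrack]:
    out = []
    for oid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        out.append(
            ShapeTrack(
                object_id=int(oid),
                t_s=grp["t_s"],
                area_um2=grp["area_um2"],
                perimeter_um=grp["perimeter_um"],
                major_um=grp["major_um"],
                minor_um=grp["minor_um"],
                cx_um=grp["cx_um"],
                cy_um=grp["cy_um"],
            )
        )
    return out


@dataclass
class HoleSeries:
    """Hole width versus time, plus optional crack-tip edge profile.

    ``profile_x_um``/``profile_y_um`` are contour points near the
    advancing tip, rotated into the propagation frame (x along the
    propagation direction, measured back from the tip; x >= 0).
    """

    t_s: np.ndarray
    width_um: np.ndarray
    profile_x_um: np.ndarray | None = None
    profile_y_um: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = _as1d(self.t_s)
        self.width_um = _as1d(self.width_um)
        if self.t_s.size != self.width_um.size:
            raise ValueError("HoleSeries time/width length mismatch")
        if np.any(self.width_um < -1e-9):
            raise ValueError("hole widths must be non-negative")
        if self.profile_x_um is not None:
            self.profile_x_um = _as1d(self.profile_x_um)
            self.profile_y_um = _as1d(self.profile_y_um)

    def __len__(self) -> int:
        return self.t_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "width_um": self.width_um})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HoleSeries":
        return cls(t_s=df["t_s"], width_um=df["width_um"])


@dataclass
class FusionSeries:
    """Neck radius rho(t) for a fusing cluster pair.

    ``R0 = sqrt((A1 + A2)/(2*pi))`` is the equivalent radius built from
    the two initial (pre-contact) projected areas; it is recomputed here
    so the invariant holds exactly.
    """

    t_s: np.ndarray
    rho_um: np.ndarray
    area1_um2: float
    area2_um2: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = _as1d(self.t_s)
        self.rho_um = _as1d(self.rho_um)
        if self.t_s.size != self.rho_um.size:
            raise ValueError("FusionSeries time/rho length mismatch")
        if np.any(self.rho_um < -1e-9):
            raise ValueError("neck radii must be non-negative")

    @property
    def R0_um(self) -> float:
        return float(np.sqrt((self.area1_um2 + self.area2_um2) / (2.0 * np.pi)))

    def __len__(self) -> int:
        return self.t_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "rho_um": self.rho_um})


@dataclass
class CountSeries:
    """Cluster counts per day for one experimental condition."""

    t_day: np.ndarray
    N: np.ndarray
    condition: str = "synthetic"
    onset_day: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_day = _as1d(self.t_day)
        self.N = _as1d(self.N)
        if self.t_day.size != self.N.size:
            raise ValueError("CountSeries time/count length mismatch")
        if np.any(np.diff(self.t_day) <= 0):
            raise ValueError("count times must be strictly increasing")
        if np.any(self.N < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.t_day.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_day": self.t_day, "N": self.N, "condition": self.condition})


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and residual diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    residual_sd: float = float("nan")
    r_squared: float = float("nan")
    n_points: int = 0
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def to_dict(self) -> dict[str, Any]:
        return {
            "params": self.params,
            "stderr": self.stderr,
            "residual_sd": self.residual_sd,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool, list))},
        }
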