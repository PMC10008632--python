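"""Hole-opening kinetics and derived material constants.

A hole in a contractile cell sheet opens like a brittle fracture of a
viscoelastic material: elastic recoil of the sheet (scaling as
``E h (R_c - a)``) drives the opening and cell-substrate friction
(``k R_c^2 da/dt``) resists it, giving exponential saturation of the
width,

    a(t) = a_max [1 - exp(-C t)],      C ~ E h / (k R_c^2).

Near the advancing tip the edge profile is the parabolic limit of the
viscoelastic-trumpet crack shape, ``y = A sqrt(x)`` with
``A ~ sqrt(G/E)`` linking the profile to adhesion energy G and sheet
modulus E.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from smcluster.types import FitResult, HoleSeries

__all__ = ["fit_hole_width", "fit_tip_parabola", "derive_constants", "HoleFitError"]

UM_PER_M = 1e6


class HoleFitError(RuntimeError):
    """Raised when the saturation law cannot be fitted."""


def _model(t: np.ndarray, a_max: float, C: float) -> np.ndarray:
    return a_max * (1.0 - np.exp(-C * t))


def fit_hole_width(
    series: HoleSeries,
    n_boot: int = 1000,
    seed: int = 0,
) -> FitResult:
    """Fit ``a(t) = a_max [1 - exp(-C t)]`` by nonlinear least squares.

    The time origin is moved to the first frame with nonzero width (the
    law presumes a(0) = 0 at nucleation).  The fit multi-starts from
    a_max0 = max width and a decade grid of rates; standard errors come
    from a pairs bootstrap over time points, which is robust to
    heteroscedastic width noise.

    Returns a_max (um), C (1/s), the stretching time 1/C (s), bootstrap
    SEs and the residual SD.  Raises :class:`HoleFitError` on a
    monotone-decreasing series or non-convergence from every start.
    """
    t = np.asarray(series.t_s, dtype=float)
    a = np.asarray(series.width_um, dtype=float)
    if t.size < 5:
        raise HoleFitError("need at least 5 time points")
    nz = np.nonzero(a > 0)[0]
    if nz.size == 0:
        raise HoleFitError("hole never opens")
    t0 = t[nz[0]] - (t[nz[0]] - t[nz[0] - 1] if nz[0] > 0 else 0.0)
    t = t - t0
    keep = t >= 0
    t, a = t[keep], a[keep]
    if a[-1] <= a[0] and np.all(np.diff(a) <= 0):
        raise HoleFitError("monotone-decreasing widths cannot follow the saturation law")
    span = t.max() - t.min()

    p, cost = _fit_once(t, a)
    if p is None:
        raise HoleFitError("nonlinear fit failed to converge from every start")
    a_max, C = p
    if span * C < 1.0:
        raise HoleFitError(
            f"series spans {span * C:.2f} stretching times; need at least one")

    resid = a - _model(t, a_max, C)
    dof = max(t.size - 2, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))

    stderr: dict[str, float] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, t.size, size=t.size)
            pb, _ = _fit_once(t[idx], a[idx], starts=[(a_max, C)])
            if pb is not None:
                boots.append(pb)
        if len(boots) >= 10:
            boots_arr = np.array(boots)
            stderr = {"a_max_um": float(boots_arr[:, 0].std(ddof=1)),
                      "C_per_s": float(boots_arr[:, 1].std(ddof=1))}

    return FitResult(
        params={"a_max_um": float(a_max), "C_per_s": float(C),
                "stretching_time_s": float(1.0 / C)},
        stderr=stderr,
        residual_sd=residual_sd,
        n_points=int(t.size),
        diagnostics={"time_origin_s": float(t0), "n_boot": int(n_boot)},
    )


def _fit_once(t, a, starts=None):
    """Least squares from multiple starts; best (params, cost) or (None, inf)."""
    if starts is None:
        a0 = max(a.max(), 1e-9)
        dt = np.median(np.diff(np.unique(t))) if np.unique(t).size > 1 else 1.0
        starts = [(a0, c0) for c0 in 10.0 ** np.arange(-6, 0)
                  if 1.0 / c0 > dt / 10]
    best, best_cost = None, np.inf
    for a0, c0 in starts:
        try:
            res = least_squares(
                lambda p: _model(t, p[0], p[1]) - a,
                x0=[a0, c0],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and res.cost < best_cost:
            best, best_cost = res.x, res.cost
    return best, best_cost


def fit_tip_parabola(x_m: np.ndarray, y_m: np.ndarray) -> float:
    """Least-squares coefficient of the crack-tip parabola y = A sqrt(x).

    Minimizing ``sum (y - A sqrt(x))^2`` has the closed form
    ``A = sum(y sqrt(x)) / sum(x)``.  Inputs in metres, A in m^(1/2).
    """
    x = np.asarray(x_m, dtype=float)
    y = np.asarray(y_m, dtype=float)
    if np.any(x < 0):
        raise ValueError("profile x must be >= 0 in the propagation frame")
    sx = x.sum()
    if sx == 0:
        raise ValueError("all profile x are zero; parabola coefficient undefined")
    return float((y * np.sqrt(x)).sum() / sx)


def derive_constants(
    fit: FitResult,
    E_pa: float = 2000.0,
    h_m: float = 30e-6,
    R_c_m: float = 200e-6,
    A_sqrt_m: float | None = None,
) -> dict[str, float]:
    """Material constants implied by the hole fit.

    * friction coefficient ``k = E h / (C R_c^2)`` (Pa s / m),
    * adhesion energy ``G = A^2 E`` (J/m^2) when the tip-parabola
      coefficient ``A`` is supplied.

    The sheet thickness default (30 um) assumes the typical three
    stacked cell layers of ~10 um each observed before cluster
    formation; no direct thickness measurement backs it, so ``k`` is an
    order-of-magnitude estimate.  All inputs are echoed for provenance.
    """
    for name, v in (("E_pa", E_pa), ("h_m", h_m), ("R_c_m", R_c_m)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    C = fit.params["C_per_s"]
    out = {
        "k_pa_s_per_m": E_pa * h_m / (C * R_c_m**2),
        "E_pa": E_pa,
        "h_m": h_m,
        "R_c_m": R_c_m,
        "C_per_s": C,
        "a_max_um": fit.params["a_max_um"],
    }
    if A_sqrt_m is not None:
        if A_sqrt_m <= 0:
            raise ValueError("A must be positive")
        out["A_sqrt_m"] = A_sqrt_m
        out["G_j_per_m2"] = A_sqrt_m**2 * E_pa
    return out
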