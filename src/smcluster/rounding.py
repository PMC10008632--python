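"""Active-dewetting rounding kinetics: anisotropy decay and capillary velocity.

A freshly torn-off cluster is an oblong, nearly prolate spheroid that
rounds up under its effective surface tension gamma against viscous
dissipation eta.  Near the sphere the shape anisotropy
``eps = (c - a)/(c + a)`` relaxes exponentially,

    ln(eps/eps0) = -(15/56) (gamma/eta) * integral dt / r,

with ``r = (2a + c)/3`` the mean radius, so the slope of
``ln(eps/eps0)`` against the cumulative ``integral dt/r`` measures the
capillary velocity gamma/eta directly.  The 15/56 prefactor comes from
the near-sphere velocity-field solution of the power balance
``gamma dS/dt = -eta int |grad u|^2 dV``; it is taken as authoritative
for fitting, while :func:`dissipation_rate_check` evaluates both sides
of that balance for a user-supplied interior velocity ansatz and reports
(never asserts) the prefactor the ansatz implies.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np

from smcluster.synth import spheroid_axes
from smcluster.types import FitResult, ShapeTrack

__all__ = ["fit_rounding", "dissipation_rate_check", "spheroid_area", "RoundingFitError"]

log = logging.getLogger(__name__)

UM_PER_M = 1e6
PREFACTOR = 15.0 / 56.0


class RoundingFitError(RuntimeError):
    pass


def fit_rounding(
    tracks: list[ShapeTrack],
    eps_min: float = 0.01,
    assume_constant_r: bool = False,
    min_frames: int = 5,
) -> FitResult:
    """Estimate gamma/eta from a set of rounding tracks.

    Per track, frames are retained while ``|eps| >= eps_min`` (below
    that, ``ln(eps/eps0)`` is noise-dominated) and while eps keeps the
    sign of its first retained frame — a sign flip marks the end of the
    measurable decay and truncates the track there.  Tracks with fewer
    than ``min_frames`` usable frames are excluded with a warning.

    ``ln(eps/eps0)`` is regressed on the cumulative trapezoidal
    ``integral dt/r`` (per-frame r; with ``assume_constant_r`` on
    ``t / mean(r)``, the constant-radius reading of the law).  Each
    track's slope gives ``gamma/eta = -(56/15) * slope``; the pooled
    estimate is the inverse-variance-weighted mean across tracks.
    """
    slopes, variances, r2s, used_ids = [], [], [], []
    for tr in tracks:
        res = _track_slope(tr, eps_min, assume_constant_r, min_frames)
        if res is None:
            log.warning("track %s excluded from rounding fit (too few usable frames)",
                        tr.object_id)
            continue
        s, var, r2 = res
        slopes.append(s)
        variances.append(var)
        r2s.append(r2)
        used_ids.append(tr.object_id)
    if not slopes:
        raise RoundingFitError("no track has enough frames above eps_min")

    go_e = -(1.0 / PREFACTOR) * np.array(slopes) / UM_PER_M  # m/s per track
    var = np.array(variances) / (PREFACTOR * UM_PER_M) ** 2
    w = 1.0 / np.maximum(var, 1e-12 * np.maximum(go_e**2, 1e-40))
    pooled = float(np.sum(w * go_e) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))

    return FitResult(
        params={"gamma_over_eta_m_s": pooled},
        stderr={"gamma_over_eta_m_s": pooled_se},
        r_squared=float(np.mean(r2s)),
        n_points=len(slopes),
        diagnostics={
            "per_track_gamma_over_eta_m_s": [float(g) for g in go_e],
            "per_track_r2": [float(r) for r in r2s],
            "track_ids": used_ids,
            "eps_min": eps_min,
            "assume_constant_r": assume_constant_r,
        },
    )


def _track_slope(tr: ShapeTrack, eps_min: float, const_r: bool, min_frames: int):
    eps = tr.eps
    r = tr.r_um
    t = tr.t_s
    keep = np.abs(eps) >= eps_min
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        return None
    # truncate at the first sign flip relative to the first retained frame
    sign0 = np.sign(eps[idx[0]])
    flip = np.nonzero(np.sign(eps[idx]) != sign0)[0]
    if flip.size:
        idx = idx[:flip[0]]
    if idx.size < min_frames:
        return None
    eps_u, r_u, t_u = eps[idx], r[idx], t[idx]
    y = np.log(eps_u / eps_u[0])
    if const_r:
        x = (t_u - t_u[0]) / r_u.mean()
    else:
        x = np.concatenate([[0.0], np.cumsum(
            0.5 * (1.0 / r_u[1:] + 1.0 / r_u[:-1]) * np.diff(t_u))])
    xm, ym = x - x.mean(), y - y.mean()
    sxx = float(np.sum(xm**2))
    if sxx == 0:
        return None
    slope = float(np.sum(xm * ym) / sxx)
    resid = ym - slope * xm
    dof = max(x.size - 2, 1)
    var_slope = float(np.sum(resid**2) / dof / sxx)
    ss_tot = float(np.sum(ym**2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return slope, var_slope, r2


# ---------------------------------------------------------------------------
# power-balance diagnostic

def spheroid_area(eps: float, volume: float) -> float:
    """Exact surface area of a volume-conserving spheroid at anisotropy eps.

    The spheroid has symmetry semi-axis ``a`` and equatorial semi-axis
    ``c`` with eps = (c-a)/(c+a): prolate for eps < 0, oblate for
    eps > 0, sphere at 0.
    """
    a, c = spheroid_axes(float(eps), volume)
    if abs(a - c) < 1e-9 * a:
        R = (a * c * c) ** (1.0 / 3.0)
        return 4.0 * np.pi * R * R
    if a > c:  # prolate
        e = np.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * np.pi * c**2 * (1.0 + (a / (c * e)) * np.arcsin(e))
    e = np.sqrt(1.0 - (a / c) ** 2)  # oblate
    return 2.0 * np.pi * c**2 * (1.0 + ((1.0 - e**2) / e) * np.arctanh(e))


def _affine_ansatz(e_a: float, e_c: float) -> Callable:
    """Affine incompressible field u = (e_c x, e_c y, e_a z)."""

    def u(x, y, z):
        return e_c * x, e_c * y, e_a * z

    return u


def dissipation_rate_check(
    eps: float,
    r_um: float,
    eps_dot: float = 1e-4,
    ansatz: Callable | None = None,
    n_quad: int = 24,
    gamma_over_eta_m_s: float = 1e-8,
) -> dict[str, float]:
    """Evaluate both sides of the surface-tension/dissipation balance.

    For a volume-conserving spheroid at anisotropy ``eps`` changing at
    rate ``eps_dot`` (1/s), computes the surface-area rate ``dS/dt``
    (exact area formula, central-difference derivative in eps) and the
    viscous dissipation integral ``int grad u : grad u dV`` of the
    interior velocity ansatz by Gauss-Legendre quadrature over the
    spheroid with finite-difference velocity gradients.  The ansatz
    defaults to the affine incompressible field consistent with the
    axis rates; any callable ``(x, y, z) -> (ux, uy, uz)`` can be
    supplied, but it must be volume conserving (divergence checked).

    Returns the two sides plus the relaxation-rate prefactor the ansatz
    implies, for comparison against the 15/56 used in fitting.  This is
    a diagnostic: a given ansatz need not reproduce 15/56.
    """
    if abs(eps) > 0.05:
        raise ValueError("diagnostic is valid only near the sphere (|eps| <= 0.05)")
    # volume giving mean radius r_um at this eps (axes scale as V^(1/3))
    a0, c0 = spheroid_axes(eps, 1.0)
    volume = (r_um / ((2 * a0 + c0) / 3.0)) ** 3

    h = 1e-5
    dS_deps = (spheroid_area(eps + h, volume) - spheroid_area(eps - h, volume)) / (2 * h)
    S_dot = dS_deps * eps_dot  # um^2/s

    a, c = spheroid_axes(eps, volume)
    ap, cp = spheroid_axes(eps + h, volume)
    am, cm = spheroid_axes(eps - h, volume)
    a_dot = (ap - am) / (2 * h) * eps_dot
    c_dot = (cp - cm) / (2 * h) * eps_dot
    e_a, e_c = a_dot / a, c_dot / c

    if ansatz is None:
        ansatz = _affine_ansatz(e_a, e_c)

    D, div_max, grad_scale = _dissipation_quadrature(ansatz, a, c, n_quad)
    if div_max > 1e-4 * max(grad_scale, 1e-30):
        raise ValueError(
            f"velocity ansatz is not volume conserving (max |div u| = {div_max:.3g})")

    implied_prefactor = np.nan
    if eps != 0.0 and D > 0:
        # balance: (gamma/eta) dS/deps = -K eps_dot with D = K eps_dot^2,
        # so eps_dot = -(gamma/eta) (dS/deps)/K = -P (gamma/eta) eps/r
        K = D / eps_dot**2
        implied_prefactor = float((dS_deps / K) * ((2 * a + c) / 3.0) / eps)

    go_um_s = gamma_over_eta_m_s * UM_PER_M
    return {
        "S_dot_um2_per_s": float(S_dot),
        "surface_power_per_eta_um3_per_s2": float(go_um_s * S_dot),
        "dissipation_integral_um3_per_s2": float(D),
        "implied_prefactor": implied_prefactor,
        "reference_prefactor": PREFACTOR,
        "volume_um3": float(volume),
        "strain_rate_a_per_s": float(e_a),
        "strain_rate_c_per_s": float(e_c),
    }


def _dissipation_quadrature(u: Callable, a: float, c: float, n: int):
    """Gauss-Legendre quadrature of |grad u|^2 over the spheroid x^2/c^2 +
    y^2/c^2 + z^2/a^2 <= 1, with central-difference gradients.

    Returns (integral, max |div u|, typical gradient magnitude).
    """
    # map unit ball -> spheroid: (x, y, z) = (c X, c Y, a Z)
    tr, wr = np.polynomial.legendre.leggauss(n)       # radius in [0, 1]
    rr = 0.5 * (tr + 1.0)
    wr = 0.5 * wr
    tc, wc = np.polynomial.legendre.leggauss(n)       # cos(polar)
    phi = np.linspace(0.0, 2.0 * np.pi, 2 * n, endpoint=False)
    wphi = 2.0 * np.pi / (2 * n)

    R, CT, PH = np.meshgrid(rr, tc, phi, indexing="ij")
    ST = np.sqrt(1.0 - CT**2)
    X = R * ST * np.cos(PH)
    Y = R * ST * np.sin(PH)
    Z = R * CT
    x, y, z = c * X, c * Y, a * Z

    W = (np.broadcast_to(wr[:, None, None], R.shape)
         * np.broadcast_to(wc[None, :, None], R.shape) * wphi
         * R**2) * (a * c * c)

    h = 1e-4 * min(a, c)
    grads = []
    div = np.zeros_like(x)
    for comp in range(3):
        for axis in range(3):
            args_p = [x.copy(), y.copy(), z.copy()]
            args_m = [x.copy(), y.copy(), z.copy()]
            args_p[axis] += h
            args_m[axis] -= h
            dudx = (u(*args_p)[comp] - u(*args_m)[comp]) / (2 * h)
            grads.append(dudx)
            if comp == axis:
                div += dudx
    gsq = sum(np.asarray(g, dtype=float) ** 2 for g in grads)
    integral = float(np.sum(W * gsq))
    grad_scale = float(np.sqrt(np.max(gsq))) if np.max(gsq) > 0 else 0.0
    return integral, float(np.max(np.abs(div))), grad_scale
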