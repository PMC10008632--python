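"""Frenkel viscous-sintering fit for cluster fusion.

Two clusters in contact coalesce like viscous drops: the neck radius
rho between them grows as

    rho^2 / R0 = (gamma/eta) * t,

with ``R0 = sqrt((A1 + A2)/(2 pi))`` the equivalent radius built from
the initial projected areas, until geometric saturation at roughly the
cluster radius.  The slope of ``rho^2 / R0`` against time (through the
origin — the law has no intercept) estimates the fusion capillary
velocity gamma/eta.
"""

from __future__ import annotations

import numpy as np

from smcluster.types import FitResult, FusionSeries

__all__ = ["fit_frenkel", "pool_fusion_fits", "FusionFitError"]

UM_PER_M = 1e6


class FusionFitError(RuntimeError):
    pass


def fit_frenkel(
    series: FusionSeries,
    growth_cutoff: float = 0.9,
    contact_rho_um: float | None = None,
) -> FitResult:
    """Fit the sintering law to one neck-growth series.

    The plateau ``rho_inf`` is the median of the last quartile of rho;
    the growth phase is the frames with ``rho < growth_cutoff *
    rho_inf`` (Frenkel's law holds before geometric saturation).  Time
    is measured from first contact, the first frame with rho above
    ``contact_rho_um`` (default: one pixel at the standard 0.65 um/px
    scale).  An ordinary least-squares line through the origin of
    ``rho^2 / R0`` versus t gives gamma/eta.

    Raises :class:`FusionFitError` with fewer than 4 growth-phase
    points or a non-positive slope.
    """
    t = np.asarray(series.t_s, dtype=float)
    rho = np.asarray(series.rho_um, dtype=float)
    R0 = series.R0_um
    if contact_rho_um is None:
        contact_rho_um = 0.65

    nz = np.nonzero(rho > contact_rho_um)[0]
    if nz.size == 0:
        raise FusionFitError("lobes never come into contact")
    i0 = nz[0]
    t0 = t[i0 - 1] if i0 > 0 else t[i0]
    tt = t - t0
    keep0 = tt >= 0
    tt, rr = tt[keep0], rho[keep0]

    q = max(rr.size // 4, 1)
    rho_inf = float(np.median(rr[-q:]))
    growth = rr < growth_cutoff * rho_inf
    growth &= tt > 0
    if growth.sum() < 4:
        raise FusionFitError(
            f"only {int(growth.sum())} growth-phase points (need >= 4)")

    x = tt[growth]
    y = rr[growth] ** 2 / R0
    slope = float(np.sum(x * y) / np.sum(x * x))
    if slope <= 0:
        raise FusionFitError("non-positive sintering slope")
    resid = y - slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    dof = max(x.size - 1, 1)
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(x * x)))

    return FitResult(
        params={"gamma_over_eta_m_s": slope / UM_PER_M,
                "R0_um": R0, "rho_inf_um": rho_inf},
        stderr={"gamma_over_eta_m_s": slope_se / UM_PER_M},
        r_squared=r2,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=int(growth.sum()),
        diagnostics={"growth_cutoff": growth_cutoff,
                     "contact_time_s": float(t0),
                     "growth_index_range": [int(np.nonzero(growth)[0][0]),
                                            int(np.nonzero(growth)[0][-1])]},
    )


def pool_fusion_fits(fits: list[FitResult]) -> FitResult:
    """Mean +- SD of gamma/eta across independently fitted pairs
    (mirrors reporting fusion experiments as mean +- SD over N pairs)."""
    if not fits:
        raise FusionFitError("no fits to pool")
    vals = np.array([f.params["gamma_over_eta_m_s"] for f in fits])
    return FitResult(
        params={"gamma_over_eta_m_s": float(vals.mean()),
                "rho_inf_um": float(np.mean([f.params["rho_inf_um"] for f in fits]))},
        stderr={"gamma_over_eta_m_s": float(vals.std(ddof=1)) if vals.size > 1 else 0.0},
        n_points=len(fits),
        diagnostics={"per_pair_gamma_over_eta_m_s": [float(v) for v in vals]},
    )
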