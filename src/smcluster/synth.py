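"""Synthetic-data generators with known ground truth.

Every input modality the analysis pipeline consumes can be generated
here from a seeded :class:`~smcluster.config.SimulationConfig`:

* hole-width series following exponential saturation
  ``a(t) = a_max [1 - exp(-C t)]``, optionally rendered as an elongating
  elliptical hole in a foreground sheet mask, with parabolic crack-tip
  profile points ``y = A sqrt(x)`` when the coefficient ``A`` is given;
* cluster rounding tracks integrating the anisotropy decay
  ``d(eps)/dt = -(15/56) (gamma/eta) eps / r`` on a volume-conserving
  prolate spheroid, emitted as morphometric tracks or rasterized
  ellipse masks;
* fusion neck series ``rho(t) = sqrt((gamma/eta) t R0)`` capped at the
  geometric plateau, optionally rendered as a disc doublet with a neck
  bridge;
* daily cluster counts from ``dN/dt = p1 - min(t/t_s, 1) p2 N``;
* nematic angle samples whose doubled angles are von-Mises distributed,
  optionally rendered as an oriented-fiber texture;
* speckle image pairs related by a known displacement field.

The generators emit the fitted kinetic laws plus measurement noise; they
are not cell-scale mechanistic simulations.  A single master seed feeds
named substreams (:func:`smcluster.rng.substream`) so outputs are
bit-reproducible and adding a modality never perturbs the others.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy import ndimage, special
from scipy.optimize import brentq
from skimage.draw import disk as draw_disk

from smcluster.config import (
    CountParams,
    FusionParams,
    HoleParams,
    OrientationParams,
    RoundingParams,
    SimulationConfig,
    SpeckleParams,
)
from smcluster.rng import substream
from smcluster.types import CountSeries, FusionSeries, HoleSeries, ShapeTrack

__all__ = [
    "gen_hole_series",
    "gen_rounding_track",
    "gen_fusion_track",
    "gen_count_series",
    "gen_orientation_sample",
    "gen_speckle_pair",
    "render_fiber_texture",
    "kappa_for_order",
    "spheroid_axes",
    "ellipse_perimeter",
]

UM_PER_M = 1e6


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# geometry helpers

def spheroid_axes(eps: float | np.ndarray, volume_um3: float):
    """Semi-axes (major a, minor c) of a spheroid with anisotropy eps.

    The spheroid has one axis of length ``a`` and two of length ``c``
    with ``eps = (c - a)/(c + a)`` and volume ``(4/3) pi a c^2`` held
    fixed.  For prolate shapes (eps < 0) ``a`` is the long axis.
    """
    q = (1.0 + np.asarray(eps)) / (1.0 - np.asarray(eps))  # c/a
    a = (3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0) * q ** (-2.0 / 3.0)
    return a, q * a


def ellipse_perimeter(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Exact ellipse perimeter via the complete elliptic integral."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    big, small = np.maximum(a, c), np.minimum(a, c)
    m = 1.0 - (small / big) ** 2
    return 4.0 * big * special.ellipe(m)


def _rasterize_ellipse(shape, center_px, semi_px, angle_rad=0.0) -> np.ndarray:
    """Filled ellipse as a uint8 0/255 mask (pixel centers at integers,
    origin top-left, x right, y down)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = center_px
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    xr = (xx - cx) * ca + (yy - cy) * sa
    yr = -(xx - cx) * sa + (yy - cy) * ca
    ax, ay = semi_px
    inside = (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0
    return np.where(inside, np.uint8(255), np.uint8(0))


# ---------------------------------------------------------------------------
# hole opening

def gen_hole_series(cfg: SimulationConfig) -> tuple[HoleSeries, np.ndarray | None]:
    """Generate a hole-width time series (and optional mask stack).

    Widths follow ``a(t) = a_max [1 - exp(-C t)]`` plus optional
    Gaussian noise.  When ``render_masks`` is set, each frame is a
    foreground sheet (255) with an enclosed elliptical hole (0) whose
    minor axis equals the (noise-free) width; when ``tip_A_sqrt_m`` is
    given, crack-tip profile points sampled from ``y = A sqrt(x)`` are
    attached.
    """
    p = cfg.params
    _require(isinstance(p, HoleParams), "config scenario must be 'hole'")
    rng = substream(cfg.seed, "hole.width")

    t = np.arange(p.n_frames) * cfg.frame_interval_s
    width = p.a_max_um * (1.0 - np.exp(-p.C_per_s * t))
    if p.width_noise_um > 0:
        width = width + rng.normal(0.0, p.width_noise_um, size=width.shape)
    width = np.clip(width, 0.0, None)
    # the model starts from a closed hole regardless of noise
    width[0] = 0.0

    profile_x = profile_y = None
    if p.tip_A_sqrt_m is not None:
        prng = substream(cfg.seed, "hole.profile")
        x_um = prng.uniform(0.0, 50.0, size=200)
        y_um = p.tip_A_sqrt_m * np.sqrt(x_um / UM_PER_M) * UM_PER_M
        profile_x, profile_y = x_um, y_um

    stack = None
    if cfg.render_masks:
        aspect = 2.2  # hole length / width; the crack runs ahead of the opening
        h, w = cfg.image_shape
        px = cfg.pixel_size_um
        need = aspect * p.a_max_um / px + 4
        _require(need <= min(h, w),
                 f"image too small to contain the saturated hole: need {need:.0f} px")
        frames = []
        for a_um in p.a_max_um * (1.0 - np.exp(-p.C_per_s * t)):
            frame = np.full((h, w), 255, dtype=np.uint8)
            if a_um / px >= 1.0:
                hole = _rasterize_ellipse(
                    (h, w), (w / 2.0, h / 2.0),
                    (aspect * a_um / (2 * px), a_um / (2 * px)))
                frame[hole > 0] = 0
            frames.append(frame)
        stack = np.stack(frames)

    series = HoleSeries(
        t_s=t, width_um=width, profile_x_um=profile_x, profile_y_um=profile_y,
        meta={"a_max_um": p.a_max_um, "C_per_s": p.C_per_s, "seed": cfg.seed},
    )
    return series, stack


# ---------------------------------------------------------------------------
# rounding

def _integrate_eps(eps0: float, k_um_s: float, volume_um3: float,
                   t_s: np.ndarray, substeps: int = 20) -> np.ndarray:
    """RK4 integration of d(eps)/dt = -(15/56) k eps / r(eps)."""
    pref = 15.0 / 56.0

    def rhs(eps: float) -> float:
        a, c = spheroid_axes(eps, volume_um3)
        r = (2.0 * a + c) / 3.0
        return -pref * k_um_s * eps / r

    out = np.empty_like(t_s, dtype=float)
    out[0] = eps = eps0
    for i in range(1, t_s.size):
        dt = (t_s[i] - t_s[i - 1]) / substeps
        for _ in range(substeps):
            k1 = rhs(eps)
            k2 = rhs(eps + 0.5 * dt * k1)
            k3 = rhs(eps + 0.5 * dt * k2)
            k4 = rhs(eps + dt * k3)
            eps = eps + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = eps
    return out


def gen_rounding_track(cfg: SimulationConfig) -> tuple[list[ShapeTrack], np.ndarray | None]:
    """Generate rounding tracks of volume-conserving prolate spheroids.

    Each track integrates the anisotropy-decay law with the configured
    capillary velocity; initial anisotropy and size vary mildly between
    tracks (as real clusters do).  Axis noise is applied to the emitted
    ellipse semi-axes, and area/perimeter are recomputed from the noisy
    axes so all morphometrics stay mutually consistent.

    Returns the tracks and, when ``render_masks`` is set, a mask stack
    of the first track's projected ellipse.
    """
    p = cfg.params
    _require(isinstance(p, RoundingParams), "config scenario must be 'rounding'")
    _require(abs(p.eps0) < 1, "|eps0| must be < 1")

    k_um_s = p.gamma_over_eta_m_s * UM_PER_M
    t = np.arange(p.n_frames) * cfg.frame_interval_s
    init_rng = substream(cfg.seed, "rounding.init")
    noise_rng = substream(cfg.seed, "rounding.axes")

    tracks: list[ShapeTrack] = []
    first_axes = None
    for i in range(p.n_tracks):
        if p.n_tracks == 1:
            eps0, r0 = p.eps0, p.r0_um
        else:
            eps0 = p.eps0 * init_rng.uniform(0.8, 1.2)
            r0 = p.r0_um * init_rng.uniform(0.8, 1.2)
        q0 = (1.0 + eps0) / (1.0 - eps0)
        a0 = 3.0 * r0 / (2.0 + q0)
        volume = 4.0 / 3.0 * np.pi * a0 * (q0 * a0) ** 2
        eps = _integrate_eps(eps0, k_um_s, volume, t)
        a, c = spheroid_axes(eps, volume)
        if p.axis_noise_um > 0:
            a = a + noise_rng.normal(0.0, p.axis_noise_um, size=a.shape)
            c = c + noise_rng.normal(0.0, p.axis_noise_um, size=c.shape)
            # keep the major/minor convention under noise
            a, c = np.maximum(a, c), np.minimum(a, c)
        if i == 0:
            first_axes = (a.copy(), c.copy())
        tracks.append(ShapeTrack(
            object_id=i,
            t_s=t,
            area_um2=np.pi * a * c,
            perimeter_um=ellipse_perimeter(a, c),
            major_um=a,
            minor_um=c,
            cx_um=np.full_like(t, cfg.image_shape[1] / 2 * cfg.pixel_size_um),
            cy_um=np.full_like(t, cfg.image_shape[0] / 2 * cfg.pixel_size_um),
            meta={"gamma_over_eta_m_s": p.gamma_over_eta_m_s, "eps0": eps0,
                  "r0_um": r0, "seed": cfg.seed},
        ))

    stack = None
    if cfg.render_masks:
        h, w = cfg.image_shape
        px = cfg.pixel_size_um
        a_px = first_axes[0] / px
        c_px = first_axes[1] / px
        _require(2 * a_px.max() + 4 <= min(h, w),
                 "image too small to contain the cluster ellipse")
        stack = np.stack([
            _rasterize_ellipse((h, w), (w / 2.0, h / 2.0), (ai, ci))
            for ai, ci in zip(a_px, c_px)
        ])
    return tracks, stack


# ---------------------------------------------------------------------------
# fusion

def _render_doublet(shape, c1, c2, R1_px, R2_px, rho_px) -> np.ndarray:
    """Two discs with a tangent-capped neck bridge of half-width rho.

    The bridge is a rectangle of half-width rho along the center-center
    axis; the exact fillet is cosmetic — only the minimal cross-width
    (2 rho) is meaningful.
    """
    h, w = shape
    img = np.zeros((h, w), dtype=np.uint8)
    for c, R in ((c1, R1_px), (c2, R2_px)):
        rr, cc = draw_disk((c[1], c[0]), R, shape=(h, w))
        img[rr, cc] = 255
    if rho_px >= 0.5:
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        d = np.hypot(c2[0] - c1[0], c2[1] - c1[1])
        ux, uy = (c2[0] - c1[0]) / d, (c2[1] - c1[1]) / d
        s = (xx - c1[0]) * ux + (yy - c1[1]) * uy        # along-axis coord
        q = -(xx - c1[0]) * uy + (yy - c1[1]) * ux       # perpendicular coord
        img[(s >= 0) & (s <= d) & (np.abs(q) <= rho_px)] = 255
    return img


def gen_fusion_track(cfg: SimulationConfig) -> tuple[FusionSeries, np.ndarray | None]:
    """Generate a Frenkel neck-growth series (and optional doublet masks).

    ``rho(t) = sqrt((gamma/eta) t R0)`` with ``R0 = sqrt((A1+A2)/(2 pi))``
    from the two initial disc areas, capped at the plateau (default the
    smaller disc radius).  Discs are rendered externally tangent; a
    plateau larger than the smaller radius would require overlapping
    initial discs and is rejected.
    """
    p = cfg.params
    _require(isinstance(p, FusionParams), "config scenario must be 'fusion'")
    rng = substream(cfg.seed, "fusion.rho")

    A1 = np.pi * p.R1_um**2
    A2 = np.pi * p.R2_um**2
    R0 = float(np.sqrt((A1 + A2) / (2 * np.pi)))
    rho_max = p.rho_max_um if p.rho_max_um is not None else min(p.R1_um, p.R2_um)
    _require(rho_max <= min(p.R1_um, p.R2_um) + 1e-9,
             "plateau beyond the smaller disc radius implies overlapping initial discs")

    k_um_s = p.gamma_over_eta_m_s * UM_PER_M
    t = np.arange(p.n_frames) * cfg.frame_interval_s
    rho = np.minimum(np.sqrt(k_um_s * t * R0), rho_max)
    rho_clean = rho.copy()
    if p.rho_noise_um > 0:
        rho = np.clip(rho + rng.normal(0.0, p.rho_noise_um, size=rho.shape), 0.0, None)

    stack = None
    if cfg.render_masks:
        h, w = cfg.image_shape
        px = cfg.pixel_size_um
        R1_px, R2_px = p.R1_um / px, p.R2_um / px
        _require(2 * (R1_px + R2_px) + 8 <= w and 2 * max(R1_px, R2_px) + 8 <= h,
                 "image too small to contain the disc doublet")
        cy = h / 2.0
        mid = w / 2.0
        c1 = (mid - R1_px, cy)
        c2 = (mid + R2_px, cy)
        stack = np.stack([
            _render_doublet((h, w), c1, c2, R1_px, R2_px, r / px)
            for r in rho_clean
        ])

    series = FusionSeries(
        t_s=t, rho_um=rho, area1_um2=A1, area2_um2=A2,
        meta={"gamma_over_eta_m_s": p.gamma_over_eta_m_s, "rho_max_um": rho_max,
              "seed": cfg.seed},
    )
    return series, stack


# ---------------------------------------------------------------------------
# counts

def gen_count_series(cfg: SimulationConfig) -> CountSeries:
    """Daily cluster counts from the population ODE, with optional noise
    and a pre-onset zero-padded delay emulating low seeding densities."""
    p = cfg.params
    _require(isinstance(p, CountParams), "config scenario must be 'counts'")
    from smcluster.population import simulate_population

    ref = simulate_population(p.p1_per_day, p.p2_per_day, p.ts_day,
                              horizon_day=p.horizon_day, dt_day=1e-3)
    days = np.arange(0.0, p.horizon_day + 0.5)
    idx = np.searchsorted(ref.t_day, days)
    N = ref.N[np.minimum(idx, ref.N.size - 1)]

    if p.noise == "poisson":
        rng = substream(cfg.seed, "counts.noise")
        N = rng.poisson(np.clip(N, 0.0, None)).astype(float)
    elif p.noise == "gaussian":
        rng = substream(cfg.seed, "counts.noise")
        N = np.clip(N + rng.normal(0.0, p.gaussian_sd, size=N.shape), 0.0, None)

    if p.onset_delay_day > 0:
        pad_days = np.arange(0.0, p.onset_delay_day)
        days = np.concatenate([pad_days, days + p.onset_delay_day])
        N = np.concatenate([np.zeros_like(pad_days), N])

    return CountSeries(
        t_day=days, N=N, condition=p.condition, onset_day=p.onset_delay_day,
        meta={"p1_per_day": p.p1_per_day, "p2_per_day": p.p2_per_day,
              "ts_day": p.ts_day, "seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# orientation

def kappa_for_order(q_target: float) -> float:
    """Concentration kappa of the doubled-angle von Mises distribution
    whose expected order parameter I1(kappa)/I0(kappa) equals q_target."""
    if not 0.0 < q_target < 1.0:
        raise ValueError("target order parameter must be in (0, 1)")

    def f(k: float) -> float:
        # scaled Bessel ratio avoids overflow at large concentration
        return special.i1e(k) / special.i0e(k) - q_target

    return float(brentq(f, 1e-8, 1e4))


def gen_orientation_sample(cfg: SimulationConfig) -> np.ndarray:
    """Draw nematic fiber angles theta in [0, pi).

    The doubled angles ``2 theta`` follow a von Mises distribution with
    mean ``2 mu`` and concentration kappa, the standard nematic noise
    model: kappa = 0 is isotropic (order parameter ~ 0), large kappa is
    near-perfect alignment (order parameter -> 1).
    """
    p = cfg.params
    _require(isinstance(p, OrientationParams), "config scenario must be 'orientation'")
    rng = substream(cfg.seed, "orientation.angles")
    doubled = rng.vonmises(2.0 * p.mu_rad, p.kappa, size=p.n_angles)
    return np.mod(0.5 * doubled, np.pi)


def render_fiber_texture(angles: np.ndarray, shape: tuple[int, int],
                         rng: np.random.Generator,
                         n_fibers: int | None = None,
                         length_px: float = 24.0) -> np.ndarray:
    """Render oriented line segments on a dark background (16-bit).

    Each fiber takes its direction from a random entry of ``angles``;
    used as ground-truth input for structure-tensor angle extraction.
    """
    h, w = shape
    angles = np.asarray(angles, dtype=float).ravel()
    if n_fibers is None:
        n_fibers = max(200, angles.size)
    img = np.zeros((h, w), dtype=float)
    theta = rng.choice(angles, size=n_fibers)
    cx = rng.uniform(0, w, size=n_fibers)
    cy = rng.uniform(0, h, size=n_fibers)
    ts = np.linspace(-0.5, 0.5, int(4 * length_px))
    for th, x0, y0 in zip(theta, cx, cy):
        xs = x0 + ts * length_px * np.cos(th)
        ys = y0 - ts * length_px * np.sin(th)  # image y points down
        # bilinear splat keeps the line subpixel-smooth (a rounded
        # staircase would bias the structure-tensor angle)
        x0i = np.floor(xs).astype(int)
        y0i = np.floor(ys).astype(int)
        fx, fy = xs - x0i, ys - y0i
        for dy_, dx_, wgt in ((0, 0, (1 - fx) * (1 - fy)), (0, 1, fx * (1 - fy)),
                              (1, 0, (1 - fx) * fy), (1, 1, fx * fy)):
            xi, yi = x0i + dx_, y0i + dy_
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            np.add.at(img, (yi[ok], xi[ok]), wgt[ok])
    img = ndimage.gaussian_filter(img, 1.2)
    if img.max() > 0:
        img = img / img.max()
    return (img * 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# speckle pairs for PIV

DisplacementField = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def gen_speckle_pair(
    cfg: SimulationConfig,
    displacement_field: DisplacementField | tuple[float, float] | None = None,
    final_window: int = 32,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate two speckle frames related by a displacement field.

    Speckles are Gaussian spots at subpixel positions; the second frame
    re-renders every speckle advected by the field evaluated at its
    position, so the pair is exactly consistent with the ground truth at
    subpixel accuracy.  ``displacement_field`` is either a uniform
    ``(dx, dy)`` shift in pixels or a callable ``(x, y) -> (u, v)``;
    omitted, the config's ``shift_px`` applies.  Displacements exceeding
    a quarter of the final interrogation window are outside the reliable
    correlation range; a warning is recorded in the returned metadata.
    """
    p = cfg.params
    _require(isinstance(p, SpeckleParams), "config scenario must be 'speckle'")
    rng = substream(cfg.seed, "speckle.positions")
    h, w = cfg.image_shape
    x = rng.uniform(0, w, size=p.n_speckles)
    y = rng.uniform(0, h, size=p.n_speckles)
    amp = rng.uniform(0.5, 1.0, size=p.n_speckles)

    if displacement_field is None:
        displacement_field = tuple(p.shift_px)
    if callable(displacement_field):
        u, v = displacement_field(x, y)
        u = np.broadcast_to(np.asarray(u, dtype=float), x.shape)
        v = np.broadcast_to(np.asarray(v, dtype=float), y.shape)
    else:
        dx, dy = displacement_field
        u = np.full_like(x, float(dx))
        v = np.full_like(y, float(dy))

    meta: dict = {"max_displacement_px": float(np.hypot(u, v).max())}
    if meta["max_displacement_px"] > final_window / 4:
        msg = (f"max displacement {meta['max_displacement_px']:.2f} px exceeds "
               f"1/4 of the final window ({final_window} px); correlation may fail")
        meta["warning"] = msg
        warnings.warn(msg, stacklevel=2)

    frame1 = _render_speckles(x, y, amp, (h, w), p.speckle_sigma_px)
    frame2 = _render_speckles(x + u, y + v, amp, (h, w), p.speckle_sigma_px)
    return frame1, frame2, meta


def _render_speckles(x, y, amp, shape, sigma) -> np.ndarray:
    """Bilinear splat of point speckles followed by Gaussian blur."""
    h, w = shape
    img = np.zeros((h + 2, w + 2), dtype=float)
    xs, ys = x + 1.0, y + 1.0
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx, fy = xs - x0, ys - y0
    ok = (x0 >= 0) & (x0 < w + 1) & (y0 >= 0) & (y0 < h + 1)
    for dy_, dx_, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        np.add.at(img, (y0[ok] + dy_, x0[ok] + dx_), (amp * wgt)[ok])
    img = ndimage.gaussian_filter(img, sigma)[1:-1, 1:-1]
    if img.max() > 0:
        img = img / img.max()
    return (img * 65535).astype(np.uint16)
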