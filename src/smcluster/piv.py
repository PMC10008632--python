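"""Minimal multi-pass cross-correlation particle image velocimetry.

Windowed FFT cross-correlation between two frames with a three-point
Gaussian subpixel peak fit; later passes halve the interrogation window
and warp the second frame by the previous pass's (integer-rounded)
field, the standard coarse-to-fine scheme.  The default settings are a
three-pass computation ending at a 32 x 32 px window with 0.5 overlap.
Spurious vectors are invalidated when their magnitude exceeds the local
(3 x 3-neighbor) mean by three local standard deviations, and the
root-mean-square velocity is summarized over the valid vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["VelocityField", "piv_pair", "filter_and_summarize"]


@dataclass
class VelocityField:
    """PIV result on a regular grid.

    ``x_px``/``y_px`` are window-center coordinates; ``u``/``v`` are
    displacements in px/frame (x right, y down); ``valid`` flags
    vectors that survived correlation (and, after filtering, the
    outlier rule).  Velocities in um/h and the per-frame V_rms are
    populated by :func:`filter_and_summarize`.
    """

    x_px: np.ndarray
    y_px: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    u_um_h: np.ndarray | None = None
    v_um_h: np.ndarray | None = None
    v_rms_um_h: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def _subpixel(corr: np.ndarray) -> tuple[float, float, bool]:
    """Peak location with 3-point Gaussian interpolation; (dy, dx, ok)."""
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    if corr[iy, ix] <= 0 or not np.isfinite(corr[iy, ix]):
        return 0.0, 0.0, False
    if iy == 0 or iy == corr.shape[0] - 1 or ix == 0 or ix == corr.shape[1] - 1:
        return float(iy), float(ix), False

    def gauss3(cm, c0, cp):
        cm, c0, cp = max(cm, 1e-12), max(c0, 1e-12), max(cp, 1e-12)
        denom = 2 * np.log(cm) - 4 * np.log(c0) + 2 * np.log(cp)
        if denom >= 0:
            return 0.0
        return (np.log(cm) - np.log(cp)) / denom

    dy = gauss3(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    dx = gauss3(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return iy + dy, ix + dx, True


def _correlate(w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Zero-mean circular FFT cross-correlation (normalization-free:
    a common intensity rescaling leaves the peak location unchanged)."""
    a = w1 - w1.mean()
    b = w2 - w2.mean()
    f = np.fft.rfft2(a)
    g = np.fft.rfft2(b)
    corr = np.fft.irfft2(np.conj(f) * g, s=a.shape)
    return np.fft.fftshift(corr)


def piv_pair(
    frame1: np.ndarray,
    frame2: np.ndarray,
    passes: int = 3,
    final_window: int = 32,
    overlap: float = 0.5,
) -> VelocityField:
    """Estimate the displacement field from frame1 to frame2.

    The first pass uses a window of ``final_window * 2**(passes-1)``;
    each later pass halves the window and warps frame2 by the previous
    field (integer shifts per window), so the residual displacement
    stays well inside the correlation range.  Windows with a flat or
    border-saturated correlation are marked invalid.  Borders without a
    full window produce no vector.
    """
    f1 = np.asarray(frame1, dtype=float)
    f2 = np.asarray(frame2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("frames must have equal shapes")
    if f1.ndim != 2:
        raise ValueError("frames must be 2-D grayscale")

    prev = None  # (x, y, u, v) from previous pass
    for p in range(passes):
        win = final_window * 2 ** (passes - 1 - p)
        step = max(int(win * (1.0 - overlap)), 1)
        field_now = _single_pass(f1, f2, win, step, prev)
        prev = field_now
    return prev


def _single_pass(f1, f2, win, step, prev: VelocityField | None) -> VelocityField:
    h, w = f1.shape
    ys = np.arange(0, h - win + 1, step)
    xs = np.arange(0, w - win + 1, step)
    cx = xs + win / 2.0 - 0.5
    cy = ys + win / 2.0 - 0.5

    if prev is not None:
        u0 = _interp_to(prev, cx, cy, "u")
        v0 = _interp_to(prev, cx, cy, "v")
    else:
        u0 = np.zeros((cy.size, cx.size))
        v0 = np.zeros((cy.size, cx.size))
    u0i = np.round(u0).astype(int)
    v0i = np.round(v0).astype(int)

    U = np.zeros((cy.size, cx.size))
    V = np.zeros((cy.size, cx.size))
    ok = np.zeros((cy.size, cx.size), dtype=bool)
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            du, dv = u0i[j, i], v0i[j, i]
            y2, x2 = y0 + dv, x0 + du
            if y2 < 0 or x2 < 0 or y2 + win > h or x2 + win > w:
                y2 = min(max(y2, 0), h - win)
                x2 = min(max(x2, 0), w - win)
                du, dv = x2 - x0, y2 - y0
            w1 = f1[y0:y0 + win, x0:x0 + win]
            w2 = f2[y2:y2 + win, x2:x2 + win]
            if w1.std() == 0 or w2.std() == 0:
                continue
            corr = _correlate(w1, w2)
            py, px, good = _subpixel(corr)
            if not good:
                continue
            U[j, i] = px - win // 2 + du
            V[j, i] = py - win // 2 + dv
            ok[j, i] = True

    X, Y = np.meshgrid(cx, cy)
    return VelocityField(x_px=X, y_px=Y, u=U, v=V, valid=ok,
                         meta={"window": win, "step": step})


def _interp_to(prev: VelocityField, cx, cy, comp: str) -> np.ndarray:
    """Nearest-valid bilinear transfer of the previous pass's field."""
    arr = getattr(prev, comp).copy()
    arr[~prev.valid] = 0.0
    px = prev.x_px[0, :]
    py = prev.y_px[:, 0]
    out = np.empty((cy.size, cx.size))
    ix = np.interp(cx, px, np.arange(px.size))
    iy = np.interp(cy, py, np.arange(py.size))
    IX, IY = np.meshgrid(ix, iy)
    out = ndimage.map_coordinates(arr, [IY, IX], order=1, mode="nearest")
    return out


def filter_and_summarize(
    fld: VelocityField,
    dt_s: float,
    pixel_size_um: float = 0.65,
) -> VelocityField:
    """Apply the local-outlier rule and compute velocities and V_rms.

    A vector is invalidated when its magnitude exceeds the mean of its
    eight 3 x 3 neighbors (the candidate itself and invalid vectors
    excluded) by more than three times the standard deviation of the
    valid-vector magnitudes.  The SD is field-wide rather than
    per-neighborhood: with clustered spurious vectors a purely local SD
    is inflated by the very outliers under test and the rule stops
    rejecting them.  The filter iterates until no vector is removed,
    since adjacent outliers shield each other on the first sweep.  Velocities
    convert px/frame to um/h via the pixel size and frame interval;
    V_rms = sqrt(<|V|^2>) over the valid vectors.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    mag = fld.magnitude
    valid = fld.valid.copy()

    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0  # the candidate itself must not inflate its own threshold
    for _ in range(10):
        m = np.where(valid, mag, np.nan)
        cnt = ndimage.convolve(np.isfinite(m).astype(float), kernel, mode="constant")
        s1 = ndimage.convolve(np.nan_to_num(m), kernel, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / cnt
        sd = float(np.std(mag[valid]))
        bad = valid & (cnt > 1) & (mag > mean + 3.0 * sd)
        if not bad.any():
            break
        valid = valid & ~bad
    if not valid.any():
        raise ValueError("no valid vectors remain after filtering")

    scale = pixel_size_um / dt_s * 3600.0  # px/frame -> um/h
    u_um_h = fld.u * scale
    v_um_h = fld.v * scale
    vm = np.hypot(u_um_h, v_um_h)[valid]
    return VelocityField(
        x_px=fld.x_px, y_px=fld.y_px, u=fld.u, v=fld.v, valid=valid,
        u_um_h=u_um_h, v_um_h=v_um_h,
        v_rms_um_h=float(np.sqrt(np.mean(vm**2))),
        meta={**fld.meta, "removed_fraction": float(bad.sum() / max(fld.valid.sum(), 1)),
              "dt_s": dt_s, "pixel_size_um": pixel_size_um},
    )
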