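"""Multi-pass PIV: displacement recovery, outlier filtering, units."""

import numpy as np
import pytest

from smcluster.config import config_from_dict
from smcluster.piv import VelocityField, filter_and_summarize, piv_pair
from smcluster.synth import gen_speckle_pair


def speckle_pair(seed, shift, shape=(256, 256)):
    cfg = config_from_dict({"seed": seed, "scenario": "speckle",
                            "image_shape": list(shape), "shift_px": list(shift)})
    f1, f2, _ = gen_speckle_pair(cfg)
    return f1, f2


class TestPivPair:
    def test_identical_frames_give_zero_field(self):
        f1, _ = speckle_pair(0, (0.0, 0.0))
        fld = piv_pair(f1, f1)
        assert fld.valid.any()
        assert np.max(np.abs(fld.u[fld.valid])) < 1e-6
        assert np.max(np.abs(fld.v[fld.valid])) < 1e-6

    def test_uniform_subpixel_shift_recovered(self):
        f1, f2 = speckle_pair(1, (3.2, -1.7))
        fld = piv_pair(f1, f2)
        du = np.median(fld.u[fld.valid]) - 3.2
        dv = np.median(fld.v[fld.valid]) + 1.7
        assert np.hypot(du, dv) <= 0.1

    def test_intensity_rescaling_invariance(self):
        f1, f2 = speckle_pair(2, (2.0, 1.0))
        a = piv_pair(f1, f2)
        b = piv_pair(2.0 * f1.astype(float), 2.0 * f2.astype(float))
        assert np.allclose(a.u[a.valid & b.valid], b.u[a.valid & b.valid], atol=1e-9)

    def test_translation_equivariance(self):
        """Shifting both frames by the same whole-pixel offset leaves
        the recovered displacement unchanged."""
        f1, f2 = speckle_pair(3, (3.0, 0.0))
        s1 = np.roll(f1, (8, 8), axis=(0, 1))
        s2 = np.roll(f2, (8, 8), axis=(0, 1))
        a, b = piv_pair(f1, f2), piv_pair(s1, s2)
        both = a.valid & b.valid
        assert np.median(np.abs(a.u[both] - b.u[both])) < 0.05

    def test_rigid_rotation_has_constant_curl_zero_divergence(self):
        """A small rigid rotation about the center is recovered with
        near-zero divergence and uniform curl 2*omega."""
        omega = np.deg2rad(0.5)
        cx = cy = 128.0

        def field(x, y):
            return -omega * (y - cy), omega * (x - cx)

        cfg = config_from_dict({"seed": 4, "scenario": "speckle",
                                "image_shape": [256, 256], "n_speckles": 4000})
        f1, f2, _ = gen_speckle_pair(cfg, field)
        fld = piv_pair(f1, f2)
        step = 16.0
        dudx = np.gradient(fld.u, step, axis=1)
        dudy = np.gradient(fld.u, step, axis=0)
        dvdx = np.gradient(fld.v, step, axis=1)
        dvdy = np.gradient(fld.v, step, axis=0)
        inner = np.zeros_like(fld.u, dtype=bool)
        inner[2:-2, 2:-2] = True
        inner &= fld.valid
        div = (dudx + dvdy)[inner]
        curl = (dvdx - dudy)[inner]
        assert np.abs(np.median(div)) < 1e-3
        assert np.median(curl) == pytest.approx(2 * omega, rel=0.15)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            piv_pair(np.zeros((64, 64)), np.zeros((64, 32)))


class TestFilterAndSummarize:
    def _clean_field(self, v0=(2.0, 1.0), n=9):
        x, y = np.meshgrid(np.arange(n) * 16.0, np.arange(n) * 16.0)
        return VelocityField(x_px=x, y_px=y,
                             u=np.full((n, n), v0[0]), v=np.full((n, n), v0[1]),
                             valid=np.ones((n, n), dtype=bool))

    def test_constant_field_vrms_exact_nothing_removed(self):
        fld = filter_and_summarize(self._clean_field((3.0, 4.0)), dt_s=3600.0,
                                   pixel_size_um=1.0)
        assert fld.meta["removed_fraction"] == 0.0
        assert fld.v_rms_um_h == pytest.approx(5.0, rel=1e-12)

    def test_injected_outliers_removed_clean_kept(self, rng):
        n = 20
        x, y = np.meshgrid(np.arange(n) * 16.0, np.arange(n) * 16.0)
        u = rng.normal(2.0, 0.05, (n, n))
        v = rng.normal(0.0, 0.05, (n, n))
        flat = rng.choice(n * n, size=n * n // 20, replace=False)  # 5 %
        bad = np.zeros(n * n, dtype=bool)
        bad[flat] = True
        bad = bad.reshape(n, n)
        u[bad] *= 10.0
        fld = VelocityField(x_px=x, y_px=y, u=u, v=v,
                            valid=np.ones((n, n), dtype=bool))
        out = filter_and_summarize(fld, dt_s=300.0)
        assert (~out.valid & bad).sum() >= 0.9 * bad.sum()
        assert (~out.valid & ~bad).sum() < 0.01 * (~bad).sum() + 1

    def test_clean_gaussian_false_positive_rate_low(self, rng):
        n = 30
        x, y = np.meshgrid(np.arange(n) * 16.0, np.arange(n) * 16.0)
        fld = VelocityField(x_px=x, y_px=y,
                            u=rng.normal(1.0, 0.2, (n, n)),
                            v=rng.normal(0.0, 0.2, (n, n)),
                            valid=np.ones((n, n), dtype=bool))
        out = filter_and_summarize(fld, dt_s=300.0)
        assert out.meta["removed_fraction"] < 0.02

    def test_unit_conversion_to_um_per_hour(self):
        """1 px/frame at 0.65 um/px and 5 min/frame is 7.8 um/h."""
        fld = filter_and_summarize(self._clean_field((1.0, 0.0)), dt_s=300.0,
                                   pixel_size_um=0.65)
        assert fld.v_rms_um_h == pytest.approx(7.8, rel=1e-12)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            filter_and_summarize(self._clean_field(), dt_s=0.0)
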