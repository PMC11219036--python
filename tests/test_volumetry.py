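"""Calibration, local background, excluded-volume sums, and traces."""

import numpy as np
import pytest

from fxmvol import volumetry as vol
from fxmvol.simulate import (
    CellRender,
    SimConfig,
    _height_patch,
    dome_radius_for_volume,
    make_pillar_mask,
    render_frame,
)


class TestAlphaCalibration:
    def test_direct_arithmetic(self):
        frame = np.zeros((50, 50))
        pil = np.zeros((50, 50), bool)
        bg = np.zeros((50, 50), bool)
        pil[:5] = True
        bg[-5:] = True
        frame[bg] = 1.0
        cal = vol.alpha_calibration(frame, pil, bg, h_chamber=10.0)
        assert cal.alpha == pytest.approx(0.1)

    def test_degenerate_calibration_rejected(self):
        frame = np.ones((20, 20))
        pil = np.zeros((20, 20), bool)
        bg = np.zeros((20, 20), bool)
        pil[:5] = True
        bg[-5:] = True
        with pytest.raises(ValueError, match="inverted"):
            vol.alpha_calibration(frame, pil, bg, h_chamber=5.0)

    def test_recovers_inverse_chamber_height_on_corrected_frame(self, small_ds):
        # after flatfield correction the background is ~1 and pillars ~0, so
        # alpha should equal 1/h_chamber
        from skimage import morphology
        from fxmvol import flatfield as ff

        cfg = small_ds.config
        raw = np.asarray(small_ds.fxm_stack[0], float)
        fg = np.zeros(cfg.shape, bool)
        for cid in range(cfg.n_cells):
            fg |= small_ds.truth.footprint_mask(cid, 0, cfg.shape)
        excl = morphology.dilation(
            fg | small_ds.truth.pillar_mask, morphology.disk(3)
        )
        pts = ff.sample_points(raw.shape, excl)
        field = ff.fit_interpolant(pts, ff.sample_values(raw, pts, excl))
        corr = ff.correct(raw, small_ds.truth.darkfield, field)
        cal = vol.alpha_calibration(
            corr, small_ds.truth.pillar_mask, ~excl, cfg.chamber_height
        )
        assert cal.alpha == pytest.approx(1.0 / cfg.chamber_height, rel=0.01)


class TestLocalBackground:
    def _scene(self):
        labels = np.zeros((80, 80), np.int32)
        labels[35:46, 35:46] = 1
        frame = np.ones((80, 80))
        return frame, labels

    def test_uniform_background(self):
        frame, labels = self._scene()
        assert vol.local_background(frame, labels, 1) == pytest.approx(1.0)

    def test_neighbor_pixels_excluded_from_annulus(self):
        frame, labels = self._scene()
        labels[35:46, 48:58] = 2  # neighbor inside the 2-10 px shell
        frame[labels == 2] = 5.0
        assert vol.local_background(frame, labels, 1) == pytest.approx(1.0)

    def test_cell_at_border_flagged(self):
        labels = np.zeros((60, 60), np.int32)
        labels[0:10, 20:30] = 1
        with pytest.raises(vol.EdgeTouching):
            vol.local_background(np.ones((60, 60)), labels, 1)

    def test_occluded_locality_rejected(self):
        labels = np.zeros((40, 40), np.int32)
        labels[15:25, 15:25] = 1
        labels[(labels == 0)] = 2  # everything else is another cell
        labels[15:25, 15:25] = 1
        with pytest.raises(vol.LocalityOccluded):
            vol.local_background(np.ones((40, 40)), labels, 1)


class TestCellVolume:
    def test_zero_when_intensity_equals_local_background(self):
        frame = np.full((30, 30), 0.8)
        fp = np.zeros((30, 30), bool)
        fp[10:20, 10:20] = True
        assert vol.cell_volume(frame, fp, imax=0.8, alpha=0.1, pixel_size=0.65) == 0.0

    def test_full_height_plug_volume_exact(self):
        # 100 px plug at full chamber height: V = A*h*px^2 = 100*10*0.4225
        frame = np.full((30, 30), 1.0)
        fp = np.zeros((30, 30), bool)
        fp[10:20, 10:20] = True
        frame[fp] = 0.0
        v = vol.cell_volume(frame, fp, imax=1.0, alpha=0.1, pixel_size=0.65)
        assert v == pytest.approx(100 * 10 * 0.65**2, rel=1e-12)

    def test_empty_footprint_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vol.cell_volume(np.ones((10, 10)), np.zeros((10, 10), bool), 1.0, 0.1, 0.65)

    def test_dome_volume_recovered_within_two_percent(self):
        cfg = SimConfig(fov_rows=200, fov_cols=200, n_frames=3, stim_frame=1,
                        n_cells=0, noise_sd=0.0, flatfield_amplitude=0.0)
        pil = make_pillar_mask(cfg)
        R = dome_radius_for_volume(320.0, cfg.dome_aspect, cfg.chamber_height)
        r0, c0, patch = _height_patch(
            65.0, 65.0, R, cfg.dome_aspect * R, cfg.chamber_height, cfg.pixel_size, cfg.shape
        )
        cell = CellRender(r0, c0, patch, (100.0, 100.0))
        fxm, _, _ = render_frame([cell], cfg, np.ones(cfg.shape), pil, None)
        truth = patch.sum() * cfg.pixel_size**2
        corr = (fxm - cfg.darkfield_level) / (cfg.alpha_true * cfg.chamber_height)
        labels = np.zeros(cfg.shape, np.int32)
        labels[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]][patch > 0] = 1
        imax = vol.local_background(corr, labels, 1, pillar_mask=pil)
        alpha = (imax - 0.0) / cfg.chamber_height
        v = vol.cell_volume(corr, labels == 1, imax, alpha, cfg.pixel_size)
        assert v == pytest.approx(truth, rel=0.02)

    def test_volume_insensitive_to_footprint_dilation(self):
        # pixels beyond the cell carry Imax - I ~ 0, so dilating the footprint
        # by 1 vs 2 px changes the noise-free volume by < 0.1%
        from skimage import morphology

        cfg = SimConfig(fov_rows=200, fov_cols=200, n_frames=3, stim_frame=1,
                        n_cells=0, noise_sd=0.0, flatfield_amplitude=0.0)
        pil = make_pillar_mask(cfg)
        R = dome_radius_for_volume(300.0, cfg.dome_aspect, cfg.chamber_height)
        r0, c0, patch = _height_patch(
            65.0, 65.0, R, cfg.dome_aspect * R, cfg.chamber_height, cfg.pixel_size, cfg.shape
        )
        from fxmvol.simulate import make_darkfield

        fxm, _, _ = render_frame(
            [CellRender(r0, c0, patch, (100.0, 100.0))], cfg, np.ones(cfg.shape), pil, None
        )
        corr = (fxm - make_darkfield(cfg)) / (cfg.alpha_true * cfg.chamber_height)
        fp = np.zeros(cfg.shape, bool)
        fp[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]] = patch > 0
        vols = []
        for rad in (1, 2):
            m = morphology.dilation(fp, morphology.disk(rad))
            vols.append(vol.cell_volume(corr, m, 1.0, 1 / cfg.chamber_height, cfg.pixel_size))
        assert abs(vols[1] - vols[0]) / vols[0] < 1e-3

    def test_unit_consistency_across_pixel_sizes(self):
        # the same dome rasterized at half resolution / double pixel size
        # yields the same volume within 3%
        vols = []
        for px, fov in ((0.65, 200), (1.30, 100)):
            cfg = SimConfig(fov_rows=fov, fov_cols=fov, pixel_size=px, n_frames=3,
                            stim_frame=1, n_cells=0, noise_sd=0.0, flatfield_amplitude=0.0)
            R = dome_radius_for_volume(310.0, cfg.dome_aspect, cfg.chamber_height)
            r0, c0, patch = _height_patch(
                fov // 2 * px, fov // 2 * px, R, cfg.dome_aspect * R,
                cfg.chamber_height, px, cfg.shape,
            )
            pil = np.zeros(cfg.shape, bool)
            fxm, _, _ = render_frame(
                [CellRender(r0, c0, patch, (fov / 2, fov / 2))], cfg,
                np.ones(cfg.shape), pil, None,
            )
            corr = (fxm - cfg.darkfield_level) / (cfg.alpha_true * cfg.chamber_height)
            fp = np.zeros(cfg.shape, bool)
            fp[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]] = patch > 0
            vols.append(vol.cell_volume(corr, fp, 1.0, 1 / cfg.chamber_height, px))
        assert abs(vols[1] - vols[0]) / vols[0] < 0.03


class TestVolumeTrace:
    def test_constant_series(self):
        t = np.arange(0, 300, 10.0)
        out = vol.build_volume_trace(np.full(len(t), 400.0), t, stim_time=200.0)
        assert np.allclose(out["volume_norm"], 1.0)
        assert np.allclose(out["volume_rollmed_um3"], 400.0)

    def test_normalization_arithmetic(self):
        t = np.array([0.0, 30.0, 60.0, 200.0])
        v = np.array([500.0, 510.0, 505.0, 575.0])
        out = vol.build_volume_trace(v, t, stim_time=90.0)
        assert out["volume_norm"].iloc[-1] == pytest.approx(575.0 / 505.0)

    def test_missing_baseline_rejected(self):
        t = np.arange(0, 100, 10.0)
        with pytest.raises(ValueError, match="baseline undefined"):
            vol.build_volume_trace(np.ones(len(t)), t, stim_time=-50.0)
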