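"""Generator correctness: walks, volume program, rendering, bookkeeping."""

import numpy as np
import pytest

import fxmvol as fx
from fxmvol.simulate import (
    CellRender,
    SimConfig,
    VolumeProgram,
    _height_patch,
    dome_radius_for_volume,
    make_pillar_mask,
    render_frame,
    simulate_coulter_run,
    simulate_experiment,
    simulate_gradient_counts,
    simulate_track,
    volume_schedule,
)
from fxmvol.bulk import fit_density_calibration, weighted_median_density

ANCHORS = [(1.3419, 1.045), (1.3467, 1.074)]


class TestTrack:
    def test_zero_speed_is_fixed_point(self):
        pos = simulate_track(50, 0.0, 0.5, 500.0, seed=3, start=(100.0, 100.0))
        assert np.allclose(pos, pos[0])

    def test_straight_walk_has_unit_steps(self):
        # 6 um/min sampled every 10 s -> 1 um per step, collinear
        pos = simulate_track(20, 6.0, 0.0, 5000.0, seed=1, dt=10.0, start=(2500.0, 2500.0))
        steps = np.diff(pos, axis=0)
        assert np.allclose(np.hypot(steps[:, 0], steps[:, 1]), 1.0)
        cross = steps[:-1, 0] * steps[1:, 1] - steps[:-1, 1] * steps[1:, 0]
        assert np.allclose(cross, 0.0, atol=1e-9)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_track(10, -1.0, 0.1, 100.0, seed=0)

    def test_reflection_keeps_positions_inside(self):
        pos = simulate_track(500, 30.0, 1.0, 40.0, seed=7, dt=10.0)
        assert pos.min() >= 0.0 and pos.max() <= 40.0


class TestVolumeSchedule:
    def test_baseline_is_one_before_stimulation(self):
        prog = VolumeProgram(fluct_amplitude=0.0)
        assert volume_schedule(-30.0, prog) == 1.0

    def test_dip_depth_matches_program(self):
        # dip_fraction 0.06 -> minimum factor 0.94, inside the 5-8% loss band
        prog = VolumeProgram(fluct_amplitude=0.0)
        t = np.linspace(0, prog.dip_duration, 601)
        m = volume_schedule(t, prog).min()
        assert 0.92 <= m <= 0.95
        assert m == pytest.approx(1 - prog.dip_fraction, abs=1e-9)

    def test_late_time_plateau_reaches_swell(self):
        prog = VolumeProgram(fluct_amplitude=0.0)
        assert volume_schedule(50 * prog.swell_tau, prog) == pytest.approx(1.15, rel=0.01)

    def test_fluctuation_rides_on_baseline(self):
        prog = VolumeProgram(fluct_amplitude=0.02, fluct_period=60.0)
        t = np.linspace(-300, -1, 1000)
        f = volume_schedule(t, prog)
        assert f.max() <= 1.02 + 1e-9 and f.min() >= 0.98 - 1e-9


def _dome_cell(cfg, volume, center_rc):
    R = dome_radius_for_volume(volume, cfg.dome_aspect, cfg.chamber_height)
    r, c = center_rc
    r0, c0, patch = _height_patch(
        c * cfg.pixel_size, r * cfg.pixel_size, R, cfg.dome_aspect * R,
        cfg.chamber_height, cfg.pixel_size, cfg.shape,
    )
    return CellRender(r0, c0, patch, (float(r), float(c)))


class TestRender:
    cfg = SimConfig(fov_rows=200, fov_cols=200, n_frames=5, stim_frame=1,
                    n_cells=0, noise_sd=0.0, flatfield_amplitude=0.0)

    def test_empty_chamber_is_background_everywhere(self):
        pil = make_pillar_mask(self.cfg)
        ff_field = np.ones(self.cfg.shape)
        fxm, _, _ = render_frame([], self.cfg, ff_field, pil, rng=None)
        from fxmvol.simulate import make_darkfield

        expect = make_darkfield(self.cfg) + self.cfg.alpha_true * self.cfg.chamber_height
        assert np.allclose(fxm[~pil], expect[~pil])
        assert np.allclose(fxm[pil], make_darkfield(self.cfg)[pil])

    def test_full_height_plug_gives_pillar_signal(self):
        pil = make_pillar_mask(self.cfg)
        plug = np.full((10, 10), self.cfg.chamber_height)
        cell = CellRender(95, 95, plug, (100.0, 100.0))
        fxm, _, _ = render_frame([cell], self.cfg, np.ones(self.cfg.shape), pil, None)
        from fxmvol.simulate import make_darkfield

        inside = fxm[95:105, 95:105]
        assert np.allclose(inside, make_darkfield(self.cfg)[95:105, 95:105])

    def test_pixelwise_inversion_recovers_height_map(self):
        pil = make_pillar_mask(self.cfg)
        cell = _dome_cell(self.cfg, 300.0, (100, 100))
        fxm, _, _ = render_frame([cell], self.cfg, np.ones(self.cfg.shape), pil, None)
        empty, _, _ = render_frame([], self.cfg, np.ones(self.cfg.shape), pil, None)
        h = (empty - fxm) / self.cfg.alpha_true
        sl = np.s_[cell.r0 : cell.r0 + cell.height.shape[0],
                   cell.c0 : cell.c0 + cell.height.shape[1]]
        recovered = h[sl][cell.height > 0].sum() * self.cfg.pixel_size**2
        truth = cell.height.sum() * self.cfg.pixel_size**2
        assert abs(recovered - truth) / truth < 1e-10

    def test_overheight_cell_rejected(self):
        pil = make_pillar_mask(self.cfg)
        bad = CellRender(95, 95, np.full((5, 5), self.cfg.chamber_height + 1), (97.0, 97.0))
        with pytest.raises(ValueError, match="chamber"):
            render_frame([bad], self.cfg, np.ones(self.cfg.shape), pil, None)


class TestExperiment:
    def test_determinism_bit_identical(self):
        cfg = SimConfig(fov_rows=250, fov_cols=250, n_frames=6, n_cells=4, stim_frame=2)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        assert a.fxm_stack.tobytes() == b.fxm_stack.tobytes()
        assert a.nuclear_stack.tobytes() == b.nuclear_stack.tobytes()
        assert a.truth.table.equals(b.truth.table)

    def test_no_cells_gives_background_only(self):
        cfg = SimConfig(fov_rows=200, fov_cols=200, n_frames=4, n_cells=0,
                        stim_frame=1, noise_sd=0.0)
        ds = simulate_experiment(cfg)
        assert len(ds.truth.table) == 0
        assert np.ptp(ds.fxm_stack[0][~ds.truth.pillar_mask]) < \
            cfg.alpha_true * cfg.chamber_height * 2 * cfg.flatfield_amplitude + 1.0

    def test_volume_bookkeeping_via_image_summation(self):
        # independent oracle: total excluded volume from the noise-free image
        # deficit equals the summed per-cell ground truth
        cfg = SimConfig(fov_rows=300, fov_cols=300, n_frames=6, n_cells=5,
                        stim_frame=2, noise_sd=0.0, flatfield_amplitude=0.0)
        ds = simulate_experiment(cfg)
        empty = simulate_experiment(
            SimConfig(fov_rows=300, fov_cols=300, n_frames=6, n_cells=0,
                      stim_frame=2, noise_sd=0.0, flatfield_amplitude=0.0,
                      seed=cfg.seed)
        )
        for f in range(cfg.n_frames):
            deficit = np.asarray(empty.fxm_stack[f], float) - np.asarray(ds.fxm_stack[f], float)
            total = deficit[~ds.truth.pillar_mask].sum() / cfg.alpha_true * cfg.pixel_size**2
            truth = ds.truth.table.query("frame == @f")["true_volume_um3"].sum()
            assert total == pytest.approx(truth, rel=1e-4)

    def test_swell_monotonicity(self):
        base = dict(fov_rows=300, fov_cols=300, n_frames=40, n_cells=4, stim_frame=5,
                    noise_sd=0.0)
        lo = simulate_experiment(SimConfig(
            **base, volume_program=VolumeProgram(swell_fraction=0.10, fluct_amplitude=0)))
        hi = simulate_experiment(SimConfig(
            **base, volume_program=VolumeProgram(swell_fraction=0.25, fluct_amplitude=0)))
        last = max(lo.truth.table["frame"])
        vlo = lo.truth.table.query("frame == @last").set_index("cell_id")["true_volume_um3"]
        vhi = hi.truth.table.query("frame == @last").set_index("cell_id")["true_volume_um3"]
        assert (vhi > vlo).all()

    def test_footprints_avoid_pillars(self, small_ds):
        pil = small_ds.truth.pillar_mask
        for (cid, f), (r0, c0, patch) in list(small_ds.truth.footprints.items())[::37]:
            window = pil[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]]
            assert not (window & patch).any()


class TestBulkGenerators:
    def test_tight_distribution_lands_in_one_fraction(self):
        cal = fit_density_calibration(ANCHORS)
        edges = np.arange(1.040, 1.0701, 0.0025)
        # medians placed mid-fraction so the tight distributions cannot
        # straddle an edge
        df = simulate_gradient_counts(1.0563, 1.0513, 1e-6, 1000, edges, cal, seed=0)
        for col, med in (("count_pop1", 1.0563), ("count_pop2", 1.0513)):
            assert (df[col] > 0).sum() == 1
            k = int(df[col].idxmax())
            assert abs(df.loc[k, "density"] - med) <= 0.00125

    def test_identical_medians_give_zero_shift(self):
        cal = fit_density_calibration(ANCHORS)
        edges = np.arange(1.040, 1.0701, 0.0025)
        df = simulate_gradient_counts(1.055, 1.055, 0.003, 5000, edges, cal, seed=1)
        m1 = weighted_median_density(df["density"], df["count_pop1"])
        m2 = weighted_median_density(df["density"], df["count_pop2"])
        assert m2 - m1 == pytest.approx(0.0, abs=2e-4)

    def test_coulter_flat_kinetics_has_constant_medians(self):
        run = simulate_coulter_run(swell_fraction=0.0, n_timepoints=8, seed=2)
        med = run.groupby("time_s")["volume_fl"].median()
        assert np.ptp(med / med.iloc[0]) < 0.02

    def test_coulter_single_draw_series(self):
        run = simulate_coulter_run(n_timepoints=5, n_per_timepoint=1, seed=3)
        assert len(run) == 5
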