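"""Phantom generator: bolus model, geometry, dynamics, reproducibility."""

import dataclasses

import numpy as np
import pytest

from perfusionkit.kinetics import signal_to_conc
from perfusionkit.myo_segment import qc_closed_loop
from perfusionkit.phantom import (
    PhantomConfig,
    desk_phantom_config,
    gamma_variate_aif,
    generate_cohort,
    generate_series,
    render_geometry,
)


class TestGammaVariate:
    def test_zero_before_arrival(self):
        t = np.linspace(0, 30, 200)
        c = gamma_variate_aif(10.0, 3.0, 2.0, 5.0, t)
        assert np.all(c[t <= 10.0] == 0.0)
        assert np.all(c >= 0) and np.all(np.isfinite(c))

    def test_peak_at_t0_plus_alpha_beta(self):
        t = np.linspace(0, 60, 60001)
        c = gamma_variate_aif(10.0, 3.0, 2.5, 4.0, t)
        t_peak = t[np.argmax(c)]
        assert t_peak == pytest.approx(10.0 + 3.0 * 2.5, abs=2e-3)
        assert c.max() == pytest.approx(4.0, rel=1e-6)  # scale is the peak value

    def test_linearity_in_scale(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 50, 300)
        for _ in range(10):
            t0, a, b, s = rng.uniform(2, 15), rng.uniform(1, 5), rng.uniform(1, 5), rng.uniform(0.5, 8)
            assert np.allclose(
                gamma_variate_aif(t0, a, b, 2 * s, t), 2 * gamma_variate_aif(t0, a, b, s, t), atol=1e-12
            )

    @pytest.mark.parametrize("bad", [dict(alpha=0), dict(beta=-1), dict(scale=0)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(t0=5.0, alpha=2.0, beta=2.0, scale=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            gamma_variate_aif(kw["t0"], kw["alpha"], kw["beta"], kw["scale"], np.arange(10.0))


class TestRenderGeometry:
    def test_annulus_area_close_to_analytic(self):
        cfg = PhantomConfig(
            image_size=128,
            lv_center_range=(0.0, 0.0),
            lv_pool_radius_range=(20.0, 20.0),
            myo_thickness_range=(10.0, 10.0),
        )
        geom = render_geometry(cfg, np.random.default_rng(0), "basal")
        area = geom["myo"].sum()
        analytic = np.pi * (30.0**2 - 20.0**2)
        assert abs(area - analytic) / analytic < 0.05

    def test_insertion_points_on_analytic_circle(self):
        cfg = PhantomConfig(
            image_size=256,
            lv_center_range=(0.0, 0.0),
            lv_pool_radius_range=(20.0, 20.0),
            myo_thickness_range=(10.0, 10.0),
            insertion_angle_anterior=240.0,
            insertion_angle_inferior=120.0,
            insertion_angle_jitter=0.0,
        )
        geom = render_geometry(cfg, np.random.default_rng(1), "basal")
        center, r = np.array(geom["center"]), 30.0 - 0.5
        for pt, ang in zip(geom["insertion_points"], (240.0, 120.0)):
            expected = center + r * np.array([np.sin(np.radians(ang)), np.cos(np.radians(ang))])
            assert np.hypot(*(pt - expected)) <= 1.0

    def test_masks_disjoint_and_closed_loop(self, desk_config):
        rng = np.random.default_rng(2)
        for _ in range(20):
            for level in ("basal", "mid", "apical"):
                geom = render_geometry(desk_config, rng, level)
                assert not (geom["myo"] & geom["lv_pool"]).any()
                assert not (geom["myo"] & geom["rv"]).any()
                assert not (geom["lv_pool"] & geom["rv"]).any()
                assert qc_closed_loop(geom["myo"])
                assert geom["rv"].any()

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(image_size=64, lv_pool_radius_range=(20.0, 24.0), myo_thickness_range=(9.0, 13.0))


class TestGenerateSeries:
    def test_deterministic_for_fixed_seed(self, desk_config):
        a = generate_series(desk_config, seed=5)
        b = generate_series(desk_config, seed=5)
        for (sa, ta), (sb, tb) in zip(a, b):
            assert np.array_equal(sa.frames, sb.frames)
            assert ta.peak_frame == tb.peak_frame
            assert np.array_equal(ta.insertion_points, tb.insertion_points)

    def test_noiseless_peak_is_argmax_of_pool_signal(self, noiseless_subject):
        for series, truth in noiseless_subject:
            pool_mean = series.frames[:, truth.lv_pool_mask].mean(axis=1)
            assert truth.peak_frame == int(np.argmax(pool_mean))

    def test_first_pass_ordering(self, noiseless_subject):
        for series, truth in noiseless_subject:
            rv = series.frames[:, truth.rv_mask].mean(axis=1)
            lv = series.frames[:, truth.lv_pool_mask].mean(axis=1)
            myo = series.frames[:, truth.myo_mask].mean(axis=1)
            assert int(np.argmax(rv)) < int(np.argmax(lv)) < int(np.argmax(myo))

    def test_signal_concentration_round_trip(self, noiseless_subject):
        series, truth = noiseless_subject[0]
        pool_sig = series.frames[:, truth.lv_pool_mask].mean(axis=1)
        conc = signal_to_conc(pool_sig)
        assert np.max(np.abs(conc - truth.aif_true.values)) <= 1e-6

    def test_truth_invariants_over_random_configs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            r_pool = rng.uniform(8, 12)
            cfg = PhantomConfig(
                image_size=96,
                n_frames=16,
                lv_center_range=(-3.0, 3.0),
                lv_pool_radius_range=(r_pool, r_pool + 2),
                myo_thickness_range=(4.0, 6.0),
                noise_sd=float(rng.uniform(0, 0.05)),
            )
            pairs = generate_series(cfg, seed=int(rng.integers(1 << 30)))
            for series, truth in pairs:
                assert series.frames.min() >= 0
                assert qc_closed_loop(truth.myo_mask)
                assert 0 <= truth.peak_frame < series.n_frames
                # insertion points on the epicardial boundary: inside the
                # dilated annulus, outside the pool
                from scipy import ndimage

                near = ndimage.binary_dilation(truth.myo_mask, iterations=2)
                for p in truth.insertion_points:
                    assert near[int(round(p[0])), int(round(p[1]))]

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(n_frames=4)

    def test_stress_enhances_more_than_rest(self, desk_config):
        cfg = dataclasses.replace(desk_config, n_slices=1, noise_sd=0.0)
        higher = 0
        n = 50
        for seed in range(n):
            pairs = dict_by_cond = {s.condition: (s, t) for s, t in generate_series(cfg, seed=seed)}
            peaks = {}
            for cond, (s, t) in dict_by_cond.items():
                myo = signal_to_conc(s.frames[:, t.myo_mask].mean(axis=1))
                peaks[cond] = myo.max()
            higher += peaks["stress"] > peaks["rest"]
        assert higher >= 0.95 * n

    def test_motion_recorded_in_truth(self, desk_config):
        cfg = dataclasses.replace(desk_config, motion_amplitude=2.0, n_slices=1, conditions=("rest",))
        series, truth = generate_series(cfg, seed=3)[0]
        assert truth.translations is not None
        assert truth.translations.shape == (cfg.n_frames, 2)
        assert np.max(np.abs(truth.translations)) <= 2.0


class TestGenerateCohort:
    def test_cohort_layout_and_determinism(self, desk_config):
        c1 = generate_cohort(desk_config, 2, seed=9)
        c2 = generate_cohort(desk_config, 2, seed=9)
        assert len(c1) == 2
        keys = set(c1[0].keys())
        assert keys == {(lv, cond) for lv in ("basal", "mid", "apical") for cond in ("rest", "stress")}
        s1 = c1[0][("basal", "rest")][0]
        s2 = c2[0][("basal", "rest")][0]
        assert np.array_equal(s1.frames, s2.frames)
        # different subjects differ
        assert not np.array_equal(s1.frames, c1[1][("basal", "rest")][0].frames)
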