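"""Field-map assembly: single-volume maps, series, filtering, smoothing."""

import numpy as np
import pytest

from refill import synthsim as ss
from refill.datamodel_io import CoilStack, ReadoutRamp, Volume
from refill.fieldmap import (
    correct_timeseries,
    filter_fieldmap,
    flash_fieldmap,
    refill_fieldmap,
    refill_series,
    smooth_fieldmap,
)
from refill.unwrap import compute_quality_map, mask_from_quality


def _two_volume_series(sc, field, offsets, phi_g_epi=0.03):
    """Reversed + regular EPI pair as a time-axis CoilStack."""
    rev = ss.simulate_epi_volume(sc.obj, sc.sens, field, sc.meta_epi,
                                 phi_g_epi=phi_g_epi, readout_polarity=-1)
    reg, field_d, _ = ss.simulate_epi_volume(
        sc.obj, sc.sens, field, sc.meta_epi, phi_g_epi=phi_g_epi,
        readout_polarity=1, return_truth=True)
    series = CoilStack(
        np.stack([rev.magnitude, reg.magnitude], axis=-1),
        np.stack([rev.phase, reg.phase], axis=-1), sc.meta_epi, "time")
    return series, field_d


class TestRefillFieldmap:
    def test_zero_phase_zero_field(self, small_scene):
        sc = small_scene
        z = np.zeros(sc.grid)
        theta = Volume(z, "phase")
        mask = Volume(np.ones(sc.grid), "mask")
        q = Volume(np.ones(sc.grid), "quality")
        fm = refill_fieldmap(theta, ReadoutRamp(0.0, "EPI"), mask, q,
                             sc.meta_epi)
        np.testing.assert_allclose(fm.values, 0.0, atol=1e-12)

    def test_noiseless_round_trip(self, small_scene, offsets_small):
        sc = small_scene
        series, field_d = _two_volume_series(sc, sc.field, offsets_small)
        fms = refill_series(series, offsets_small, sc.meta_epi)
        m = fms.mask.values.astype(bool)
        rms = np.sqrt(np.mean((fms.fields[..., 0][m] - field_d[m]) ** 2))
        assert rms < 1.0

    def test_te_invariance(self, small_scene, offsets_small):
        """The same underlying field is recovered at different EPI echo
        times (the phase scales with TE, the map does not)."""
        sc = small_scene
        maps = []
        for te in (22e-3, 30e-3):
            meta = ss.default_epi_meta(te=te)
            rev = ss.simulate_epi_volume(sc.obj, sc.sens, sc.field, meta,
                                         0.03, readout_polarity=-1)
            reg = ss.simulate_epi_volume(sc.obj, sc.sens, sc.field, meta,
                                         0.03, readout_polarity=1)
            series = CoilStack(
                np.stack([rev.magnitude, reg.magnitude], axis=-1),
                np.stack([rev.phase, reg.phase], axis=-1), meta, "time")
            fms = refill_series(series, offsets_small, meta)
            maps.append((fms.fields[..., 0], fms.mask.values.astype(bool)))
        common = maps[0][1] & maps[1][1]
        np.testing.assert_allclose(maps[0][0][common], maps[1][0][common],
                                   atol=1e-6)

    def test_bad_te_rejected(self, small_scene):
        sc = small_scene
        theta = Volume(np.zeros(sc.grid), "phase")
        mask = Volume(np.ones(sc.grid), "mask")
        q = Volume(np.ones(sc.grid), "quality")
        meta = sc.meta_epi.with_(echo_times=())
        with pytest.raises(ValueError):
            refill_fieldmap(theta, ReadoutRamp(0.0, "EPI"), mask, q, meta)


class TestRefillSeries:
    def test_static_field_stationary_maps(self, small_scene, offsets_small):
        sc = small_scene
        series, _ = sc.timeseries(6)
        fms = refill_series(series, offsets_small, sc.meta_epi)
        m = fms.mask.values.astype(bool)
        for t in range(1, fms.n_volumes):
            np.testing.assert_allclose(fms.fields[..., t][m],
                                       fms.fields[..., 0][m], atol=1e-9)

    def test_respiration_tracked(self, small_scene, offsets_small):
        sc = small_scene
        spec = ss.FieldSpec(uniform=sc.fieldspec.uniform,
                            linear=sc.fieldspec.linear,
                            resp_amplitude=2 * np.pi * 1.0, resp_period=5)
        series, truth = sc.timeseries(12, fieldspec=spec)
        fms = refill_series(series, offsets_small, sc.meta_epi)
        m = fms.mask.values.astype(bool)
        est = fms.fields[m]                          # (nvox, nt-1)
        true = truth.fields_distorted[m][:, 1:]
        # per-voxel temporal profiles track the truth essentially exactly
        r = np.corrcoef(est.ravel(), true.ravel())[0, 1]
        assert r > 0.99

    def test_drift_slope_recovered(self, small_scene, offsets_small):
        sc = small_scene
        spec = ss.FieldSpec(uniform=2 * np.pi * 3, drift=2 * np.pi * 0.5)
        series, truth = sc.timeseries(8, fieldspec=spec)
        fms = refill_series(series, offsets_small, sc.meta_epi)
        m = fms.mask.values.astype(bool)
        medians = [np.nanmedian(fms.fields[..., t][m])
                   for t in range(fms.n_volumes)]
        slope = np.polyfit(np.arange(len(medians)), medians, 1)[0]
        np.testing.assert_allclose(slope, 2 * np.pi * 0.5, rtol=0.05)

    def test_missing_reversed_volume_refused(self, small_scene,
                                             offsets_small):
        sc = small_scene
        series, _ = sc.timeseries(3)
        with pytest.raises(ValueError, match="readout-reversed"):
            refill_series(series, offsets_small, sc.meta_epi,
                          reversed_first=False)


class TestFlashFieldmap:
    def test_phase_difference_arithmetic(self):
        """A pi/2 phase advance over a 5 ms echo-time difference is
        100*pi rad/s (25 Hz)."""
        grid = (8, 8, 2)
        meta = ss.default_flash_meta()  # TE1/TE3 differ by 5 ms
        mag = np.ones(grid + (1, 3))
        omega = 100 * np.pi
        phase = np.stack([
            np.full(grid + (1,), 0.0),
            np.full(grid + (1,), 0.0),
            np.full(grid + (1,), omega * 5e-3),  # = pi/2
        ], axis=-1)
        from refill.datamodel_io import wrap_phase
        ref = CoilStack(mag, wrap_phase(phase), meta, "echo")
        fm = flash_fieldmap(ref)
        got = fm.values[np.isfinite(fm.values)]
        np.testing.assert_allclose(got, omega, atol=1e-9)

    def test_zero_difference_zero_field(self):
        grid = (8, 8, 2)
        meta = ss.default_flash_meta()
        ref = CoilStack(np.ones(grid + (1, 3)), np.zeros(grid + (1, 3)),
                        meta, "echo")
        fm = flash_fieldmap(ref)
        np.testing.assert_allclose(fm.values[np.isfinite(fm.values)], 0.0,
                                   atol=1e-12)

    def test_noiseless_accuracy(self, scene, reference):
        fm = flash_fieldmap(reference)
        m = np.isfinite(fm.values)
        rms = np.sqrt(np.mean((fm.values[m] - scene.field[m]) ** 2))
        assert rms < 1.0

    def test_opposite_polarity_echoes_refused(self, reference):
        with pytest.raises(ValueError, match="polarity"):
            flash_fieldmap(reference, echo_a=1, echo_b=2)


class TestFilterAndSmooth:
    def test_range_filter(self):
        v = np.array([[[2500.0, -700.0, 0.0, 100.0]]])
        fm = filter_fieldmap(Volume(v, "fieldmap_rad_s"))
        assert np.isnan(fm.values[0, 0, 0])
        assert np.isnan(fm.values[0, 0, 1])
        assert fm.values[0, 0, 2] == 0.0
        assert fm.values[0, 0, 3] == 100.0

    def test_filter_bad_bounds(self):
        with pytest.raises(ValueError):
            filter_fieldmap(Volume(np.zeros((2, 2, 2)), "fieldmap_rad_s"),
                            lo=10, hi=-10)

    def test_constant_with_holes_restored(self):
        v = np.full((12, 12, 4), 42.0)
        v[3:5, 3:5, 1] = np.nan
        out = smooth_fieldmap(Volume(v, "fieldmap_rad_s"), 2.0)
        np.testing.assert_allclose(out.values, 42.0, rtol=1e-10)

    def test_ramp_with_holes_restored(self):
        x = np.arange(32, dtype=float)[:, None, None]
        v = np.broadcast_to(10.0 * x, (32, 16, 4)).copy()
        rng = np.random.default_rng(4)
        holes = rng.uniform(size=v.shape) < 0.2
        v[holes] = np.nan
        out = smooth_fieldmap(Volume(v, "fieldmap_rad_s"), 1.5)
        interior = np.zeros_like(v, dtype=bool)
        interior[4:-4] = True
        err = np.abs(out.values - 10.0 * x)[interior]
        assert err.max() < 0.01 * np.nanmax(np.abs(v))

    def test_sigma_zero_identity(self):
        v = np.random.default_rng(5).normal(size=(6, 6, 2))
        out = smooth_fieldmap(Volume(v, "fieldmap_rad_s"), 0.0)
        np.testing.assert_array_equal(out.values, v)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            smooth_fieldmap(Volume(np.full((3, 3, 1), np.nan),
                                   "fieldmap_rad_s"), 1.0)


class TestPipeline:
    def test_deterministic(self, small_scene):
        sc = small_scene
        ref = sc.flash_reference(noise_sd=0.01, seed=21)
        series, _ = sc.timeseries(4, noise_sd=0.01, seed=22)
        a = correct_timeseries(series, ref, sc.meta_epi, smooth_sigma=1.5)
        b = correct_timeseries(series, ref, sc.meta_epi, smooth_sigma=1.5)
        np.testing.assert_array_equal(a.corrected, b.corrected)
        np.testing.assert_array_equal(a.fieldmaps.fields, b.fieldmaps.fields)

    def test_static_field_matches_static_correction(self, small_scene):
        """With a time-constant field, per-volume correction and
        volume-1-only correction coincide."""
        from refill.datamodel_io import Volume as V
        from refill.unwarp import apply_vsm
        sc = small_scene
        ref = sc.flash_reference()
        series, _ = sc.timeseries(4)
        res = correct_timeseries(series, ref, sc.meta_epi)
        vsm1 = V(res.vsm[..., 0], "vsm_voxels")
        for t in range(1, res.corrected.shape[-1]):
            static = apply_vsm(V(res.uncorrected[..., t], "magnitude"),
                               vsm1, "unwarp")
            d = res.corrected[..., t] - static.values
            ok = np.isfinite(d)
            np.testing.assert_allclose(d[ok], 0.0, atol=1e-9)
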