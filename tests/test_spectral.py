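"""Profile extraction, in-band spectral scoring, FSNR screening, traces."""

import numpy as np
import pandas as pd
import pytest

import myofind as mf
from myofind.spectral import trace_baseline


def sin_profile(period_um, ps=0.25, n=256, amp=100.0, level=1000.0, phase=0.0):
    x = np.arange(n) * ps
    return level + amp * np.sin(2 * np.pi * x / period_um + phase)


class TestProfile:
    def test_constant_region_constant_profile(self):
        fr = mf.Frame(np.full((128, 300), 77.0), 0.25)
        p = mf.profile(fr, mf.MeasureRegion((63.5, 149.5)))
        assert p.shape == (256,)
        assert np.allclose(p, 77.0)

    def test_column_structure_preserved(self):
        px = np.tile(np.sin(2 * np.pi * np.arange(300) / 8.0), (64, 1))
        fr = mf.Frame(px, 0.25)
        p = mf.profile(fr, mf.MeasureRegion((31.5, 149.5)))
        # periodic with period 8 px
        assert np.allclose(p[:-8], p[8:], atol=1e-6)

    def test_single_bright_row_scaled_by_height(self):
        px = np.zeros((128, 300))
        px[63, :] = 30.0
        fr = mf.Frame(px, 0.25)
        # region rows 48..78 (30 rows) include the bright row once
        p = mf.profile(fr, mf.MeasureRegion((62.5, 149.5)))
        assert np.allclose(p, 1.0)

    def test_out_of_bounds_region_raises(self):
        fr = mf.Frame(np.zeros((64, 300)), 0.25)
        with pytest.raises(ValueError, match="outside"):
            mf.profile(fr, mf.MeasureRegion((10.0, 149.5)))


class TestSpectrum:
    def test_pure_sinusoid_recovered(self):
        spec = mf.spectrum(sin_profile(1.8), 0.25)
        assert spec.sarcomere_length == pytest.approx(1.8, abs=0.05)
        assert spec.FSNR > 2.5

    def test_flat_profile_zero_scores(self):
        spec = mf.spectrum(np.full(256, 5.0), 0.25)
        assert spec.Fmax == 0.0 and spec.FSNR == 0.0
        assert spec.sarcomere_length is None

    def test_out_of_band_period_scores_low(self):
        in_band = mf.spectrum(sin_profile(1.8), 0.25)
        out_band = mf.spectrum(sin_profile(3.0), 0.25)
        assert out_band.Fmax < 0.05 * in_band.Fmax

    def test_band_bins_from_physical_frequencies(self):
        spec = mf.spectrum(sin_profile(1.5), 0.25)
        i0, i1 = spec.band
        # 256 samples at 0.25 µm/px: 1/(2 µm)=0.5 c/µm is bin 32,
        # 1/(1 µm)=1.0 c/µm is bin 64
        assert (i0, i1) == (32, 64)
        assert spec.freqs[i0] >= 0.5 and spec.freqs[i1] <= 1.0

    def test_coarse_pixel_size_rejected_with_bound(self):
        with pytest.raises(ValueError, match="pixel_size"):
            mf.spectrum(np.zeros(256), 8.0)

    def test_linearity_in_profile_scale(self):
        p = sin_profile(1.7)
        a = mf.spectrum(p, 0.25)
        b = mf.spectrum(p * 3.0, 0.25)
        assert np.allclose(b.magnitudes, 3.0 * a.magnitudes)
        assert b.FSNR == pytest.approx(a.FSNR)

    def test_fsnr_never_increased_by_noise(self):
        # median FSNR over noise draws is non-increasing in noise sd
        base = sin_profile(1.8)
        rng = np.random.default_rng(42)
        med = []
        for sd in (0.0, 20.0, 60.0):
            vals = [mf.spectrum(base + rng.normal(0, sd, 256), 0.25).FSNR
                    for _ in range(25)]
            med.append(np.median(vals))
        assert med[0] >= med[1] >= med[2]


class TestSnrFilter:
    def _cand(self, fsnr):
        mask = np.zeros((64, 64), dtype=bool)
        mask[1:10, 1:10] = True
        c = mf.CellCandidate(id=0, mask=mask, bbox=(1, 1, 10, 10),
                             centroid=(5.0, 5.0), area=10.0, aspect_ratio=0.5,
                             fill_ratio=1.0, orientation=0.0)
        c.fsnr = fsnr
        return c

    def test_below_threshold_excluded(self):
        kept = mf.snr_filter([self._cand(2.4)], threshold=2.5)
        assert kept == []

    def test_boundary_inclusive(self):
        cands = [self._cand(2.5)]
        assert mf.snr_filter(cands, threshold=2.5) == cands

    def test_published_exclusion_arithmetic(self):
        # 278 beating cells, 66 below the 2.5 threshold -> 212 retained
        rng = np.random.default_rng(0)
        cands = ([self._cand(float(f)) for f in rng.uniform(2.5, 8, 212)]
                 + [self._cand(float(f)) for f in rng.uniform(0.1, 2.49, 66)])
        assert len(mf.snr_filter(cands, 2.5)) == 212


class TestTrace:
    def test_static_phantom_constant_trace(self):
        spec = mf.PhantomSpec(image_size=(512, 512), n_cells=1, seed=9,
                              orientation_range=(0.0, 0.0), noise_sd=0.0,
                              beat_fraction=0.0, n_frames=5,
                              min_separation=10.0)
        stack, truth = mf.generate_video(spec)
        trace = mf.measure_trace(stack, mf.MeasureRegion(truth[0].centroid))
        sl = trace["sarcomere_length_um"]
        assert sl.notna().all()
        assert sl.std() == pytest.approx(0.0, abs=1e-9)
        df = 1.0 / (256 * 0.25)
        one_bin = truth[0].sarcomere_period ** 2 * df
        assert abs(sl.iloc[0] - truth[0].sarcomere_period) <= one_bin

    def test_beating_phantom_shortens_by_contraction_amplitude(self):
        spec = mf.PhantomSpec(image_size=(512, 512), n_cells=1, seed=9,
                              orientation_range=(0.0, 0.0), noise_sd=0.0,
                              beat_fraction=1.0, n_frames=20,
                              contraction_amplitude=0.08,
                              min_separation=10.0)
        stack, truth = mf.generate_video(spec)
        trace = mf.measure_trace(stack, mf.MeasureRegion(truth[0].centroid))
        base = trace_baseline(trace)
        shortening = 1.0 - trace["sarcomere_length_um"].min() / base
        assert shortening == pytest.approx(0.08, abs=0.02)

    def test_empty_stack_empty_trace(self):
        stack = mf.FrameStack(np.zeros((0, 64, 64)), 0.25)
        trace = mf.measure_trace(stack, mf.MeasureRegion((31.5, 31.5)))
        assert len(trace) == 0

    def test_low_snr_frames_marked_missing(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(1000, 30, size=(4, 128, 300))
        stack = mf.FrameStack(frames, 0.25)
        trace = mf.measure_trace(stack, mf.MeasureRegion((63.5, 149.5)),
                                 fsnr_threshold=1e9)
        assert trace["sarcomere_length_um"].isna().all()


class TestPeriodRecoveryProperty:
    def test_recovery_rate_over_random_periods(self):
        # stripes with periods across the band; estimate within
        # max(one bin, 0.05 µm) nearly always
        rng = np.random.default_rng(2024)
        ps = 0.25
        df = 1.0 / (256 * ps)
        hits = 0
        n = 40
        for _ in range(n):
            period = rng.uniform(1.4, 1.9)
            fr = mf.stripe_frame(period, 0.0, ps, shape=(128, 300),
                                 noise_sd=40.0, seed=int(rng.integers(2**31)))
            est = mf.measure_frame(fr, mf.MeasureRegion((63.5, 149.5))
                                   ).sarcomere_length
            tol = max(period ** 2 * df, 0.05)
            hits += abs(est - period) <= tol
        assert hits / n >= 0.95
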