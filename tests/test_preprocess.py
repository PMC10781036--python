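import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppg_bioauth.preprocess import (PipelineStageError, PreprocessConfig,
                                    bandpass_filter, estimate_snr, normalize,
                                    preprocess_record, quality_screen,
                                    remove_baseline,
                                    remove_motion_artifacts_pca, resample,
                                    segment)
from ppg_bioauth.signals import Segment, SignalRecord
from ppg_bioauth.synth import NoiseConfig, synth_cohort

CFG = PreprocessConfig()


def _tone(f, fs=250.0, duration=30.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalRecord(samples=amp * np.sin(2 * np.pi * f * t), fs=fs)


def _rms(x):
    return np.sqrt(np.mean(x**2))


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = _tone(1.5)
        out = bandpass_filter(rec, CFG)
        interior = slice(1000, -1000)
        assert _rms(out.samples[interior]) == pytest.approx(
            _rms(rec.samples[interior]), rel=0.05)

    @pytest.mark.parametrize("f", [0.05, 45.0])
    def test_stopband_attenuated_20db(self, f):
        rec = _tone(f, duration=60.0)
        out = bandpass_filter(rec, CFG)
        assert _rms(out.samples) <= 0.1 * _rms(rec.samples)

    def test_zero_in_zero_out(self):
        rec = SignalRecord(samples=np.zeros(1000), fs=250.0)
        assert np.all(bandpass_filter(rec, CFG).samples == 0)

    def test_band_above_nyquist_rejected(self):
        rec = _tone(1.0, fs=10.0, duration=10.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, CFG)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        fx = bandpass_filter(SignalRecord(samples=x, fs=250.0), CFG).samples
        fy = bandpass_filter(SignalRecord(samples=y, fs=250.0), CFG).samples
        fxy = bandpass_filter(SignalRecord(samples=2 * x + 3 * y, fs=250.0),
                              CFG).samples
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, atol=1e-9)


class TestBaseline:
    def test_constant_removed(self):
        rec = SignalRecord(samples=np.full(500, 3.7), fs=250.0)
        np.testing.assert_allclose(remove_baseline(rec, CFG).samples, 0,
                                   atol=1e-12)

    def test_ramp_removal_matches_direct_computation(self):
        rng = np.random.default_rng(1)
        fs = 250.0
        t = np.arange(2500) / fs
        base = np.sin(2 * np.pi * 1.7 * t) * 0.3
        ramp = 0.5 * t
        out_with = remove_baseline(SignalRecord(samples=base + ramp, fs=fs), CFG)
        out_wo = remove_baseline(SignalRecord(samples=base, fs=fs), CFG)
        # away from the edges the ramp is absorbed by the moving average
        inner = slice(300, -300)
        np.testing.assert_allclose(out_with.samples[inner],
                                   out_wo.samples[inner], atol=5e-3)

    def test_zero_in_zero_out(self):
        rec = SignalRecord(samples=np.zeros(500), fs=250.0)
        assert np.all(remove_baseline(rec, CFG).samples == 0)


class TestPCA:
    def _periodic(self, n_periods=10, period=250):
        t = np.arange(period) / period
        cycle = np.sin(2 * np.pi * t) + 0.4 * np.sin(4 * np.pi * t)
        return np.tile(cycle, n_periods)

    def test_rank_one_signal_reconstructed_exactly(self):
        x = self._periodic()
        rec = SignalRecord(samples=x, fs=250.0)
        out = remove_motion_artifacts_pca(rec, CFG)
        np.testing.assert_allclose(out.samples, x, atol=1e-9)

    def test_burst_removed_correlation(self):
        """One burst-corrupted epoch; reconstruction tracks the clean signal.

        Cross-checked against an independent eigendecomposition oracle of
        the same epoch matrix.
        """
        clean = self._periodic()
        x = clean.copy()
        x[3 * 250 : 4 * 250] += 1.5 * np.hanning(250)
        cfg = PreprocessConfig(pca_variance_keep=0.8)
        out = remove_motion_artifacts_pca(SignalRecord(samples=x, fs=250.0), cfg)
        r = np.corrcoef(out.samples, clean)[0, 1]
        assert r >= 0.95

        # oracle: explicit eigendecomposition of the second-moment matrix
        X = x.reshape(10, 250)
        C = X.T @ X
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        cum = np.cumsum(w) / w.sum()
        k = int(np.searchsorted(cum, 0.8 - 1e-12) + 1)
        recon = X @ V[:, :k] @ V[:, :k].T
        np.testing.assert_allclose(out.samples, recon.ravel(), atol=1e-8)

    def test_keep_all_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2500)
        cfg = PreprocessConfig(pca_variance_keep=1.0)
        out = remove_motion_artifacts_pca(SignalRecord(samples=x, fs=250.0), cfg)
        np.testing.assert_allclose(out.samples, x, atol=1e-9)

    def test_too_short_rejected(self):
        rec = SignalRecord(samples=np.zeros(300), fs=250.0)
        with pytest.raises(ValueError):
            remove_motion_artifacts_pca(rec, CFG)


class TestNormalize:
    def test_peak_scaled_to_one(self):
        x = 5.0 * np.sin(np.linspace(0, 10, 500))
        out = normalize(SignalRecord(samples=x, fs=250.0))
        assert np.abs(out.samples).max() == pytest.approx(1.0)

    def test_constant_maps_to_zero(self):
        out = normalize(SignalRecord(samples=np.full(100, 2.0), fs=250.0))
        assert np.all(out.samples == 0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rec = SignalRecord(samples=rng.normal(size=500), fs=250.0)
        once = normalize(rec)
        twice = normalize(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)


class TestResample:
    def test_length_arithmetic(self):
        rec = SignalRecord(samples=np.zeros(8 * 60 * 125), fs=125.0)
        out = resample(rec, 250.0)
        assert out.samples.size == 120_000 and out.fs == 250.0

    def test_identity_resampling(self):
        rng = np.random.default_rng(4)
        rec = SignalRecord(samples=rng.normal(size=1000), fs=250.0)
        out = resample(rec, 250.0)
        np.testing.assert_allclose(out.samples, rec.samples, atol=1e-9)

    def test_sinusoid_against_analytic_values(self):
        fs_in, fs_out, f = 125.0, 250.0, 2.0
        t_in = np.arange(int(10 * fs_in)) / fs_in
        rec = SignalRecord(samples=np.sin(2 * np.pi * f * t_in), fs=fs_in)
        out = resample(rec, fs_out)
        t_out = np.arange(out.samples.size) / fs_out
        inner = (t_out > 0.1) & (t_out < t_in[-1] - 0.1)
        err = np.abs(out.samples[inner] - np.sin(2 * np.pi * f * t_out[inner]))
        assert err.max() <= 1e-3


class TestSegmentation:
    def test_counting_example(self):
        rec = SignalRecord(samples=np.zeros(1500), fs=50.0)
        assert len(segment(rec, PreprocessConfig(window_s=5.0, overlap=0.5))) == 11

    def test_single_window_boundary(self):
        rec = SignalRecord(samples=np.arange(1250.0), fs=250.0)
        segs = segment(rec, CFG)
        assert len(segs) == 1
        np.testing.assert_array_equal(segs[0].samples, rec.samples)

    def test_disjoint_cover_no_overlap(self):
        rec = SignalRecord(samples=np.arange(2500.0), fs=250.0)
        segs = segment(rec, PreprocessConfig(overlap=0.0))
        assert len(segs) == 2
        np.testing.assert_array_equal(
            np.concatenate([s.samples for s in segs]), rec.samples)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(10, 3000), st.integers(2, 400), st.data())
    def test_count_formula_property(self, L, W, data):
        """count = floor((L-W)/S)+1 vs an explicit sliding-window oracle."""
        if W > L:
            W = L
        S = data.draw(st.integers(1, W))
        x = np.arange(float(L))
        starts = []
        i = 0
        while i + W <= L:
            starts.append(i)
            i += S
        fs = 1.0
        cfg = PreprocessConfig(window_s=W / fs, overlap=1 - S / W)
        segs = segment(SignalRecord(samples=x, fs=fs), cfg)
        assert len(segs) == len(starts) == (L - W) // S + 1
        for s, i0 in zip(segs, starts):
            assert s.samples[0] == i0
            assert s.samples.size == W


class TestSNR:
    def test_in_band_tone_high_snr(self):
        t = np.arange(1250) / 250.0
        seg = Segment(samples=np.sin(2 * np.pi * 1.2 * t), fs=250.0,
                      start_time_s=0)
        assert estimate_snr(seg, CFG) >= 20.0

    def test_out_of_band_tone_low_snr(self):
        t = np.arange(1250) / 250.0
        seg = Segment(samples=np.sin(2 * np.pi * 20.0 * t), fs=250.0,
                      start_time_s=0)
        assert estimate_snr(seg, CFG) <= -10.0

    def test_white_noise_matches_flat_spectrum_expectation(self):
        fs = 50.0
        lo, hi = CFG.cardiac_band_hz
        expected = 10 * np.log10((hi - lo) / (fs / 2 - (hi - lo)))
        vals = []
        for k in range(10):
            rng = np.random.default_rng(k)
            seg = Segment(samples=rng.normal(size=2500), fs=fs, start_time_s=0)
            vals.append(estimate_snr(seg, CFG))
        assert abs(np.mean(vals) - expected) <= 3.0

    def test_quality_screen_thresholds(self):
        segs = [Segment(samples=np.zeros(10), fs=10.0, start_time_s=i,
                        snr_db=v) for i, v in enumerate((2.0, 5.0, 9.0))]
        all_cfg = PreprocessConfig(snr_min_db=-np.inf)
        none_cfg = PreprocessConfig(snr_min_db=np.inf)
        mid_cfg = PreprocessConfig(snr_min_db=5.0)
        assert quality_screen(segs, all_cfg) == segs
        assert quality_screen(segs, none_cfg) == []
        kept = quality_screen(segs, mid_cfg)
        assert [s.snr_db for s in kept] == [5.0, 9.0]


class TestFullPipeline:
    def test_zero_noise_cohort_survival(self):
        recs = synth_cohort(4, 5, 10.0, 250.0, NoiseConfig.silent(), seed=0)
        # 10 s at 250 Hz, 5 s windows, 50% overlap -> 3 windows per record
        total = 3 * len(recs)
        kept = sum(len(preprocess_record(rec, CFG)) for rec in recs)
        assert kept >= 0.9 * total

    def test_chain_equals_composition(self, steady_identity):
        from ppg_bioauth.synth import synth_signal

        rec = synth_signal(steady_identity, 12.0, 225.0, NoiseConfig(), seed=3)
        chained = preprocess_record(rec, CFG)
        x = bandpass_filter(rec, CFG)
        x = remove_baseline(x, CFG)
        x = remove_motion_artifacts_pca(x, CFG)
        x = normalize(x)
        x = resample(x, CFG.target_fs)
        segs = segment(x, CFG)
        for s in segs:
            estimate_snr(s, CFG)
        manual = quality_screen(segs, CFG)
        assert len(chained) == len(manual)
        for a, b in zip(chained, manual):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_deterministic(self, steady_identity):
        from ppg_bioauth.synth import synth_signal

        rec = synth_signal(steady_identity, 12.0, 250.0, NoiseConfig(), seed=3)
        a = preprocess_record(rec, CFG)
        b = preprocess_record(rec, CFG)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.samples, sb.samples)

    def test_short_record_yields_empty_list(self):
        rec = SignalRecord(samples=np.sin(np.arange(750) / 25), fs=250.0)
        assert preprocess_record(rec, CFG) == []

    def test_stage_error_carries_stage_name(self):
        rec = SignalRecord(samples=np.sin(np.arange(300) / 25), fs=250.0)
        with pytest.raises(PipelineStageError, match="remove_motion_artifacts_pca"):
            preprocess_record(rec, CFG)

    def test_surviving_segments_normalized(self, steady_identity):
        from ppg_bioauth.synth import synth_signal

        rec = synth_signal(steady_identity, 20.0, 250.0, NoiseConfig(), seed=5)
        for s in preprocess_record(rec, CFG):
            assert np.abs(s.samples).max() <= 1 + 1e-9
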