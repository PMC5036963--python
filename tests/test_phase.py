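"""Filterbank construction, Hilbert phases, circular statistics,
Rayleigh testing and the ECDF phase correction."""

import math

import numpy as np
import pytest
from scipy.special import i0, i1

from striatumtools.phase import (
    BAND_PRESETS,
    FilterBank,
    SampledSignal,
    analytic_phase,
    band_locking,
    build_filterbank,
    circular_stats,
    ecdf_phase_correction,
    locking_profile,
    proportion_significant,
    rayleigh_test,
    spike_phases,
)
from striatumtools.spikes import SpikeTrain
from striatumtools.synthetic import simulate_field, simulate_locked_train


def sinusoid(freq=1.0, duration=30.0, fs=1000.0, phase0=0.0):
    t = np.arange(int(duration * fs)) / fs
    return SampledSignal(samples=np.cos(2 * np.pi * freq * t + phase0), fs=fs)


class TestFilterBank:
    def test_default_construction(self):
        fb = build_filterbank()
        assert fb.n_bands == 107
        assert fb.centers[0] == pytest.approx(1.0)
        assert fb.centers[-1] == pytest.approx(80.0)

    def test_two_band_limits(self):
        fb = build_filterbank(n=2)
        assert fb.centers.tolist() == pytest.approx([1.0, 80.0])

    def test_adjacent_bands_overlap_and_widths_increase(self):
        fb = build_filterbank()
        assert np.all(fb.lows[1:] < fb.highs[:-1])
        widths = fb.highs - fb.lows
        assert np.all(np.diff(widths) > 0)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank(f_lo=0.0)
        with pytest.raises(ValueError):
            FilterBank(centers=np.array([2.0, 1.0]), lows=np.array([1.0, 0.5]),
                       highs=np.array([3.0, 1.5]))

    def test_gamma_presets_available(self):
        assert BAND_PRESETS["gamma_figures"] == (30.0, 80.0)
        assert BAND_PRESETS["gamma_swa"] == (27.0, 45.0)
        assert BAND_PRESETS["gamma_cluster"] == (30.0, 48.0)


class TestAnalyticPhase:
    def test_sinusoid_phase_advances_linearly(self):
        s = sinusoid(freq=4.0)
        phase, _ = analytic_phase(s, (2.7, 6.0))
        core = slice(2000, -2000)
        slope = np.polyfit(s.times()[core], np.unwrap(phase)[core], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 4.0, rel=1e-3)

    def test_unit_sinusoid_amplitude_near_one(self):
        s = sinusoid(freq=4.0)
        _, amp = analytic_phase(s, (2.7, 6.0))
        assert np.allclose(amp[2000:-2000], 1.0, atol=0.01)

    def test_zero_phase_filter_preserves_peak_times(self):
        """Forward-backward filtering keeps sinusoid peaks in place:
        local maxima of the filtered signal match the raw peaks within
        one sample."""
        from scipy.signal import butter, sosfiltfilt

        s = sinusoid(freq=2.0, phase0=0.3)
        sos = butter(2, [1.3, 3.0], btype="bandpass", fs=s.fs, output="sos")
        filtered = sosfiltfilt(sos, s.samples)

        def peak_idx(x):
            return np.flatnonzero(np.diff(np.signbit(np.diff(x))) > 0)[5:-5] + 1

        raw, filt = peak_idx(s.samples), peak_idx(filtered)
        assert raw.size == filt.size
        assert np.max(np.abs(raw - filt)) <= 1

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            analytic_phase(sinusoid(fs=100.0), (10.0, 60.0))


class TestSpikePhases:
    def test_spikes_at_peaks_have_zero_phase(self):
        s = sinusoid(freq=1.0)
        phase, _ = analytic_phase(s, (0.6, 1.6))
        peaks = np.arange(2.0, 28.0)  # cos peaks at integer seconds
        train = SpikeTrain(times=peaks, epoch=(0.0, s.duration))
        ph = spike_phases(train, phase, s.fs)
        assert np.max(np.abs(np.degrees(ph))) < 3.0

    def test_spikes_at_troughs_have_180_degrees(self):
        s = sinusoid(freq=1.0)
        phase, _ = analytic_phase(s, (0.6, 1.6))
        troughs = np.arange(2.5, 27.5)
        ph = spike_phases(troughs, phase, s.fs)
        assert np.min(np.abs(np.degrees(ph))) > 177.0

    def test_jittered_peak_spikes_circular_spread(self):
        """5 ms jitter on a 1 Hz cycle is 1.8 degrees of phase."""
        rng = np.random.default_rng(0)
        s = sinusoid(freq=1.0, duration=600.0)
        phase, _ = analytic_phase(s, (0.6, 1.6))
        peaks = np.arange(2.0, 598.0) + rng.normal(0, 0.005, size=596)
        ph = spike_phases(np.sort(peaks), phase, s.fs)
        r, _ = circular_stats(ph)
        circ_sd_deg = math.degrees(math.sqrt(-2 * math.log(r)))
        assert circ_sd_deg == pytest.approx(1.8, abs=0.4)

    def test_spike_outside_span_rejected(self):
        s = sinusoid(duration=10.0)
        phase, _ = analytic_phase(s, (0.6, 1.6))
        with pytest.raises(ValueError):
            spike_phases(np.array([11.0]), phase, s.fs)


class TestEcdfCorrection:
    def test_uniform_distribution_identity(self):
        rng = np.random.default_rng(1)
        sig_ph = rng.uniform(-np.pi, np.pi, size=200_000)
        spikes = rng.uniform(-np.pi + 0.01, np.pi - 0.01, size=500)
        corrected = ecdf_phase_correction(spikes, sig_ph)
        assert np.max(np.abs(corrected - spikes)) < 0.05

    def test_monotone_rank_preserving(self):
        rng = np.random.default_rng(2)
        sig_ph = rng.vonmises(0.5, 1.0, size=10_000)
        spikes = np.sort(rng.uniform(-np.pi, np.pi, size=100))
        corrected = ecdf_phase_correction(spikes, sig_ph)
        assert np.all(np.diff(corrected) >= 0)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            ecdf_phase_correction(np.array([0.0]), np.array([]))

    def test_restores_nominal_false_positive_rate_on_skewed_wave(self):
        """Poisson spikes on a sawtooth-skewed slow wave: uncorrected
        Rayleigh rejects far too often, corrected is ~nominal."""
        sig = simulate_field(duration=60.0, fs=250.0, skew=4.0, spindle_amp=0,
                             gamma_amp=0, noise_amp=0.05, seed=11)
        theta, _ = analytic_phase(sig, (0.4, 1.6))
        rng = np.random.default_rng(12)
        n_reps, fp_unc, fp_cor = 200, 0, 0
        for _ in range(n_reps):
            times = np.sort(rng.uniform(0, sig.duration - 1 / sig.fs, size=400))
            sp = spike_phases(times, theta, sig.fs)
            fp_unc += rayleigh_test(sp) < 0.05
            fp_cor += rayleigh_test(ecdf_phase_correction(sp, theta)) < 0.05
        assert fp_unc / n_reps > 0.2
        assert 0.02 <= fp_cor / n_reps <= 0.08


class TestCircularStats:
    def test_identical_phases_unit_vector(self):
        r, mean = circular_stats(np.full(10, 0.7))
        assert r == pytest.approx(1.0)
        assert mean == pytest.approx(0.7)

    def test_symmetric_four_point_set_zero(self):
        r, _ = circular_stats(np.deg2rad([0, 90, 180, 270]))
        assert r == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0])
    def test_von_mises_vector_length_bessel_ratio(self, kappa):
        rng = np.random.default_rng(3)
        draws = rng.vonmises(0.0, kappa, size=2000)
        r, _ = circular_stats(draws)
        assert r == pytest.approx(i1(kappa) / i0(kappa), abs=0.05)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(4)
        ph = rng.vonmises(0.2, 2.0, size=500)
        rot = 1.1
        r0, m0 = circular_stats(ph)
        r1, m1 = circular_stats(np.angle(np.exp(1j * (ph + rot))))
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert np.angle(np.exp(1j * (m1 - m0 - rot))) == pytest.approx(0.0, abs=1e-9)


class TestRayleigh:
    def test_perfect_locking_tiny_p(self):
        assert rayleigh_test(np.zeros(40)) < 1e-15

    def test_symmetric_set_p_near_one(self):
        assert rayleigh_test(np.deg2rad([0, 90, 180, 270])) > 0.99

    def test_uniform_null_rejection_rate(self):
        """1000 seeded draws of 40 uniform phases: rejection 0.05 +/- 0.02."""
        rng = np.random.default_rng(5)
        rejections = sum(
            rayleigh_test(rng.uniform(-np.pi, np.pi, size=40)) < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


@pytest.fixture(scope="module")
def slow_locked():
    sig = simulate_field(duration=120.0, fs=250.0, spindle_amp=0.1,
                         gamma_amp=0.0, noise_amp=0.1, seed=6)
    train = simulate_locked_train(sig, (0.6, 1.6), rate=8.0, kappa=2.0, seed=7)
    fb = build_filterbank(n=30, f_lo=0.8, f_hi=60.0)
    return train, sig, fb


class TestLockingProfile:

    def test_significance_concentrates_at_the_locked_frequency(self, slow_locked):
        train, sig, fb = slow_locked
        prof = locking_profile(train, sig, fb)
        sig_bands = prof.significant()
        low = fb.centers < 3.0
        gamma = fb.centers > 25.0
        assert sig_bands[low].any()
        assert not sig_bands[gamma].all()
        assert prof.band_range_significant(0.8, 2.0)

    def test_histograms_conserve_spike_count(self, slow_locked):
        train, sig, fb = slow_locked
        prof = locking_profile(train, sig, fb)
        counted = prof.phase_histograms.sum(axis=1)
        assert np.all(counted[prof.tested] == train.n_spikes)
        assert prof.phase_histograms.shape[1] == 20

    def test_too_few_spikes_never_tested(self):
        sig = simulate_field(duration=61.0, fs=250.0, seed=8)
        train = SpikeTrain(times=np.linspace(1, 60, 30), epoch=(0.0, sig.duration))
        prof = locking_profile(train, sig, build_filterbank(n=5, f_lo=1, f_hi=20))
        assert not prof.tested.any()
        assert np.isnan(prof.rayleigh_p).all()

    def test_null_spikes_on_noise_about_five_percent_of_bands(self):
        """Poisson spikes against pure noise: ~5% of tested bands come
        out significant."""
        rng = np.random.default_rng(9)
        rates = []
        fb = build_filterbank(n=20, f_lo=1.5, f_hi=40.0)
        for seed in range(8):
            sig = SampledSignal(
                samples=np.random.default_rng(100 + seed).standard_normal(30_000),
                fs=250.0,
            )
            times = np.sort(rng.uniform(0, sig.duration - 0.01, size=300))
            train = SpikeTrain(times=times, epoch=(0.0, sig.duration))
            prof = locking_profile(train, sig, fb)
            rates.append(prof.significant().sum() / prof.tested.sum())
        assert np.mean(rates) < 0.15

    def test_proportion_summary(self, slow_locked):
        train, sig, fb = slow_locked
        prof = locking_profile(train, sig, fb)
        assert proportion_significant([prof], (0.8, 2.0)) == 1.0
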