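"""Firing times on the normalized time base of slow-oscillation peaks in
the inverted LFP.

During slow-wave activity the striatal LFP is inverted (iLFP) so its
peaks track the synchronized depolarized 'up states' of the projection
neuron population.  The iLFP is bandpass filtered at 0.4-1.6 Hz
(zero-phase, 2nd-order Butterworth); each peak is the stretch between
consecutive troughs, i.e. one full Hilbert-phase cycle from -pi to pi.
Peaks shorter than 0.625 s or longer than 2.5 s -- the periods of the
filter corners -- are discarded.  Every retained peak is divided into
100 time bins on a nominal -1..1 scale so firing times are comparable
across peaks of different durations; the median normalized firing time
summarizes each neuron and is compared between populations with a
Kruskal-Wallis / Dunn analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .spikes import SpikeTrain
from .stats import TestResult, kruskal_wallis_dunn

ILFP_BAND = (0.4, 1.6)
#: admissible trough-to-trough durations: the corner periods of the band
DURATION_GATE_S = (1.0 / ILFP_BAND[1], 1.0 / ILFP_BAND[0])  # (0.625, 2.5)
N_BINS = 100


@dataclass(frozen=True)
class ILfpPeak:
    """One trough-to-trough stretch of the filtered iLFP."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("peak must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PeakAlignedHistogram:
    """100-bin histogram of firing on the normalized -1..1 time base."""

    counts: np.ndarray
    mean_amplitude: np.ndarray
    median_firing_time: float | None
    n_peaks: int
    n_spikes_in_peaks: int

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, N_BINS + 1)


def invert_and_filter(samples: np.ndarray, fs: float,
                      band: tuple[float, float] = ILFP_BAND) -> np.ndarray:
    """Invert LFP polarity and apply the zero-phase 0.4-1.6 Hz bandpass."""
    if fs < 10:
        raise ValueError("sampling rate too low for the slow-oscillation band")
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError("band reaches Nyquist")
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, -np.asarray(samples, dtype=float))


def segment_peaks(
    filtered_ilfp: np.ndarray,
    fs: float,
    duration_gate_s: tuple[float, float] = DURATION_GATE_S,
) -> list[ILfpPeak]:
    """Delimit iLFP peaks as full Hilbert-phase cycles between troughs.

    Troughs are the crossings of odd multiples of pi on the unwrapped
    instantaneous phase (phase -pi -> pi spans one peak), not amplitude
    minima.  Peaks with duration outside the gate are discarded;
    incomplete cycles at the epoch edges are dropped.  An epoch with no
    complete peak returns an empty list.
    """
    x = np.asarray(filtered_ilfp, dtype=float)
    if x.size < 4:
        return []
    phase = np.unwrap(np.angle(hilbert(x)))
    # trough phases are pi + 2*pi*k within the observed phase range
    k_lo = int(np.ceil((phase[0] - np.pi) / (2 * np.pi)))
    k_hi = int(np.floor((phase[-1] - np.pi) / (2 * np.pi)))
    if k_hi < k_lo + 1:
        return []
    trough_times = []
    idx = np.arange(x.size)
    for k in range(k_lo, k_hi + 1):
        target = np.pi + 2 * np.pi * k
        j = int(np.searchsorted(phase, target))
        if j == 0 or j >= x.size:
            continue
        # linear interpolation between the bracketing samples
        p0, p1 = phase[j - 1], phase[j]
        frac = (target - p0) / (p1 - p0) if p1 > p0 else 0.0
        trough_times.append((idx[j - 1] + frac) / fs)
    peaks = []
    lo, hi = duration_gate_s
    for t0, t1 in zip(trough_times[:-1], trough_times[1:]):
        if lo <= (t1 - t0) <= hi:
            peaks.append(ILfpPeak(start_s=t0, end_s=t1))
    return peaks


def normalized_time(spike_time: float, peak: ILfpPeak) -> float:
    """Map a spike inside a peak to the nominal -1..1 time base."""
    return 2.0 * (spike_time - peak.start_s) / peak.duration_s - 1.0


def spike_normalized_times(
    t: SpikeTrain | np.ndarray, peaks: list[ILfpPeak]
) -> np.ndarray:
    """Normalized times of all spikes falling inside retained peaks.

    A spike exactly on a trough boundary belongs to the peak beginning
    there; spikes outside every peak are ignored.
    """
    times = t.times if isinstance(t, SpikeTrain) else np.asarray(t, dtype=float)
    if not peaks:
        raise ValueError("no retained peaks")
    starts = np.array([p.start_s for p in peaks])
    ends = np.array([p.end_s for p in peaks])
    out = []
    for st in times:
        j = int(np.searchsorted(starts, st, side="right")) - 1
        if j >= 0 and st < ends[j]:
            out.append(2.0 * (st - starts[j]) / (ends[j] - starts[j]) - 1.0)
    return np.asarray(out)


def normalized_histogram(
    t: SpikeTrain | np.ndarray,
    peaks: list[ILfpPeak],
    filtered_ilfp: np.ndarray | None = None,
    fs: float | None = None,
) -> PeakAlignedHistogram:
    """Accumulate spikes over 100 normalized-time bins across peaks.

    Also averages the (filtered) iLFP amplitude per normalized bin when
    the signal is supplied.  With no spikes inside any peak, the count
    histogram is all-zero and the median firing time is flagged None.
    """
    u = spike_normalized_times(t, peaks)
    edges = np.linspace(-1.0, 1.0, N_BINS + 1)
    counts, _ = np.histogram(u, bins=edges)
    amp = np.zeros(N_BINS)
    if filtered_ilfp is not None:
        if fs is None:
            raise ValueError("fs required with a signal")
        sig = np.asarray(filtered_ilfp, dtype=float)
        per_peak = np.zeros((len(peaks), N_BINS))
        tgrid = (np.arange(N_BINS) + 0.5) / N_BINS
        for i, p in enumerate(peaks):
            sample_t = p.start_s + tgrid * p.duration_s
            per_peak[i] = np.interp(sample_t * fs, np.arange(sig.size), sig)
        amp = per_peak.mean(axis=0)
    median = float(np.median(u)) if u.size else None
    return PeakAlignedHistogram(
        counts=counts,
        mean_amplitude=amp,
        median_firing_time=median,
        n_peaks=len(peaks),
        n_spikes_in_peaks=int(u.size),
    )


def compare_firing_times(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis / Dunn comparison of per-neuron median firing
    times between cell populations."""
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2 or any(a.size < 3 for a in arrs):
        raise ValueError("need >= 2 groups with >= 3 neurons each")
    return kruskal_wallis_dunn(arrs)


def compare_peak_properties(
    duration_groups: list[np.ndarray] | None = None,
    amplitude_groups: list[np.ndarray] | None = None,
) -> dict[str, TestResult]:
    """Control comparisons of peak durations / amplitudes between the
    epochs used for different populations."""
    out = {}
    if duration_groups is not None:
        out["durations"] = kruskal_wallis_dunn(duration_groups)
    if amplitude_groups is not None:
        out["amplitudes"] = kruskal_wallis_dunn(amplitude_groups)
    if not out:
        raise ValueError("nothing to compare")
    return out
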