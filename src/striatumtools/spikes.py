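"""Single-neuron spike-train and waveform features.

Covers mean firing rate, log-spaced ISI histograms and their pairwise
Spearman correlation (firing-pattern similarity), the local-variability
statistic CV2 with its derived ratio feature, log-ISI percentiles, and
the D1/D2 segmentation of the mean spike waveform.

CV2 for consecutive inter-spike intervals is

    CV2_i = 2 |ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i)

which is 0 for a perfectly regular train and has mean 1 for a Poisson
train.  The CV2 ratio compares the proportion of CV2 values below 0.2
(regular stretches) with the proportion above 1.85 (abrupt changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import spearman_rho

#: default log-spaced ISI histogram edges: 100 bins, 1 ms to 10 s
DEFAULT_ISI_EDGES = np.logspace(-3, 1, 101)

CV2_LOW = 0.2
CV2_HIGH = 1.85
MIN_EPOCH_S = 60.0


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) within an epoch, with brain state and identity.

    ``state`` is ``"swa"`` (slow-wave activity, ~1 Hz cortical slow
    oscillation present) or ``"activation"``.  ``identity`` is a
    molecular marker combination label such as ``"PV+/Scgn+"``.
    """

    times: np.ndarray
    epoch: tuple[float, float]
    state: str = "swa"
    identity: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", t)
        t0, t1 = self.epoch
        if not t1 > t0:
            raise ValueError("epoch must have positive length")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < t0 or t[-1] > t1):
            raise ValueError("spike times must lie within the epoch")

    @property
    def duration(self) -> float:
        return self.epoch[1] - self.epoch[0]

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        if self.n_spikes < 2:
            raise ValueError("need at least 2 spikes for ISIs")
        return np.diff(self.times)

    def meets_epoch_minimum(self, min_s: float = MIN_EPOCH_S) -> bool:
        return self.duration >= min_s


@dataclass(frozen=True)
class ISIHistogram:
    bin_edges: np.ndarray
    percent_count: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "percent_count", np.asarray(self.percent_count, dtype=float))
        if self.percent_count.size != self.bin_edges.size - 1:
            raise ValueError("percent_count must have len(bin_edges) - 1 entries")


@dataclass(frozen=True)
class WaveformSegments:
    """D1/D2 split of a mean spike waveform, in milliseconds.

    D1 is baseline-departure to the deflection extremum, D2 the
    extremum back to a sustained return within the baseline band.
    ``d2_ms`` is None (flagged) when the waveform never returns.
    """

    d1_ms: float
    d2_ms: float | None

    @property
    def total_ms(self) -> float | None:
        return None if self.d2_ms is None else self.d1_ms + self.d2_ms


def firing_rate(t: SpikeTrain) -> float:
    """Mean firing rate: spike count divided by epoch duration (spikes/s)."""
    return t.n_spikes / t.duration


def isi_histogram(t: SpikeTrain, edges: np.ndarray = DEFAULT_ISI_EDGES) -> ISIHistogram:
    """Percent-count ISI histogram over log-spaced bins.

    ISIs outside the edge range accumulate in the boundary bins so the
    histogram always sums to 100 when at least one ISI exists.
    """
    edges = np.asarray(edges, dtype=float)
    isis = t.isis()
    centers_clip = np.clip(isis, np.nextafter(edges[0], np.inf), np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(centers_clip, bins=edges)
    return ISIHistogram(bin_edges=edges, percent_count=100.0 * counts / counts.sum())


def isi_pair_correlation(h_a: ISIHistogram, h_b: ISIHistogram) -> float:
    """Spearman correlation between two neurons' ISI histograms.

    High rho means similar firing patterns.  Requires identical bins.
    """
    if not np.array_equal(h_a.bin_edges, h_b.bin_edges):
        raise ValueError("ISI histograms have mismatched bin edges")
    return spearman_rho(h_a.percent_count, h_b.percent_count)


def cv2_series(t: SpikeTrain) -> np.ndarray:
    """CV2 value for each consecutive ISI pair."""
    isis = t.isis()
    if isis.size < 2:
        raise ValueError("need at least 2 ISIs for CV2")
    return 2.0 * np.abs(np.diff(isis)) / (isis[1:] + isis[:-1])


def cv2_features(t: SpikeTrain) -> dict:
    """CV2 summary features and the classical coefficient of variation.

    Returns a dict with ``cv2_mean``, the smoothed ``cv2_ratio``
    (#{CV2 < 0.2} + 1) / (#{CV2 > 1.85} + 1) used as a clustering
    feature, the unsmoothed ratio (inf when no CV2 exceeds 1.85), and
    ``cv_isi`` = sd(ISI)/mean(ISI).
    """
    series = cv2_series(t)
    isis = t.isis()
    n_low = int(np.sum(series < CV2_LOW))
    n_high = int(np.sum(series > CV2_HIGH))
    p_low = n_low / series.size
    p_high = n_high / series.size
    return {
        "cv2_series": series,
        "cv2_mean": float(np.mean(series)),
        "cv2_ratio": (n_low + 1) / (n_high + 1),
        "cv2_ratio_unsmoothed": p_low / p_high if n_high else float("inf"),
        "cv_isi": float(np.std(isis, ddof=1) / np.mean(isis)) if isis.size > 1 else 0.0,
    }


def log_isi_percentile(t: SpikeTrain, q: float) -> float:
    """log10 of the linearly interpolated q-th ISI percentile (seconds)."""
    isis = t.isis()
    return float(np.log10(np.percentile(isis, q, method="linear")))


def feature_record(t: SpikeTrain) -> dict:
    """The full per-neuron feature vector used downstream in clustering."""
    feats = cv2_features(t)
    p10, p50, p85 = (log_isi_percentile(t, q) for q in (10, 50, 85))
    assert p10 <= p50 <= p85
    return {
        "rate": firing_rate(t),
        "log_isi_p10": p10,
        "log_isi_p50": p50,
        "log_isi_p85": p85,
        "cv_isi": feats["cv_isi"],
        "cv2_mean": feats["cv2_mean"],
        "cv2_ratio": feats["cv2_ratio"],
    }


def waveform_segments(
    w: np.ndarray,
    fs: float,
    baseline_samples: int,
    k: float = 3.0,
    sustained: int = 3,
) -> WaveformSegments:
    """Segment a mean spike waveform into D1 (baseline-to-peak) and D2
    (peak-to-baseline) durations.

    The baseline is the mean of the first ``baseline_samples``
    (pre-trigger) samples; departure/return use a band of ``k`` baseline
    standard deviations, with a return requiring ``sustained``
    consecutive in-band samples.  If the waveform never returns to the
    baseline band, D2 is flagged undefined (None).
    """
    w = np.asarray(w, dtype=float).ravel()
    if baseline_samples < 2 or baseline_samples >= w.size:
        raise ValueError("baseline window must contain >= 2 samples and precede the spike")
    base = w[:baseline_samples]
    mu = float(np.mean(base))
    sd = float(np.std(base))
    band = max(k * sd, 1e-12 * max(1.0, float(np.max(np.abs(w - mu)))))
    dev = np.abs(w - mu)
    out = dev > band
    post = out[baseline_samples:]
    if not np.any(post):
        raise ValueError("no deflection beyond the baseline band after the trigger")
    first_out = baseline_samples + int(np.argmax(post))
    # last in-band sample before the deflection = baseline departure
    departure = first_out - 1 if first_out > 0 else 0
    peak = int(np.argmax(dev[first_out:])) + first_out
    d1_ms = 1000.0 * (peak - departure) / fs
    inband = ~out[peak:]
    d2_ms = None
    if inband.size >= sustained:
        runs = np.convolve(inband.astype(int), np.ones(sustained, dtype=int), mode="valid")
        hits = np.nonzero(runs == sustained)[0]
        if hits.size:
            d2_ms = 1000.0 * hits[0] / fs
    return WaveformSegments(d1_ms=d1_ms, d2_ms=d2_ms)
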