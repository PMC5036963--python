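# Methods

This note documents the models and procedures implemented in
`striatumtools`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Statistics core

All inference is nonparametric. Mann–Whitney U uses exact enumeration
when both groups have n ≤ 8 and the pooled sample is tie-free, and the
normal approximation with tie and continuity correction otherwise. The
Wilcoxon signed-rank test against zero drops exact zeros before ranking
(Wilcoxon's convention); an all-zero input returns a flagged degenerate
result with p = 1. Kruskal–Wallis is followed by Dunn's z-test on
pooled mean ranks with the Σ(t³−t) tie correction; pairwise p-values
are reported both raw and BH-adjusted, and downstream significance
conventions use the raw values (the post-hoc adjustment choice is
genuinely open; both are exposed). Fisher's exact test reports the
two-sided hypergeometric point-probability p together with the sample
odds ratio (flagged 0/∞ with a zero cell) and the conditional-MLE odds
ratio, which remains finite more often. FDR control is
Benjamini–Hochberg step-up. Spearman correlation uses average ranks for
ties and returns NaN for a constant input, where rank correlation is
undefined.

Small-sample exactness matters here because per-plane anatomical
comparisons routinely involve 6–20 neurons.

## Stereology

The optical disector counts a nucleus iff its top depth d satisfies
guard < d ≤ guard + depth, with the boundary case d = guard excluded
(already in focus at the top of the probe). Defaults: 420 × 320 µm
frame, 10 µm depth, 2 µm guard. Internal units are µm; volumes are
reported in mm³.

The Cavalieri estimator is V(ref) = a(p) · t · ΣP. The coefficient of
error uses the Gundersen–Jensen systematic-sampling formula at
smoothness class m = 1 with the point-count nugget:

    VarSURS = (3(A − ΣP) − 4B + C) / 240,   CE = sqrt(VarSURS + ΣP) / ΣP

with A = ΣPᵢ², B = ΣPᵢPᵢ₊₁, C = ΣPᵢPᵢ₊₂. Commercial stereology packages
do not document their exact variant; m = 1 with the ΣP nugget is the
standard modern choice and is validated against an independent oracle
implementation in the tests. With equal counts per section the CE
reduces to the pure point noise 1/√ΣP.

## Topography

A neuron's normalized position is computed per axis from the *first*
polygon-boundary crossings of the axis-aligned line through the neuron,
so in irregular or non-convex contours the effective "medial" and
"lateral" borders shift with the neuron's position on the other axis.
The coordinate is the linear position between the two crossings mapped
to [−1, 1]; the sign convention (+1 = lateral, +1 = dorsal) is carried
as contour metadata since only the range, not the sign, is canonical.
Points exactly on the boundary are rejected (measure zero, and the
mapping is ambiguous there). Crossings use a half-open edge rule so a
line through a vertex is counted once; the implementation is a
vectorized edge scan validated to 1e-9 against an independent
shapely-based segment-intersection oracle, including on notched
non-convex contours.

Planes with ≤ 5 neurons are skipped with an explicit record rather than
tested. The cross-plane variability statistic for plane s is
d_s = mean over s′ ≠ s of |m_s − m_s′| by default; the alternative
reading |mean(m_s − m_s′)| is available via `mode="abs_mean"`. The
default is chosen because the statistic is meant to be sensitive to a
drifting mean position and the absolute-difference form keeps opposite
drifts from cancelling.

## Spike-train features

Epochs of at least 60 s are the intended analysis unit. ISI histograms
use 100 log-spaced bins from 1 ms to 10 s by default (configurable);
out-of-range intervals accumulate in the boundary bins so the
percent-count always sums to 100. CV2 is 2|ISIᵢ₊₁ − ISIᵢ|/(ISIᵢ₊₁ +
ISIᵢ); the clustering feature "CV2 ratio" is the smoothed
(#{CV2 < 0.2} + 1)/(#{CV2 > 1.85} + 1) so that perfectly regular trains
yield a finite feature, with the unsmoothed ratio reported alongside.
For a Poisson train, ISIᵢ₊₁/(ISIᵢ + ISIᵢ₊₁) is Uniform(0,1), so CV2 =
2|2U − 1| has mean 1, P(CV2 < 0.2) = 0.1 and P(CV2 > 1.85) = 0.075,
giving an unsmoothed ratio of 4/3 — used as a closed-form check.
Percentiles are linearly interpolated between order statistics.

Waveform segmentation defines the baseline as the mean of the
pre-trigger window and a band of k = 3 baseline SDs (configurable);
D1 runs from the last in-band sample before the deflection to the
global deflection extremum, D2 from the extremum to the first run of 3
consecutive in-band samples. A waveform that never returns to the band
gets a flagged undefined D2 rather than a fabricated value.

## Phase locking

The filterbank has geometrically spaced centers c_k = f_lo ·
(f_hi/f_lo)^(k/(n−1)) with n = 107 spanning 1–80 Hz. Band edges are
proportional, [c/1.5, 1.5c]: a literal "center ± 1.5 × center" width
would produce negative lower edges, so the proportional-bandwidth
reading is used — it preserves both the stated overlap and the
increasing widths, and the ratio is configurable. Filtering is a
2nd-order Butterworth applied forward–backward (zero phase; doubles the
effective order), then the Hilbert analytic signal; with this
convention cos-like oscillation peaks are at 0° and troughs at ±180°.
Spike phases are read at the nearest sample (≤ 30 µs error at the
16.6 kHz acquisition rate this emulates; linear interpolation is
available for low sampling rates).

Below 5 Hz, slow oscillations are non-sinusoidal, so the signal spends
unequal time at different phases and even rate-independent spikes show
spurious phase concentration. The correction maps each spike phase
through the empirical CDF of *all* signal phase samples in the band,
θ′ = 2πF(θ) − π: a monotone, rank-preserving transform that makes the
phases of rate-independent spikes uniform by construction. The
alternative (correcting against a surrogate spike-phase distribution)
was considered and rejected as noisier for no benefit.

Rayleigh's test uses Z = nR² with the standard finite-n corrected
p-value. The ≥ 40-spike inclusion gate is enforced in the per-neuron
profile (bands below the gate are marked untested), not in the raw test
function, which remains usable for small constructed examples. Three
gamma-range conventions are shipped as named presets (30–80, 27–45,
30–48 Hz) because all three ranges are in active use for different
purposes (figure summaries, slow-wave-state characterization, and the
clustering feature respectively).

## Peak-aligned firing

The LFP is inverted so that peaks correspond to synchronized
up states, then bandpass filtered at 0.4–1.6 Hz (zero-phase, 2nd
order). Peaks are full Hilbert-phase cycles between troughs, located as
crossings of odd multiples of π on the unwrapped phase — not amplitude
minima — with sub-sample interpolation. Durations outside
[0.625 s, 2.5 s] (the filter corner periods) are discarded, as are
incomplete cycles at epoch edges. Spikes inside retained peaks map to
u = 2(t − start)/duration − 1 and accumulate over 100 equal bins on
[−1, 1]; a spike exactly on a trough boundary belongs to the peak
beginning there. The per-neuron summary is the median u; populations
are compared by Kruskal–Wallis/Dunn on those medians, with peak
durations and amplitudes comparable as controls. The per-bin iLFP
amplitude profile is computed on the filtered signal (configurable to
raw by passing that signal instead).

## Cluster-number inference

Features are Ward-linked; heights are reported on the squared-Euclidean
scale, matching Ward's within-cluster-variance objective (the monotone
rescaling does not affect merge order). Real mixed-unit feature tables
are z-scored by default so that no single parameter (e.g. firing rate)
dominates the distance; a raw-scale mode exists for feature matrices
already on a common scale, and the synthetic benchmark uses it because
its features share a unit noise scale by construction (z-scoring there
would shrink exactly the separated columns and quietly reduce the
generated separation).

Candidate cluster counts k correspond to gaps between successive merge
heights: cutting between h_{n−k} and h_{n−k+1} yields k clusters. The
null is built from surrogates in which every feature column is
independently permuted across neurons — destroying joint structure
while preserving every marginal. Three referral modes are provided:

- `max` (default): each real gap is compared with the distribution of
  each surrogate's *largest* gap. The smallest selected p-value is then
  exactly uniform under a column-exchangeable null, so the procedure's
  false-positive rate is controlled at α even though many gaps are
  examined.
- `by_rank`: gap at k versus surrogate gaps at the same k. This is the
  most literal per-gap reading but, combined with lowest-p selection,
  it takes a minimum over ~n dependent uniform p-values and rejects on
  unstructured data almost always; it is provided for comparison, not
  as the default.
- `pooled`: real gaps versus all surrogate gaps pooled.

The cut is the midpoint of the two heights bracketing the winning gap
(lowest p < α; ties broken toward the larger gap); if no gap beats α
the result is zero significant clusters and all rows share one label.
Two feature presets mirror the two anesthesia brain states: the
slow-wave-activity set {log ISI p10, CV ISI, CV2 ratio, iLFP-peak
median time, slow/spindle/gamma vector lengths} (7 features, with a
6-feature variant omitting CV ISI, since both rosters are in
circulation) and the cortical-activation set {log ISI p10/p50/p85,
rate, CV2 ratio, CV2 mean}.

Known limitation: at moderate separations greedy Ward agglomeration
occasionally commits a few boundary points to the wrong branch even
when every point is nearest its own cluster centroid; on the synthetic
benchmark (3 clusters, centers 5 SD apart, n = 60 in 6-D) the correct
cluster *count* is recovered essentially always, while label purity has
median ≈ 0.97 and falls below 0.95 in roughly 15% of random draws. The
permutation null is also mildly conservative when cluster structure is
strongly axis-aligned, because column shuffling then preserves
marginal multimodality.

## Synthetic data

Generators are deterministic given a seed and are first-class, tested
code. Contours are superellipses (optionally notched to exercise the
non-convex first-crossing logic) arranged in a waxing-and-waning
rostro-caudal series of 13 planes. Biased point clouds draw target
normalized coordinates from Beta distributions mapped onto (−1, 1)
(mean = the requested bias, concentration 5 by default — chosen so
per-plane spreads resemble real per-plane scatter) and place points by
inverting the ray parametrization with an alternating fixed-point
iteration; recovery through the forward mapping is exact to 1e-9.

Field signals sum a ~1 Hz slow wave, narrowband spindle (7–12 Hz) and
gamma components (filtered noise), and 1/f noise; default sampling is
1 kHz for desk-scale runs, with the 16.6 kHz acquisition rate available.
Waveform skew passes the slow sinusoid through the monotone shaper
(exp(κs) − 1)/κ, which preserves the period but sharpens peaks, making
the slow band's phase occupancy non-uniform — the regime the ECDF
correction exists for. Note the analysis bandpass removes most of the
injected harmonics, so the residual occupancy bias is moderate; the
demonstration scenario (skew 4, 400 spikes per epoch) produces an
uncorrected Rayleigh false-positive rate around 0.4 against a corrected
rate at nominal α.

Locked spike trains are inhomogeneous Poisson with intensity ∝
exp(κ·cos(θ(t) − µ)) normalized to the target rate (time-rescaling
construction), so the spike phase distribution is von Mises and the
expected vector length is I₁(κ)/I₀(κ). Peak-timed trains place
Poisson-many spikes per retained peak at truncated-Gaussian normalized
times. Feature clusters put unit-variance Gaussians at simplex vertices
scaled so every pairwise center distance equals the requested
separation, with identity labels agreeing with the true labels at a
controllable rate. Stereology fixtures provide uniform nucleus-top
depths at a target density and randomly offset point-grid counts over
an analytic ellipsoid.

What the generators do *not* emulate: biophysical membrane dynamics,
state transitions within an epoch, electrode drift and spike-sorting
contamination, anatomically accurate striatal outlines, and
correlations between anatomy and physiology across modalities. Passing
tests therefore demonstrate correctness of the estimators and the
stated statistical operating characteristics under clean conditions,
not robustness to every artifact of real recordings.

## Problem sizes and tolerances

Simulation-based tests and the acceptance script use desk-scale
problem sizes chosen as the smallest that make the checked property
statistically sharp: 250 Hz synthetic sampling for slow-band analyses,
60–250 s epochs, ~2000 spikes for vector-length recovery (±0.05 of the
Bessel ratio), 500–1000 repetitions for error-rate estimates (bands
[0.03, 0.07] at α = 0.05), 100 seeded runs for unbiasedness checks
(within 2 SE), 1000 surrogates and 20 seeds for cluster-number
recovery, and 10⁢–10³ Monte-Carlo repetitions elsewhere. Numerical
tie-breaks and degenerate-input behavior (empty groups, all-zero
counts, constant features, never-returning waveforms, epochs with no
complete oscillation peak) are defined explicitly in each module and
exercised by the tests.
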