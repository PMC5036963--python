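# striatumtools

Quantitative methods for splitting striatal parvalbumin-expressing (PV+)
interneurons into molecularly defined subpopulations — PV+/Scgn+ versus
PV+/Scgn− — from anatomy and in vivo electrophysiology, implemented as a
tested, reusable Python library and exercised end-to-end on synthetic
data with known ground truth.

## Who this is for

Systems neuroscientists quantifying (a) how many neurons of a given
molecular type a structure contains and where they sit within it, and
(b) how identified single neurons fire relative to ongoing cortical and
striatal population activity. The package covers the full analysis
chain:

- **stereology** — optical-disector counting (a cell is counted when the
  top of its nucleus first comes into focus inside a 420 × 320 × 10 µm
  probe below a 2 µm guard zone), densities, the Cavalieri volume
  estimator *V*(ref) = a(p)·t·ΣP, total numbers *N* = N_V·*V*(ref), and
  the Gundersen–Jensen coefficient of error.
- **topography** — each neuron in a coronal contour gets mediolateral
  and dorsoventral coordinates in [−1, 1] by ray-casting to the *first*
  contour crossing on either side (0 = equidistant from the borders);
  per-plane Wilcoxon bias tests, between-population Mann–Whitney tests
  with Benjamini–Hochberg FDR across planes, and a cross-plane
  variability statistic.
- **spikes** — firing rate, log-spaced ISI histograms and their pairwise
  Spearman similarity, log-ISI percentiles, the local variability
  statistic CV2ᵢ = 2|ISIᵢ₊₁ − ISIᵢ|/(ISIᵢ₊₁ + ISIᵢ) with its derived
  ratio feature, and D1/D2 spike-waveform segmentation.
- **phase** — spike–field phase locking across a 107-band geometric
  filterbank (1–80 Hz), zero-phase Butterworth filtering + Hilbert
  analytic phase (peak = 0°, trough = 180°), vector length *R*, Rayleigh
  uniformity test (*Z* = n·R²), and ECDF phase correction below 5 Hz for
  non-sinusoidal slow oscillations.
- **peaks** — the inverted striatal LFP (iLFP) is filtered at 0.4–1.6 Hz
  and segmented into trough-to-trough peaks (admissible durations
  0.625–2.5 s, the filter corner periods); spikes are mapped onto 100
  normalized time bins from −1 to 1 and populations are compared by the
  median normalized firing time.
- **clustering** — Ward linkage on squared Euclidean distances with a
  resampling variant of Thorndike's criterion: merge-height gaps are
  referred to a null from 10 000 column-permutation surrogates, the gap
  with the lowest p < 0.05 sets the cut, and *zero* significant clusters
  is an allowed outcome.
- **synthetic** — deterministic generators for every input above:
  striatum-like contours with biased point clouds, oscillatory field
  signals (slow/spindle/gamma + 1/f noise, optionally skewed),
  phase-locked and peak-timed inhomogeneous-Poisson spike trains,
  Gaussian feature clusters, and stereology fixtures.

## Worked example

```bash
python examples/phase_locking_profile.py
```

generates a 120 s slow-wave-state field signal, a spike train locked to
its ~1 Hz component with von Mises concentration κ = 2, and prints the
locking profile:

```
961 spikes over 120 s
    0.80 Hz  R = 0.682  Rayleigh p = 9.47e-225 *
    0.97 Hz  R = 0.683  Rayleigh p = 2.84e-225 *
    ...
    3.59 Hz  R = 0.003  Rayleigh p = 9.94e-01
    ...
   49.73 Hz  R = 0.018  Rayleigh p = 7.23e-01
slow-band vector length 0.683 (von Mises expectation I1(2)/I0(2) = 0.698), mean phase 2 deg
```

Significant bands (`*`) concentrate around the 1 Hz oscillation the
spikes were locked to; spindle and gamma bands stay at chance; the
slow-band vector length recovers the Bessel-ratio expectation
I₁(κ)/I₀(κ) set by the generator, with the mean phase at the oscillation
peak. The other scripts in `examples/` walk through stereological
estimation, topographic bias detection, normalized-time firing
comparison, cluster-number inference and spike-feature extraction the
same way.

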