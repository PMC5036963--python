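"""Compare firing times of two populations on the normalized iLFP scale.

Simulates a striatal LFP during slow-wave activity, segments the
inverted signal into trough-to-trough peaks (duration-gated to
0.625-2.5 s), generates one population firing early in the peak
(mu* = -0.3) and one near the peak center (mu* = +0.1), and compares
their median normalized firing times.
"""

import numpy as np

from striatumtools.peaks import (
    compare_firing_times, invert_and_filter, normalized_histogram, segment_peaks,
)
from striatumtools.synthetic import simulate_field, simulate_peak_timed_train

sig = simulate_field(duration=150.0, fs=250.0, seed=0, channel="lfp")
filtered = invert_and_filter(sig.samples, sig.fs)
peaks = segment_peaks(filtered, sig.fs)
durations = [p.duration_s for p in peaks]
print(f"{len(peaks)} retained iLFP peaks, mean duration {np.mean(durations):.2f} s")

groups = []
for mu, base in ((-0.3, 100), (0.1, 200)):
    medians = []
    for i in range(15):
        tr = simulate_peak_timed_train(peaks, mu_star=mu, sigma_star=0.1,
                                       spikes_per_peak=4.0, seed=base + i)
        medians.append(normalized_histogram(tr, peaks).median_firing_time)
    groups.append(np.array(medians))
    print(f"population at mu* = {mu:+.1f}: median firing times "
          f"{np.median(medians):+.3f} (n = 15 neurons)")

res = compare_firing_times(groups)
print(f"Kruskal-Wallis p = {res.p_value:.2e}")
# The early-firing population's medians sit near -0.3 and the late one
# near +0.1; the omnibus test separates them decisively, mirroring an
# early- vs late-firing cell-type comparison during up states.
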