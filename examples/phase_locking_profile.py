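"""Spike-field phase locking of a simulated slow-oscillation-locked neuron.

Generates a slow-wave-state field signal, a spike train phase-locked to
its ~1 Hz component (von Mises concentration kappa = 2), and profiles
locking across a geometric filterbank: vector length, mean phase and
Rayleigh significance per band, with ECDF phase correction below 5 Hz.
"""

import numpy as np
from scipy.special import i0, i1

from striatumtools.phase import BAND_PRESETS, band_locking, build_filterbank, locking_profile
from striatumtools.synthetic import simulate_field, simulate_locked_train

sig = simulate_field(duration=120.0, fs=250.0, seed=0)
train = simulate_locked_train(sig, (0.6, 1.6), rate=8.0, kappa=2.0, seed=1)
print(f"{train.n_spikes} spikes over {sig.duration:.0f} s")

fb = build_filterbank(n=24, f_lo=0.8, f_hi=60.0)
prof = locking_profile(train, sig, fb)
for c, r, p in zip(fb.centers, prof.vector_length, prof.rayleigh_p):
    flag = "*" if p < 0.05 else " "
    print(f"  {c:6.2f} Hz  R = {r:.3f}  Rayleigh p = {p:.2e} {flag}")

slow = band_locking(train, sig, BAND_PRESETS["slow"])
print(f"slow-band vector length {slow['vector_length']:.3f} "
      f"(von Mises expectation I1(2)/I0(2) = {i1(2)/i0(2):.3f}), "
      f"mean phase {slow['mean_phase_deg']:.0f} deg")
# Significant bands (*) concentrate around 1 Hz where the locking was
# generated; gamma bands stay at chance. The slow-band vector length
# recovers the Bessel ratio set by kappa.
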