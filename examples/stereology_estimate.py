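"""Estimate total neuron number from disector counts and a Cavalieri volume.

Simulates nucleus-top depths in a 50 um tissue slab at a known density,
counts them with the 420 x 320 x 10 um optical disector (2 um guard
zone), estimates the striatal reference volume of an ellipsoid phantom
by Cavalieri point counting, and combines both into N = Nv * V(ref)
with the Gundersen coefficient of error.
"""

from striatumtools.stereology import (
    CavalieriInput, DisectorSpec, cavalieri_volume, disector_density,
    gundersen_ce, total_number,
)
from striatumtools.synthetic import (
    ellipsoid_volume, simulate_nucleus_stack, simulate_point_grid,
)

TRUE_DENSITY = 8000.0  # cells / mm^3

depths = simulate_nucleus_stack(TRUE_DENSITY, slab_um=50.0, seed=0)
count, nv = disector_density(depths, DisectorSpec())
print(f"disector count: {count} nuclei -> Nv = {nv:.0f} cells/mm^3 "
      f"(truth {TRUE_DENSITY:.0f})")

axes = (2.0, 1.5, 1.0)  # mm; analytic volume 4*pi*abc/3 = 12.566 mm^3
counts = simulate_point_grid(axes, a_p_mm2=0.01, t_mm=0.2, seed=1)
cav = CavalieriInput(tuple(counts), area_per_point=0.01, section_spacing=0.2)
v_ref = cavalieri_volume(cav)
print(f"Cavalieri V(ref) = {v_ref:.3f} mm^3 (analytic {ellipsoid_volume(axes):.3f}), "
      f"CE = {gundersen_ce(counts):.4f}")

n_total = total_number(nv, v_ref)
print(f"estimated total N = Nv * V(ref) = {n_total:.0f} cells")
# Nv recovers the simulated density within sampling error; the CE (~0.01)
# says the systematic point count alone contributes ~1% error to V(ref).
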