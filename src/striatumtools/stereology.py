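"""Design-based stereology: optical disector counts, densities, Cavalieri
volumes and the Gundersen coefficient of error.

The optical disector counts a cell when the top of its nucleus first
comes into focus inside a probe of fixed depth placed below a guard
zone; a nucleus already in focus at the top of the probe is excluded.
Total numbers follow N = Nv * V(ref), where Nv is the numerical density
and V(ref) the reference volume from the Cavalieri point-counting
estimator V(ref) = a(p) * t * sum(P).

Canonical internal units are micrometres; volumes are reported in mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class DisectorSpec:
    """Geometry of the optical disector probe.

    Defaults: 420 x 320 um counting frame, 10 um probe depth, 2 um guard
    zone below the section's upper surface.
    """

    frame_width_um: float = 420.0
    frame_height_um: float = 320.0
    depth_um: float = 10.0
    guard_um: float = 2.0

    def __post_init__(self):
        for v in (self.frame_width_um, self.frame_height_um, self.depth_um, self.guard_um):
            if v <= 0 and v != 0.0:
                raise ValueError("disector dimensions must be positive")
        if self.depth_um <= 0:
            raise ValueError("disector depth must be positive")
        if self.guard_um < 0:
            raise ValueError("guard zone cannot be negative")

    @property
    def frame_area_um2(self) -> float:
        return self.frame_width_um * self.frame_height_um

    @property
    def probe_volume_um3(self) -> float:
        return self.frame_area_um2 * self.depth_um


@dataclass(frozen=True)
class CavalieriInput:
    """Point counts on systematic sections for the Cavalieri estimator.

    ``area_per_point`` and ``section_spacing`` must be in consistent
    units (both mm-based or both um-based).
    """

    point_counts_per_section: tuple
    area_per_point: float  # mm^2 (or um^2 with matching spacing units)
    section_spacing: float  # mm (or um)

    def __post_init__(self):
        counts = np.asarray(self.point_counts_per_section)
        if counts.size == 0:
            raise ValueError("no sections")
        if np.any(counts < 0) or not np.all(counts == counts.astype(int)):
            raise ValueError("point counts must be nonnegative integers")
        if self.area_per_point <= 0 or self.section_spacing <= 0:
            raise ValueError("area_per_point and section_spacing must be positive")


@dataclass(frozen=True)
class DensityEstimate:
    count: int
    volume_mm3: float
    nv_per_mm3: float
    total_n: float
    ce: float


def apply_disector_rule(
    nucleus_top_depths_um: Sequence[float], spec: DisectorSpec = DisectorSpec()
) -> np.ndarray:
    """Select the nucleus-top depths counted by the optical disector.

    A nucleus is counted iff its top lies strictly below the guard zone
    and within the probe: depth in (guard, guard + depth].  A top exactly
    at the guard boundary is already in focus at the top of the probe and
    is excluded.

    Parameters
    ----------
    nucleus_top_depths_um : sequence of float
        Depths of nucleus tops measured from the section's upper
        surface, in micrometres (all >= 0).
    """
    d = np.asarray(nucleus_top_depths_um, dtype=float).ravel()
    if np.any(d < 0):
        raise ValueError("nucleus depths must be nonnegative")
    lo = spec.guard_um
    hi = spec.guard_um + spec.depth_um
    return d[(d > lo) & (d <= hi)]


def disector_density(
    nucleus_top_depths_um: Sequence[float],
    spec: DisectorSpec = DisectorSpec(),
    n_frames: int = 1,
) -> tuple[int, float]:
    """Count nuclei under the disector rule and convert to a density.

    Returns ``(count, nv_per_mm3)`` where the density refers to the
    total probe volume of ``n_frames`` disector frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    counted = apply_disector_rule(nucleus_top_depths_um, spec)
    volume_mm3 = n_frames * spec.probe_volume_um3 / UM3_PER_MM3
    return counted.size, counted.size / volume_mm3


def cavalieri_volume(c: CavalieriInput) -> float:
    """Cavalieri volume estimate V(ref) = a(p) * t * sum(P)."""
    total_points = float(np.sum(c.point_counts_per_section))
    return c.area_per_point * c.section_spacing * total_points


def total_number(nv: float, v_ref: float) -> float:
    """Estimated total cell number N = Nv * V(ref) (no rounding)."""
    if nv < 0 or v_ref < 0:
        raise ValueError("density and volume must be nonnegative")
    return nv * v_ref


def gundersen_ce(point_counts_per_section: Sequence[float]) -> float:
    """Gundersen-Jensen coefficient of error for systematic point counts.

    Smoothness class m = 1 with the sum(P) nugget for point-counting
    noise:

        VarSURS = (3*(A - sum(P)) - 4*B + C) / 240
        CE      = sqrt(VarSURS + sum(P)) / sum(P)

    where A = sum(P_i^2), B = sum(P_i * P_{i+1}), C = sum(P_i * P_{i+2}).
    Requires at least 3 sections; all-zero counts are undefined.
    """
    p = np.asarray(point_counts_per_section, dtype=float).ravel()
    if p.size < 3:
        raise ValueError("Gundersen CE needs at least 3 sections")
    if np.any(p < 0):
        raise ValueError("point counts must be nonnegative")
    total = float(np.sum(p))
    if total == 0:
        raise ValueError("CE undefined for all-zero counts")
    a = float(np.sum(p * p))
    b = float(np.sum(p[:-1] * p[1:]))
    c = float(np.sum(p[:-2] * p[2:]))
    var_surs = (3.0 * (a - total) - 4.0 * b + c) / 240.0
    return math.sqrt(max(var_surs, 0.0) + total) / total


def estimate(
    count: int,
    disector_volume_mm3: float,
    cavalieri: CavalieriInput,
) -> DensityEstimate:
    """End-to-end stereological estimate for one marker and animal.

    Combines a disector count within a known probe volume with the
    Cavalieri reference volume into Nv, N and the Gundersen CE.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    if disector_volume_mm3 <= 0:
        raise ValueError("disector volume must be positive")
    v_ref = cavalieri_volume(cavalieri)
    nv = count / disector_volume_mm3
    return DensityEstimate(
        count=count,
        volume_mm3=v_ref,
        nv_per_mm3=nv,
        total_n=total_number(nv, v_ref),
        ce=gundersen_ce(cavalieri.point_counts_per_section),
    )
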