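"""Contour-normalized neuron positions and spatial-bias statistics.

Each neuron inside a coronal contour polygon is assigned a mediolateral
(ml) and dorsoventral (dv) coordinate in [-1, 1] by casting axis-aligned
rays from the neuron to the *first* contour crossing in each direction:
0 means equidistant from the two borders hit by the ray, +1 sits on the
lateral (or dorsal) border.  Because the rays use the first crossing,
the effective "medial"/"lateral" borders shift with the neuron's
position in irregular, possibly non-convex contours.

Per-plane bias is tested with the Wilcoxon signed-rank test against 0,
two populations are compared per plane with the Mann-Whitney U test with
BH-FDR across planes, and the rostro-caudal variability of per-plane
means is summarized by the mean absolute pairwise difference statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import (
    TestResult,
    fdr_adjust,
    kruskal_wallis_dunn,
    mann_whitney,
    wilcoxon_signed_vs_zero,
)

#: planes with this many neurons or fewer are skipped, not tested
MIN_NEURONS_PER_PLANE = 6  # i.e. analysis requires > 5 neurons


@dataclass(frozen=True)
class PlaneContour:
    """Closed, simple polygon delineating one coronal plane.

    ``lateral_dir``/``dorsal_dir`` give the sign convention: +1 means
    increasing x is lateral (increasing y is dorsal).  Coordinates are
    in micrometres; hemispheres are assumed pre-reflected so +x is
    always lateral under the default convention.
    """

    plane_id: str
    vertices: np.ndarray  # (n, 2), not necessarily repeated-first-vertex
    bregma_mm: float = 0.0
    lateral_dir: int = +1
    dorsal_dir: int = +1

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs at least 3 (x, y) vertices")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        object.__setattr__(self, "vertices", v)
        if self.lateral_dir not in (+1, -1) or self.dorsal_dir not in (+1, -1):
            raise ValueError("axis directions must be +1 or -1")

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        return v, np.roll(v, -1, axis=0)


@dataclass(frozen=True)
class NormalizedPosition:
    ml: float
    dv: float

    def __post_init__(self):
        if not (-1.0 <= self.ml <= 1.0 and -1.0 <= self.dv <= 1.0):
            raise ValueError("normalized coordinates must lie in [-1, 1]")


@dataclass
class SkipRecord:
    """Explicit record of an analysis skipped for an undersized plane."""

    plane_id: str
    n: int
    reason: str = "plane contains <= 5 neurons"


def _ray_crossings(contour: PlaneContour, px: float, py: float, axis: int) -> np.ndarray:
    """Sorted coordinates where the axis-aligned line through (px, py)
    crosses the polygon boundary.

    ``axis`` 0 casts a horizontal line (returns x of crossings at y=py),
    1 casts vertical (returns y of crossings at x=px).  Half-open edge
    rule so each vertex crossing is counted once.
    """
    a, b = contour.edges
    if axis == 0:
        c0, c1, o0, o1, pc = a[:, 1], b[:, 1], a[:, 0], b[:, 0], py
    else:
        c0, c1, o0, o1, pc = a[:, 0], b[:, 0], a[:, 1], b[:, 1], px
    hit = ((c0 <= pc) & (pc < c1)) | ((c1 <= pc) & (pc < c0))
    if not np.any(hit):
        raise ValueError("degenerate ray: no contour crossing")
    t = (pc - c0[hit]) / (c1[hit] - c0[hit])
    return np.sort(o0[hit] + t * (o1[hit] - o0[hit]))


def _first_crossings(crossings: np.ndarray, p: float) -> tuple[float, float]:
    """Nearest crossing below and above p along the ray."""
    below = crossings[crossings < p]
    above = crossings[crossings > p]
    if below.size == 0 or above.size == 0:
        raise ValueError("point is outside the contour (ray not bracketed)")
    return float(below[-1]), float(above[0])


def axis_interval(contour: PlaneContour, x: float, y: float, axis: int) -> tuple[float, float]:
    """The (low, high) border coordinates bracketing (x, y) along an axis.

    For a point inside the polygon these are the first contour crossings
    in the negative and positive directions.
    """
    p = x if axis == 0 else y
    return _first_crossings(_ray_crossings(contour, x, y, axis), p)


def point_in_contour(contour: PlaneContour, x: float, y: float) -> bool:
    """Even-odd ray-casting point-in-polygon test."""
    try:
        crossings = _ray_crossings(contour, x, y, 0)
    except ValueError:
        return False
    if np.any(np.isclose(crossings, x)):
        return False  # on the boundary: rejected by convention
    return int(np.sum(crossings < x)) % 2 == 1


def normalize_position(contour: PlaneContour, x: float, y: float) -> NormalizedPosition:
    """Map a neuron at (x, y) um to normalized (ml, dv) in [-1, 1].

    For each axis the neuron's coordinate is placed linearly between the
    first contour crossings on either side; the sign convention puts +1
    at the lateral / dorsal border per the contour's axis metadata.
    Raises if the neuron is outside or exactly on the contour.
    """
    if not point_in_contour(contour, x, y):
        raise ValueError(f"point ({x}, {y}) is not strictly inside contour {contour.plane_id}")
    x_lo, x_hi = axis_interval(contour, x, y, axis=0)
    y_lo, y_hi = axis_interval(contour, x, y, axis=1)
    ml = 2.0 * (x - x_lo) / (x_hi - x_lo) - 1.0
    dv = 2.0 * (y - y_lo) / (y_hi - y_lo) - 1.0
    return NormalizedPosition(ml=ml * contour.lateral_dir, dv=dv * contour.dorsal_dir)


def normalize_positions(
    contour: PlaneContour, xy: np.ndarray
) -> pd.DataFrame:
    """Vector convenience: normalize an (n, 2) array of positions."""
    xy = np.asarray(xy, dtype=float)
    rows = [normalize_position(contour, px, py) for px, py in xy]
    return pd.DataFrame({"ml": [r.ml for r in rows], "dv": [r.dv for r in rows]})


def invert_normalized(
    contour: PlaneContour,
    ml: float,
    dv: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Place a point whose normalized coordinates equal (ml, dv).

    Inverts the ray parametrization by alternating between axes: given a
    y, solve x from the horizontal chord; given that x, solve y from the
    vertical chord; iterate to a fixed point.  Converges for star-shaped
    chord structures (e.g. superellipse contours); raises if the
    iteration does not settle.
    """
    if not (-1.0 < ml < 1.0 and -1.0 < dv < 1.0):
        raise ValueError("target normalized coordinates must lie in (-1, 1)")
    ml_in = ml * contour.lateral_dir
    dv_in = dv * contour.dorsal_dir
    x = float(np.mean(contour.vertices[:, 0]))
    y = float(np.mean(contour.vertices[:, 1]))
    for _ in range(max_iter):
        x_lo, x_hi = axis_interval(contour, x, y, axis=0)
        x_new = x_lo + 0.5 * (ml_in + 1.0) * (x_hi - x_lo)
        y_lo, y_hi = axis_interval(contour, x_new, y, axis=1)
        y_new = y_lo + 0.5 * (dv_in + 1.0) * (y_hi - y_lo)
        if abs(x_new - x) < tol and abs(y_new - y) < tol:
            return x_new, y_new
        x, y = x_new, y_new
    raise RuntimeError("normalized-coordinate inversion did not converge")


def plane_bias_test(
    values: Sequence[float], plane_id: str = "", min_n: int = MIN_NEURONS_PER_PLANE
) -> TestResult | SkipRecord:
    """Wilcoxon signed-rank test of per-plane normalized values vs 0.

    Planes with fewer than ``min_n`` neurons (default: <= 5) are skipped
    with an explicit record, mirroring the counting protocol.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < min_n:
        return SkipRecord(plane_id=plane_id, n=int(v.size))
    return wilcoxon_signed_vs_zero(v)


def compare_populations(
    pop_a: Sequence[float],
    pop_b: Sequence[float],
    plane_id: str = "",
    min_n: int = MIN_NEURONS_PER_PLANE,
) -> TestResult | SkipRecord:
    """Mann-Whitney comparison of two populations' axis values in one plane."""
    a = np.asarray(pop_a, dtype=float).ravel()
    b = np.asarray(pop_b, dtype=float).ravel()
    if a.size < min_n or b.size < min_n:
        return SkipRecord(plane_id=plane_id, n=int(min(a.size, b.size)))
    return mann_whitney(a, b)


def across_planes_fdr(
    results: Sequence[TestResult | SkipRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """BH-FDR adjustment of per-plane test results across planes.

    Skipped planes are carried through with NaN p-values and excluded
    from the adjustment.
    """
    raw = [r.p_value if isinstance(r, TestResult) else np.nan for r in results]
    tested = ~np.isnan(raw)
    adj = np.full(len(raw), np.nan)
    sig = np.zeros(len(raw), dtype=bool)
    if np.any(tested):
        adj_t, sig_t = fdr_adjust(np.asarray(raw)[tested], alpha=alpha)
        adj[tested] = adj_t
        sig[tested] = sig_t
    return pd.DataFrame({"p_raw": raw, "p_fdr": adj, "significant": sig})


def cross_plane_variability(per_plane_means: Sequence[float], mode: str = "mean_abs") -> np.ndarray:
    """Per-plane rostro-caudal variability statistic.

    For plane s with mean normalized value m_s, the default statistic is
    d_s = mean over s' != s of |m_s - m_s'| (``mode='mean_abs'``); the
    alternative reading |mean over s' of (m_s - m_s')| is available as
    ``mode='abs_mean'``.  The statistic is high when the mean position
    drifts across planes and near zero for a consistent bias.
    """
    m = np.asarray(per_plane_means, dtype=float).ravel()
    if m.size < 3:
        raise ValueError("need at least 3 planes")
    diffs = m[:, None] - m[None, :]
    mask = ~np.eye(m.size, dtype=bool)
    if mode == "mean_abs":
        return np.array([np.mean(np.abs(diffs[i][mask[i]])) for i in range(m.size)])
    if mode == "abs_mean":
        return np.array([abs(np.mean(diffs[i][mask[i]])) for i in range(m.size)])
    raise ValueError(f"unknown mode {mode!r}")


def compare_variability(
    groups_of_plane_means: Sequence[Sequence[float]], mode: str = "mean_abs"
) -> TestResult:
    """Kruskal-Wallis/Dunn comparison of cross-plane variability between
    neuron populations (each group is one population's per-plane means)."""
    d_groups = [cross_plane_variability(g, mode=mode) for g in groups_of_plane_means]
    return kruskal_wallis_dunn(d_groups)
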