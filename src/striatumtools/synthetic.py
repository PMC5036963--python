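"""Ground-truth generators for every input the pipeline consumes.

These generators emulate the study conditions end to end: striatum-like
contour polygons with spatially biased neuron point clouds, oscillatory
field signals (a ~1 Hz slow wave -- optionally skewed so its phase
distribution is non-uniform -- plus spindle, gamma and 1/f noise
components), spike trains phase-locked to a field band via a von Mises
intensity, spike trains timed to slow-oscillation peaks on the
normalized -1..1 scale, Gaussian feature clusters with known labels, and
nucleus-depth / point-grid fixtures for the stereology stage.  Every
generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.signal import butter, sosfiltfilt

from .peaks import ILfpPeak
from .phase import SampledSignal, analytic_phase
from .spikes import SpikeTrain
from .topography import PlaneContour, invert_normalized

N_PLANES_DEFAULT = 13  # coronal planes delineated in the rat protocol


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# contours and biased point clouds


def superellipse_contour(
    plane_id: str = "p0",
    half_width_um: float = 2000.0,
    half_height_um: float = 1500.0,
    exponent: float = 2.5,
    n_vertices: int = 64,
    center: tuple[float, float] = (0.0, 0.0),
    notch_depth: float = 0.0,
    bregma_mm: float = 0.0,
) -> PlaneContour:
    """A striatum-like simple polygon from a superellipse outline.

    ``notch_depth`` in (0, 1) carves a wedge into the medial (-x) side,
    producing a non-convex "C"-shaped outline that exercises the
    first-crossing ray logic.
    """
    if half_width_um <= 0 or half_height_um <= 0 or exponent <= 0:
        raise ValueError("degenerate shape parameters")
    if not (0.0 <= notch_depth < 1.0):
        raise ValueError("notch_depth must be in [0, 1)")
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy = center
    x = cx + half_width_um * np.sign(np.cos(theta)) * np.abs(np.cos(theta)) ** (2 / exponent)
    y = cy + half_height_um * np.sign(np.sin(theta)) * np.abs(np.sin(theta)) ** (2 / exponent)
    verts = np.column_stack([x, y])
    if notch_depth > 0:
        # pull the vertices near theta = pi inward to carve the notch
        window = np.exp(-((np.angle(np.exp(1j * (theta - np.pi)))) ** 2) / (2 * 0.35**2))
        shrink = 1.0 - notch_depth * window
        verts[:, 0] = cx + (verts[:, 0] - cx) * shrink
    return PlaneContour(plane_id=plane_id, vertices=verts, bregma_mm=bregma_mm)


def make_contours(
    n_planes: int = N_PLANES_DEFAULT,
    base_half_width_um: float = 2000.0,
    base_half_height_um: float = 1500.0,
    notch_depth: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[PlaneContour]:
    """A rostro-caudal series of striatum-like plane contours.

    Plane size waxes then wanes along the series, as the striatal
    cross-section does; bregma offsets step caudally by 0.4 mm.
    """
    if n_planes < 1:
        raise ValueError("need at least one plane")
    rng = _rng(seed)
    contours = []
    for i in range(n_planes):
        frac = (i + 0.5) / n_planes
        scale = 0.7 + 0.6 * math.sin(math.pi * frac)  # waxing/waning profile
        contours.append(
            superellipse_contour(
                plane_id=f"plane{i:02d}",
                half_width_um=base_half_width_um * scale * rng.uniform(0.95, 1.05),
                half_height_um=base_half_height_um * scale * rng.uniform(0.95, 1.05),
                exponent=rng.uniform(2.0, 3.0),
                notch_depth=notch_depth,
                bregma_mm=2.0 - 0.4 * i,
            )
        )
    return contours


def _beta_params(bias: float, concentration: float) -> tuple[float, float]:
    mean01 = (bias + 1.0) / 2.0
    return mean01 * concentration, (1.0 - mean01) * concentration


def sample_biased_neurons(
    contour: PlaneContour,
    n: int,
    ml_bias: float = 0.0,
    dv_bias: float = 0.0,
    concentration: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Points inside a contour with a target mean normalized position.

    Target normalized coordinates are drawn from Beta distributions
    affinely mapped onto (-1, 1) with mean equal to the requested bias
    (``concentration`` = Beta a+b, setting the spread), then placed by
    inverting the ray parametrization, so the realized mean of
    ``topography.normalize_position`` recovers the bias up to sampling
    error.  Returns an (n, 2) array of (x, y) um.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (abs(ml_bias) < 1 and abs(dv_bias) < 1):
        raise ValueError("biases must lie in (-1, 1)")
    rng = _rng(seed)
    a_ml, b_ml = _beta_params(ml_bias, concentration)
    a_dv, b_dv = _beta_params(dv_bias, concentration)
    ml = 2.0 * rng.beta(a_ml, b_ml, size=n) - 1.0
    dv = 2.0 * rng.beta(a_dv, b_dv, size=n) - 1.0
    # keep targets off the exact border where the inversion degenerates
    ml = np.clip(ml, -0.999, 0.999)
    dv = np.clip(dv, -0.999, 0.999)
    pts = np.array([invert_normalized(contour, m, d) for m, d in zip(ml, dv)])
    return pts


# ---------------------------------------------------------------------------
# field signals and spike trains


def _narrowband_noise(n: int, fs: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    sos = butter(2, list(band), btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n=n)
    return x / x.std()


def simulate_field(
    duration: float = 100.0,
    fs: float = 1000.0,
    slow_amp: float = 1.0,
    spindle_amp: float = 0.3,
    gamma_amp: float = 0.15,
    noise_amp: float = 0.2,
    slow_freq: float = 1.0,
    skew: float = 0.0,
    spindle_band: tuple[float, float] = (7.0, 12.0),
    gamma_band: tuple[float, float] = (30.0, 48.0),
    seed: int | np.random.Generator = 0,
    channel: str = "ecog",
) -> SampledSignal:
    """Synthetic ECoG/LFP: slow wave + spindle + gamma + 1/f noise.

    The slow component is a ~1 Hz sinusoid passed through the monotone
    waveshaper (exp(skew*s) - 1)/skew when ``skew`` > 0.  Waveshaping
    preserves the period but sharpens peaks and flattens troughs, so the
    Hilbert phase of the slow band is no longer uniformly occupied --
    the non-sinusoidal regime that motivates the ECDF phase correction.
    The default 1 kHz sampling keeps desk-scale runs cheap; pass
    fs=16600 to match the acquisition rate of the recordings emulated.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 200:
        raise ValueError("sampling rate too low")
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    s = np.sin(2 * np.pi * slow_freq * t + rng.uniform(0, 2 * np.pi))
    if skew != 0.0:
        s = (np.exp(skew * s) - 1.0) / skew
        s = (s - s.mean()) / s.std()
    x = slow_amp * s
    if spindle_amp:
        x = x + spindle_amp * _narrowband_noise(n, fs, spindle_band, rng)
    if gamma_amp:
        x = x + gamma_amp * _narrowband_noise(n, fs, gamma_band, rng)
    if noise_amp:
        x = x + noise_amp * _pink_noise(n, rng)
    return SampledSignal(samples=x, fs=fs, channel=channel)


def _inhomogeneous_poisson(intensity: np.ndarray, fs: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Spike times from a sampled intensity via time rescaling."""
    cum = np.concatenate([[0.0], np.cumsum(intensity) / fs])
    total = cum[-1]
    n_spk = rng.poisson(total)
    marks = np.sort(rng.uniform(0, total, size=n_spk))
    grid = np.arange(cum.size) / fs
    times = np.interp(marks, cum, grid)
    return np.unique(times)


def simulate_locked_train(
    s: SampledSignal,
    band: tuple[float, float],
    rate: float = 10.0,
    kappa: float = 1.0,
    mu: float = 0.0,
    seed: int | np.random.Generator = 0,
    state: str = "swa",
    identity: str = "",
) -> SpikeTrain:
    """Inhomogeneous-Poisson train phase-locked to one band of a signal.

    Intensity lambda(t) proportional to exp(kappa*cos(theta(t) - mu)),
    normalized to the target mean rate.  The spike phase distribution is
    then von Mises-like, so the recovered vector length approaches the
    Bessel ratio I1(kappa)/I0(kappa).  ``mu`` is in radians (0 = peak).
    kappa = 0 reduces to a homogeneous Poisson train.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if band[1] >= s.fs / 2:
        raise ValueError("band outside the signal's Nyquist range")
    rng = _rng(seed)
    theta, _ = analytic_phase(s, band)
    lam = np.exp(kappa * np.cos(theta - mu))
    lam *= rate / lam.mean()
    times = _inhomogeneous_poisson(lam, s.fs, rng)
    return SpikeTrain(times=times, epoch=(0.0, s.duration), state=state, identity=identity)


def simulate_peak_timed_train(
    peaks: list[ILfpPeak],
    mu_star: float = -0.3,
    sigma_star: float = 0.1,
    spikes_per_peak: float = 5.0,
    seed: int | np.random.Generator = 0,
    epoch: tuple[float, float] | None = None,
    state: str = "swa",
    identity: str = "",
) -> SpikeTrain:
    """Spikes placed at truncated-Gaussian normalized times within peaks.

    Per retained peak, Poisson(spikes_per_peak) spikes get normalized
    times from a Gaussian(mu_star, sigma_star) truncated to (-1, 1) and
    are mapped back to real time within the peak.
    """
    if not peaks:
        raise ValueError("no peaks to time spikes against")
    if not (-1.0 < mu_star < 1.0):
        raise ValueError("mu_star must lie in (-1, 1)")
    if sigma_star <= 0:
        raise ValueError("sigma_star must be positive")
    rng = _rng(seed)
    a = (-1.0 - mu_star) / sigma_star
    b = (1.0 - mu_star) / sigma_star
    times = []
    for p in peaks:
        k = rng.poisson(spikes_per_peak)
        if k == 0:
            continue
        u = sps.truncnorm.rvs(a, b, loc=mu_star, scale=sigma_star, size=k,
                              random_state=rng)
        times.append(p.start_s + (u + 1.0) / 2.0 * p.duration_s)
    all_times = np.unique(np.concatenate(times)) if times else np.array([])
    if epoch is None:
        epoch = (0.0, max(p.end_s for p in peaks))
    return SpikeTrain(times=all_times, epoch=epoch, state=state, identity=identity)


# ---------------------------------------------------------------------------
# feature clusters


def simulate_feature_clusters(
    k: int = 3,
    n_per_cluster: int = 20,
    separation: float = 5.0,
    dims: int = 6,
    label_accuracy: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-variance Gaussian clusters with controllable separation.

    Cluster centers sit at simplex vertices scaled so every pairwise
    center distance equals ``separation`` standard deviations.  Returns
    ``(features, true_labels, identities)`` where identities agree with
    the true labels with probability ``label_accuracy``.
    """
    if k < 1:
        raise ValueError("need k >= 1")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    if k > 1 and dims < k:
        raise ValueError("dims must be >= k to embed the simplex")
    rng = _rng(seed)
    centers = np.zeros((k, dims))
    for i in range(k):
        if k > 1:
            centers[i, i] = separation / math.sqrt(2.0)
    labels = np.repeat(np.arange(k), n_per_cluster)
    x = centers[labels] + rng.standard_normal((labels.size, dims))
    identities = labels.copy()
    flip = rng.uniform(size=labels.size) > label_accuracy
    identities[flip] = rng.integers(0, k, size=int(flip.sum()))
    return x, labels, identities


# ---------------------------------------------------------------------------
# stereology fixtures


def simulate_nucleus_stack(
    density_per_mm3: float,
    slab_um: float = 50.0,
    frame_area_um2: float = 420.0 * 320.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Nucleus-top depths uniform in a tissue slab at a given density.

    The Poisson-distributed number of nuclei matches the expected count
    for the slab volume; depths are uniform over [0, slab_um].
    """
    if density_per_mm3 <= 0 or slab_um <= 0 or frame_area_um2 <= 0:
        raise ValueError("density and slab dimensions must be positive")
    rng = _rng(seed)
    volume_mm3 = frame_area_um2 * slab_um / 1e9
    n = rng.poisson(density_per_mm3 * volume_mm3)
    return np.sort(rng.uniform(0.0, slab_um, size=n))


def ellipsoid_section_areas(
    semi_axes_mm: tuple[float, float, float], spacing_mm: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-section z positions (systematic, random start) and analytic
    ellipse semi-axes products for an axis-aligned ellipsoid."""
    a, b, c = semi_axes_mm
    start = rng.uniform(0, spacing_mm)
    z = np.arange(-c + start, c, spacing_mm)
    scale = 1.0 - (z / c) ** 2
    return z, scale


def simulate_point_grid(
    semi_axes_mm: tuple[float, float, float] = (2.0, 1.5, 1.0),
    a_p_mm2: float = 0.01,
    t_mm: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Cavalieri point counts for an analytic ellipsoid.

    Sections the ellipsoid systematically with random start at spacing
    ``t_mm`` and counts the nodes of a randomly offset square grid of
    area ``a_p_mm2`` per point that fall inside each elliptical
    cross-section.  The paired analytic volume is 4*pi*a*b*c/3.
    """
    if min(semi_axes_mm) <= 0 or a_p_mm2 <= 0 or t_mm <= 0:
        raise ValueError("dimensions must be positive")
    rng = _rng(seed)
    a, b, c = semi_axes_mm
    z, scale = ellipsoid_section_areas(semi_axes_mm, t_mm, rng)
    step = math.sqrt(a_p_mm2)
    counts = []
    for sc in scale:
        if sc <= 0:
            counts.append(0)
            continue
        ea, eb = a * math.sqrt(sc), b * math.sqrt(sc)
        ox, oy = rng.uniform(0, step, size=2)
        gx = np.arange(-ea - step + ox, ea + step, step)
        gy = np.arange(-eb - step + oy, eb + step, step)
        xx, yy = np.meshgrid(gx, gy)
        counts.append(int(np.sum((xx / ea) ** 2 + (yy / eb) ** 2 <= 1.0)))
    return np.asarray(counts, dtype=int)


def ellipsoid_volume(semi_axes_mm: tuple[float, float, float]) -> float:
    a, b, c = semi_axes_mm
    return 4.0 * math.pi * a * b * c / 3.0
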