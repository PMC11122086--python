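"""Full-reference similarity metrics: PSNR, SSIM, MS-SSIM, FSIM.

Each metric compares a *target* slice against a *reference* slice of
identical dimensions.  MRI intensities carry arbitrary units, so every pair
is first **jointly** min-max normalised by the shared minimum and maximum of
the two images — per-image normalisation would erase genuine intensity
differences between contrast phases.  PSNR/SSIM/MS-SSIM then operate on unit
range; FSIM maps the pair to 0-255 because its gradient stabiliser assumes an
8-bit scale.

Conventions fixed here (and relied upon elsewhere):

* PSNR = ``10*log10(1 / (MSE + eps))`` with ``eps = 1e-8`` on unit range, so
  a slice compared against itself prints exactly 80.0 dB instead of an
  infinity.
* SSIM uses an 11x11 Gaussian window (sigma 1.5), stabilisers
  ``C1=(0.01*L)^2``, ``C2=(0.03*L)^2``; the reported score is the mean of the
  local map over positions whose window lies fully inside the image.
* MS-SSIM uses 5 dyadic scales with 2x2 average-pool downsampling, the
  standard scale weights, contrast-structure at every scale and luminance
  only at the coarsest; negative component means are clamped at zero before
  exponentiation (non-negative-luminance convention).
* FSIM weights the product of phase-congruency similarity and
  Scharr-gradient similarity by the pointwise maximum phase congruency.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import fft2, ifft2, ifftshift
from scipy.ndimage import correlate1d

from .config import DEFAULT_METRIC_CONFIG, MetricConfig
from .volume_io import ImageSlice

__all__ = [
    "psnr", "ssim", "ms_ssim", "fsim", "phase_congruency",
    "joint_unit_range",
]


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageSlice):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    return arr


def _check_pair(target, reference) -> tuple[np.ndarray, np.ndarray]:
    t, r = _as_array(target), _as_array(reference)
    if t.shape != r.shape:
        raise ValueError(f"dimension mismatch: target {t.shape} vs reference {r.shape}")
    return t, r


def joint_unit_range(target: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalise a pair by their shared extrema onto [0, 1]."""
    lo = min(target.min(), reference.min())
    hi = max(target.max(), reference.max())
    if hi == lo:
        return np.zeros_like(target), np.zeros_like(reference)
    return (target - lo) / (hi - lo), (reference - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------

def psnr(target, reference, config: MetricConfig = DEFAULT_METRIC_CONFIG) -> float:
    """Peak signal-to-noise ratio in dB on jointly unit-normalised intensities.

    The epsilon-stabilised MSE gives identical images a finite ceiling of
    ``10*log10(1/eps)`` = 80.0 dB at the default ``eps = 1e-8``.
    """
    t, r = _check_pair(target, reference)
    t, r = joint_unit_range(t, r)
    mse = float(np.mean((t - r) ** 2))
    return float(10.0 * np.log10(1.0 / (mse + config.psnr_epsilon)))


# ---------------------------------------------------------------------------
# SSIM / MS-SSIM
# ---------------------------------------------------------------------------

def _gaussian_kernel1d(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def _filter2_valid(image: np.ndarray, kernel1d: np.ndarray) -> np.ndarray:
    """Separable correlation, cropped to positions with full window support."""
    pad = (len(kernel1d) - 1) // 2
    out = correlate1d(image, kernel1d, axis=0, mode="nearest")
    out = correlate1d(out, kernel1d, axis=1, mode="nearest")
    return out[pad:image.shape[0] - pad, pad:image.shape[1] - pad]


def _ssim_components(t: np.ndarray, r: np.ndarray, config: MetricConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel luminance and contrast-structure maps on unit-range inputs."""
    win = config.ssim_window
    if min(t.shape) < win:
        raise ValueError(
            f"image {t.shape} smaller than SSIM window {win}x{win}"
        )
    k = _gaussian_kernel1d(win, config.ssim_sigma)
    c1 = (config.ssim_k1 * 1.0) ** 2
    c2 = (config.ssim_k2 * 1.0) ** 2

    mu_t = _filter2_valid(t, k)
    mu_r = _filter2_valid(r, k)
    var_t = _filter2_valid(t * t, k) - mu_t ** 2
    var_r = _filter2_valid(r * r, k) - mu_r ** 2
    cov = _filter2_valid(t * r, k) - mu_t * mu_r

    luminance = (2 * mu_t * mu_r + c1) / (mu_t ** 2 + mu_r ** 2 + c1)
    cs = (2 * cov + c2) / (var_t + var_r + c2)
    return luminance, cs


def ssim(target, reference, config: MetricConfig = DEFAULT_METRIC_CONFIG,
         return_map: bool = False):
    """Structural similarity index; symmetric in its arguments.

    Returns the mean of the local SSIM map, optionally with the map itself.
    """
    t, r = _check_pair(target, reference)
    t, r = joint_unit_range(t, r)
    luminance, cs = _ssim_components(t, r, config)
    ssim_map = luminance * cs
    score = float(ssim_map.mean())
    return (score, ssim_map) if return_map else score


def _downsample2(image: np.ndarray) -> np.ndarray:
    """2x2 average pooling (floor semantics on odd dims)."""
    m, n = (image.shape[0] // 2) * 2, (image.shape[1] // 2) * 2
    x = image[:m, :n]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def ms_ssim(target, reference, config: MetricConfig = DEFAULT_METRIC_CONFIG) -> float:
    """Multi-scale SSIM over five dyadic scales.

    Contrast-structure terms enter at every scale, luminance only at the
    coarsest; each term's mean is clamped at zero before exponentiation so
    the score stays in [0, 1] for non-negative-intensity images.
    """
    t, r = _check_pair(target, reference)
    n_scales = len(config.msssim_weights)
    min_dim = config.ssim_window * 2 ** (n_scales - 1)
    if min(t.shape) < min_dim:
        raise ValueError(
            f"image {t.shape} too small for {n_scales}-scale MS-SSIM; "
            f"minimum in-plane size is {min_dim}x{min_dim}"
        )
    t, r = joint_unit_range(t, r)
    score = 1.0
    for level, weight in enumerate(config.msssim_weights):
        luminance, cs = _ssim_components(t, r, config)
        if level == n_scales - 1:
            lum_mean = max(float(luminance.mean()), 0.0)
            score *= lum_mean ** weight
        cs_mean = max(float(cs.mean()), 0.0)
        score *= cs_mean ** weight
        if level < n_scales - 1:
            t, r = _downsample2(t), _downsample2(r)
    return float(score)


# ---------------------------------------------------------------------------
# Phase congruency and FSIM
# ---------------------------------------------------------------------------

def _log_gabor_bank(shape: tuple[int, int], n_scales: int, n_orient: int,
                    min_wavelength: float = 6.0, mult: float = 2.0,
                    sigma_on_f: float = 0.55, d_theta_on_sigma: float = 1.2
                    ) -> list[list[np.ndarray]]:
    """Frequency-domain log-Gabor filters, indexed [orientation][scale]."""
    rows, cols = shape
    y = (np.arange(rows) - rows // 2) / rows
    x = (np.arange(cols) - cols // 2) / cols
    xx, yy = np.meshgrid(x, y)
    radius = ifftshift(np.hypot(xx, yy))
    radius[0, 0] = 1.0   # avoid log(0) at DC
    theta = ifftshift(np.arctan2(-yy, xx))
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    # Low-pass to suppress wrap-around artifacts at the FFT boundary.
    lp = ifftshift(1.0 / (1.0 + (np.hypot(xx, yy) / 0.45) ** (2 * 15)))

    theta_sigma = np.pi / n_orient / d_theta_on_sigma
    bank: list[list[np.ndarray]] = []
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta ** 2) / (2 * theta_sigma ** 2))
        per_scale = []
        for s in range(n_scales):
            wavelength = min_wavelength * mult ** s
            f0 = 1.0 / wavelength
            radial = np.exp(-(np.log(radius / f0) ** 2)
                            / (2 * np.log(sigma_on_f) ** 2)) * lp
            radial[0, 0] = 0.0
            per_scale.append(radial * spread)
        bank.append(per_scale)
    return bank


def phase_congruency(image, config: MetricConfig = DEFAULT_METRIC_CONFIG,
                     noise_k: float = 2.0) -> np.ndarray:
    """Phase-congruency map in [0, 1] from a log-Gabor quadrature bank.

    Contrast invariant by construction: phase congruency is the ratio of
    local energy to the summed filter amplitudes, with a noise floor
    estimated from the smallest-scale response (Rayleigh model, ``noise_k``
    standard deviations above its mean).
    """
    arr = _as_array(image)
    if min(arr.shape) < 16:
        raise ValueError("phase congruency requires at least a 16x16 image")
    eps = 1e-4
    spectrum = fft2(arr)
    bank = _log_gabor_bank(arr.shape, config.fsim_scales, config.fsim_orientations)
    mult = 2.0

    energy_total = np.zeros(arr.shape)
    amplitude_total = np.zeros(arr.shape)
    for per_scale in bank:
        sum_even = np.zeros(arr.shape)
        sum_odd = np.zeros(arr.shape)
        sum_amp = np.zeros(arr.shape)
        amp_scale0 = None
        for s, filt in enumerate(per_scale):
            response = ifft2(spectrum * filt)
            even, odd = response.real, response.imag
            amp = np.hypot(even, odd)
            sum_even += even
            sum_odd += odd
            sum_amp += amp
            if s == 0:
                amp_scale0 = amp
        mean_norm = np.hypot(sum_even, sum_odd) + eps
        mean_e, mean_o = sum_even / mean_norm, sum_odd / mean_norm
        energy = np.zeros(arr.shape)
        for filt in per_scale:
            response = ifft2(spectrum * filt)
            even, odd = response.real, response.imag
            energy += even * mean_e + odd * mean_o - np.abs(even * mean_o - odd * mean_e)

        # Rayleigh noise floor from the smallest-scale amplitude median.
        tau = np.median(amp_scale0) / np.sqrt(np.log(4.0))
        total_tau = tau * (1.0 - (1.0 / mult) ** config.fsim_scales) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        threshold = noise_mean + noise_k * noise_sigma

        energy_total += np.maximum(energy - threshold, 0.0)
        amplitude_total += sum_amp

    pc = energy_total / (amplitude_total + eps)
    return np.clip(pc, 0.0, 1.0)


_SCHARR_X = np.array([[3.0, 0.0, -3.0],
                      [10.0, 0.0, -10.0],
                      [3.0, 0.0, -3.0]]) / 16.0


def _scharr_gradient_magnitude(image: np.ndarray) -> np.ndarray:
    from scipy.ndimage import correlate
    gx = correlate(image, _SCHARR_X, mode="nearest")
    gy = correlate(image, _SCHARR_X.T, mode="nearest")
    return np.hypot(gx, gy)


def fsim(target, reference, config: MetricConfig = DEFAULT_METRIC_CONFIG) -> float:
    """Feature similarity index combining phase congruency and gradients.

    Intensities are jointly mapped to 0-255 (the scale the gradient
    stabiliser ``T2`` assumes); the similarity product is averaged with the
    pointwise maximum phase congruency as weight, so structurally salient
    locations dominate the score.
    """
    t, r = _check_pair(target, reference)
    if min(t.shape) < 16:
        raise ValueError("FSIM requires at least a 16x16 image")
    t, r = joint_unit_range(t, r)
    t, r = t * 255.0, r * 255.0

    pc_t = phase_congruency(t, config)
    pc_r = phase_congruency(r, config)
    g_t = _scharr_gradient_magnitude(t)
    g_r = _scharr_gradient_magnitude(r)

    t1, t2 = config.fsim_t1, config.fsim_t2
    s_pc = (2 * pc_t * pc_r + t1) / (pc_t ** 2 + pc_r ** 2 + t1)
    s_g = (2 * g_t * g_r + t2) / (g_t ** 2 + g_r ** 2 + t2)
    s_l = s_pc * s_g
    pc_max = np.maximum(pc_t, pc_r)
    denom = float(pc_max.sum())
    if denom == 0.0:
        # Structureless pair: fall back to the unweighted mean similarity.
        return float(s_l.mean())
    return float((s_l * pc_max).sum() / denom)
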