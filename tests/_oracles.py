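"""Independent brute-force oracles for metric cross-checks.

Everything here is written as direct loops / dense grids from the metric
definitions, deliberately sharing no code path with the package (beyond
numpy), so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma as gamma_fn


def tv_bruteforce(image: np.ndarray) -> float:
    """Per-pixel isotropic total variation via an explicit double loop."""
    arr = np.asarray(image, float)
    lo, hi = arr.min(), arr.max()
    arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    m, n = arr.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            dr = arr[i + 1, j] - arr[i, j] if i + 1 < m else 0.0
            dc = arr[i, j + 1] - arr[i, j] if j + 1 < n else 0.0
            total += (dr * dr + dc * dc) ** 0.5
    return total / (m * n)


def _gauss2d(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size] - half
    w = np.exp(-(x ** 2 + y ** 2) / (2 * sigma ** 2))
    return w / w.sum()


def ssim_bruteforce(target: np.ndarray, reference: np.ndarray,
                    win: int = 11, sigma: float = 1.5,
                    k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local SSIM over all fully contained sliding windows."""
    t = np.asarray(target, float)
    r = np.asarray(reference, float)
    w = _gauss2d(win, sigma)
    c1, c2 = k1 ** 2, k2 ** 2
    m, n = t.shape
    scores = []
    for i in range(m - win + 1):
        for j in range(n - win + 1):
            pt = t[i:i + win, j:j + win]
            pr = r[i:i + win, j:j + win]
            mu_t = (w * pt).sum()
            mu_r = (w * pr).sum()
            var_t = (w * pt * pt).sum() - mu_t ** 2
            var_r = (w * pr * pr).sum() - mu_r ** 2
            cov = (w * pt * pr).sum() - mu_t * mu_r
            scores.append(
                ((2 * mu_t * mu_r + c1) * (2 * cov + c2))
                / ((mu_t ** 2 + mu_r ** 2 + c1) * (var_t + var_r + c2)))
    return float(np.mean(scores))


def mscn_bruteforce(image: np.ndarray, win: int = 7, sigma: float = 7.0 / 6.0,
                    c: float = 1.0) -> np.ndarray:
    """MSCN field via explicit windowed loops with replicate borders."""
    arr = np.asarray(image, float)
    w = _gauss2d(win, sigma)
    half = win // 2
    m, n = arr.shape
    out = np.empty_like(arr)
    for i in range(m):
        for j in range(n):
            mu = 0.0
            sq = 0.0
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    v = arr[min(max(i + di, 0), m - 1),
                            min(max(j + dj, 0), n - 1)]
                    weight = w[di + half, dj + half]
                    mu += weight * v
                    sq += weight * v * v
            sd = max(sq - mu * mu, 0.0) ** 0.5
            out[i, j] = (arr[i, j] - mu) / (sd + c)
    return out


def aggd_fit_bruteforce(samples: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-matching AGGD fit with a dense shape-parameter grid."""
    x = np.asarray(samples, float).ravel()
    left = x[x < 0]
    right = x[x >= 0]
    sigma_l = float(np.sqrt(np.mean(left ** 2)))
    sigma_r = float(np.sqrt(np.mean(right ** 2)))
    g = sigma_l / sigma_r
    r_hat = np.mean(np.abs(x)) ** 2 / np.mean(x ** 2)
    target = r_hat * (g ** 3 + 1) * (g + 1) / (g ** 2 + 1) ** 2
    grid = np.arange(0.05, 15.0, 0.0005)
    rho = gamma_fn(2.0 / grid) ** 2 / (gamma_fn(1.0 / grid) * gamma_fn(3.0 / grid))
    alpha = float(grid[np.argmin(np.abs(rho - target))])
    eta = (sigma_r - sigma_l) * gamma_fn(2.0 / alpha) / np.sqrt(
        gamma_fn(1.0 / alpha) * gamma_fn(3.0 / alpha))
    return alpha, float(eta), sigma_l, sigma_r


def brisque_features_bruteforce(image: np.ndarray) -> np.ndarray:
    """36 BRISQUE features from the brute-force MSCN and AGGD fits."""
    arr = np.asarray(image, float)
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) * 255.0
    feats = []
    for scale in range(2):
        mscn = mscn_bruteforce(arr)
        alpha, _, _, _ = aggd_fit_bruteforce(mscn)
        feats.extend([alpha, float(np.sqrt(np.mean(mscn ** 2)))])
        for product in (
            mscn[:, :-1] * mscn[:, 1:],
            mscn[:-1, :] * mscn[1:, :],
            mscn[:-1, :-1] * mscn[1:, 1:],
            mscn[1:, :-1] * mscn[:-1, 1:],
        ):
            feats.extend(aggd_fit_bruteforce(product))
        if scale == 0:
            m, n = (arr.shape[0] // 2) * 2, (arr.shape[1] // 2) * 2
            blocks = arr[:m, :n].reshape(m // 2, 2, n // 2, 2)
            arr = blocks.mean(axis=(1, 3))
    return np.asarray(feats)


def sample_aggd(alpha: float, sigma_l: float, sigma_r: float, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform AGGD sampler (gamma-variate magnitude construction)."""
    beta_l = sigma_l * np.sqrt(gamma_fn(1.0 / alpha) / gamma_fn(3.0 / alpha))
    beta_r = sigma_r * np.sqrt(gamma_fn(1.0 / alpha) / gamma_fn(3.0 / alpha))
    p_left = beta_l / (beta_l + beta_r)
    side = rng.random(n) < p_left
    magnitude = rng.gamma(1.0 / alpha, 1.0, size=n) ** (1.0 / alpha)
    out = np.where(side, -beta_l * magnitude, beta_r * magnitude)
    return out


def masked_stats_bruteforce(image: np.ndarray, mask: np.ndarray,
                            code: int) -> tuple[float, float, int]:
    """Mean / (n-1) sd of labeled voxels via an explicit loop."""
    values = [v for v, m in zip(np.asarray(image, float).ravel(),
                                np.asarray(mask).ravel()) if m == code]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var ** 0.5, n
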