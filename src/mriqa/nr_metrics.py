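"""No-reference quality metrics: Total Variation and BRISQUE.

Total Variation aggregates the image gradient magnitude — higher values
indicate more edge content and hence, comparatively, higher-contrast slices.
BRISQUE scores a single image from natural-scene statistics: the image is
locally mean-subtracted and contrast-normalised (MSCN), asymmetric
generalised Gaussian distributions (AGGD) are fitted to the MSCN field and
its four directional pairwise products at two scales (36 features), and a
pretrained RBF support-vector regressor maps the features to a quality score
where *smaller is better*.

MRI intensities are arbitrary-unit, so each slice is min-max normalised
before metric computation: to [0, 1] for Total Variation and to 0-255 for
BRISQUE (whose MSCN stabiliser ``C = 1`` assumes an 8-bit-like scale).

The bundled regressor is a compact synthetic stand-in (see
:func:`load_default_model`); any model file in the same plain-text format —
for instance a conversion of the published LIVE-trained coefficients — can
be loaded in its place.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate1d
from scipy.optimize import brentq
from scipy.special import gamma as gamma_fn

from .config import DEFAULT_METRIC_CONFIG, MetricConfig
from .volume_io import ImageSlice

__all__ = [
    "AGGDParams", "BrisqueModel", "total_variation", "mscn_coefficients",
    "fit_aggd", "brisque_features", "brisque_score", "load_brisque_model",
    "load_default_model",
]


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageSlice):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    return arr


def _unit_range(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Total Variation
# ---------------------------------------------------------------------------

def total_variation(image) -> float:
    """Isotropic total variation per pixel on a min-max-normalised slice.

    Forward differences along rows and columns (zero beyond the last
    row/column) are combined as ``sqrt(drow**2 + dcol**2)``, summed, and
    divided by the pixel count.  A constant image scores 0.  The absolute
    value depends on this convention; scores are meant for comparison across
    slices, not as physical quantities.
    """
    arr = _unit_range(_as_array(image))
    drow = np.zeros_like(arr)
    dcol = np.zeros_like(arr)
    drow[:-1, :] = arr[1:, :] - arr[:-1, :]
    dcol[:, :-1] = arr[:, 1:] - arr[:, :-1]
    return float(np.hypot(drow, dcol).sum() / arr.size)


# ---------------------------------------------------------------------------
# MSCN field
# ---------------------------------------------------------------------------

def _gaussian_kernel1d(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def mscn_coefficients(image, config: MetricConfig = DEFAULT_METRIC_CONFIG
                      ) -> np.ndarray:
    """Mean-subtracted contrast-normalised field ``(I - mu)/(sigma + C)``.

    ``mu`` and ``sigma`` are the local Gaussian-weighted mean and standard
    deviation (7x7 window, sigma 7/6, replicate borders); ``C`` stabilises
    flat regions.  Operates on the intensities as given — the caller decides
    the intensity scale that makes ``C`` meaningful.
    """
    arr = _as_array(image)
    if min(arr.shape) < 8:
        raise ValueError("MSCN requires at least an 8x8 image")
    k = _gaussian_kernel1d(config.mscn_window, config.mscn_sigma)

    def smooth(x: np.ndarray) -> np.ndarray:
        out = correlate1d(x, k, axis=0, mode="nearest")
        return correlate1d(out, k, axis=1, mode="nearest")

    mu = smooth(arr)
    sigma = np.sqrt(np.maximum(smooth(arr * arr) - mu ** 2, 0.0))
    return (arr - mu) / (sigma + config.mscn_c)


# ---------------------------------------------------------------------------
# AGGD fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AGGDParams:
    """Moment-matched asymmetric generalised Gaussian parameters."""

    alpha: float          # shape
    sigma_l: float        # left (negative-side) scale
    sigma_r: float        # right (non-negative-side) scale
    eta: float = 0.0      # mean-offset term, used for pairwise-product fits

    def __post_init__(self) -> None:
        for name in ("alpha", "sigma_l", "sigma_r"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"AGGD {name} must be positive and finite")


def _rho(alpha: float) -> float:
    """Generalised-Gaussian moment ratio Gamma(2/a)^2 / (Gamma(1/a) Gamma(3/a))."""
    return gamma_fn(2.0 / alpha) ** 2 / (gamma_fn(1.0 / alpha) * gamma_fn(3.0 / alpha))


def _invert_rho(target: float, lo: float = 0.05, hi: float = 30.0) -> float:
    """Solve rho(alpha) = target; rho is strictly increasing in alpha."""
    target = min(max(target, _rho(lo) + 1e-12), _rho(hi) - 1e-12)
    return brentq(lambda a: _rho(a) - target, lo, hi, xtol=1e-10)


def fit_aggd(samples) -> AGGDParams:
    """Moment-matching AGGD fit of a 1D sample collection.

    Left/right scales come from the one-sided second moments; the shape is
    recovered by inverting the generalised-Gaussian moment ratio on the
    asymmetry-corrected statistic.  Raises on one-sided or degenerate input.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("AGGD fit needs at least 2 samples")
    left = x[x < 0]
    right = x[x >= 0]
    if left.size == 0 or right.size == 0 or not np.any(right > 0):
        raise ValueError("AGGD fit needs samples on both sides of zero")
    sigma_l = float(np.sqrt(np.mean(left ** 2)))
    sigma_r = float(np.sqrt(np.mean(right ** 2)))
    if sigma_l == 0.0 or sigma_r == 0.0:
        raise ValueError("AGGD fit: degenerate one-sided spread")
    gamma_hat = sigma_l / sigma_r
    r_hat = np.mean(np.abs(x)) ** 2 / np.mean(x ** 2)
    big_r = r_hat * (gamma_hat ** 3 + 1.0) * (gamma_hat + 1.0) / (gamma_hat ** 2 + 1.0) ** 2
    alpha = _invert_rho(big_r)
    eta = (sigma_r - sigma_l) * gamma_fn(2.0 / alpha) / np.sqrt(
        gamma_fn(1.0 / alpha) * gamma_fn(3.0 / alpha))
    return AGGDParams(alpha=alpha, sigma_l=sigma_l, sigma_r=sigma_r, eta=float(eta))


# ---------------------------------------------------------------------------
# BRISQUE features
# ---------------------------------------------------------------------------

def _pairwise_products(mscn: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "horizontal": mscn[:, :-1] * mscn[:, 1:],
        "vertical": mscn[:-1, :] * mscn[1:, :],
        "diag_main": mscn[:-1, :-1] * mscn[1:, 1:],
        "diag_anti": mscn[1:, :-1] * mscn[:-1, 1:],
    }


def _scale_features(mscn: np.ndarray) -> list[float]:
    field = mscn.ravel()
    symmetric = fit_aggd(field)
    feats = [symmetric.alpha, float(np.sqrt(np.mean(field ** 2)))]
    for product in _pairwise_products(mscn).values():
        p = fit_aggd(product)
        feats.extend([p.alpha, p.eta, p.sigma_l, p.sigma_r])
    return feats


def brisque_features(image, config: MetricConfig = DEFAULT_METRIC_CONFIG
                     ) -> np.ndarray:
    """36-element BRISQUE feature vector of one slice.

    Per scale (original, then 2x box-smoothed-and-decimated): the MSCN
    field's shape and overall scale, plus (alpha, eta, sigma_l, sigma_r)
    for each of the four directional pairwise products.
    """
    arr = _as_array(image)
    if min(arr.shape) < 16:
        raise ValueError("BRISQUE requires at least a 16x16 image")
    if arr.max() == arr.min():
        raise ValueError("featureless input: constant image")
    arr = _unit_range(arr) * 255.0

    feats: list[float] = []
    for scale in range(2):
        feats.extend(_scale_features(mscn_coefficients(arr, config)))
        if scale == 0:
            # 2x decimation after 2x2 box smoothing == block average
            m, n = (arr.shape[0] // 2) * 2, (arr.shape[1] // 2) * 2
            x = arr[:m, :n]
            arr = 0.25 * (x[0::2, 0::2] + x[1::2, 0::2]
                          + x[0::2, 1::2] + x[1::2, 1::2])
    return np.asarray(feats)


# ---------------------------------------------------------------------------
# SVR model and scoring
# ---------------------------------------------------------------------------

@dataclass
class BrisqueModel:
    """RBF support-vector regressor over 36 scaled BRISQUE features."""

    support_vectors: np.ndarray    # (n_sv, 36)
    coefficients: np.ndarray       # (n_sv,) dual coefficients
    gamma: float                   # RBF kernel width
    rho: float                     # bias; score = sum_i coef_i K_i - rho
    feature_min: np.ndarray        # (36,) per-feature scaling lower bound
    feature_max: np.ndarray        # (36,) per-feature scaling upper bound

    def __post_init__(self) -> None:
        self.support_vectors = np.atleast_2d(np.asarray(self.support_vectors, float))
        self.coefficients = np.asarray(self.coefficients, float).ravel()
        self.feature_min = np.asarray(self.feature_min, float).ravel()
        self.feature_max = np.asarray(self.feature_max, float).ravel()
        n_feat = self.support_vectors.shape[1]
        if n_feat != 36:
            raise ValueError(f"model dimension {n_feat} != 36")
        if self.coefficients.shape[0] != self.support_vectors.shape[0]:
            raise ValueError("one dual coefficient per support vector required")
        if self.feature_min.shape[0] != 36 or self.feature_max.shape[0] != 36:
            raise ValueError("scaling ranges must have 36 entries")
        if np.any(self.feature_min >= self.feature_max):
            raise ValueError("feature scaling requires min < max per feature")
        self.support_vectors_scaled = self.scale(self.support_vectors)

    def scale(self, features: np.ndarray) -> np.ndarray:
        """Map raw features into [-1, 1] by the training ranges."""
        return -1.0 + 2.0 * (features - self.feature_min) / (
            self.feature_max - self.feature_min)


def brisque_score(features, model: BrisqueModel) -> float:
    """Evaluate the SVR on a 36-feature vector; lower scores mean better quality."""
    x = np.asarray(features, dtype=float).ravel()
    if x.shape[0] != 36:
        raise ValueError(f"expected 36 features, got {x.shape[0]}")
    xs = model.scale(x)
    sq_dist = np.sum((model.support_vectors_scaled - xs) ** 2, axis=1)
    return float(np.dot(model.coefficients, np.exp(-model.gamma * sq_dist)) - model.rho)


def load_brisque_model(path: str | Path) -> BrisqueModel:
    """Parse a plain-text BRISQUE SVR model file.

    Format: ``#``-comment lines; ``key value`` scalar lines (``gamma``,
    ``rho``); matrix blocks introduced by ``<name> <rows> <cols>`` followed
    by that many whitespace-separated rows, for ``support_vectors``
    (n_sv x 36), ``coefficients`` (n_sv x 1), ``feature_min`` and
    ``feature_max`` (1 x 36).
    """
    scalars: dict[str, float] = {}
    blocks: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0] in ("gamma", "rho"):
            scalars[parts[0]] = float(parts[1])
            i += 1
        elif len(parts) == 3:
            name, rows, cols = parts[0], int(parts[1]), int(parts[2])
            data = [[float(v) for v in lines[i + 1 + r].split()] for r in range(rows)]
            arr = np.asarray(data)
            if arr.shape != (rows, cols):
                raise ValueError(f"block {name}: expected {rows}x{cols}, got {arr.shape}")
            blocks[name] = arr
            i += 1 + rows
        else:
            raise ValueError(f"unparseable model line: {lines[i]!r}")
    try:
        return BrisqueModel(
            support_vectors=blocks["support_vectors"],
            coefficients=blocks["coefficients"].ravel(),
            gamma=scalars["gamma"],
            rho=scalars["rho"],
            feature_min=blocks["feature_min"].ravel(),
            feature_max=blocks["feature_max"].ravel(),
        )
    except KeyError as exc:
        raise ValueError(f"model file missing section {exc}") from exc


_DEFAULT_MODEL: BrisqueModel | None = None


def load_default_model() -> BrisqueModel:
    """Load the bundled regressor (cached).

    The bundled file is **synthetic**: a compact SVR trained on simulated MR
    phantom slices with graded blur/noise degradations standing in for a
    DMOS-trained model.  It preserves the scoring contract (lower = better;
    blur and noise raise the score) and the file format accepts drop-in
    replacements trained on real opinion scores.
    """
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        ref = resources.files("mriqa.data").joinpath("brisque_svr_synthetic.txt")
        with resources.as_file(ref) as path:
            _DEFAULT_MODEL = load_brisque_model(path)
    return _DEFAULT_MODEL
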