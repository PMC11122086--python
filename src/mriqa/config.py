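"""Shared metric constants and pipeline configuration.

All similarity and no-reference metrics read their constants from a single
:class:`MetricConfig` so that a study is always assessed under one fixed,
documented convention.  The defaults follow the original formulations of the
respective metrics (SSIM/MS-SSIM window and stabilisers, FSIM thresholds and
log-Gabor bank, BRISQUE normalisation window); MRI intensities are in
arbitrary scanner units, so every metric first maps intensities onto a fixed
range (unit range for PSNR/SSIM/MS-SSIM, 0-255 for FSIM and BRISQUE).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class MetricConfig:
    """Constants used by the full-reference and no-reference metrics.

    Attributes
    ----------
    ssim_window, ssim_sigma:
        Size and standard deviation of the Gaussian weighting window used for
        the local SSIM statistics.
    ssim_k1, ssim_k2:
        Stabiliser factors; the stabilisers are ``C1 = (k1 * L)**2`` and
        ``C2 = (k2 * L)**2`` on data range ``L``.
    msssim_weights:
        Per-scale exponents of the five dyadic scales of MS-SSIM.
    fsim_t1, fsim_t2:
        Stabilisers of the phase-congruency and gradient-magnitude similarity
        terms of FSIM.  ``fsim_t2`` assumes intensities on a 0-255 scale.
    fsim_scales, fsim_orientations:
        Geometry of the log-Gabor filter bank behind phase congruency.
    psnr_epsilon:
        Added to the unit-range MSE before taking the logarithm; gives
        identical images a finite 80 dB ceiling.
    mscn_window, mscn_sigma, mscn_c:
        Local Gaussian window and stabiliser of the mean-subtracted
        contrast-normalised (MSCN) field behind BRISQUE.
    """

    ssim_window: int = 11
    ssim_sigma: float = 1.5
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    msssim_weights: tuple[float, ...] = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
    fsim_t1: float = 0.85
    fsim_t2: float = 160.0
    fsim_scales: int = 4
    fsim_orientations: int = 4
    psnr_epsilon: float = 1e-8
    mscn_window: int = 7
    mscn_sigma: float = 7.0 / 6.0
    mscn_c: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.msssim_weights) - 1.0) > 1e-3:
            raise ValueError("msssim_weights must sum to 1 within 1e-3")
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, (int, float)) and not value > 0:
                raise ValueError(f"{f.name} must be positive, got {value!r}")
        if self.ssim_window % 2 == 0 or self.mscn_window % 2 == 0:
            raise ValueError("window sizes must be odd")


DEFAULT_METRIC_CONFIG = MetricConfig()


@dataclass
class PipelineConfig:
    """Run-level options for an assessment.

    ``roi_spheres`` entries are ``{"label": ..., "center": [z, y, x] voxel,
    "radius_mm": ...}`` and are rasterised against the series geometry.
    """

    mode: str = "DCE"                      # "DCE" | "Conventional"
    k_locations: int = 10                  # equidistant slice locations for FR metrics
    flag_threshold: float = 2.0            # robust deviations below median to flag
    metrics: MetricConfig = field(default_factory=MetricConfig)
    roi_spheres: list[dict] = field(default_factory=list)
    write_plots: bool = True
    write_xlsx: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("DCE", "Conventional"):
            raise ValueError(f"mode must be 'DCE' or 'Conventional', got {self.mode!r}")
        if self.k_locations < 1:
            raise ValueError("k_locations must be >= 1")
        if self.flag_threshold <= 0:
            raise ValueError("flag_threshold must be positive")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a JSON key-value config file; unknown keys are rejected.

    Metric-constant overrides live under a ``"metrics"`` sub-object.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    metric_overrides = raw.pop("metrics", {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    metrics = replace(DEFAULT_METRIC_CONFIG, **{
        k: tuple(v) if isinstance(v, list) else v for k, v in metric_overrides.items()
    })
    return PipelineConfig(metrics=metrics, **raw)
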