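"""ROI-based, medically oriented quality statistics.

Regions carry one of four fixed labels — ``pos1``/``pos2`` for two tissue
types, ``FG`` for the foreground patch, ``BG`` for background — supplied as
integer label grids (0 unlabeled, 1 pos1, 2 pos2, 3 FG, 4 BG) matching the
image grid, rasterised from sphere specs, or initialised from two histogram
thresholds.  From the per-region mean and standard deviation the module
derives:

* SNR      = mu_tissue / sigma_BG
* CNR      = |mu_pos1 - mu_pos2| / sigma_BG
* CVP      = sigma_FG / mu_FG            (shading/bias-field indicator)
* CJV      = (sigma_1 + sigma_2) / |mu_1 - mu_2|
* relative SNR = SNR(pos1)/SNR(pos2), which reduces to mu_pos1/mu_pos2

SNR and CNR use the standard background-noise-referenced definitions; no
Rician correction is applied to the background spread, a known small bias
for magnitude MR images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import ImageSlice

__all__ = [
    "LABELS", "LABEL_CODES", "RegionStats", "RoiReport", "region_stats",
    "snr", "cnr", "cvp", "cjv", "relative_snr", "init_rois_by_histogram",
    "sphere_mask", "roi_report",
]

LABELS = ("pos1", "pos2", "FG", "BG")
LABEL_CODES = {"pos1": 1, "pos2": 2, "FG": 3, "BG": 4}


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageSlice):
        return image.pixels
    return np.asarray(image, dtype=float)


@dataclass(frozen=True)
class RegionStats:
    """Sample mean and (n-1) standard deviation of one labeled region."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.n < 2:
            raise ValueError("a region needs at least 2 voxels")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class RoiReport:
    """Derived contrast and noise indices of one image given its ROIs."""

    stats: dict
    snr_pos1: float
    snr_pos2: float
    snr_fg: float
    cnr: float
    cvp: float
    cjv: float
    relative_snr: float          # ratio of background-referenced SNRs
    relative_snr_mean_ratio: float   # equivalent mu_pos1/mu_pos2 form

    def as_dict(self) -> dict:
        out = {f"{label}_mean": s.mean for label, s in self.stats.items()}
        out.update({f"{label}_sd": s.sd for label, s in self.stats.items()})
        out.update({f"{label}_n": s.n for label, s in self.stats.items()})
        out.update(snr_pos1=self.snr_pos1, snr_pos2=self.snr_pos2,
                   snr_fg=self.snr_fg, cnr=self.cnr, cvp=self.cvp,
                   cjv=self.cjv, relative_snr=self.relative_snr,
                   relative_snr_mean_ratio=self.relative_snr_mean_ratio)
        return out


def region_stats(image, mask, label: str) -> RegionStats:
    """Mean/sd of the voxels carrying ``label`` in an integer label grid."""
    arr = _as_array(image)
    mask = np.asarray(mask)
    if mask.shape != arr.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {arr.shape}")
    if label not in LABEL_CODES:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    values = arr[mask == LABEL_CODES[label]]
    if values.size < 2:
        raise ValueError(f"region {label!r} has {values.size} voxels; need >= 2")
    return RegionStats(label=label, mean=float(values.mean()),
                       sd=float(values.std(ddof=1)), n=int(values.size))


def snr(tissue: RegionStats, background: RegionStats) -> float:
    """Signal-to-noise ratio: tissue mean over background standard deviation."""
    if background.sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    return tissue.mean / background.sd


def cnr(pos1: RegionStats, pos2: RegionStats, background: RegionStats) -> float:
    """Contrast-to-noise ratio between two tissues, background-referenced."""
    if background.sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    return abs(pos1.mean - pos2.mean) / background.sd


def cvp(foreground: RegionStats) -> float:
    """Coefficient of variation of the foreground patch (shading indicator)."""
    if foreground.mean == 0:
        raise ValueError("foreground mean is zero; CVP undefined")
    return foreground.sd / foreground.mean


def cjv(pos1: RegionStats, pos2: RegionStats) -> float:
    """Coefficient of joint variation: (sd1 + sd2) / |mean1 - mean2|."""
    if pos1.mean == pos2.mean:
        raise ValueError("tissues indistinguishable: equal means")
    return (pos1.sd + pos2.sd) / abs(pos1.mean - pos2.mean)


def relative_snr(pos1: RegionStats, pos2: RegionStats,
                 background: RegionStats) -> float:
    """Ratio of the two background-referenced SNRs (= mu_pos1 / mu_pos2)."""
    if background.sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    if pos2.mean == 0:
        raise ValueError("pos2 mean is zero; relative SNR undefined")
    return snr(pos1, background) / snr(pos2, background)


def init_rois_by_histogram(image, thresholds: tuple[float, float]) -> np.ndarray:
    """Label grid from two ascending intensity cut points.

    Below the lower cut is background; the two upper histogram sub-sections
    become pos1 and pos2; the foreground is their union (labels are emitted
    as codes, with FG recoverable as ``pos1 | pos2``; every voxel carries
    exactly one of BG/pos1/pos2).
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError(f"thresholds must be strictly ascending, got {thresholds}")
    arr = _as_array(image)
    labels = np.full(arr.shape, LABEL_CODES["BG"], dtype=np.int8)
    labels[(arr >= lo) & (arr < hi)] = LABEL_CODES["pos1"]
    labels[arr >= hi] = LABEL_CODES["pos2"]
    return labels


def foreground_mask(labels: np.ndarray) -> np.ndarray:
    """FG as the logical union of pos1 and pos2 when no explicit FG exists."""
    labels = np.asarray(labels)
    if np.any(labels == LABEL_CODES["FG"]):
        return labels == LABEL_CODES["FG"]
    return (labels == LABEL_CODES["pos1"]) | (labels == LABEL_CODES["pos2"])


def sphere_mask(shape: tuple[int, ...], center: tuple[float, ...],
                radius_mm: float, spacing: tuple[float, ...]) -> np.ndarray:
    """Boolean ball of ``radius_mm`` around a voxel center (2D or 3D grids)."""
    if len(shape) != len(center) or len(shape) != len(spacing):
        raise ValueError("shape, center and spacing must have equal length")
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist_sq = sum(((g - c) * sp) ** 2 for g, c, sp in zip(grids, center, spacing))
    return dist_sq <= radius_mm ** 2


def roi_report(image, labels) -> RoiReport:
    """All derived indices from an image and its label grid.

    An explicit FG region is used when present; otherwise FG is taken as
    pos1 union pos2.
    """
    arr = _as_array(image)
    labels = np.asarray(labels)
    stats = {lbl: region_stats(arr, labels, lbl)
             for lbl in ("pos1", "pos2", "BG")}

    fg = foreground_mask(labels)
    fg_values = arr[fg]
    if fg_values.size < 2:
        raise ValueError("foreground region has fewer than 2 voxels")
    stats["FG"] = RegionStats(label="FG", mean=float(fg_values.mean()),
                              sd=float(fg_values.std(ddof=1)),
                              n=int(fg_values.size))

    rel = relative_snr(stats["pos1"], stats["pos2"], stats["BG"])
    return RoiReport(
        stats=stats,
        snr_pos1=snr(stats["pos1"], stats["BG"]),
        snr_pos2=snr(stats["pos2"], stats["BG"]),
        snr_fg=snr(stats["FG"], stats["BG"]),
        cnr=cnr(stats["pos1"], stats["pos2"], stats["BG"]),
        cvp=cvp(stats["FG"]),
        cjv=cjv(stats["pos1"], stats["pos2"]),
        relative_snr=rel,
        relative_snr_mean_ratio=stats["pos1"].mean / stats["pos2"].mean,
    )
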