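"""Assessment orchestration and the ``IQA`` output folder.

No-reference metrics (BRISQUE, Total Variation) are computed per slice for
every image; full-reference metrics (PSNR, SSIM, MS-SSIM, FSIM) are computed
at ``k`` equidistant slice locations across all timepoints of a dynamic
study, each timepoint's slice compared against the same slice of the
pre-contrast phase (timepoint 0), whose own rows therefore sit at the
identity values (80.0 dB, 1.0, 1.0, 1.0).  Local minima of the quality
direction that fall well below the robust baseline are flagged so attention
goes straight to the suspicious slices or timepoints.

All outputs land in a folder named exactly ``IQA`` inside the inspected
images' directory: the questionnaire response as text, header metadata as a
spreadsheet plus CSV twin, the metric profiles and flags as CSV, per-metric
line plots, and a mean +/- sd summary of the FR metrics per timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fr_metrics, nr_metrics
from .config import PipelineConfig
from .questionnaire import QuestionnaireResponse, serialize_response
from .volume_io import AttributeSummary, DynamicStudy, ImageVolume

logger = logging.getLogger("mriqa")

FR_METRICS = ("psnr", "ssim", "ms_ssim", "fsim")
NR_METRICS = ("brisque", "total_variation")

#: Scores where smaller means better quality (minima search flips direction).
LOWER_IS_BETTER = {"brisque"}


@dataclass(frozen=True)
class Flag:
    """A suspicious coordinate in a metric profile."""

    metric: str
    axis: str            # "timepoint" | "slice"
    coordinate: int
    severity: float      # robust deviations below (above, for BRISQUE) baseline


def select_equidistant_slices(n_slices: int, k: int = 10) -> list[int]:
    """``k`` evenly spaced slice indices (all of them when ``n_slices <= k``).

    Uses the cell-midpoint rule ``round((i + 0.5) * n / k)`` clipped to
    bounds and deduplicated, so the selection stays centred in the stack.
    """
    if n_slices < 1 or k < 1:
        raise ValueError("n_slices and k must be >= 1")
    if n_slices <= k:
        return list(range(n_slices))
    raw = [min(n_slices - 1, max(0, round((i + 0.5) * n_slices / k)))
           for i in range(k)]
    out: list[int] = []
    for idx in raw:
        if not out or idx > out[-1]:
            out.append(idx)
    return out


# ---------------------------------------------------------------------------
# Assessment
# ---------------------------------------------------------------------------

def _nr_rows(volume: ImageVolume, timepoint: int,
             model: nr_metrics.BrisqueModel, config: PipelineConfig) -> list[dict]:
    rows = []
    for k, s in enumerate(volume.slices):
        row = {"timepoint": timepoint, "slice": k,
               "brisque": np.nan, "total_variation": np.nan}
        try:
            row["total_variation"] = nr_metrics.total_variation(s)
            feats = nr_metrics.brisque_features(s, config.metrics)
            row["brisque"] = nr_metrics.brisque_score(feats, model)
        except ValueError as exc:
            logger.warning("NR metric failed at timepoint %d slice %d: %s",
                           timepoint, k, exc)
        rows.append(row)
    return rows


def assess_conventional(volume: ImageVolume,
                        config: Optional[PipelineConfig] = None,
                        model: Optional[nr_metrics.BrisqueModel] = None
                        ) -> pd.DataFrame:
    """NR profile of a conventional series: one row per slice.

    A metric failure on a slice is recorded as NaN and processing continues.
    """
    config = config or PipelineConfig(mode="Conventional")
    model = model or nr_metrics.load_default_model()
    return pd.DataFrame(_nr_rows(volume, 0, model, config))


def assess_dynamic(study: DynamicStudy,
                   config: Optional[PipelineConfig] = None,
                   model: Optional[nr_metrics.BrisqueModel] = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NR and FR profiles of a dynamic study.

    The FR profile has one row per (selected slice location x timepoint),
    comparing each timepoint against the pre-contrast phase at the same
    slice location.
    """
    config = config or PipelineConfig(mode="DCE")
    model = model or nr_metrics.load_default_model()

    nr_rows: list[dict] = []
    for t, vol in enumerate(study.timepoints):
        nr_rows.extend(_nr_rows(vol, t, model, config))
    nr_profile = pd.DataFrame(nr_rows)

    reference = study.timepoints[0]
    locations = select_equidistant_slices(reference.n_slices, config.k_locations)
    fr_rows: list[dict] = []
    for loc_index, slice_index in enumerate(locations):
        ref_slice = reference.slices[slice_index]
        for t, vol in enumerate(study.timepoints):
            target = vol.slices[slice_index]
            row = {"location": loc_index, "slice": slice_index, "timepoint": t}
            for name, fn in (("psnr", fr_metrics.psnr), ("ssim", fr_metrics.ssim),
                             ("ms_ssim", fr_metrics.ms_ssim),
                             ("fsim", fr_metrics.fsim)):
                try:
                    row[name] = fn(target, ref_slice, config.metrics)
                except ValueError as exc:
                    logger.warning("FR metric %s failed at location %d "
                                   "timepoint %d: %s", name, loc_index, t, exc)
                    row[name] = np.nan
            fr_rows.append(row)
    return nr_profile, pd.DataFrame(fr_rows)


def fr_summary(fr_profile: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each FR metric over slice locations, per timepoint."""
    grouped = fr_profile.groupby("timepoint")[list(FR_METRICS)]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{metric}_{stat}" for metric, stat in summary.columns]
    return summary.reset_index()


# ---------------------------------------------------------------------------
# Minima flagging
# ---------------------------------------------------------------------------

def _flag_series(values: np.ndarray, metric: str, axis: str,
                 threshold: float) -> list[Flag]:
    lower_better = metric in LOWER_IS_BETTER
    v = -values if lower_better else values      # minima of quality direction
    finite = np.isfinite(v)
    if finite.sum() < 3:
        return []
    median = float(np.median(v[finite]))
    mad = float(np.median(np.abs(v[finite] - median)))
    robust_sd = 1.4826 * mad

    flags = []
    n = len(v)
    for i in range(n):
        if not finite[i]:
            continue
        left = v[i - 1] if i > 0 and finite[i - 1] else None
        right = v[i + 1] if i < n - 1 and finite[i + 1] else None
        is_min = ((left is None or v[i] < left)
                  and (right is None or v[i] < right)
                  and not (left is None and right is None))
        if not is_min or v[i] >= median:
            continue
        severity = (median - v[i]) / robust_sd if robust_sd > 0 else np.inf
        if severity > threshold:
            flags.append(Flag(metric=metric, axis=axis, coordinate=i,
                              severity=float(severity)))
    return flags


def flag_minima(profile: pd.DataFrame, metric: str, axis: str = "timepoint",
                threshold: float = 2.0) -> list[Flag]:
    """Flag strict local minima of the quality direction in a metric profile.

    The profile is averaged over the non-scanned coordinate first (e.g. FR
    metrics over slice locations when scanning timepoints).  A coordinate is
    flagged when it is a strict local minimum of quality (maximum, for
    BRISQUE where smaller is better) *and* lies more than ``threshold``
    robust deviations (1.4826 x median absolute deviation) below the median.
    Severity is that deviation multiple; a constant profile yields no flags.
    """
    if metric not in profile.columns:
        raise ValueError(f"profile has no metric column {metric!r}")
    if axis not in profile.columns:
        raise ValueError(f"profile has no axis column {axis!r}")
    series = profile.groupby(axis)[metric].mean().sort_index()
    coords = series.index.to_numpy()
    flags = _flag_series(series.to_numpy(dtype=float), metric, axis, threshold)
    return [Flag(f.metric, f.axis, int(coords[f.coordinate]), f.severity)
            for f in flags]


def flag_profiles(nr_profile: Optional[pd.DataFrame],
                  fr_profile: Optional[pd.DataFrame],
                  threshold: float = 2.0) -> list[Flag]:
    """Default flag sweep: NR metrics along slices, FR metrics along timepoints."""
    flags: list[Flag] = []
    if nr_profile is not None and len(nr_profile):
        for metric in NR_METRICS:
            flags.extend(flag_minima(nr_profile, metric, axis="slice",
                                     threshold=threshold))
    if fr_profile is not None and len(fr_profile):
        for metric in FR_METRICS:
            flags.extend(flag_minima(fr_profile, metric, axis="timepoint",
                                     threshold=threshold))
    return flags


# ---------------------------------------------------------------------------
# Output folder
# ---------------------------------------------------------------------------

_CSV_KW = dict(index=False, lineterminator="\n", float_format="%.10g")


def write_outputs(images_dir: str | Path,
                  nr_profile: Optional[pd.DataFrame] = None,
                  fr_profile: Optional[pd.DataFrame] = None,
                  flags: Optional[list[Flag]] = None,
                  attributes: Optional[AttributeSummary] = None,
                  response: Optional[QuestionnaireResponse] = None,
                  config: Optional[PipelineConfig] = None) -> list[Path]:
    """Write every artifact of an assessment into ``<images_dir>/IQA``.

    Deterministic: identical inputs produce byte-identical text outputs.
    Raises before any partial write when the target is not writable.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or PipelineConfig()
    images_dir = Path(images_dir)
    if not images_dir.is_dir():
        raise OSError(f"images directory does not exist: {images_dir}")
    out = images_dir / "IQA"
    try:
        out.mkdir(exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}: {exc}") from exc

    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    if response is not None:
        emit(out / "questionnaire_response.txt").write_text(
            serialize_response(response), encoding="utf-8")

    if attributes is not None:
        meta = pd.DataFrame(
            sorted(attributes.as_dict().items()), columns=["attribute", "value"]
        ).astype({"value": str})
        meta.to_csv(emit(out / "metadata.csv"), **_CSV_KW)
        if config.write_xlsx:
            meta.to_excel(emit(out / "metadata.xlsx"), index=False)

    if nr_profile is not None:
        nr_profile.to_csv(emit(out / "nr_metrics.csv"), **_CSV_KW)
    if fr_profile is not None:
        fr_profile.to_csv(emit(out / "fr_metrics.csv"), **_CSV_KW)
        fr_summary(fr_profile).to_csv(emit(out / "fr_summary.csv"), **_CSV_KW)

    flag_frame = pd.DataFrame(
        [{"metric": f.metric, "axis": f.axis, "coordinate": f.coordinate,
          "severity": f.severity} for f in (flags or [])],
        columns=["metric", "axis", "coordinate", "severity"])
    flag_frame.to_csv(emit(out / "flags.csv"), **_CSV_KW)

    if config.write_plots:
        if nr_profile is not None and len(nr_profile):
            for metric in NR_METRICS:
                fig, ax = plt.subplots(figsize=(6, 3.5))
                for t, group in nr_profile.groupby("timepoint"):
                    ax.plot(group["slice"], group[metric], marker=".",
                            label=f"t{t}")
                ax.set_xlabel("slice index")
                ax.set_ylabel(metric)
                if nr_profile["timepoint"].nunique() > 1:
                    ax.legend(fontsize=7, ncols=2)
                fig.tight_layout()
                fig.savefig(emit(out / f"nr_{metric}.png"), dpi=100)
                plt.close(fig)
        if fr_profile is not None and len(fr_profile):
            for metric in FR_METRICS:
                fig, ax = plt.subplots(figsize=(6, 3.5))
                series = fr_profile.groupby("timepoint")[metric].mean()
                ax.plot(series.index, series.to_numpy(), marker="o")
                ax.set_xlabel("timepoint")
                ax.set_ylabel(f"mean {metric}")
                fig.tight_layout()
                fig.savefig(emit(out / f"fr_{metric}.png"), dpi=100)
                plt.close(fig)

    return written


def run_assessment(data: DynamicStudy | ImageVolume, images_dir: str | Path,
                   config: Optional[PipelineConfig] = None,
                   attributes: Optional[AttributeSummary] = None,
                   response: Optional[QuestionnaireResponse] = None
                   ) -> dict:
    """Full pipeline: assess, flag, and populate the ``IQA`` folder."""
    config = config or PipelineConfig(
        mode="DCE" if isinstance(data, DynamicStudy) else "Conventional")
    if isinstance(data, DynamicStudy):
        nr_profile, fr_profile = assess_dynamic(data, config)
    else:
        nr_profile, fr_profile = assess_conventional(data, config), None
    flags = flag_profiles(nr_profile, fr_profile, config.flag_threshold)
    files = write_outputs(images_dir, nr_profile=nr_profile,
                          fr_profile=fr_profile, flags=flags,
                          attributes=attributes, response=response,
                          config=config)
    return {"nr_profile": nr_profile, "fr_profile": fr_profile,
            "flags": flags, "files": files}
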