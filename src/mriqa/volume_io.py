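"""DICOM series discovery, reading, and header attribute extraction.

A *Conventional* input is a single directory of DICOM slices forming one 3D
volume; a *DCE* (dynamic contrast-enhanced) input is a directory of
per-timepoint sub-directories forming a 4D study whose first timepoint is the
pre-contrast phase.  Slices are ordered geometrically: by the projection of
ImagePositionPatient onto the slice normal, falling back to SliceLocation and
then InstanceNumber.  RescaleSlope/Intercept are applied exactly once at read
time and pixels are kept as floating point thereafter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pydicom

logger = logging.getLogger("mriqa")

#: DICOM header tags surfaced in the descriptive-attributes component.
ATTRIBUTE_TAGS = {
    "repetition_time_ms": "RepetitionTime",
    "echo_time_ms": "EchoTime",
    "slice_thickness_mm": "SliceThickness",
    "pixel_spacing_mm": "PixelSpacing",
    "acquisition_matrix": "AcquisitionMatrix",
    "field_strength_T": "MagneticFieldStrength",
    "sequence_name": "SequenceName",
    "series_description": "SeriesDescription",
    "manufacturer": "Manufacturer",
}


class SeriesReadError(Exception):
    """A DICOM series could not be discovered or assembled."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageSlice:
    """A single 2D MR image in arbitrary scanner units."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)   # (row mm, col mm)
    slice_location: float = 0.0                       # mm along the slice axis
    instance_number: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImageSlice.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageSlice.pixels must be finite")
        if self.rows < 8 or self.cols < 8:
            raise ValueError("ImageSlice must be at least 8x8")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise ValueError("pixel_spacing must be positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class AttributeSummary:
    """Informative acquisition parameters pulled from the DICOM header.

    Any field may be ``None`` when the originating tag is absent; values are
    never defaulted.
    """

    repetition_time_ms: Optional[float] = None
    echo_time_ms: Optional[float] = None
    slice_thickness_mm: Optional[float] = None
    pixel_spacing_mm: Optional[tuple[float, float]] = None
    acquisition_matrix: Optional[tuple[int, ...]] = None
    field_strength_T: Optional[float] = None
    sequence_name: Optional[str] = None
    series_description: Optional[str] = None
    manufacturer: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("repetition_time_ms", "echo_time_ms", "slice_thickness_mm",
                     "field_strength_T"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be positive when present")

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class ImageVolume:
    """An ordered stack of co-planar slices."""

    slices: list[ImageSlice]
    slice_thickness: Optional[float] = None
    header: dict = field(default_factory=dict)   # raw tag snapshot of slice 0

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("ImageVolume needs at least one slice")
        first = self.slices[0]
        for s in self.slices:
            if (s.rows, s.cols) != (first.rows, first.cols):
                raise ValueError("all slices in a volume must share in-plane dims")
            if s.pixel_spacing != first.pixel_spacing:
                raise ValueError("all slices in a volume must share pixel spacing")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.slices), self.slices[0].rows, self.slices[0].cols)

    def to_array(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices])


@dataclass
class DynamicStudy:
    """An ordered list of co-registered volumes over timepoints.

    Index 0 is the pre-contrast phase and serves as the full-reference
    comparison reference.
    """

    timepoints: list[ImageVolume]
    acquisition_times: Optional[list[float]] = None   # seconds

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("DynamicStudy needs at least 2 timepoints")
        shape = self.timepoints[0].shape
        for i, vol in enumerate(self.timepoints):
            if vol.shape != shape:
                raise ValueError(
                    f"timepoint {i} shape {vol.shape} differs from timepoint 0 {shape}"
                )

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)


@dataclass
class SeriesDescriptor:
    """A discovered input: one volume directory or an ordered timepoint list."""

    mode: str                       # "Conventional" | "DCE"
    directories: list[Path]         # 1 for Conventional, >= 2 for DCE
    files: list[list[Path]]         # DICOM candidates per directory


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------

def _dicom_candidates(directory: Path) -> list[Path]:
    return sorted(p for p in directory.iterdir() if p.is_file())


def discover_inputs(root: str | Path, mode: str) -> list[SeriesDescriptor]:
    """Find DICOM series under ``root``.

    Conventional mode returns one descriptor per directory of DICOM files
    (``root`` itself, or each of its sub-directories).  DCE mode returns a
    single study descriptor whose timepoints are the sub-directories of
    ``root`` ordered by DICOM AcquisitionTime when every timepoint carries
    one, else by name.
    """
    root = Path(root)
    if mode not in ("DCE", "Conventional"):
        raise ValueError(f"mode must be 'DCE' or 'Conventional', got {mode!r}")
    if not root.is_dir():
        raise SeriesReadError(f"input directory does not exist: {root}")

    loose = _dicom_candidates(root)
    # a prior assessment's output folder is never part of the input series
    subdirs = sorted(p for p in root.iterdir()
                     if p.is_dir() and p.name != "IQA")
    if loose and subdirs:
        raise SeriesReadError(
            f"mixed loose files and sub-directories under {root}: "
            f"offending file {loose[0]}"
        )
    if not loose and not subdirs:
        raise SeriesReadError(f"no DICOM series found under {root}")

    if mode == "Conventional":
        if loose:
            return [SeriesDescriptor("Conventional", [root], [loose])]
        out = []
        for d in subdirs:
            files = _dicom_candidates(d)
            if files:
                out.append(SeriesDescriptor("Conventional", [d], [files]))
        if not out:
            raise SeriesReadError(f"no DICOM series found under {root}")
        return out

    # DCE: sub-directories are timepoints
    if not subdirs:
        raise SeriesReadError(
            f"DCE mode expects per-timepoint sub-directories under {root}"
        )
    files = [_dicom_candidates(d) for d in subdirs]
    empty = [d for d, f in zip(subdirs, files) if not f]
    if empty:
        raise SeriesReadError(f"timepoint directory contains no files: {empty[0]}")
    order = _timepoint_order(subdirs, files)
    return [SeriesDescriptor("DCE", [subdirs[i] for i in order],
                             [files[i] for i in order])]


def _acquisition_seconds(ds: pydicom.Dataset) -> Optional[float]:
    raw = getattr(ds, "AcquisitionTime", None)
    if raw in (None, ""):
        return None
    raw = str(raw)
    try:
        hh, mm, ss = int(raw[0:2]), int(raw[2:4]), float(raw[4:] or 0)
    except ValueError:
        return None
    return hh * 3600 + mm * 60 + ss


def _timepoint_order(subdirs: Sequence[Path], files: Sequence[Sequence[Path]]
                     ) -> list[int]:
    times = []
    for flist in files:
        t = None
        for f in flist:
            try:
                ds = pydicom.dcmread(f, stop_before_pixels=True)
            except Exception:
                continue
            t = _acquisition_seconds(ds)
            break
        times.append(t)
    if all(t is not None for t in times):
        return sorted(range(len(times)), key=lambda i: (times[i], subdirs[i].name))
    return list(range(len(subdirs)))   # subdirs already lexicographic


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _iter_datasets(paths: Sequence[Path]) -> Iterator[tuple[Path, pydicom.Dataset]]:
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            logger.warning("skipping non-DICOM file %s", p)
            warnings.warn(f"skipping non-DICOM file {p}", stacklevel=2)
            continue
        if not hasattr(ds, "PixelData"):
            logger.warning("skipping DICOM without pixel data %s", p)
            continue
        yield p, ds


def _slice_sort_key(ds: pydicom.Dataset) -> tuple:
    # Primary: ImagePositionPatient projected onto the slice normal.
    iop = getattr(ds, "ImageOrientationPatient", None)
    ipp = getattr(ds, "ImagePositionPatient", None)
    if iop is not None and ipp is not None and len(iop) == 6 and len(ipp) == 3:
        row = np.asarray(iop[:3], float)
        col = np.asarray(iop[3:], float)
        normal = np.cross(row, col)
        return (0, float(np.dot(np.asarray(ipp, float), normal)))
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return (1, float(loc))
    return (2, float(getattr(ds, "InstanceNumber", 0)))


def _slice_from_dataset(ds: pydicom.Dataset) -> ImageSlice:
    pixels = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    spacing = (float(spacing[0]), float(spacing[1])) if spacing is not None else (1.0, 1.0)
    key = _slice_sort_key(ds)
    loc = key[1] if key[0] in (0, 1) else float(getattr(ds, "SliceLocation", 0.0) or 0.0)
    return ImageSlice(
        pixels=pixels,
        pixel_spacing=spacing,
        slice_location=loc,
        instance_number=int(getattr(ds, "InstanceNumber", 0) or 0),
    )


def _header_snapshot(ds: pydicom.Dataset) -> dict:
    header = {}
    for field_name, tag in ATTRIBUTE_TAGS.items():
        value = getattr(ds, tag, None)
        if value not in (None, ""):
            header[field_name] = value
    t = _acquisition_seconds(ds)
    if t is not None:
        header["acquisition_seconds"] = t
    return header


def _read_volume(paths: Sequence[Path]) -> ImageVolume:
    entries = []
    for p, ds in _iter_datasets(paths):
        entries.append((_slice_sort_key(ds), ds, p))
    if not entries:
        raise SeriesReadError("no readable DICOM slices in series")
    entries.sort(key=lambda e: (e[0], int(getattr(e[1], "InstanceNumber", 0) or 0)))

    # Duplicate slice positions: keep highest InstanceNumber.
    deduped: dict[tuple, tuple] = {}
    for key, ds, p in entries:
        if key in deduped:
            logger.warning("duplicate slice position %s; keeping highest "
                           "InstanceNumber (%s)", key, p)
        deduped[key] = (key, ds, p)
    entries = sorted(deduped.values(), key=lambda e: e[0])

    slices, dims = [], None
    for _, ds, p in entries:
        s = _slice_from_dataset(ds)
        if dims is None:
            dims = (s.rows, s.cols)
        elif (s.rows, s.cols) != dims:
            raise SeriesReadError(
                f"inconsistent in-plane dims in series: {p} is "
                f"{(s.rows, s.cols)}, expected {dims}"
            )
        slices.append(s)

    first_ds = entries[0][1]
    thickness = getattr(first_ds, "SliceThickness", None)
    return ImageVolume(
        slices=slices,
        slice_thickness=float(thickness) if thickness not in (None, "") else None,
        header=_header_snapshot(first_ds),
    )


def read_series(descriptor: SeriesDescriptor) -> ImageVolume | DynamicStudy:
    """Assemble the volume (Conventional) or study (DCE) behind a descriptor."""
    if descriptor.mode == "Conventional":
        return _read_volume(descriptor.files[0])
    volumes = [_read_volume(f) for f in descriptor.files]
    n = volumes[0].n_slices
    for i, v in enumerate(volumes):
        if v.n_slices != n:
            raise SeriesReadError(
                f"timepoint {i} has {v.n_slices} slices, expected {n}"
            )
    times = [v.header.get("acquisition_seconds") for v in volumes]
    return DynamicStudy(
        timepoints=volumes,
        acquisition_times=list(times) if all(t is not None for t in times) else None,
    )


def extract_attributes(volume: ImageVolume) -> AttributeSummary:
    """Build the descriptive-attributes summary from a volume's header.

    Missing tags stay absent (``None``); nothing is defaulted.
    """
    h = volume.header
    spacing = h.get("pixel_spacing_mm")
    matrix = h.get("acquisition_matrix")
    return AttributeSummary(
        repetition_time_ms=_opt_float(h.get("repetition_time_ms")),
        echo_time_ms=_opt_float(h.get("echo_time_ms")),
        slice_thickness_mm=_opt_float(h.get("slice_thickness_mm")),
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])) if spacing is not None else None,
        acquisition_matrix=tuple(int(v) for v in matrix) if matrix is not None else None,
        field_strength_T=_opt_float(h.get("field_strength_T")),
        sequence_name=_opt_str(h.get("sequence_name")),
        series_description=_opt_str(h.get("series_description")),
        manufacturer=_opt_str(h.get("manufacturer")),
    )


def _opt_float(v) -> Optional[float]:
    return None if v is None else float(v)


def _opt_str(v) -> Optional[str]:
    return None if v is None else str(v)
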