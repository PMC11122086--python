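"""Synthetic DCE-MRI phantom generator and minimal DICOM writer.

The phantom emulates a multi-phase dynamic contrast-enhanced breast study at
desk scale: ellipsoidal tissue compartments with per-timepoint multiplicative
enhancement, a static spatially-correlated texture field (so structure is
shared across phases and full-reference comparisons are meaningful), additive
Gaussian noise drawn independently per timepoint, and controllable
degradations per timepoint — in-plane Gaussian blur (motion surrogate) or a
through-plane slice shift (patient translocation between phases).

The writer emits one Part-10 DICOM file per slice with the geometry and
timing tags the reader consumes, quantising intensities to 16-bit with
RescaleSlope/Intercept, so write-then-read round trips reproduce the study
within the quantisation step.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import correlate1d, gaussian_filter

from .volume_io import DynamicStudy, ImageSlice, ImageVolume

__all__ = [
    "Ellipsoid", "PhantomSpec", "default_breast_spec", "make_dce_study",
    "make_volume", "apply_gaussian_blur", "apply_slice_shift",
    "write_dicom_series", "load_phantom_spec",
]

MR_IMAGE_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.4"


@dataclass(frozen=True)
class Ellipsoid:
    """A tissue compartment: axis-aligned ellipsoid in voxel coordinates."""

    center: tuple[float, float, float]     # (slice, row, col) voxels
    radii: tuple[float, float, float]      # (slice, row, col) voxels
    intensity: float                       # baseline signal, arbitrary units
    enhancement: tuple[float, ...] = ()    # multiplicative factor per timepoint

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
        return (((z - self.center[0]) / self.radii[0]) ** 2
                + ((y - self.center[1]) / self.radii[1]) ** 2
                + ((x - self.center[2]) / self.radii[2]) ** 2) <= 1.0


@dataclass
class PhantomSpec:
    """Study-level description of a synthetic dynamic acquisition.

    ``degradations`` maps timepoint index to ``("blur", kernel_size)`` or
    ``("shift", n_slices)``.  Overlapping compartments resolve last-listed
    wins.  ``texture_amplitude`` is the relative standard deviation of the
    multiplicative texture field; ``texture_scale_vox`` its correlation
    length.
    """

    shape: tuple[int, int, int] = (30, 192, 192)     # slices, rows, cols
    spacing: tuple[float, float, float] = (2.0, 0.8, 0.8)   # mm
    n_timepoints: int = 7
    compartments: list[Ellipsoid] = field(default_factory=list)
    noise_sigma: float = 4.0          # additive Gaussian, arbitrary units
    texture_amplitude: float = 0.12
    texture_scale_vox: float = 2.0
    degradations: dict[int, tuple] = field(default_factory=dict)
    seed: int = 0
    temporal_resolution_s: float = 90.0

    def __post_init__(self) -> None:
        if self.shape[1] < 16 or self.shape[2] < 16:
            raise ValueError("phantom in-plane dims must be at least 16")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        for comp in self.compartments:
            if comp.enhancement and len(comp.enhancement) != self.n_timepoints:
                raise ValueError("enhancement curve length must equal n_timepoints")
            if comp.enhancement and any(e <= 0 for e in comp.enhancement):
                raise ValueError("enhancement factors must be positive")
        for t, action in self.degradations.items():
            if not 0 <= t < self.n_timepoints:
                raise ValueError(f"degradation timepoint {t} out of range")
            kind = action[0]
            if kind == "blur" and action[1] % 2 == 0:
                raise ValueError("blur kernel size must be odd")
            if kind not in ("blur", "shift"):
                raise ValueError(f"unknown degradation {kind!r}")


def default_breast_spec(n_timepoints: int = 7,
                        shape: tuple[int, int, int] = (30, 192, 192),
                        noise_sigma: float = 4.0,
                        degradations: Optional[dict[int, tuple]] = None,
                        seed: int = 0) -> PhantomSpec:
    """A breast-like DCE phantom: fat body, fibroglandular core, enhancing lesion.

    Enhancement follows a typical wash-in/plateau lesion curve at ~90 s
    temporal resolution; fibroglandular tissue enhances mildly, fat hardly.
    """
    def curve(peak: float, wash_in: int = 2) -> tuple[float, ...]:
        factors = []
        for t in range(n_timepoints):
            if t == 0:
                factors.append(1.0)
            elif t < wash_in:
                factors.append(1.0 + (peak - 1.0) * t / wash_in)
            else:
                factors.append(peak * (1.0 - 0.02 * (t - wash_in)))
        return tuple(factors)

    nz, ny, nx = shape
    compartments = [
        Ellipsoid(center=(nz / 2, ny / 2, nx / 2),
                  radii=(nz * 0.45, ny * 0.40, nx * 0.42),
                  intensity=220.0, enhancement=curve(1.05)),
        Ellipsoid(center=(nz / 2, ny * 0.45, nx * 0.5),
                  radii=(nz * 0.30, ny * 0.22, nx * 0.28),
                  intensity=140.0, enhancement=curve(1.25)),
        Ellipsoid(center=(nz * 0.55, ny * 0.40, nx * 0.62),
                  radii=(nz * 0.12, ny * 0.08, nx * 0.08),
                  intensity=180.0, enhancement=curve(2.2)),
    ]
    return PhantomSpec(shape=shape, n_timepoints=n_timepoints,
                       compartments=compartments, noise_sigma=noise_sigma,
                       degradations=dict(degradations or {}), seed=seed)


# ---------------------------------------------------------------------------
# Study synthesis
# ---------------------------------------------------------------------------

def _baseline_and_masks(spec: PhantomSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    baseline = np.zeros(spec.shape)
    masks = []
    for comp in spec.compartments:
        m = comp.mask(spec.shape)
        baseline[m] = comp.intensity          # last-listed wins on overlap
        masks.append(m)
    # Later compartments override earlier ones where they overlap.
    for i, comp in enumerate(spec.compartments):
        for later in masks[i + 1:]:
            masks[i] = masks[i] & ~later
    return baseline, masks


def _texture_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.texture_amplitude <= 0:
        return np.ones(spec.shape)
    raw = gaussian_filter(rng.standard_normal(spec.shape), spec.texture_scale_vox)
    raw /= raw.std() if raw.std() > 0 else 1.0
    return np.clip(1.0 + spec.texture_amplitude * raw, 0.05, None)


def _volume_from_array(arr: np.ndarray, spec: PhantomSpec) -> ImageVolume:
    slices = [
        ImageSlice(pixels=arr[k],
                   pixel_spacing=(spec.spacing[1], spec.spacing[2]),
                   slice_location=k * spec.spacing[0],
                   instance_number=k + 1)
        for k in range(arr.shape[0])
    ]
    return ImageVolume(slices=slices, slice_thickness=spec.spacing[0])


def make_volume(spec: PhantomSpec, timepoint: int = 0) -> ImageVolume:
    """Single 3D volume of the phantom at one timepoint (with noise)."""
    return _volume_from_array(_make_arrays(spec)[timepoint], spec)


def _make_arrays(spec: PhantomSpec) -> list[np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    baseline, masks = _baseline_and_masks(spec)
    texture = _texture_field(spec, rng)

    arrays = []
    for t in range(spec.n_timepoints):
        vol = baseline.copy()
        for comp, mask in zip(spec.compartments, masks):
            factor = comp.enhancement[t] if comp.enhancement else 1.0
            vol[mask] = comp.intensity * factor
        vol *= texture
        action = spec.degradations.get(t)
        if action is not None and action[0] == "blur":
            vol = np.stack([apply_gaussian_blur(sl, action[1]) for sl in vol])
        if spec.noise_sigma > 0:
            vol = vol + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        arrays.append(vol)
    return arrays


def make_dce_study(spec: PhantomSpec) -> DynamicStudy:
    """Synthesise the dynamic study described by ``spec``.

    Timepoint 0 carries baseline intensities; each timepoint applies the
    enhancement curves, then any scheduled in-plane degradation, then fresh
    additive noise; through-plane shifts are applied volume-wise at the end.
    Deterministic for a fixed seed.
    """
    if spec.n_timepoints < 2:
        raise ValueError("a dynamic study needs >= 2 timepoints; "
                         "use make_volume for a conventional phantom")
    arrays = _make_arrays(spec)
    volumes = [_volume_from_array(a, spec) for a in arrays]
    times = [float(t * spec.temporal_resolution_s) for t in range(spec.n_timepoints)]
    study = DynamicStudy(timepoints=volumes, acquisition_times=times)
    for t, action in spec.degradations.items():
        if action[0] == "shift":
            study = apply_slice_shift(study, action[1], {t})
    return study


# ---------------------------------------------------------------------------
# Degradations
# ---------------------------------------------------------------------------

def _blur_kernel(size: int) -> np.ndarray:
    if size % 2 == 0 or size < 3:
        raise ValueError("blur kernel size must be odd and >= 3")
    sigma = 0.3 * ((size - 1) / 2.0 - 1.0) + 0.8
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def apply_gaussian_blur(image, kernel: int = 7) -> np.ndarray:
    """2D Gaussian blur with an odd ``kernel x kernel`` window.

    Sigma follows the common computer-vision default
    ``0.3*((kernel-1)/2 - 1) + 0.8``; borders are reflective, so the mean
    intensity is preserved exactly for the symmetric kernel.
    """
    arr = image.pixels if isinstance(image, ImageSlice) else np.asarray(image, float)
    k = _blur_kernel(kernel)
    out = correlate1d(arr, k, axis=0, mode="reflect")
    return correlate1d(out, k, axis=1, mode="reflect")


def apply_slice_shift(study: DynamicStudy, shift: int,
                      timepoints: Sequence[int] | set[int]) -> DynamicStudy:
    """Shift listed timepoints along the slice axis with edge replication.

    Simulates through-plane patient translocation between phases: slice ``i``
    of a shifted volume shows the anatomy of slice ``i - shift``; slices
    pushed past the edge replicate the boundary slice.
    """
    n = study.timepoints[0].n_slices
    if abs(shift) >= n:
        raise ValueError(f"|shift| = {abs(shift)} must be smaller than "
                         f"slice count {n}")
    targets = set(timepoints)
    new_volumes = []
    for t, vol in enumerate(study.timepoints):
        if t not in targets or shift == 0:
            new_volumes.append(vol)
            continue
        arr = vol.to_array()
        idx = np.clip(np.arange(n) - shift, 0, n - 1)
        shifted = arr[idx]
        slices = [
            ImageSlice(pixels=shifted[k],
                       pixel_spacing=vol.slices[k].pixel_spacing,
                       slice_location=vol.slices[k].slice_location,
                       instance_number=vol.slices[k].instance_number)
            for k in range(n)
        ]
        new_volumes.append(ImageVolume(slices=slices,
                                       slice_thickness=vol.slice_thickness,
                                       header=dict(vol.header)))
    return DynamicStudy(timepoints=new_volumes,
                        acquisition_times=study.acquisition_times)


# ---------------------------------------------------------------------------
# DICOM writer
# ---------------------------------------------------------------------------

def _format_acquisition_time(seconds: float) -> str:
    base = datetime.timedelta(hours=12) + datetime.timedelta(seconds=seconds)
    total = base.total_seconds()
    hh, rem = divmod(int(total), 3600)
    mm, ss = divmod(rem, 60)
    frac = total - int(total)
    return f"{hh:02d}{mm:02d}{ss:02d}.{int(round(frac * 1e6)):06d}"


def _write_slice(path: Path, pixels: np.ndarray, *, spacing: tuple[float, float],
                 thickness: float, location: float, instance: int,
                 series_uid: str, acq_seconds: float,
                 series_description: str) -> None:
    lo, hi = float(pixels.min()), float(pixels.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    stored = np.round((pixels - lo) / slope).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE_UID
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = MR_IMAGE_STORAGE_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.SeriesInstanceUID = series_uid
    ds.SeriesDescription = series_description
    ds.Manufacturer = "mriqa phantom"
    ds.SequenceName = "fl3d_dce"
    ds.MagneticFieldStrength = 3.0
    ds.RepetitionTime = 4.5
    ds.EchoTime = 1.8
    ds.AcquisitionMatrix = [0, pixels.shape[1], pixels.shape[0], 0]
    ds.AcquisitionTime = _format_acquisition_time(acq_seconds)
    ds.InstanceNumber = instance
    # decimal-string tags are formatted to satisfy the 16-char DS limit
    ds.SliceThickness = f"{thickness:.8g}"
    ds.SliceLocation = f"{location:.8g}"
    ds.PixelSpacing = [f"{spacing[0]:.8g}", f"{spacing[1]:.8g}"]
    ds.ImagePositionPatient = [0, 0, f"{location:.8g}"]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{lo:.10g}"
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_dicom_series(data: DynamicStudy | ImageVolume, out_dir: str | Path,
                       series_description: str = "mriqa phantom") -> list[Path]:
    """Write a volume (flat directory) or study (``t0``..``tN`` sub-directories).

    Returns the written file paths.  Intensities are quantised to 16 bits
    with per-slice RescaleSlope/Intercept, so read-back error is bounded by
    half a quantisation step.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: list[Path] = []

    def write_volume(vol: ImageVolume, directory: Path, acq_seconds: float,
                     description: str) -> None:
        directory.mkdir(parents=True, exist_ok=True)
        series_uid = generate_uid()
        for k, s in enumerate(vol.slices):
            path = directory / f"slice{k:03d}.dcm"
            _write_slice(
                path, s.pixels, spacing=s.pixel_spacing,
                thickness=vol.slice_thickness or 1.0,
                location=s.slice_location, instance=s.instance_number or k + 1,
                series_uid=series_uid, acq_seconds=acq_seconds,
                series_description=description,
            )
            written.append(path)

    if isinstance(data, DynamicStudy):
        times = data.acquisition_times or [90.0 * t for t in range(data.n_timepoints)]
        for t, vol in enumerate(data.timepoints):
            write_volume(vol, out_dir / f"t{t}", times[t],
                         f"{series_description} phase {t}")
    else:
        write_volume(data, out_dir, 0.0, series_description)
    return written


# ---------------------------------------------------------------------------
# Spec files
# ---------------------------------------------------------------------------

def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Read a PhantomSpec from a JSON file (see ``PhantomSpec`` fields)."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    compartments = [
        Ellipsoid(center=tuple(c["center"]), radii=tuple(c["radii"]),
                  intensity=float(c["intensity"]),
                  enhancement=tuple(c.get("enhancement", ())))
        for c in raw.pop("compartments", [])
    ]
    degradations = {
        int(k): tuple(v) for k, v in raw.pop("degradations", {}).items()
    }
    for key in ("shape", "spacing"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomSpec(compartments=compartments, degradations=degradations, **raw)


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    raw = asdict(spec)
    raw["degradations"] = {str(k): list(v) for k, v in spec.degradations.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(raw, fh, indent=2)
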