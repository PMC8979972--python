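"""Cine series/stack containers and file I/O.

Conventions used throughout the package:

* frames are stored ``(time, row, col)`` with the superior anatomy at row 0;
* pixel indices are 0-based; ROIs are half-open ``[min, max)``;
* lengths in mm, areas in cm**2, volumes in ml, mass in g, time in ms.

Supported on-disk formats: a fixture container (one compressed ``.npz``
per slice holding the frame array plus a JSON metadata sidecar), NIfTI-1
(read), and single-frame DICOM series (read).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "CineSeries",
    "CineStack",
    "RespROI",
    "MaskSet",
    "crop_roi",
    "read_cine",
    "write_fixture",
    "read_fixture",
]


@dataclass
class CineSeries:
    """One slice's 2D+time image sequence with geometry and timing metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; frames ordered by
        acquisition time.
    pixel_spacing
        ``(row, col)`` spacing in mm.
    frame_interval
        Time between frames in ms.
    slice_thickness, slice_gap
        Slice thickness and inter-slice gap in mm.
    slice_location
        Position along the stack axis in mm (base -> apex increasing here).
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_interval: float
    slice_thickness: float
    slice_gap: float = 0.0
    slice_location: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, rows, cols) array with n_frames >= 1")
        sr, sc = self.pixel_spacing
        if sr <= 0 or sc <= 0:
            raise ValueError("incomplete geometry: pixel_spacing must be positive")
        if self.frame_interval <= 0:
            raise ValueError("incomplete geometry: frame_interval must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("incomplete geometry: slice_thickness must be positive")
        if self.slice_gap < 0:
            raise ValueError("incomplete geometry: slice_gap must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm**2."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0

    def metadata(self) -> dict:
        return {
            "pixel_spacing": list(self.pixel_spacing),
            "frame_interval": self.frame_interval,
            "slice_thickness": self.slice_thickness,
            "slice_gap": self.slice_gap,
            "slice_location": self.slice_location,
            "label": self.label,
        }


@dataclass
class CineStack:
    """Ordered collection of :class:`CineSeries`, base -> apex."""

    slices: list[CineSeries]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("stack too short: no slices")
        locs = [s.slice_location for s in self.slices]
        d = np.diff(locs)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("inconsistent series: slice locations not strictly monotone")
        sp = self.slices[0].pixel_spacing
        for s in self.slices[1:]:
            if s.pixel_spacing != sp:
                raise ValueError("inconsistent series: pixel spacing differs across slices")

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[CineSeries]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> CineSeries:
        return self.slices[i]

    @property
    def slice_spacing_mm(self) -> float:
        s0 = self.slices[0]
        return s0.slice_thickness + s0.slice_gap


@dataclass(frozen=True)
class RespROI:
    """Rectangular ROI, 0-based half-open pixel ranges ``[min, max)``."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("ROI outside image: empty ROI")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("ROI outside image: negative index")
        if self.area_px < 64:
            raise ValueError("ROI outside image: ROI area below 64 px")

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_max - self.row_min, self.col_max - self.col_min

    @property
    def area_px(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)

    def validate_bounds(self, frame_shape: tuple[int, int]) -> None:
        if self.row_max > frame_shape[0] or self.col_max > frame_shape[1]:
            raise ValueError("ROI outside image")

    @classmethod
    def from_string(cls, text: str) -> "RespROI":
        """Parse ``"r0:r1,c0:c1"``."""
        rows, cols = text.split(",")
        r0, r1 = (int(v) for v in rows.split(":"))
        c0, c1 = (int(v) for v in cols.split(":"))
        return cls(r0, r1, c0, c1)


def crop_roi(series: CineSeries, roi: RespROI) -> np.ndarray:
    """Crop an ROI from every frame and flatten to vectors.

    Returns an ``(n_frames, n_pixels)`` array, one flattened sub-image per
    frame in acquisition order (a 40x40 ROI yields 1600-dimensional vectors).
    """
    roi.validate_bounds(series.frame_shape)
    sub = series.frames[:, roi.row_min:roi.row_max, roi.col_min:roi.col_max]
    return sub.reshape(series.n_frames, -1)


class MaskSet:
    """Binary endo/epicardial masks keyed by (slice index, state, phase).

    ``state`` is a respiratory state label (e.g. ``"expiration"``), ``phase``
    is ``"ed"`` or ``"es"``. Endocardial masks must be contained in the
    epicardial masks.
    """

    def __init__(self) -> None:
        self._masks: dict[tuple[int, str, str], dict[str, np.ndarray]] = {}

    def add(self, slice_index: int, state: str, phase: str,
            endo: np.ndarray, epi: np.ndarray) -> None:
        endo = np.asarray(endo, dtype=bool)
        epi = np.asarray(epi, dtype=bool)
        if endo.shape != epi.shape:
            raise ValueError("invalid mask: endo/epi shapes differ")
        if np.any(endo & ~epi):
            raise ValueError("inverted delineation: endo mask outside epi mask")
        self._masks[(slice_index, state, phase)] = {"endo": endo, "epi": epi}

    def get(self, slice_index: int, state: str, phase: str) -> dict[str, np.ndarray]:
        return self._masks[(slice_index, state, phase)]

    def __contains__(self, key: tuple[int, str, str]) -> bool:
        return key in self._masks

    def keys(self):
        return self._masks.keys()

    def slice_indices(self, state: str, phase: str) -> list[int]:
        return sorted(i for (i, s, p) in self._masks if s == state and p == phase)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = []
        for n, ((i, s, p), m) in enumerate(sorted(self._masks.items())):
            name = f"mask_{n:03d}.npz"
            np.savez_compressed(directory / name, endo=m["endo"], epi=m["epi"])
            index.append({"slice": i, "state": s, "phase": p, "file": name})
        (directory / "masks.json").write_text(json.dumps(index, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "MaskSet":
        directory = Path(directory)
        index = json.loads((directory / "masks.json").read_text())
        out = cls()
        for rec in index:
            with np.load(directory / rec["file"]) as z:
                out.add(rec["slice"], rec["state"], rec["phase"], z["endo"], z["epi"])
        return out


# ---------------------------------------------------------------------------
# fixture container

def write_fixture(data: CineSeries | CineStack, path: str | Path) -> Path:
    """Write a series or stack to the fixture format.

    A series becomes ``<path>.npz`` + ``<path>.json``; a stack becomes a
    directory of per-slice containers plus a ``stack.json`` manifest.
    """
    path = Path(path)
    if isinstance(data, CineSeries):
        base = path.with_suffix("") if path.suffix == ".npz" else path
        np.savez_compressed(base.with_suffix(".npz"), frames=data.frames)
        base.with_suffix(".json").write_text(json.dumps(data.metadata(), indent=1))
        return base.with_suffix(".npz")
    path.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(data.slices):
        name = f"slice_{i:03d}"
        np.savez_compressed(path / f"{name}.npz", frames=s.frames)
        (path / f"{name}.json").write_text(json.dumps(s.metadata(), indent=1))
        manifest.append(name)
    (path / "stack.json").write_text(json.dumps({"slices": manifest}, indent=1))
    return path


def _read_fixture_series(npz_path: Path) -> CineSeries:
    sidecar = npz_path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"incomplete geometry: missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    with np.load(npz_path) as z:
        frames = z["frames"]
    return CineSeries(
        frames=frames,
        pixel_spacing=tuple(meta["pixel_spacing"]),
        frame_interval=meta["frame_interval"],
        slice_thickness=meta["slice_thickness"],
        slice_gap=meta.get("slice_gap", 0.0),
        slice_location=meta.get("slice_location", 0.0),
        label=meta.get("label", ""),
    )


def read_fixture(path: str | Path) -> CineSeries | CineStack:
    path = Path(path)
    if path.is_dir():
        manifest = json.loads((path / "stack.json").read_text())
        return CineStack([_read_fixture_series(path / f"{n}.npz") for n in manifest["slices"]])
    return _read_fixture_series(path if path.suffix == ".npz" else path.with_suffix(".npz"))


# ---------------------------------------------------------------------------
# NIfTI

def _read_nifti(path: Path, frame_interval: float | None,
                slice_thickness: float | None) -> CineSeries | CineStack:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[1]), float(zooms[0]))  # (row, col) = (j, i)
    if data.ndim == 3:
        # (i, j, t): single slice
        dt = frame_interval
        if dt is None:
            raise ValueError("incomplete geometry: frame interval missing (pass frame_interval)")
        th = slice_thickness if slice_thickness is not None else float(zooms[2]) if len(zooms) > 2 else None
        if th is None or th <= 0:
            raise ValueError("incomplete geometry: slice thickness missing")
        frames = data.transpose(2, 1, 0)
        return CineSeries(frames, spacing, dt, th, label=path.name)
    if data.ndim == 4:
        dt = frame_interval
        if dt is None:
            tz = float(zooms[3]) if len(zooms) > 3 else 0.0
            units = img.header.get_xyzt_units()[1] if hasattr(img.header, "get_xyzt_units") else "unknown"
            if tz > 0:
                dt = tz * 1000.0 if units == "sec" else tz
        if dt is None or dt <= 0:
            raise ValueError("incomplete geometry: frame interval missing (pass frame_interval)")
        th = slice_thickness if slice_thickness is not None else float(zooms[2])
        if th <= 0:
            raise ValueError("incomplete geometry: slice thickness missing")
        slices = []
        for k in range(data.shape[2]):
            frames = data[:, :, k, :].transpose(2, 1, 0)
            slices.append(CineSeries(frames, spacing, dt, th,
                                     slice_location=k * th, label=f"{path.name}[{k}]"))
        return slices[0] if len(slices) == 1 else CineStack(slices)
    raise ValueError("inconsistent series: expected 3D or 4D NIfTI")


# ---------------------------------------------------------------------------
# DICOM (single-frame files grouped by series, ordered by instance/time)

def _read_dicom_dir(path: Path, frame_interval: float | None) -> CineSeries | CineStack:
    import pydicom

    datasets = []
    for f in sorted(path.iterdir()):
        if f.is_file():
            try:
                datasets.append(pydicom.dcmread(str(f)))
            except Exception:
                continue
    if not datasets:
        raise ValueError("inconsistent series: no readable DICOM files")
    for ds in datasets:
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise ValueError("inconsistent series: multi-frame DICOM not supported")

    by_slice: dict[tuple, list] = {}
    for ds in datasets:
        key = (str(getattr(ds, "SeriesInstanceUID", "")),
               float(getattr(ds, "SliceLocation", 0.0)))
        by_slice.setdefault(key, []).append(ds)

    def sort_key(ds):
        inst = getattr(ds, "InstanceNumber", None)
        t = getattr(ds, "TriggerTime", None)
        if t is None:
            t = getattr(ds, "AcquisitionTime", None)
        return (float(inst) if inst is not None else np.inf,
                float(t) if t is not None else np.inf)

    slices = []
    for (_, loc), group in sorted(by_slice.items(), key=lambda kv: kv[0][1]):
        group.sort(key=sort_key)
        frames = np.stack([ds.pixel_array.astype(float) for ds in group])
        ds0 = group[0]
        spacing = getattr(ds0, "PixelSpacing", None)
        thickness = getattr(ds0, "SliceThickness", None)
        if spacing is None or thickness is None:
            raise ValueError("incomplete geometry: missing PixelSpacing/SliceThickness")
        dt = frame_interval
        if dt is None:
            ft = getattr(ds0, "FrameTime", None)
            if ft is not None:
                dt = float(ft)
            elif len(group) > 1:
                t0, t1 = sort_key(group[0])[1], sort_key(group[1])[1]
                if np.isfinite(t0) and np.isfinite(t1) and t1 > t0:
                    dt = float(t1 - t0)
        if dt is None or dt <= 0:
            raise ValueError("incomplete geometry: frame interval missing (pass frame_interval)")
        slices.append(CineSeries(frames, (float(spacing[0]), float(spacing[1])),
                                 dt, float(thickness), slice_location=float(loc),
                                 label=str(getattr(ds0, "SeriesDescription", ""))))
    if len(slices) == 1:
        return slices[0]
    return CineStack(slices)


def read_cine(path: str | Path, format: str | None = None, *,
              frame_interval: float | None = None,
              slice_thickness: float | None = None) -> CineSeries | CineStack:
    """Read a cine series or stack from disk.

    ``format`` is one of ``"fixture"``, ``"nifti"``, ``"dicom"``; when omitted
    it is inferred from the path. Missing metadata (e.g. a NIfTI without a
    time step) must be supplied through the override keyword arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
            format = "nifti"
        elif path.suffix == ".npz" or (path.is_dir() and (path / "stack.json").exists()):
            format = "fixture"
        elif path.is_dir():
            format = "dicom"
        else:
            raise ValueError(f"cannot infer format for {path}")
    if format == "fixture":
        return read_fixture(path)
    if format == "nifti":
        return _read_nifti(path, frame_interval, slice_thickness)
    if format in ("dicom", "dicom-series"):
        return _read_dicom_dir(path, frame_interval)
    raise ValueError(f"unknown format {format!r}")
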