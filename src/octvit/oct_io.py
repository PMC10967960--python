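"""Reading OCT B-scan stacks and writing feature/summary tables.

A stack is one eye at one visit: an ordered set of 2-D greyscale B-scans
(rows = axial depth, columns = lateral position) plus the per-pixel area in
µm² and eye metadata.  Sources supported:

* a directory of PNG/TIFF frames (sorted lexicographically),
* a multipage TIFF,
* an AVI video container (frames extracted in order; best-effort since
  lossy codecs do not round-trip intensities).

Intensities are normalised to [0, 1] on read by dividing by the maximum
representable value of the stored integer dtype, so analysis thresholds are
bit-depth independent.  Colour frames are reduced by an unweighted channel
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import EmptyStackError, FormatError, InputError
from .opacities import OpacityRecord

#: per-pixel area printed by the acquisition protocol (µm²)
DEFAULT_PIXEL_AREA_UM2 = 3.815

#: acquisition geometry: 3 mm lateral scan over 1536 columns, 496 rows
SCAN_WIDTH_UM = 3000.0
SCAN_WIDTH_PX = 1536
SCAN_HEIGHT_PX = 496
SCANS_PER_EYE = 61

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
_VIDEO_SUFFIXES = {".avi", ".mp4", ".mov"}

FEATURE_COLUMNS = [
    "frame_index",
    "centroid_row",
    "centroid_col",
    "area_px",
    "area_um2",
    "mean_intensity",
    "eccentricity",
    "orientation_deg",
    "size_class",
    "animal",
    "cohort",
    "sex",
    "eye",
    "week",
]


def pixel_area_from_scan(
    scan_width_um: float = SCAN_WIDTH_UM, width_px: int = SCAN_WIDTH_PX
) -> float:
    """Per-pixel area (µm²) for square pixels spanning a known lateral width.

    The standard rodent posterior-pole protocol covers 3 mm with 1536
    columns, i.e. 1.953125 µm square pixels → 3.8147 µm²/pixel.
    """
    if scan_width_um <= 0 or width_px <= 0:
        raise ValueError("scan width and pixel count must be positive")
    return (scan_width_um / width_px) ** 2


def frame_area_mm2(
    width_px: int = SCAN_WIDTH_PX,
    height_px: int = SCAN_HEIGHT_PX,
    pixel_area_um2: float | None = None,
) -> float:
    """Total B-scan area in mm² from raster size and per-pixel area."""
    if pixel_area_um2 is None:
        pixel_area_um2 = pixel_area_from_scan()
    return width_px * height_px * pixel_area_um2 * 1e-6


@dataclass
class BScanStack:
    """Ordered greyscale B-scans of one eye at one timepoint."""

    frames: np.ndarray  # (n_frames, height, width) float array in [0, 1]
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2
    eye_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n, height, width) array")
        if self.frames.shape[0] == 0:
            raise EmptyStackError("stack contains zero frames")
        if not np.isfinite(self.frames).all() or (self.frames < 0).any():
            raise FormatError("intensities must be finite and non-negative")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]


def _to_grey(arr: np.ndarray) -> np.ndarray:
    """Greyscale conversion (unweighted channel mean) and [0,1] normalisation."""
    a = np.asarray(arr)
    if a.ndim == 3:  # colour: unweighted channel mean
        a = a.astype(np.float64).mean(axis=2)
        dtype = np.asarray(arr).dtype
    elif a.ndim == 2:
        dtype = a.dtype
        a = a.astype(np.float64)
    else:
        raise FormatError(f"frame has unsupported dimensionality {a.ndim}")
    if np.issubdtype(dtype, np.integer):
        a = a / np.iinfo(dtype).max
    return a


def _read_frames_from_dir(path: Path) -> list[np.ndarray]:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not files:
        raise EmptyStackError(f"no image frames found in {path}")
    return [iio.imread(p) for p in files]


def _read_frames_from_file(path: Path) -> list[np.ndarray]:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            return [arr]
        return list(arr)
    if suffix in _VIDEO_SUFFIXES:
        import imageio.v3 as iio

        frames = list(iio.imiter(path))
        if not frames:
            raise EmptyStackError(f"no frames decoded from {path}")
        return frames
    if suffix in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        return [iio.imread(path)]
    raise InputError(f"unsupported container: {path}")


def read_stack(
    path: str | Path,
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2,
    eye_meta: dict | None = None,
) -> BScanStack:
    """Read an ordered B-scan stack from a directory, multipage TIFF or video.

    Raises
    ------
    InputError / EmptyStackError / FormatError
        For an unreadable path, zero frames, or inconsistent frame sizes.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"path does not exist: {path}")
    try:
        raw = _read_frames_from_dir(path) if path.is_dir() else _read_frames_from_file(path)
    except (EmptyStackError, InputError):
        raise
    except Exception as exc:  # codec/parse failures from the readers
        raise InputError(f"cannot read stack from {path}: {exc}") from exc
    if len(raw) == 0:
        raise EmptyStackError(f"stack at {path} contains zero frames")
    grey = [_to_grey(f) for f in raw]
    shapes = {g.shape for g in grey}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent frame sizes in {path}: {sorted(shapes)}")
    return BScanStack(
        frames=np.stack(grey), pixel_area_um2=pixel_area_um2, eye_meta=dict(eye_meta or {})
    )


def write_stack(stack: BScanStack, path: str | Path) -> None:
    """Write a stack as a lossless multipage float32 TIFF (read/write round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32), photometric="minisblack")


def write_feature_table(
    records: list[OpacityRecord], path: str | Path, eye_meta: dict | None = None
) -> None:
    """Write one row per opacity as CSV; numeric fields round-trip exactly.

    An empty record list produces a header-only table.
    """
    meta = dict(eye_meta or {})
    rows = []
    for r in records:
        rows.append(
            {
                "frame_index": r.frame_index,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "mean_intensity": r.mean_intensity,
                "eccentricity": r.eccentricity,
                "orientation_deg": r.orientation_deg,
                "size_class": r.size_class,
                "animal": meta.get("animal"),
                "cohort": meta.get("cohort"),
                "sex": meta.get("sex"),
                "eye": meta.get("eye"),
                "week": meta.get("week"),
            }
        )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, float_precision="round_trip")


def write_summary_table(summaries: list, path: str | Path) -> None:
    """Write per-eye summaries (one row per animal/eye/week) as CSV."""
    rows = []
    for s in summaries:
        row = {
            "animal": s.eye_meta.get("animal"),
            "cohort": s.eye_meta.get("cohort"),
            "sex": s.eye_meta.get("sex"),
            "eye": s.eye_meta.get("eye"),
            "week": s.eye_meta.get("week"),
            "iop_mmHg": s.eye_meta.get("iop_mmHg"),
            "vit_rpe": s.vit_rpe,
            "total_area_um2": s.total_area_um2,
            "mean_n_opacities": s.mean_n_opacities,
            "mean_area_um2": s.mean_area_um2,
            "n_opacities": s.n_opacities,
            "n_frames": s.n_frames,
        }
        for c, v in s.class_percent.items():
            row[f"percent_{c}"] = v
        for c, v in s.class_mean_area_um2.items():
            row[f"mean_area_{c}"] = v
        for c, v in s.class_mean_eccentricity.items():
            row[f"mean_ecc_{c}"] = v
        for c, v in s.class_mean_intensity.items():
            row[f"mean_int_{c}"] = v
        for c, v in s.class_mean_orientation_deg.items():
            row[f"mean_orient_{c}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
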