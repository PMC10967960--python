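"""Synthetic OCT phantom with known ground truth.

The phantom emulates the acquisition geometry of a rodent posterior-pole
protocol — 61 B-scans of 1536 × 496 pixels at 3.815 µm²/pixel — as a layered
scene: dark vitreous above a bright retinal band terminating in a brighter
RPE band, dark below, with sinusoidally curved boundaries, multiplicative
gamma speckle, and elliptical hyperreflective blobs injected into the
vitreous.  The generator records ground truth for every blob
(post-rasterisation centroid, pixel area, eccentricity, orientation, mean
intensity, size class), the true layer boundaries per frame, and the
designed VIT/RPE ratio — the oracle for every other module.

Ground truth stores values re-measured on the rasterised pixel masks with
the same moment code used by the detector, so feature-recovery tests are
exact rather than limited by rasterisation aliasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PhantomError
from .oct_io import DEFAULT_PIXEL_AREA_UM2, BScanStack
from .opacities import CLASS_NAMES, classify_size, shape_features

#: per-class area sampling ranges (µm²), kept clear of the class boundaries
#: so rasterisation (±1–2 px ≈ ±7.6 µm²) cannot flip a blob's true class
DEFAULT_CLASS_AREA_RANGES = {
    "isolated": (3.0, 8.0),
    "non_activated": (16.0, 44.0),
    "activated": (60.0, 230.0),
    "complex": (280.0, 500.0),
}

#: class-midpoint areas (µm²) used by taxonomy self-tests
CLASS_MIDPOINT_AREAS = {
    "isolated": 5.0,
    "non_activated": 30.0,
    "activated": 150.0,
    "complex": 400.0,
}


@dataclass
class BlobSpec:
    """One requested opacity: placement is random unless row/col given."""

    area_um2: float
    eccentricity: float = 0.6
    orientation_deg: float = 0.0
    contrast: float = 6.0  # intensity added, in multiples of vitreous mean
    frame: int | None = None
    row: int | None = None
    col: int | None = None


@dataclass
class PhantomConfig:
    """Scene layout, noise model and blob population of a phantom stack."""

    height_px: int = 496
    width_px: int = 1536
    n_frames: int = 61
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2
    # layer geometry (rows)
    ilm_row_mean: int = 200
    curve_amplitude_px: float = 15.0
    curve_period_px: float = 512.0
    retina_thickness_px: int = 120
    rpe_thickness_px: int = 20
    # intensities in [0, 1]
    vitreous_intensity: float = 0.054
    retina_intensity: float = 0.25
    rpe_intensity: float = 0.45
    # multiplicative speckle: gamma(shape, 1/shape), mean 1
    speckle_shape: float = 4.0
    # blob population: explicit specs, or n per class sampled from ranges
    blobs: list[BlobSpec] | None = None
    class_counts: dict[str, int] | None = None
    class_area_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_AREA_RANGES)
    )
    eccentricity_range: tuple[float, float] = (0.3, 0.9)
    blob_contrast: float = 6.0
    min_blob_separation_px: int = 3
    ilm_clearance_px: int = 8  # blobs stay this many rows above the ILM
    top_clearance_px: int = 5
    max_placement_attempts: int = 500
    seed: int = 0

    @property
    def designed_vit_rpe(self) -> float:
        return self.vitreous_intensity / self.rpe_intensity

    def validate(self) -> None:
        if min(self.height_px, self.width_px, self.n_frames) <= 0:
            raise PhantomError("dimensions must be positive")
        for v in (self.vitreous_intensity, self.retina_intensity, self.rpe_intensity):
            if not 0.0 <= v <= 1.0:
                raise PhantomError("intensities must lie in [0, 1]")
        if self.speckle_shape <= 0:
            raise PhantomError("speckle_shape must be positive")
        if self.pixel_area_um2 <= 0:
            raise PhantomError("pixel_area_um2 must be positive")


@dataclass
class GroundTruthBlob:
    """Rasterised truth for one injected blob."""

    frame: int
    pixels: np.ndarray  # (n, 2) (row, col)
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    eccentricity: float
    orientation_deg: float
    mean_intensity: float
    size_class: str
    requested_area_um2: float
    requested_eccentricity: float
    requested_orientation_deg: float


@dataclass
class PhantomGroundTruth:
    """Everything the generator knows about the scene it rendered."""

    blobs: list[GroundTruthBlob]
    ilm_rows: np.ndarray  # (n_frames, width)
    rpe_inner_rows: np.ndarray
    rpe_outer_rows: np.ndarray
    designed_vit_rpe: float
    config: PhantomConfig

    def blobs_in_frame(self, frame: int) -> list[GroundTruthBlob]:
        return [b for b in self.blobs if b.frame == frame]


def rasterise_ellipse(
    area_px: float, eccentricity: float, orientation_deg: float
) -> np.ndarray:
    """Pixel offsets (relative to the centre) of a filled rotated ellipse.

    Semi-axes follow from the requested area and eccentricity
    (``pi*a*b = area``, ``b = a*sqrt(1-e^2)``); a pixel belongs to the blob
    if its centre lies inside the ellipse.  Targets of 1–3 px fall below the
    rasterisation limit and are realised as a horizontal strip of that many
    pixels (the true features are re-measured on the raster anyway).
    """
    if area_px <= 0:
        raise ValueError("area_px must be positive")
    n_target = max(1, round(area_px))
    if n_target <= 3:
        return np.array([(0, c) for c in range(n_target)], dtype=int)
    q = math.sqrt(max(1.0 - eccentricity**2, 1e-12))
    a = math.sqrt(area_px / (math.pi * q))
    b = a * q
    theta = math.radians(orientation_deg)
    span = int(math.ceil(a)) + 1
    rr, cc = np.mgrid[-span : span + 1, -span : span + 1]
    x = cc.astype(float)
    y = -rr.astype(float)  # y-up convention, matching shape_features
    u = x * math.cos(theta) + y * math.sin(theta)
    v = -x * math.sin(theta) + y * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not inside.any():
        return np.array([(0, 0)], dtype=int)
    return np.column_stack([rr[inside], cc[inside]])


def _sample_blobs(config: PhantomConfig, rng: np.random.Generator) -> list[BlobSpec]:
    if config.blobs is not None:
        return list(config.blobs)
    if not config.class_counts:
        return []
    specs: list[BlobSpec] = []
    for cls in CLASS_NAMES:
        n = config.class_counts.get(cls, 0)
        lo, hi = config.class_area_ranges[cls]
        for _ in range(n):
            specs.append(
                BlobSpec(
                    area_um2=float(rng.uniform(lo, hi)),
                    eccentricity=float(rng.uniform(*config.eccentricity_range)),
                    orientation_deg=float(rng.uniform(-89.0, 90.0)),
                    contrast=config.blob_contrast,
                )
            )
    return specs


def _place_blob(
    offsets: np.ndarray,
    frame_idx: int,
    ilm_cols: np.ndarray,
    occupied: np.ndarray,
    config: PhantomConfig,
    rng: np.random.Generator,
    fixed_rc: tuple[int | None, int | None],
) -> tuple[np.ndarray, np.ndarray] | None:
    h, w = occupied.shape
    rmin, rmax = offsets[:, 0].min(), offsets[:, 0].max()
    cmin, cmax = offsets[:, 1].min(), offsets[:, 1].max()
    sep = config.min_blob_separation_px
    for _ in range(config.max_placement_attempts):
        c0 = fixed_rc[1] if fixed_rc[1] is not None else int(
            rng.integers(-cmin + sep, w - cmax - sep)
        )
        cols = np.clip(np.arange(c0 + cmin - sep, c0 + cmax + sep + 1), 0, w - 1)
        ceiling = int(ilm_cols[cols].min()) - config.ilm_clearance_px
        lo_row = config.top_clearance_px - rmin
        hi_row = ceiling - rmax
        if hi_row <= lo_row:
            if fixed_rc[0] is not None or fixed_rc[1] is not None:
                break
            continue
        r0 = fixed_rc[0] if fixed_rc[0] is not None else int(rng.integers(lo_row, hi_row))
        rr = offsets[:, 0] + r0
        cc = offsets[:, 1] + c0
        if rr.min() < config.top_clearance_px or rr.max() >= ceiling:
            if fixed_rc[0] is not None:
                break
            continue
        # keep a separation ring so 8-connectivity never merges two blobs
        r_lo = max(rr.min() - sep, 0)
        r_hi = min(rr.max() + sep + 1, h)
        c_lo = max(cc.min() - sep, 0)
        c_hi = min(cc.max() + sep + 1, w)
        if occupied[r_lo:r_hi, c_lo:c_hi].any():
            if fixed_rc[0] is not None and fixed_rc[1] is not None:
                break
            continue
        occupied[r_lo:r_hi, c_lo:c_hi] = True
        return rr, cc
    return None


def generate_phantom(config: PhantomConfig) -> tuple[BScanStack, PhantomGroundTruth]:
    """Render a phantom stack and its ground truth; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w, nf = config.height_px, config.width_px, config.n_frames
    cols = np.arange(w)

    specs = _sample_blobs(config, rng)
    # distribute sampled blobs over frames uniformly
    frame_of = [
        s.frame if s.frame is not None else int(rng.integers(0, nf)) for s in specs
    ]

    frames = np.empty((nf, h, w), dtype=np.float32)
    ilm_rows = np.empty((nf, w), dtype=int)
    rpe_in_rows = np.empty((nf, w), dtype=int)
    rpe_out_rows = np.empty((nf, w), dtype=int)
    gt_blobs: list[GroundTruthBlob] = []

    for f in range(nf):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        ilm = np.round(
            config.ilm_row_mean
            + config.curve_amplitude_px
            * np.sin(2.0 * math.pi * cols / config.curve_period_px + phase)
        ).astype(int)
        ilm = np.clip(ilm, 1, h - config.retina_thickness_px - config.rpe_thickness_px - 2)
        rpe_in = ilm + config.retina_thickness_px
        rpe_out = rpe_in + config.rpe_thickness_px - 1
        ilm_rows[f], rpe_in_rows[f], rpe_out_rows[f] = ilm, rpe_in, rpe_out

        rows = np.arange(h)[:, None]
        clean = np.full((h, w), config.vitreous_intensity)
        clean[(rows >= ilm[None, :]) & (rows < rpe_in[None, :])] = config.retina_intensity
        clean[(rows >= rpe_in[None, :]) & (rows <= rpe_out[None, :])] = config.rpe_intensity
        noise = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, size=(h, w))
        frame = clean * noise

        occupied = np.zeros((h, w), dtype=bool)
        for bi, spec in enumerate(specs):
            if frame_of[bi] != f:
                continue
            offsets = rasterise_ellipse(
                spec.area_um2 / config.pixel_area_um2,
                spec.eccentricity,
                spec.orientation_deg,
            )
            placed = _place_blob(
                offsets, f, ilm, occupied, config, rng, (spec.row, spec.col)
            )
            if placed is None:
                raise PhantomError(
                    f"blob of {spec.area_um2:.1f} µm² could not be placed in frame {f} "
                    f"after {config.max_placement_attempts} attempts"
                )
            rr, cc = placed
            frame[rr, cc] += spec.contrast * config.vitreous_intensity
            np.clip(frame, 0.0, 1.0, out=frame)
            pixels = np.column_stack([rr, cc])
            ecc, orient = shape_features(pixels)
            area_px = len(rr)
            area_um2 = area_px * config.pixel_area_um2
            gt_blobs.append(
                GroundTruthBlob(
                    frame=f,
                    pixels=pixels,
                    centroid=(float(rr.mean()), float(cc.mean())),
                    area_px=area_px,
                    area_um2=area_um2,
                    eccentricity=ecc,
                    orientation_deg=orient,
                    mean_intensity=float(frame[rr, cc].mean()),
                    size_class=classify_size(area_um2),
                    requested_area_um2=spec.area_um2,
                    requested_eccentricity=spec.eccentricity,
                    requested_orientation_deg=spec.orientation_deg,
                )
            )
        np.clip(frame, 0.0, 1.0, out=frame)
        frames[f] = frame.astype(np.float32)

    stack = BScanStack(frames=frames, pixel_area_um2=config.pixel_area_um2)
    truth = PhantomGroundTruth(
        blobs=gt_blobs,
        ilm_rows=ilm_rows,
        rpe_inner_rows=rpe_in_rows,
        rpe_outer_rows=rpe_out_rows,
        designed_vit_rpe=config.designed_vit_rpe,
        config=config,
    )
    return stack, truth
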