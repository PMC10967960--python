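"""VIT/RPE relative intensity.

The VIT/RPE ratio — mean vitreous intensity divided by mean RPE intensity in
the same B-scan — is a normalised proxy for vitreous turbidity/inflammation:
the RPE is the brightest stable band, so dividing by its mean makes the
measure independent of overall device gain.  The per-eye value is the
unweighted mean over all B-scans of the stack.

The vitreous region used here deliberately includes any opacities: the ratio
is a bulk turbidity measure, computed independently of opacity detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFrameError, SegmentationError
from .layers import LayerSegmentation, rpe_mask, segment_layers, vitreous_mask


@dataclass
class VitRpeResult:
    """Per-frame and per-eye VIT/RPE relative intensity."""

    per_frame_ratio: list[float]
    vit_mean_intensity: list[float]
    rpe_mean_intensity: list[float]
    frame_indices: list[int]
    failed_frames: list[int] = field(default_factory=list)

    @property
    def eye_mean(self) -> float:
        """Mean ratio over all successfully segmented B-scans."""
        if not self.per_frame_ratio:
            raise DegenerateFrameError("no frame yielded a VIT/RPE ratio")
        return float(np.mean(self.per_frame_ratio))


def vit_rpe_ratio(
    frame: np.ndarray,
    seg: LayerSegmentation,
    margin_rows: int = 0,
    top_margin_rows: int = 0,
) -> float:
    """VIT/RPE relative intensity of one B-scan.

    Mean intensity over the vitreous mask divided by mean intensity over the
    RPE band.  Scale-invariant: multiplying the frame by c > 0 leaves the
    ratio unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    vmask = vitreous_mask(seg, frame.shape, margin_rows=margin_rows,
                          top_margin_rows=top_margin_rows)
    rmask = rpe_mask(seg, frame.shape)
    if not vmask.any():
        raise DegenerateFrameError("empty vitreous region")
    if not rmask.any():
        raise DegenerateFrameError("empty RPE region")
    rpe_mean = float(frame[rmask].mean())
    if rpe_mean <= 0:
        raise DegenerateFrameError("RPE mean intensity is zero")
    return float(frame[vmask].mean()) / rpe_mean


def eye_vit_rpe(
    stack,
    segs: list[LayerSegmentation | None],
    margin_rows: int = 0,
    top_margin_rows: int = 0,
) -> VitRpeResult:
    """Per-eye VIT/RPE: the mean of the per-B-scan ratios.

    ``segs`` holds one segmentation per frame; entries that are ``None``
    (frames whose segmentation failed) are excluded from the mean and
    reported in ``failed_frames``.
    """
    if len(segs) != stack.n_frames:
        raise ValueError("need one segmentation (or None) per frame")
    ratios: list[float] = []
    vit_means: list[float] = []
    rpe_means: list[float] = []
    kept: list[int] = []
    failed: list[int] = []
    for i, (frame, seg) in enumerate(zip(stack.frames, segs)):
        if seg is None:
            failed.append(i)
            continue
        try:
            frame = np.asarray(frame, dtype=float)
            vmask = vitreous_mask(seg, frame.shape, margin_rows=margin_rows,
                                  top_margin_rows=top_margin_rows)
            rmask = rpe_mask(seg, frame.shape)
            vit = float(frame[vmask].mean())
            rpe = float(frame[rmask].mean())
            if rpe <= 0:
                raise DegenerateFrameError("RPE mean intensity is zero")
        except (DegenerateFrameError, SegmentationError):
            failed.append(i)
            continue
        ratios.append(vit / rpe)
        vit_means.append(vit)
        rpe_means.append(rpe)
        kept.append(i)
    return VitRpeResult(
        per_frame_ratio=ratios,
        vit_mean_intensity=vit_means,
        rpe_mean_intensity=rpe_means,
        frame_indices=kept,
        failed_frames=failed,
    )


def segment_stack(stack, smoothing_window: int = 15, min_band_rows: int = 5):
    """Segment every frame of a stack; failed frames yield ``None``."""
    segs: list[LayerSegmentation | None] = []
    for i, frame in enumerate(stack.frames):
        try:
            segs.append(segment_layers(frame, smoothing_window=smoothing_window,
                                       min_band_rows=min_band_rows, frame_index=i))
        except SegmentationError:
            segs.append(None)
    return segs
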