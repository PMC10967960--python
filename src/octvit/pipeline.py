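"""End-to-end analysis of one B-scan stack.

Chains segmentation → VIT/RPE ratio → background suppression → opacity
detection → per-eye summary with a single parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intensity import VitRpeResult, eye_vit_rpe, segment_stack
from .layers import (
    DEFAULT_MARGIN_ROWS,
    DEFAULT_MIN_BAND_ROWS,
    DEFAULT_SMOOTHING_WINDOW,
    LayerSegmentation,
    vitreous_mask,
)
from .oct_io import BScanStack
from .opacities import (
    EyeTimepointSummary,
    OpacityRecord,
    detect_opacities,
    summarise_eye,
    suppress_background,
)


@dataclass
class AnalysisParams:
    """Tunable parameters of the stack-analysis pipeline."""

    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    min_band_rows: int = DEFAULT_MIN_BAND_ROWS
    margin_rows: int = DEFAULT_MARGIN_ROWS  # ILM exclusion margin for detection
    top_margin_rows: int = 0
    k_sigma: float = 6.0
    min_area_px: int = 1
    connectivity: int = 8

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class StackAnalysis:
    """Everything the pipeline computed for one stack."""

    segmentations: list[LayerSegmentation | None]
    vit_rpe: VitRpeResult
    records: list[OpacityRecord]
    summary: EyeTimepointSummary
    params: AnalysisParams = field(default_factory=AnalysisParams)


def analyze_stack(stack: BScanStack, params: AnalysisParams | None = None) -> StackAnalysis:
    """Run the full per-eye analysis on one stack.

    Frames whose segmentation fails contribute neither to the VIT/RPE mean
    nor to opacity detection; they are listed in ``vit_rpe.failed_frames``.
    """
    params = params or AnalysisParams()
    segs = segment_stack(
        stack, smoothing_window=params.smoothing_window, min_band_rows=params.min_band_rows
    )
    vr = eye_vit_rpe(stack, segs)

    records: list[OpacityRecord] = []
    for i, (frame, seg) in enumerate(zip(stack.frames, segs)):
        if seg is None:
            continue
        mask = vitreous_mask(
            seg,
            frame.shape,
            margin_rows=params.margin_rows,
            top_margin_rows=params.top_margin_rows,
        )
        binary = suppress_background(frame, mask, k_sigma=params.k_sigma)
        records.extend(
            detect_opacities(
                binary,
                frame,
                pixel_area_um2=stack.pixel_area_um2,
                min_area_px=params.min_area_px,
                connectivity=params.connectivity,
                frame_index=i,
            )
        )
    summary = summarise_eye(
        records,
        n_frames=stack.n_frames,
        vit_rpe=vr.eye_mean if vr.per_frame_ratio else None,
        eye_meta=stack.eye_meta,
    )
    return StackAnalysis(
        segmentations=segs, vit_rpe=vr, records=records, summary=summary, params=params
    )
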