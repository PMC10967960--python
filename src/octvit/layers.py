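"""Vitreous / RPE segmentation of OCT B-scans.

Each B-scan column is an axial intensity profile: dark vitreous on top, a
bright retinal band below it that terminates in the hyperreflective RPE,
and a dark region beneath.  The segmenter locates, per column,

* ``ilm_row``       — the inner limiting membrane, top of the retinal band,
* ``rpe_inner_row`` — the top of the brightest sustained band (RPE),
* ``rpe_outer_row`` — the bottom of the retinal band (outer RPE).

Intensities are smoothed laterally (across columns) only, so axial step
edges are not displaced; boundary curves are median-smoothed across columns
afterwards.  The retinal band in a column is taken as the longest sustained
supra-threshold run, which keeps the detector indifferent to bright vitreous
opacities floating above the ILM (those form short runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import SegmentationError

DEFAULT_SMOOTHING_WINDOW = 15
DEFAULT_MIN_BAND_ROWS = 5
DEFAULT_MARGIN_ROWS = 2


@dataclass
class LayerSegmentation:
    """Per-column boundary rows of one B-scan (0-based, inclusive)."""

    ilm_row: np.ndarray
    rpe_inner_row: np.ndarray
    rpe_outer_row: np.ndarray
    frame_index: int = 0

    @property
    def width(self) -> int:
        return len(self.ilm_row)

    def validate(self, height_px: int) -> None:
        ok = (
            (self.ilm_row >= 0).all()
            and (self.ilm_row < self.rpe_inner_row).all()
            and (self.rpe_inner_row <= self.rpe_outer_row).all()
            and (self.rpe_outer_row < height_px).all()
        )
        if not ok:
            raise SegmentationError("boundary ordering violated")


def _column_runs(bright: np.ndarray, min_rows: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Longest sustained bright run per column.

    Dark gaps shorter than a sustained transition (< min_rows rows) are
    closed first, so speckle dropouts inside the retinal band do not split
    it: only a dark run that is itself sustained ends the band.
    """
    closed = ndimage.binary_closing(
        bright, structure=np.ones((max(2, min_rows), 1), dtype=bool), border_value=0
    )
    # label vertical runs only
    structure = np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=bool)
    labels, n = ndimage.label(closed, structure=structure)
    h, w = bright.shape
    start = np.zeros(w, dtype=int)
    end = np.zeros(w, dtype=int)
    best = np.zeros(w, dtype=int)
    valid = np.zeros(w, dtype=bool)
    if n == 0:
        return start, end, valid
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        col = sl[1].start
        length = sl[0].stop - sl[0].start
        if length >= min_rows and length > best[col]:
            best[col] = length
            start[col] = sl[0].start
            end[col] = sl[0].stop - 1
            valid[col] = True
    return start, end, valid


def _interpolate_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    cols = np.arange(len(values))
    return np.interp(cols, cols[valid], values[valid])


def segment_layers(
    frame: np.ndarray,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    min_band_rows: int = DEFAULT_MIN_BAND_ROWS,
    frame_index: int = 0,
) -> LayerSegmentation:
    """Locate ILM and inner/outer RPE boundaries on one normalised B-scan.

    Parameters
    ----------
    frame
        2-D raster, rows = depth, intensities in [0, 1].
    smoothing_window
        Lateral moving-average window (columns) for intensity smoothing and
        median window for boundary-curve smoothing.
    min_band_rows
        Minimum number of consecutive supra-threshold rows for a transition
        to count as sustained; also the axial window used when locating the
        RPE band inside the retina.

    Raises
    ------
    SegmentationError
        If fewer than 50% of columns contain a sustained dark→bright
        transition (e.g. a uniform frame).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    h, w = frame.shape
    if h < min_band_rows:
        raise ValueError("frame has fewer rows than min_band_rows")

    sm = ndimage.uniform_filter1d(frame, size=max(1, smoothing_window), axis=1, mode="nearest")
    if float(sm.max() - sm.min()) < 1e-9:
        raise SegmentationError("uniform frame: no dark→bright transition")
    tau = float(threshold_otsu(sm))
    bright = sm > tau

    start, end, valid = _column_runs(bright, min_band_rows)
    if valid.sum() < 0.5 * w:
        raise SegmentationError(
            f"no sustained dark→bright transition in {w - int(valid.sum())}/{w} columns"
        )

    ilm = _interpolate_invalid(start.astype(float), valid)
    rpe_outer = _interpolate_invalid(end.astype(float), valid)

    # RPE inner: within [ilm, rpe_outer], the brightest sustained band is the
    # RPE; scan the axially smoothed profile for the run containing the peak.
    sm2 = ndimage.uniform_filter1d(sm, size=max(1, min_band_rows), axis=0, mode="nearest")
    rpe_inner = np.empty(w, dtype=float)
    ilm_i = np.round(ilm).astype(int)
    out_i = np.round(rpe_outer).astype(int)
    for c in range(w):
        lo, hi = ilm_i[c], out_i[c]
        if hi <= lo:
            rpe_inner[c] = lo + 1
            continue
        band = sm2[lo : hi + 1, c]
        level = float(np.median(band))
        peak_idx = int(np.argmax(band))
        tau_rpe = 0.5 * (level + float(band[peak_idx]))
        r = peak_idx
        while r > 0 and band[r - 1] >= tau_rpe:
            r -= 1
        rpe_inner[c] = lo + r

    win = max(1, smoothing_window)
    ilm = ndimage.median_filter(ilm, size=win, mode="nearest")
    rpe_inner = ndimage.median_filter(rpe_inner, size=win, mode="nearest")
    rpe_outer = ndimage.median_filter(rpe_outer, size=win, mode="nearest")

    ilm = np.clip(np.round(ilm).astype(int), 0, h - 3)
    rpe_outer = np.clip(np.round(rpe_outer).astype(int), 0, h - 1)
    rpe_outer = np.maximum(rpe_outer, ilm + 2)
    rpe_inner = np.clip(np.round(rpe_inner).astype(int), ilm + 1, rpe_outer)

    seg = LayerSegmentation(
        ilm_row=ilm, rpe_inner_row=rpe_inner, rpe_outer_row=rpe_outer, frame_index=frame_index
    )
    seg.validate(h)
    return seg


def vitreous_mask(
    seg: LayerSegmentation,
    frame_shape: tuple[int, int],
    margin_rows: int = DEFAULT_MARGIN_ROWS,
    top_margin_rows: int = 0,
) -> np.ndarray:
    """Binary mask of the vitreous compartment above the ILM.

    True for pixels strictly above ``ilm_row - margin_rows`` in each column
    (a safety margin keeps ILM-adherent pixels out), excluding the top
    ``top_margin_rows`` rows of the frame (acquisition artefact band).
    """
    h, w = frame_shape
    if seg.width != w:
        raise ValueError("segmentation width does not match frame shape")
    rows = np.arange(h)[:, None]
    mask = rows < (seg.ilm_row[None, :] - margin_rows)
    if top_margin_rows > 0:
        mask[:top_margin_rows, :] = False
    return mask


def rpe_mask(seg: LayerSegmentation, frame_shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of the RPE band (rpe_inner ≤ row ≤ rpe_outer per column)."""
    h, w = frame_shape
    if seg.width != w:
        raise ValueError("segmentation width does not match frame shape")
    rows = np.arange(h)[:, None]
    return (rows >= seg.rpe_inner_row[None, :]) & (rows <= seg.rpe_outer_row[None, :])
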