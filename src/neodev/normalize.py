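"""Fluorescence normalization: dF/F in two baselining variants, sensor-trace
smoothing, ratiometric correction, and subregion-grid summarization.

Two dF/F conventions are supported.  ``dff_mean_baseline`` divides by the
mean fluorescence over a baseline window, the usual choice for sensor traces
and adult recordings.  ``dff_percentile`` divides by a low percentile (first
by default) of each cell's whole-recording fluorescence, which is more stable
across development when resting calcium levels drift.  Both are invariant
under positive rescaling of the raw signal and map constant traces to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import FluorescenceRecording, ValidationError


@dataclass
class DffRecording:
    """A cells x frames dF/F matrix plus provenance of its normalization."""

    dff: np.ndarray
    frame_rate: float
    coords: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValidationError("dff must be 2-D (cells x frames)")
        if not np.all(np.isfinite(self.dff)):
            raise ValidationError("non-finite dF/F value")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


def dff_mean_baseline(
    rec: FluorescenceRecording, baseline: tuple[int, int] | None = None
) -> DffRecording:
    """dF/F = (F - Fmean) / Fmean with Fmean the per-cell mean over the
    baseline window ``[start, end)`` (whole recording when omitted)."""
    if baseline is None:
        baseline = (0, rec.n_frames)
    start, end = baseline
    if not (0 <= start < end <= rec.n_frames):
        raise ValidationError(f"empty or out-of-range baseline window {baseline}")
    fmean = rec.raw[:, start:end].mean(axis=1)
    bad = np.nonzero(fmean <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"non-positive baseline mean for cell(s) {bad[:5].tolist()}"
        )
    dff = (rec.raw - fmean[:, None]) / fmean[:, None]
    return DffRecording(
        dff,
        rec.frame_rate,
        rec.coords,
        {"method": "mean_baseline", "baseline_window": [int(start), int(end)]},
    )


def dff_percentile(rec: FluorescenceRecording, percentile: float = 1.0) -> DffRecording:
    """dF/F = (F - F(p)) / F(p) with F(p) the per-cell ``percentile`` of raw
    fluorescence across the whole recording (linear-interpolation convention)."""
    f0 = np.percentile(rec.raw, percentile, axis=1)
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"non-positive percentile baseline for cell(s) {bad[:5].tolist()}"
        )
    dff = (rec.raw - f0[:, None]) / f0[:, None]
    return DffRecording(
        dff,
        rec.frame_rate,
        rec.coords,
        {
            "method": "first_percentile",
            "percentile": float(percentile),
            "percentile_convention": "linear",
        },
    )


def savgol_smooth(
    trace: np.ndarray, window_frames: int = 31, polyorder: int = 3
) -> np.ndarray:
    """Savitzky-Golay smoothing (least-squares local polynomial fit).

    Mirror padding is used at the edges so short traces do not pick up
    boundary transients.  The window must be odd, longer than the polynomial
    order and no longer than the trace.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValidationError("savgol_smooth expects a 1-D trace")
    if window_frames % 2 == 0:
        raise ValidationError(f"window must be odd, got {window_frames}")
    if window_frames <= polyorder:
        raise ValidationError("window must exceed polynomial order")
    if window_frames > trace.size:
        raise ValidationError(
            f"window {window_frames} longer than trace ({trace.size} frames)"
        )
    return savgol_filter(trace, window_frames, polyorder, mode="mirror")


def ratiometric_correct(
    green_dff: np.ndarray,
    red_dff: np.ndarray,
    mode: str = "subtract",
) -> np.ndarray:
    """Correct a sensor trace with a structural (activity-independent) channel.

    ``subtract`` removes the control channel's fractional change sample-wise
    (appropriate when both inputs are dF/F); ``divide`` forms the ratio of
    ``1 + dF/F`` terms and re-expresses it as a fractional change.
    """
    green_dff = np.asarray(green_dff, dtype=float)
    red_dff = np.asarray(red_dff, dtype=float)
    if green_dff.shape != red_dff.shape:
        raise ValidationError(
            f"channel length mismatch: {green_dff.shape} vs {red_dff.shape}"
        )
    if mode == "subtract":
        return green_dff - red_dff
    if mode == "divide":
        return (1.0 + green_dff) / (1.0 + red_dff) - 1.0
    raise ValidationError(f"unknown ratiometric mode {mode!r}")


def subregion_grid_means(
    frame_stack: np.ndarray, grid: tuple[int, int] = (16, 16)
) -> np.ndarray:
    """Mean intensity per grid tile per frame.

    ``frame_stack`` is (frames, height, width); the image is tiled into
    ``grid`` = (rows, cols) rectangles in row-major order (256 tiles at the
    default 16 x 16).  When the image size is not divisible by the grid the
    last tile in each direction absorbs the remainder.  Returns an array of
    shape (rows*cols, frames).
    """
    frame_stack = np.asarray(frame_stack, dtype=float)
    if frame_stack.ndim != 3:
        raise ValidationError("frame_stack must be (frames, height, width)")
    n_frames, h, w = frame_stack.shape
    gr, gc = grid
    if gr > h or gc > w:
        raise ValidationError(f"grid {grid} larger than image ({h} x {w})")
    row_edges = [(h // gr) * i for i in range(gr)] + [h]
    col_edges = [(w // gc) * j for j in range(gc)] + [w]
    out = np.empty((gr * gc, n_frames))
    for i in range(gr):
        for j in range(gc):
            tile = frame_stack[:, row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            out[i * gc + j] = tile.mean(axis=(1, 2))
    return out
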