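"""Correlation structure, distribution comparisons, stimulus-triggered
responses, responsiveness statistics and interneuron identification.

Responsiveness of a cell to a stimulus is tested on paired per-trial samples
(mean dF/F over 1 s before vs after onset).  The paired differences are first
checked for normality with a Shapiro-Wilk test; normal cells use a paired
t-test, non-normal ones a Wilcoxon signed-rank test, and p-values are
Benjamini-Hochberg adjusted across all cells tested for one stimulus type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FluorescenceRecording, StimulusLog, ValidationError
from .normalize import DffRecording

logger = logging.getLogger("neodev")


@dataclass
class CorrelationByDistance:
    """Mean pairwise correlation in contiguous distance bins from 0 um."""

    bin_edges_um: np.ndarray          # length n_bins + 1, starting at 0
    mean_correlation: np.ndarray      # NaN where a bin holds no pair
    pair_counts: np.ndarray


@dataclass
class ResponseResult:
    """Per-cell responsiveness to one stimulus type."""

    stimulus_type: str
    amplitude: np.ndarray             # per-cell mean of per-trial max dF/F
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    responsive: np.ndarray
    test_used: list[str]              # "t" or "wilcoxon" per cell

    @property
    def recruitment(self) -> float:
        return float(self.responsive.sum()) / self.responsive.size


def pairwise_correlations(dff: DffRecording) -> np.ndarray:
    """Pearson correlation between all cell pairs.

    Zero-variance cells are excluded (their rows/columns are NaN) and
    logged; an error is raised only when no cell has variance.
    """
    x = dff.dff
    var = x.var(axis=1)
    valid = var > 0
    if not valid.any():
        raise ValidationError("all cells have zero variance")
    if not valid.all():
        logger.warning(
            "excluding %d zero-variance cell(s) from correlation analysis",
            int((~valid).sum()),
        )
    n = dff.n_cells
    corr = np.full((n, n), np.nan)
    sub = np.corrcoef(x[valid])
    sub = np.atleast_2d(sub)
    idx = np.nonzero(valid)[0]
    corr[np.ix_(idx, idx)] = sub
    corr[idx, idx] = 1.0
    return corr


def correlation_vs_distance(
    corr: np.ndarray, coords: np.ndarray, bin_um: float = 40.0
) -> CorrelationByDistance:
    """Average cell-to-cell correlation in left-closed distance bins
    ``[k*bin_um, (k+1)*bin_um)``."""
    coords = np.asarray(coords, dtype=float)
    n = corr.shape[0]
    if coords.shape != (n, 2):
        raise ValidationError("coords must be (n_cells, 2) matching the matrix")
    iu, ju = np.triu_indices(n, k=1)
    r = corr[iu, ju]
    ok = np.isfinite(r)
    iu, ju, r = iu[ok], ju[ok], r[ok]
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    n_bins = int(np.floor(d.max() / bin_um)) + 1 if d.size else 1
    edges = np.arange(n_bins + 1) * bin_um
    which = np.minimum((d / bin_um).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    return CorrelationByDistance(edges, means, counts)


def cumulative_dff_comparison(
    dff_a: np.ndarray, dff_b: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray], float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of pooled dF/F samples.

    Returns ``(cdf_a, cdf_b, ks_statistic, p_value)`` where each CDF is a
    ``(sorted_values, cumulative_probability)`` pair for plotting.
    """
    a = np.asarray(dff_a, dtype=float).ravel()
    b = np.asarray(dff_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b)
    cdf_a = (np.sort(a), np.arange(1, a.size + 1) / a.size)
    cdf_b = (np.sort(b), np.arange(1, b.size + 1) / b.size)
    return cdf_a, cdf_b, float(ks.statistic), float(ks.pvalue)


def _trial_windows(
    dff: DffRecording, onsets: np.ndarray, pre_frames: int, post_frames: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack peri-stimulus snippets; trials running off either edge are
    dropped (logged).  Returns (kept_onsets, cells x trials x window)."""
    keep = [o for o in onsets if o - pre_frames >= 0 and o + post_frames <= dff.n_frames]
    dropped = len(onsets) - len(keep)
    if dropped:
        logger.warning("dropping %d edge trial(s)", dropped)
    if not keep:
        raise ValidationError("no trial window fits inside the recording")
    snips = np.stack(
        [dff.dff[:, o - pre_frames:o + post_frames] for o in keep], axis=1
    )
    return np.asarray(keep), snips


def stimulus_triggered_average(
    dff: DffRecording,
    stim_log: StimulusLog,
    pre_s: float = 2.0,
    post_s: float = 10.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Baseline-aligned peri-stimulus average per stimulus type.

    Each trial snippet is aligned by subtracting its pre-window mean per
    cell, then averaged over trials and cells.  Returns, per type, the time
    axis (s, 0 = onset), the mean trace and its SEM over cells x trials.
    """
    fr = dff.frame_rate
    pre_f, post_f = int(round(pre_s * fr)), int(round(post_s * fr))
    if pre_f < 1 or post_f < 1:
        raise ValidationError("pre and post windows must span at least one frame")
    out: dict[str, dict[str, np.ndarray]] = {}
    for stim_type in stim_log.types():
        onsets = stim_log.onsets(stim_type)
        _, snips = _trial_windows(dff, onsets, pre_f, post_f)
        baseline = snips[:, :, :pre_f].mean(axis=2, keepdims=True)
        aligned = snips - baseline
        flat = aligned.reshape(-1, aligned.shape[-1])
        out[stim_type] = {
            "time_s": (np.arange(-pre_f, post_f)) / fr,
            "mean": flat.mean(axis=0),
            "sem": flat.std(axis=0, ddof=1) / np.sqrt(flat.shape[0]),
            "n_trials": np.array(snips.shape[1]),
        }
    return out


def response_amplitude(
    dff: DffRecording, stim_log: StimulusLog, window_s: float = 20.0
) -> dict[str, np.ndarray]:
    """Per-cell, per-trial response amplitude: the maximum dF/F within the
    post-stimulus window ``[onset, onset + window_s)``.

    Returns per stimulus type a (cells x trials) array; trials whose window
    runs past the recording end are dropped.
    """
    fr = dff.frame_rate
    w = int(round(window_s * fr))
    if w < 1:
        raise ValidationError("window must span at least one frame")
    out: dict[str, np.ndarray] = {}
    for stim_type in stim_log.types():
        onsets = stim_log.onsets(stim_type)
        _, snips = _trial_windows(dff, onsets, 0, w)
        out[stim_type] = snips.max(axis=2)
    return out


def responsiveness_test(
    dff: DffRecording,
    stim_log: StimulusLog,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    alpha: float = 0.05,
    amplitude_window_s: float = 20.0,
) -> dict[str, ResponseResult]:
    """Shapiro-gated paired test with BH correction, per stimulus type.

    For each cell, the paired samples are the per-trial means over the 1 s
    pre- and post-onset windows.  Shapiro-Wilk on the paired differences (at
    ``alpha``) chooses between a paired t-test and a Wilcoxon signed-rank
    test; BH adjustment runs across all cells within one stimulus type and a
    cell is responsive when its adjusted p-value is below ``alpha``.
    """
    fr = dff.frame_rate
    pre_f, post_f = int(round(pre_s * fr)), int(round(post_s * fr))
    results: dict[str, ResponseResult] = {}
    amplitudes = response_amplitude(dff, stim_log, amplitude_window_s)
    for stim_type in stim_log.types():
        onsets = stim_log.onsets(stim_type)
        kept, snips = _trial_windows(dff, onsets, pre_f, post_f)
        if snips.shape[1] < 2:
            raise ValidationError(
                f"need >=2 trials for {stim_type!r}, got {snips.shape[1]}"
            )
        pre = snips[:, :, :pre_f].mean(axis=2)    # cells x trials
        post = snips[:, :, pre_f:].mean(axis=2)
        diffs = post - pre
        n_cells = diffs.shape[0]
        p_raw = np.ones(n_cells)
        test_used: list[str] = []
        for c in range(n_cells):
            d = diffs[c]
            if np.allclose(d, d[0]):
                # constant differences: Shapiro and Wilcoxon are undefined
                p_raw[c] = 1.0 if np.isclose(d[0], 0.0) else stats.ttest_rel(post[c], pre[c]).pvalue
                test_used.append("t")
                continue
            normal = stats.shapiro(d).pvalue > alpha
            if normal:
                p_raw[c] = stats.ttest_rel(post[c], pre[c]).pvalue
                test_used.append("t")
            else:
                p_raw[c] = stats.wilcoxon(d).pvalue
                test_used.append("wilcoxon")
        p_raw = np.nan_to_num(p_raw, nan=1.0)
        responsive, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
        results[stim_type] = ResponseResult(
            stimulus_type=stim_type,
            amplitude=amplitudes[stim_type].mean(axis=1),
            p_raw=p_raw,
            p_adjusted=p_adj,
            responsive=responsive,
            test_used=test_used,
        )
    return results


def identify_interneurons(
    red: FluorescenceRecording, percentile: float = 97.0
) -> np.ndarray:
    """Flag cells whose mean red-channel fluorescence is at or above the
    given percentile of the per-cell means (ties included)."""
    means = red.raw.mean(axis=1)
    cutoff = np.percentile(means, percentile)
    mask = means >= cutoff
    if mask.all() and red.n_cells > 1:
        logger.warning("degenerate red channel: all cells at the percentile cutoff")
    return mask


def cell_neuropil_correlation(cell: np.ndarray, neuropil: np.ndarray) -> float:
    """Pearson r between an ROI trace and its surrounding neuropil trace.

    Returns NaN (with a warning) when either trace has zero variance.
    """
    cell = np.asarray(cell, dtype=float)
    neuropil = np.asarray(neuropil, dtype=float)
    if cell.shape != neuropil.shape:
        raise ValidationError("cell and neuropil traces must have equal length")
    if cell.std() == 0 or neuropil.std() == 0:
        logger.warning("zero-variance trace in cell-neuropil correlation")
        return float("nan")
    return float(stats.pearsonr(cell, neuropil).statistic)
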