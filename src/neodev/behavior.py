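"""Movement extraction from pose tracking and wake/sleep-state scoring.

Neonatal sleep states are scored from limb movement: sustained movement is
wakefulness, immobility is quiet sleep (QS), and immobility punctuated by
brief myoclonic twitches is active sleep (AS).  The qualitative criteria are
made operational with configurable thresholds: displacement is median-
filtered, thresholded at ``move_threshold``, suprathreshold runs longer than
``max_twitch_s`` count as movement (wake), shorter ones as twitches, and
sleep frames within ``as_halo_s`` of an isolated twitch are labelled AS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .config import AnalysisConfig, ConfigError
from .io import ValidationError

logger = logging.getLogger("neodev")

STATES = ("wake", "QS", "AS")


@dataclass
class MovementTrace:
    """Per-frame displacement (units/frame) for each tracked marker.

    Each displacement series has length ``n_frames - 1``; entry ``t`` is the
    Euclidean step between frames ``t`` and ``t + 1``.
    """

    displacement: dict[str, np.ndarray]
    frame_rate: float

    def __post_init__(self) -> None:
        for marker, d in self.displacement.items():
            d = np.asarray(d, dtype=float)
            if (d < 0).any():
                raise ValidationError(f"negative displacement for marker {marker!r}")
            self.displacement[marker] = d

    @property
    def n_frames(self) -> int:
        return next(iter(self.displacement.values())).size + 1


@dataclass
class SleepBout:
    """A labelled interval; bouts tile the scored recording."""

    state: str
    start_frame: int
    end_frame: int  # half-open

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if not self.start_frame < self.end_frame:
            raise ValidationError("empty bout")


def movement_from_pose(
    pose: pd.DataFrame,
    frame_rate: float = 30.0,
    likelihood_threshold: float = 0.9,
    max_interp_gap_s: float = 0.5,
) -> MovementTrace:
    """Frame-to-frame Euclidean displacement per marker.

    ``pose`` is long-format with columns frame, marker, x, y and optionally
    likelihood (DeepLabCut-style).  Low-likelihood or missing points are
    linearly interpolated up to ``max_interp_gap_s``; longer gaps are
    interpolated too but reported, since the stricter remedy (marking the
    interval unscorable) is a per-experiment decision.
    """
    required = {"frame", "marker", "x", "y"}
    if not required.issubset(pose.columns):
        raise ValidationError(f"pose table needs columns {sorted(required)}")
    displacement: dict[str, np.ndarray] = {}
    max_gap = int(round(max_interp_gap_s * frame_rate))
    for marker, grp in pose.groupby("marker"):
        grp = grp.sort_values("frame")
        if len(grp) < 2:
            raise ValidationError(f"marker {marker!r} has fewer than 2 frames")
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        if "likelihood" in grp.columns:
            bad = grp["likelihood"].to_numpy() < likelihood_threshold
            if bad.any():
                n_long = _count_long_runs(bad, max_gap)
                if n_long:
                    logger.warning(
                        "marker %r: %d low-confidence gap(s) exceed %.2f s; "
                        "interpolating anyway",
                        marker, n_long, max_interp_gap_s,
                    )
                else:
                    logger.info(
                        "marker %r: interpolating %d low-confidence point(s)",
                        marker, int(bad.sum()),
                    )
                xy = xy.copy()
                xy[bad] = np.nan
                for col in range(2):
                    s = pd.Series(xy[:, col])
                    xy[:, col] = s.interpolate(limit_direction="both").to_numpy()
        displacement[str(marker)] = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return MovementTrace(displacement, frame_rate)


def _count_long_runs(mask: np.ndarray, max_len: int) -> int:
    runs = _runs(mask)
    return sum(1 for s, e in runs if e - s > max_len)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def score_sleep_states(
    move: MovementTrace,
    marker: str = "left_forelimb",
    config: AnalysisConfig | None = None,
) -> tuple[list[SleepBout], np.ndarray]:
    """Score wake/QS/AS bouts from one marker's movement.

    Returns the bout list and the per-frame state labels (length
    ``n_frames``).  The scoring is invariant to uniform spatial scaling of
    the coordinates when ``move_threshold`` is scaled identically.
    """
    cfg = config or AnalysisConfig()
    if cfg.max_twitch_s >= cfg.min_wake_s:
        raise ConfigError("max_twitch_s must be < min_wake_s")
    if marker not in move.displacement:
        raise ValidationError(
            f"marker {marker!r} not tracked (have {sorted(move.displacement)})"
        )
    fr = move.frame_rate
    d = move.displacement[marker]
    k = int(round(cfg.median_filter_s * fr))
    k = max(1, k + (1 - k % 2))  # odd kernel
    smooth = medfilt(d, k) if k > 1 else d.copy()
    above = smooth >= cfg.move_threshold

    max_twitch = int(round(cfg.max_twitch_s * fr))
    min_still = int(round(cfg.min_still_s * fr))
    min_gap = int(round(cfg.min_gap_s * fr))
    halo = int(round(cfg.as_halo_s * fr))
    n = d.size  # displacement samples; frames = n + 1

    movement_runs = []
    twitch_runs = []
    for s, e in _runs(above):
        (movement_runs if e - s > max_twitch else twitch_runs).append((s, e))

    # wake = movement runs, with sub-minimum-stillness gaps between them
    # absorbed so brief pauses do not fragment a wake bout
    wake = np.zeros(n, dtype=bool)
    for s, e in movement_runs:
        wake[s:e] = True
    gaps = _runs(~wake)
    for s, e in gaps:
        if s > 0 and e < n and e - s < min_still:
            wake[s:e] = True

    # twitches adjacent to wake (within min_gap) are movement continuation
    as_mark = np.zeros(n, dtype=bool)
    for s, e in twitch_runs:
        lo = max(0, s - min_gap)
        hi = min(n, e + min_gap)
        if wake[lo:hi].any():
            wake[s:e] = True
            continue
        as_mark[max(0, s - halo):min(n, e + halo)] = True

    labels = np.full(n, "QS", dtype=object)
    labels[as_mark & ~wake] = "AS"
    labels[wake] = "wake"

    frame_labels = np.append(labels, labels[-1])  # last frame inherits
    bouts = []
    start = 0
    for t in range(1, frame_labels.size + 1):
        if t == frame_labels.size or frame_labels[t] != frame_labels[start]:
            bouts.append(SleepBout(str(frame_labels[start]), start, t))
            start = t
    return bouts, frame_labels


def state_conditioned_signal(
    signal: np.ndarray, bouts: list[SleepBout]
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-state mean of a signal and the fraction of time in each state.

    States absent from the bout list get NaN means and zero fractions;
    fractions sum to 1 over the scored interval.
    """
    signal = np.asarray(signal, dtype=float)
    n_scored = max(b.end_frame for b in bouts) if bouts else 0
    if n_scored > signal.size:
        raise ValidationError(
            f"signal ({signal.size} frames) shorter than scored interval ({n_scored})"
        )
    sums = {s: 0.0 for s in STATES}
    counts = {s: 0 for s in STATES}
    for b in bouts:
        seg = signal[b.start_frame:b.end_frame]
        sums[b.state] += float(seg.sum())
        counts[b.state] += seg.size
    total = sum(counts.values())
    means = {
        s: (sums[s] / counts[s]) if counts[s] else float("nan") for s in STATES
    }
    fractions = {s: (counts[s] / total if total else 0.0) for s in STATES}
    return means, fractions


def bouts_to_records(bouts: list[SleepBout], frame_rate: float) -> list[dict]:
    return [
        {
            "state": b.state,
            "start_frame": b.start_frame,
            "end_frame": b.end_frame,
            "duration_s": (b.end_frame - b.start_frame) / frame_rate,
        }
        for b in bouts
    ]
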