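"""Detection and classification of population synchrony events.

Developing sensory cortex produces spontaneous calcium events in which a
large fraction of the local population is co-active.  Events recruiting more
than 80% of recorded cells are called H- (high-synchronicity) events, those
recruiting 20-80% L- (low-synchronicity) events.  Detection operates on the
population-mean dF/F trace in 6 s time bins:

1. within each bin, if the population mean ever exceeds its reference mean
   (recording-wide by default), the bin maximum is a candidate event peak;
2. adjacent bins are searched and the peak moves to any larger maximum,
   iterated until the peak is stable (events can straddle bin boundaries);
3. the event extent is the maximal contiguous super-threshold interval
   around the peak, and events resolving to the same interval are merged;
4. a cell participates when its mean dF/F inside the event exceeds its own
   whole-recording mean; the participation fraction sets the event class.

All thresholds are strict ``>`` except the L-class bounds, which are
inclusive on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .normalize import DffRecording

H_THRESHOLD = 0.80
L_THRESHOLD = 0.20


@dataclass
class PopulationEvent:
    """One detected synchrony event.

    Frames are 0-based; ``[start_frame, end_frame)`` is half-open and is the
    maximal contiguous interval around ``peak_frame`` where the population
    mean stays above threshold.  ``amplitude`` is the population-mean dF/F at
    the peak frame.
    """

    peak_frame: int
    start_frame: int
    end_frame: int
    duration_s: float
    amplitude: float
    participation: float
    participant_mask: np.ndarray
    event_class: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.start_frame <= self.peak_frame < self.end_frame):
            raise ValidationError(
                f"event peak {self.peak_frame} outside interval "
                f"[{self.start_frame}, {self.end_frame})"
            )
        if not (0.0 <= self.participation <= 1.0):
            raise ValidationError(f"participation {self.participation} outside [0, 1]")


@dataclass
class EventSummary:
    """Per-recording event statistics, stratified by class."""

    n_events: int
    n_h: int
    n_l: int
    n_unclassified: int
    mean_amplitude: dict[str, float]
    mean_duration_s: dict[str, float]
    frequency_per_min: dict[str, float]


def population_mean_trace(dff: DffRecording) -> np.ndarray:
    """Unweighted per-frame mean dF/F across cells."""
    return dff.dff.mean(axis=0)


def classify_event(
    participation: float,
    h_threshold: float = H_THRESHOLD,
    l_threshold: float = L_THRESHOLD,
) -> str:
    """H if participation > h_threshold, L if within [l_threshold,
    h_threshold] (inclusive), else unclassified."""
    if not (0.0 <= participation <= 1.0):
        raise ValidationError(f"participation {participation} outside [0, 1]")
    if participation > h_threshold:
        return "H"
    if l_threshold <= participation <= h_threshold:
        return "L"
    return "unclassified"


def score_participation(
    dff: DffRecording, start_frame: int, end_frame: int
) -> tuple[np.ndarray, float]:
    """Participant mask and fraction for the interval ``[start, end)``.

    A cell participates when its mean dF/F within the interval is strictly
    greater than its mean over the whole recording, so a constant cell never
    participates.  The comparison is invariant to per-cell positive affine
    rescaling of the traces.
    """
    if not (0 <= start_frame < end_frame <= dff.n_frames):
        raise ValidationError(
            f"empty or out-of-range event interval [{start_frame}, {end_frame})"
        )
    inside = dff.dff[:, start_frame:end_frame].mean(axis=1)
    overall = dff.dff.mean(axis=1)
    mask = inside > overall
    return mask, float(mask.sum()) / dff.n_cells


def _superthreshold_interval(trace: np.ndarray, peak: int, threshold: float) -> tuple[int, int]:
    """Maximal contiguous run with trace > threshold containing ``peak``."""
    above = trace > threshold
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak + 1
    while end < trace.size and above[end]:
        end += 1
    return start, end


def detect_events(
    dff: DffRecording,
    bin_s: float = 6.0,
    h_threshold: float = H_THRESHOLD,
    l_threshold: float = L_THRESHOLD,
    reference: str = "recording",
) -> list[PopulationEvent]:
    """Detect population events on the population-mean trace.

    ``reference`` selects the threshold the mean trace must exceed:
    ``"recording"`` (default) uses the trace's whole-recording mean,
    ``"bin"`` the per-bin mean.  Returns events sorted by peak frame.
    """
    trace = population_mean_trace(dff)
    n_frames = trace.size
    bin_frames = int(round(bin_s * dff.frame_rate))
    if bin_frames < 1 or bin_frames > n_frames:
        raise ValidationError(
            f"bin of {bin_frames} frames invalid for a {n_frames}-frame recording"
        )
    if reference not in ("recording", "bin"):
        raise ValidationError(f"unknown threshold reference {reference!r}")
    global_threshold = trace.mean()

    n_bins = int(np.ceil(n_frames / bin_frames))
    bin_bounds = [
        (b * bin_frames, min((b + 1) * bin_frames, n_frames)) for b in range(n_bins)
    ]

    peaks: list[int] = []
    for b, (lo, hi) in enumerate(bin_bounds):
        threshold = trace[lo:hi].mean() if reference == "bin" else global_threshold
        seg = trace[lo:hi]
        if not np.any(seg > threshold):
            continue
        peak = lo + int(np.argmax(seg))
        # let the peak migrate to a larger maximum in adjacent bins until
        # stable, so events straddling bin edges resolve to one peak
        while True:
            pb = peak // bin_frames
            w_lo = max(0, (pb - 1) * bin_frames)
            w_hi = min(n_frames, (pb + 2) * bin_frames)
            cand = w_lo + int(np.argmax(trace[w_lo:w_hi]))
            if trace[cand] > trace[peak]:
                peak = cand
            else:
                break
        peaks.append(peak)

    events: dict[tuple[int, int], PopulationEvent] = {}
    for peak in peaks:
        if reference == "bin":
            pb = peak // bin_frames
            lo, hi = bin_bounds[min(pb, n_bins - 1)]
            threshold = trace[lo:hi].mean()
        else:
            threshold = global_threshold
        if not trace[peak] > threshold:
            continue
        start, end = _superthreshold_interval(trace, peak, threshold)
        key = (start, end)
        prev = events.get(key)
        if prev is not None and prev.amplitude >= trace[peak]:
            continue
        mask, participation = score_participation(dff, start, end)
        events[key] = PopulationEvent(
            peak_frame=int(peak),
            start_frame=int(start),
            end_frame=int(end),
            duration_s=(end - start) / dff.frame_rate,
            amplitude=float(trace[peak]),
            participation=participation,
            participant_mask=mask,
            event_class=classify_event(participation, h_threshold, l_threshold),
            truncated=bool(start == 0 or end == n_frames),
        )
    return sorted(events.values(), key=lambda e: e.peak_frame)


def summarize_events(
    events: list[PopulationEvent],
    duration_s: float,
    include_truncated_durations: bool = False,
) -> EventSummary:
    """Class-stratified mean amplitude, mean duration and events/min.

    Events truncated by the recording edges count towards frequencies and
    amplitudes but are excluded from duration means by default.  Means over
    empty classes are reported as NaN.
    """
    if duration_s <= 0:
        raise ValidationError("recording duration must be > 0")
    minutes = duration_s / 60.0
    mean_amp: dict[str, float] = {}
    mean_dur: dict[str, float] = {}
    freq: dict[str, float] = {}
    by_class = {"H": [], "L": [], "unclassified": []}
    for ev in events:
        by_class[ev.event_class].append(ev)
    for cls, evs in by_class.items():
        freq[cls] = len(evs) / minutes
        mean_amp[cls] = float(np.mean([e.amplitude for e in evs])) if evs else float("nan")
        durs = [
            e.duration_s
            for e in evs
            if include_truncated_durations or not e.truncated
        ]
        mean_dur[cls] = float(np.mean(durs)) if durs else float("nan")
    return EventSummary(
        n_events=len(events),
        n_h=len(by_class["H"]),
        n_l=len(by_class["L"]),
        n_unclassified=len(by_class["unclassified"]),
        mean_amplitude=mean_amp,
        mean_duration_s=mean_dur,
        frequency_per_min=freq,
    )


def events_to_records(events: list[PopulationEvent]) -> list[dict]:
    """Flatten events to CSV-ready rows (participant mask as a count)."""
    return [
        {
            "peak_frame": e.peak_frame,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "duration_s": e.duration_s,
            "amplitude": e.amplitude,
            "participation": e.participation,
            "n_participants": int(e.participant_mask.sum()),
            "event_class": e.event_class,
            "truncated": e.truncated,
        }
        for e in events
    ]
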