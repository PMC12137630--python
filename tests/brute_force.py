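"""Exhaustive pure-Python reference detector for population events.

Independent of the package's vectorised implementation: the population-mean
trace, the threshold, every super-threshold contiguous interval, the
bin-seeded peak search and the participation rule are all recomputed with
explicit loops.  Used as the equality oracle on small recordings.
"""

from __future__ import annotations


def brute_force_detect(dff_matrix, frame_rate, bin_s=6.0):
    """Return a list of dicts (peak, start, end, amplitude, participation,
    participants, event_class) sorted by peak frame."""
    n_cells = len(dff_matrix)
    n_frames = len(dff_matrix[0])

    trace = []
    for t in range(n_frames):
        s = 0.0
        for c in range(n_cells):
            s += dff_matrix[c][t]
        trace.append(s / n_cells)

    threshold = sum(trace) / n_frames
    bin_frames = int(round(bin_s * frame_rate))
    assert 1 <= bin_frames <= n_frames

    # every maximal contiguous super-threshold interval
    intervals = []
    t = 0
    while t < n_frames:
        if trace[t] > threshold:
            start = t
            while t < n_frames and trace[t] > threshold:
                t += 1
            intervals.append((start, t))
        else:
            t += 1

    def argmax_range(lo, hi):
        best = lo
        for i in range(lo + 1, hi):
            if trace[i] > trace[best]:
                best = i
        return best

    n_bins = (n_frames + bin_frames - 1) // bin_frames
    peaks = []
    for b in range(n_bins):
        lo, hi = b * bin_frames, min((b + 1) * bin_frames, n_frames)
        if not any(trace[i] > threshold for i in range(lo, hi)):
            continue
        peak = argmax_range(lo, hi)
        while True:
            pb = peak // bin_frames
            w_lo = max(0, (pb - 1) * bin_frames)
            w_hi = min(n_frames, (pb + 2) * bin_frames)
            cand = argmax_range(w_lo, w_hi)
            if trace[cand] > trace[peak]:
                peak = cand
            else:
                break
        peaks.append(peak)

    events = {}
    for peak in peaks:
        if not trace[peak] > threshold:
            continue
        containing = None
        for (s, e) in intervals:
            if s <= peak < e:
                containing = (s, e)
                break
        assert containing is not None
        prev = events.get(containing)
        if prev is not None and prev["amplitude"] >= trace[peak]:
            continue
        s, e = containing
        participants = []
        for c in range(n_cells):
            inside = sum(dff_matrix[c][t] for t in range(s, e)) / (e - s)
            overall = sum(dff_matrix[c]) / n_frames
            if inside > overall:
                participants.append(c)
        participation = len(participants) / n_cells
        if participation > 0.80:
            cls = "H"
        elif 0.20 <= participation <= 0.80:
            cls = "L"
        else:
            cls = "unclassified"
        events[containing] = {
            "peak": peak,
            "start": s,
            "end": e,
            "amplitude": trace[peak],
            "participation": participation,
            "participants": participants,
            "event_class": cls,
        }
    return sorted(events.values(), key=lambda d: d["peak"])
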