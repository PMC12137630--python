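"""LSPS input-map analysis and optogenetic PSC feature extraction.

A laser-scanning photostimulation (LSPS) map records, for each position of
an 11 x 17 stimulation grid (~50 um spacing), the mean synaptic charge
evoked in a patched cell when caged glutamate is photolysed at that
position.  Maps are normalised to unit total input, summed along rows
(columnar profile) or within manually assigned cortical layers, and
averaged across cells after aligning each map at the L4-L5 boundary.

Postsynaptic currents evoked by optogenetic stimulation are reduced to
onset latency, peak amplitude and charge.  Onset is the first sustained
crossing of 3 baseline standard deviations inside the 0-50 ms detection
window; charge integrates the baseline-subtracted current from onset until
a sustained return to within 1 SD of baseline (or a 200 ms cap).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ValidationError

logger = logging.getLogger("neodev")

GRID_SHAPE = (11, 17)


@dataclass
class LSPSMap:
    """Grid of mean evoked synaptic charge (pC) per stimulation position."""

    grid: np.ndarray
    row_spacing_um: float = 50.0
    layer_rows: dict[str, tuple[int, int]] = field(default_factory=dict)
    soma_position: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValidationError("LSPS grid must be 2-D")
        if np.nanmin(self.grid) < 0:
            raise ValidationError("charges must be >= 0 after rectification")
        prev_end = 0
        for layer, (lo, hi) in self.layer_rows.items():
            if not (0 <= lo < hi <= self.grid.shape[0]):
                raise ValidationError(f"layer {layer!r} rows [{lo}, {hi}) out of grid")
            if lo < prev_end:
                raise ValidationError(
                    f"layer {layer!r} overlaps the previous layer (rows must be "
                    "disjoint and ordered pia to white matter)"
                )
            prev_end = hi

    @property
    def l4_l5_boundary(self) -> int:
        """Row index of the base of L4 (first L5 row)."""
        for name in ("L4", "l4"):
            if name in self.layer_rows:
                return self.layer_rows[name][1]
        raise ValidationError("map has no L4 layer range; cannot align at L4-L5")


@dataclass
class PSCFeatures:
    """Features of one evoked postsynaptic current."""

    peak_amplitude_pa: float
    charge_pc: float
    onset_latency_ms: float
    is_failure: bool
    polarity: int = 0  # +1 outward, -1 inward, 0 failure


def normalize_map(m: LSPSMap) -> LSPSMap:
    """Divide each position by the summed input so pixels sum to 1."""
    total = np.nansum(m.grid)
    if total <= 0:
        raise ValidationError("cannot normalise an all-zero map")
    return LSPSMap(m.grid / total, m.row_spacing_um, dict(m.layer_rows), m.soma_position)


def columnar_profile(m: LSPSMap) -> np.ndarray:
    """Sum of inputs along each grid row (depth profile across cortex)."""
    return np.nansum(m.grid, axis=1)


def layer_input_sums(m: LSPSMap) -> dict[str, float]:
    """Total input per cortical layer; layer ranges must cover all rows."""
    if not m.layer_rows:
        raise ValidationError("map has no layer boundaries")
    covered = np.zeros(m.grid.shape[0], dtype=bool)
    for lo, hi in m.layer_rows.values():
        covered[lo:hi] = True
    if not covered.all():
        missing = np.nonzero(~covered)[0]
        raise ValidationError(f"rows {missing.tolist()} not assigned to any layer")
    return {
        layer: float(np.nansum(m.grid[lo:hi]))
        for layer, (lo, hi) in m.layer_rows.items()
    }


def align_and_average_maps(maps: list[LSPSMap]) -> tuple[np.ndarray, np.ndarray]:
    """Average maps after row-shifting each so L4-L5 boundaries coincide.

    Rows that fall outside an individual map after shifting are treated as
    missing; the returned mean is the per-pixel mean over available values,
    alongside the per-pixel observation count.
    """
    if not maps:
        raise ValidationError("no maps to average")
    n_cols = maps[0].grid.shape[1]
    boundaries = [m.l4_l5_boundary for m in maps]
    ref = max(boundaries)
    shifts = [ref - b for b in boundaries]
    n_rows = max(m.grid.shape[0] + s for m, s in zip(maps, shifts))
    stack = np.full((len(maps), n_rows, n_cols), np.nan)
    for i, (m, s) in enumerate(zip(maps, shifts)):
        if m.grid.shape[1] != n_cols:
            raise ValidationError("maps must share the same number of columns")
        stack[i, s:s + m.grid.shape[0], :] = m.grid
    counts = np.sum(~np.isnan(stack), axis=0)
    if not (counts > 0).any():
        raise ValidationError("no overlap after alignment")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return mean, counts


def extract_psc_features(
    sweep: np.ndarray,
    stim_onset_s: float,
    sample_rate_hz: float = 20_000.0,
    window_ms: tuple[float, float] = (0.0, 50.0),
    baseline_window_s: tuple[float, float] | None = None,
    onset_sd: float = 3.0,
    onset_sustain_ms: float = 0.5,
    return_sd: float = 1.0,
    return_sustain_ms: float = 5.0,
    integration_cap_ms: float = 200.0,
) -> PSCFeatures:
    """Extract onset latency, peak amplitude and charge from one sweep.

    ``sweep`` is current in pA.  Baseline statistics come from
    ``baseline_window_s`` (default: everything before the stimulus).  The
    event onset is the first sample in the detection window whose absolute
    deviation from baseline exceeds ``onset_sd`` baseline SDs and stays
    above threshold for ``onset_sustain_ms``; with no such crossing the
    sweep is a failure.  Charge is the rectangular integral of the deviation
    from onset until the deviation stays within ``return_sd`` SDs for
    ``return_sustain_ms`` (or the cap), reported as a magnitude in pC with
    the polarity flagged separately.
    """
    sweep = np.asarray(sweep, dtype=float)
    dt = 1.0 / sample_rate_hz
    stim_idx = int(round(stim_onset_s * sample_rate_hz))
    w_lo = stim_idx + int(round(window_ms[0] / 1000.0 * sample_rate_hz))
    w_hi = stim_idx + int(round(window_ms[1] / 1000.0 * sample_rate_hz))
    if not (0 <= w_lo < w_hi <= sweep.size):
        raise ValidationError("detection window outside sweep")
    if baseline_window_s is None:
        b_lo, b_hi = 0, stim_idx
    else:
        b_lo = int(round(baseline_window_s[0] * sample_rate_hz))
        b_hi = int(round(baseline_window_s[1] * sample_rate_hz))
    if not (0 <= b_lo < b_hi <= sweep.size):
        raise ValidationError("baseline window outside sweep")
    base = sweep[b_lo:b_hi]
    mu, sd = float(base.mean()), float(base.std())
    dev = sweep - mu
    thresh = max(onset_sd * sd, 1e-12)
    sustain = max(1, int(round(onset_sustain_ms / 1000.0 * sample_rate_hz)))

    above = np.abs(dev) > thresh
    onset_idx = None
    for s, e in _bool_runs(above[w_lo:w_hi]):
        if e - s >= sustain or e == w_hi - w_lo:  # run may extend past the window
            full_len = _run_length(above, w_lo + s)
            if full_len >= sustain:
                onset_idx = w_lo + s
                break
    if onset_idx is None:
        return PSCFeatures(0.0, 0.0, float("nan"), True, 0)

    cap = min(sweep.size, onset_idx + int(round(integration_cap_ms / 1000.0 * sample_rate_hz)))
    seg = dev[onset_idx:cap]
    polarity = 1 if seg[np.argmax(np.abs(seg))] > 0 else -1
    # integration end: sustained return to within return_sd baseline SDs
    ret_thresh = max(return_sd * sd, 1e-12)
    ret_sustain = max(1, int(round(return_sustain_ms / 1000.0 * sample_rate_hz)))
    inside = np.abs(seg) <= ret_thresh
    end = seg.size
    for s, e in _bool_runs(inside):
        if e - s >= ret_sustain:
            end = s
            break
    if end == seg.size and cap == onset_idx + int(round(integration_cap_ms / 1000.0 * sample_rate_hz)):
        logger.debug("charge integration hit the %.0f ms cap", integration_cap_ms)
    used = seg[:end]
    peak = float(np.max(np.abs(used))) if used.size else 0.0
    charge_pc = float(np.abs(np.sum(used)) * dt)  # pA * s = pC
    onset_ms = (onset_idx - stim_idx) * dt * 1000.0
    return PSCFeatures(peak, charge_pc, onset_ms, False, polarity)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _run_length(mask: np.ndarray, start: int) -> int:
    n = 0
    while start + n < mask.size and mask[start + n]:
        n += 1
    return n


def minimal_input_summary(sweeps: list[PSCFeatures]) -> dict[str, float]:
    """Failure rate and mean amplitude/charge over successful sweeps.

    Minimal-stimulation experiments titrate to ~50% failures; at least 6
    sweeps are required for the rate to be meaningful.
    """
    if len(sweeps) < 6:
        raise ValidationError(f"need >= 6 sweeps, got {len(sweeps)}")
    failures = [s for s in sweeps if s.is_failure]
    successes = [s for s in sweeps if not s.is_failure]
    out = {
        "n_sweeps": float(len(sweeps)),
        "failure_rate": len(failures) / len(sweeps),
        "mean_amplitude_pa": float("nan"),
        "mean_charge_pc": float("nan"),
    }
    if successes:
        out["mean_amplitude_pa"] = float(np.mean([s.peak_amplitude_pa for s in successes]))
        out["mean_charge_pc"] = float(np.mean([s.charge_pc for s in successes]))
    return out


# ---------------------------------------------------------------------------
# on-disk format: CSV grid + JSON sidecar for layer rows / soma position


def write_lsps_map(m: LSPSMap, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, m.grid, delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "row_spacing_um": m.row_spacing_um,
                "layer_rows": {k: list(v) for k, v in m.layer_rows.items()},
                "soma_position": list(m.soma_position) if m.soma_position else None,
            },
            fh,
            indent=1,
        )
    return path


def read_lsps_map(path: str | Path) -> LSPSMap:
    path = Path(path)
    grid = np.loadtxt(path, delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return LSPSMap(
        grid=np.atleast_2d(grid),
        row_spacing_um=meta.get("row_spacing_um", 50.0),
        layer_rows={k: tuple(v) for k, v in meta.get("layer_rows", {}).items()},
        soma_position=tuple(meta["soma_position"]) if meta.get("soma_position") else None,
    )
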