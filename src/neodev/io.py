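"""Readers, writers and the shared recording data model.

The central container is :class:`FluorescenceRecording`: a cells x frames
matrix of raw fluorescence together with per-cell ROI centroids (micrometres
within the field of view) and the acquisition frame rate.  Traces are accepted
from three on-disk layouts -- a self-describing HDF5 container, an NPY matrix
paired with a centroid CSV, or a single CSV matrix -- and are validated on
load so that downstream modules can assume finite values and matching
cell counts.

Frame indices are 0-based everywhere and all windows are half-open
``[start, end)``.
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("neodev")

STIMULUS_TYPES = frozenset(
    {"single_whisker", "multi_whisker", "airpuff", "auditory", "smooth", "rough"}
)

DEFAULT_FOV_UM = 643.0
DEFAULT_FRAME_RATE = 30.0


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be interpreted in its declared format."""


@dataclass
class FluorescenceRecording:
    """Raw fluorescence traces for one imaging session.

    Parameters
    ----------
    raw:
        cells x frames matrix of raw fluorescence (arbitrary units).
    coords:
        cells x 2 array of ROI centroids, (x, y) in micrometres with the
        origin at the upper-left corner of the field of view.
    frame_rate:
        Acquisition rate in Hz.
    channel:
        ``"green"`` (activity indicator) or ``"red"`` (structural marker).
    metadata:
        Free-form string map (animal id, age, condition, ...).
    """

    raw: np.ndarray
    coords: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    channel: str = "green"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.raw.ndim != 2:
            raise ValidationError(f"traces must be 2-D (cells x frames), got shape {self.raw.shape}")
        n_cells, n_frames = self.raw.shape
        if n_cells < 1 or n_frames < 2:
            raise ValidationError(
                f"need >=1 cell and >=2 frames, got {n_cells} cells x {n_frames} frames"
            )
        if self.coords.shape != (n_cells, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {n_cells} cells "
                "(expected one (x, y) row per cell)"
            )
        bad = ~np.isfinite(self.raw)
        if bad.any():
            c, t = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite fluorescence at cell {int(c)}, frame {int(t)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite ROI coordinate")
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.channel not in ("green", "red"):
            raise ValidationError(f"channel must be 'green' or 'red', got {self.channel!r}")

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class StimulusLog:
    """Typed stimulus onsets aligned to imaging frames.

    ``events`` is a list of ``(onset_frame, stimulus_type)`` with strictly
    increasing onsets.  Unknown stimulus labels are kept but reported through
    the package logger so typos surface without aborting an analysis.
    """

    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        events = [(int(f), str(s)) for f, s in self.events]
        onsets = [f for f, _ in events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError(f"stimulus onsets must be strictly increasing, got {onsets}")
        if any(f < 0 for f in onsets):
            raise ValidationError("negative stimulus onset frame")
        for f, s in events:
            if s not in STIMULUS_TYPES:
                logger.warning("unknown stimulus type %r at frame %d", s, f)
        self.events = events

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self, stimulus_type: str | None = None) -> np.ndarray:
        """Onset frames, optionally restricted to one stimulus type."""
        return np.array(
            [f for f, s in self.events if stimulus_type is None or s == stimulus_type],
            dtype=int,
        )

    def types(self) -> list[str]:
        """Distinct stimulus types in onset order of first appearance."""
        seen: list[str] = []
        for _, s in self.events:
            if s not in seen:
                seen.append(s)
        return seen

    def check_within(self, n_frames: int) -> None:
        for f, s in self.events:
            if f >= n_frames:
                raise ValidationError(
                    f"stimulus {s!r} onset {f} beyond recording length {n_frames}"
                )


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: FluorescenceRecording, path: str | Path) -> Path:
    """Write a recording to the HDF5 layout ``/traces``, ``/coords`` with
    ``frame_rate`` and ``channel`` stored as root attributes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        # track_times=False keeps byte-identical files across reruns
        f.create_dataset("traces", data=rec.raw, track_times=False)
        f.create_dataset("coords", data=rec.coords, track_times=False)
        f.attrs["frame_rate"] = rec.frame_rate
        f.attrs["channel"] = rec.channel
        for k, v in rec.metadata.items():
            f.attrs[f"meta_{k}"] = str(v)
    return path


def read_recording(
    path: str | Path,
    format: str = "hdf5",
    coords_path: str | Path | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    channel: str = "green",
) -> FluorescenceRecording:
    """Read a recording from disk.

    ``format`` is one of ``hdf5`` (self-describing container written by
    :func:`write_recording`), ``npy+csv`` (NPY trace matrix plus a centroid
    CSV with columns x,y given via ``coords_path``) or ``csv`` (plain matrix;
    centroid CSV optional, defaults to zeros).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("traces", "coords"):
                if key not in f:
                    raise ParseError(f"{path}: missing dataset '/{key}'")
            raw = np.asarray(f["traces"])
            coords = np.asarray(f["coords"])
            frame_rate = float(f.attrs.get("frame_rate", frame_rate))
            channel = str(f.attrs.get("channel", channel))
            metadata = {
                k[5:]: str(v) for k, v in f.attrs.items() if k.startswith("meta_")
            }
        return FluorescenceRecording(raw, coords, frame_rate, channel, metadata)
    if format == "npy+csv":
        if coords_path is None:
            raise ParseError("npy+csv format requires coords_path")
        raw = np.load(path)
        coords = pd.read_csv(coords_path)[["x", "y"]].to_numpy(dtype=float)
        return FluorescenceRecording(raw, coords, frame_rate, channel)
    if format == "csv":
        raw = pd.read_csv(path, header=None).to_numpy(dtype=float)
        if coords_path is not None:
            coords = pd.read_csv(coords_path)[["x", "y"]].to_numpy(dtype=float)
        else:
            coords = np.zeros((raw.shape[0], 2))
        return FluorescenceRecording(raw, coords, frame_rate, channel)
    raise ParseError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# stimulus logs


def read_stimulus_log(path: str | Path) -> StimulusLog:
    """Read a stimulus log CSV with columns ``onset_frame, stimulus_type``.

    A header row is recognised and skipped; an empty file yields an empty log.
    """
    path = Path(path)
    events: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or not "".join(row).strip():
                continue
            if i == 0 and row[0].strip().lower() in ("onset_frame", "frame"):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{i + 1}: expected 'onset_frame,stimulus_type'")
            try:
                onset = int(row[0])
            except ValueError as e:
                raise ParseError(f"{path}:{i + 1}: bad onset_frame {row[0]!r}") from e
            events.append((onset, row[1].strip()))
    return StimulusLog(events)


def write_stimulus_log(log: StimulusLog, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_frame", "stimulus_type"])
        w.writerows(log.events)
    return path


# ---------------------------------------------------------------------------
# result tables


def write_results_table(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write keyed result rows as CSV with a deterministic column order.

    All records must share the same key set; the column order is ``columns``
    when given, else the key order of the first record.  An empty list
    produces a header-only file (header from ``columns``, or empty).
    """
    path = Path(path)
    records = list(records)
    if not records:
        header = ",".join(columns) + "\n" if columns else ""
        path.write_text(header)
        return path
    keys = list(columns) if columns is not None else list(records[0].keys())
    for i, r in enumerate(records[1:], start=2):
        if set(r.keys()) != set(keys):
            raise ValidationError(
                f"record {i} keys {sorted(r.keys())} differ from {sorted(keys)}"
            )
    df = pd.DataFrame(records, columns=keys)
    df.to_csv(path, index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def setup_logging(verbose: bool = False) -> None:
    """Configure structured logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
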