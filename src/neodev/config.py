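"""Analysis configuration: every tunable parameter of the pipeline in one
validated object, loadable from YAML.

Defaults follow the acquisition and analysis conventions the package is
built around: 30 Hz imaging in a 643 um field of view, first-percentile
dF/F baselining, 6 s detection bins with 80%/20% participation thresholds,
40 um distance bins, 1 s pre/post responsiveness windows, and an
L2-penalised logistic decoder with 7000-permutation significance thresholds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration parameter is outside its documented range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class AnalysisConfig:
    # acquisition geometry
    frame_rate: float = 30.0          # Hz
    fov_um: float = 643.0             # field-of-view width in micrometres
    um_per_pixel: float | None = None  # conversion if coordinates arrive in pixels

    # normalization
    dff_percentile: float = 1.0       # baseline percentile for developmental dF/F
    savgol_window_frames: int = 31    # ~1 s at 30 Hz
    savgol_polyorder: int = 3
    ratiometric_mode: str = "subtract"  # or "divide"
    subregion_grid: tuple[int, int] = (16, 16)

    # event detection
    event_bin_s: float = 6.0
    h_threshold: float = 0.80         # participation > h_threshold -> H
    l_threshold: float = 0.20         # l_threshold <= participation <= h_threshold -> L
    event_reference: str = "recording"  # mean-dF/F reference: "recording" or "bin"

    # population metrics
    distance_bin_um: float = 40.0
    response_window_s: float = 20.0
    responsiveness_pre_s: float = 1.0
    responsiveness_post_s: float = 1.0
    alpha: float = 0.05
    interneuron_percentile: float = 97.0

    # sleep scoring
    move_threshold: float = 1.0       # displacement units/frame after smoothing
    min_wake_s: float = 1.0
    min_still_s: float = 2.0
    max_twitch_s: float = 0.5
    min_gap_s: float = 1.0
    as_halo_s: float = 5.0            # sleep frames within this range of a twitch -> AS
    median_filter_s: float = 0.2
    max_interp_gap_s: float = 0.5

    # decoding
    decode_n_cells: int = 500
    decode_bin_ms: float = 500.0
    decode_window_s: float = 20.0
    l2_strength: float = 0.001
    l2_strength_is_inverse: bool = True  # sklearn C convention; False -> penalty weight
    train_fraction: float = 0.6
    n_permutations: int = 7000
    null_quantile: float = 0.95

    # LSPS / PSC extraction
    lsps_rows: int = 11
    lsps_cols: int = 17
    lsps_row_spacing_um: float = 50.0
    psc_window_ms: tuple[float, float] = (0.0, 50.0)
    psc_onset_sd: float = 3.0
    psc_onset_sustain_ms: float = 0.5
    psc_integration_cap_ms: float = 200.0
    psc_sample_rate_hz: float = 20_000.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check(self.frame_rate > 0, "frame_rate must be > 0")
        _check(self.fov_um > 0, "fov_um must be > 0")
        _check(0 < self.dff_percentile < 100, "dff_percentile must be in (0, 100)")
        _check(self.savgol_window_frames % 2 == 1, "savgol window must be odd")
        _check(
            self.savgol_window_frames > self.savgol_polyorder,
            "savgol window must exceed polyorder",
        )
        _check(self.ratiometric_mode in ("subtract", "divide"), "bad ratiometric_mode")
        _check(self.event_bin_s > 0, "event_bin_s must be > 0")
        _check(
            0 <= self.l_threshold < self.h_threshold <= 1,
            "need 0 <= l_threshold < h_threshold <= 1",
        )
        _check(self.event_reference in ("recording", "bin"), "bad event_reference")
        _check(self.distance_bin_um > 0, "distance_bin_um must be > 0")
        _check(0 < self.alpha < 1, "alpha must be in (0, 1)")
        _check(0 < self.interneuron_percentile < 100, "interneuron_percentile in (0,100)")
        _check(self.move_threshold > 0, "move_threshold must be > 0")
        _check(
            self.max_twitch_s < self.min_wake_s,
            "max_twitch_s must be < min_wake_s (a twitch is shorter than sustained movement)",
        )
        _check(self.min_still_s > 0 and self.min_gap_s > 0, "sleep durations must be > 0")
        _check(self.decode_n_cells >= 1, "decode_n_cells must be >= 1")
        _check(self.decode_bin_ms > 0, "decode_bin_ms must be > 0")
        _check(self.l2_strength > 0, "l2_strength must be > 0")
        _check(0 < self.train_fraction < 1, "train_fraction must be in (0, 1)")
        _check(self.n_permutations >= 1, "n_permutations must be >= 1")
        _check(0 < self.null_quantile <= 1, "null_quantile must be in (0, 1]")
        _check(self.lsps_rows >= 1 and self.lsps_cols >= 1, "LSPS grid must be non-empty")
        _check(self.psc_window_ms[0] < self.psc_window_ms[1], "bad psc_window_ms")
        _check(self.psc_sample_rate_hz > 0, "psc_sample_rate_hz must be > 0")

    @property
    def sklearn_C(self) -> float:
        """L2 penalty translated to scikit-learn's inverse-strength C."""
        return self.l2_strength if self.l2_strength_is_inverse else 1.0 / self.l2_strength

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subregion_grid"] = list(self.subregion_grid)
        d["psc_window_ms"] = list(self.psc_window_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("subregion_grid", "psc_window_ms"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
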