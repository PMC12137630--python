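"""Synthetic recordings with known ground truth.

The generator emulates the statistical structure the analysis assumes for
neonatal two-photon recordings: 30 Hz acquisition in a 643 um field of view,
per-cell baseline fluorescence, GCaMP6s-like transients (difference of
exponentials, 0.18 s rise / 1.6 s decay), population events recruiting a
controlled fraction of cells, distance-dependent shared noise, stimulus-
locked responses in a responder subset, a sparse bright red channel marking
interneurons, wake/quiet-sleep/active-sleep movement regimes, and state- and
stimulus-modulated serotonin-sensor traces.

The trace model is::

    raw[c, t] = F0_c * (1 + drive_c(t) + shared_c(t) + eps_c(t))

where ``drive`` is the planted transient drive convolved with the indicator
kernel, ``shared`` is a Gaussian field with exponential spatial covariance
(white in time), and ``eps`` is white noise.  Both noise terms are expressed
in fractional (dF/F-like) units so their scales read directly as dF/F noise.

Every random draw flows from one master seed through independent named
streams (cell placement, events, noise, stimuli, red channel, movement,
serotonin), so e.g. changing the noise level does not perturb event timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io import FluorescenceRecording, StimulusLog, ValidationError

_STREAMS = (
    "placement",
    "events",
    "noise",
    "stim",
    "red",
    "red_noise",
    "movement",
    "serotonin",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic recording generator."""

    n_cells: int = 200
    duration_s: float = 600.0
    frame_rate: float = 30.0
    fov_um: float = 643.0
    # per-cell baseline fluorescence ~ N(mean, sd), clipped to min
    baseline_mean: float = 100.0
    baseline_sd: float = 20.0
    baseline_min: float = 20.0
    # indicator kernel (difference of exponentials), seconds
    kernel_rise_s: float = 0.18
    kernel_decay_s: float = 1.6
    # noise (fractional units)
    noise_sd: float = 0.05
    shared_noise_sd: float = 0.03
    spatial_corr_length_um: float = 100.0
    # population events: explicit schedule [(time_s, duration_s, participation,
    # amplitude)] or None to draw one at event_rate_per_min
    event_schedule: list[tuple[float, float, float, float]] | None = None
    event_rate_per_min: float = 1.5
    event_min_separation_s: float = 15.0
    h_participation_range: tuple[float, float] = (0.85, 1.0)
    l_participation_range: tuple[float, float] = (0.30, 0.70)
    h_event_fraction: float = 0.5
    event_amplitude_range: tuple[float, float] = (0.8, 1.2)
    event_duration_range_s: tuple[float, float] = (1.0, 4.0)
    # stimuli: [(onset_s, stimulus_type, amplitude, responder_fraction)]
    stim_schedule: list[tuple[float, str, float, float]] = dc_field(default_factory=list)
    stim_duration_s: float = 1.0
    # red channel
    red_interneuron_fraction: float = 0.03
    red_bright_mean: float = 100.0
    red_dim_mean: float = 10.0
    red_noise_sd: float = 1.0
    red_duration_s: float = 20.0
    # movement generator (displacement units per frame; the scorer's default
    # threshold is 1.0)
    wake_step_mean: float = 3.0
    wake_step_sd: float = 0.5
    sleep_jitter_sd: float = 0.2
    twitch_rate_hz: float = 0.3
    twitch_amplitude: float = 6.0
    twitch_duration_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValidationError("duration_s and frame_rate must be > 0")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= 0:
            raise ValidationError("kernel time constants must be > 0")
        if self.kernel_rise_s >= self.kernel_decay_s:
            raise ValidationError("kernel rise must be shorter than decay")
        if self.event_schedule is not None:
            for t, dur, p, a in self.event_schedule:
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(f"participation {p} outside [0, 1]")
                if t + dur > self.duration_s:
                    raise ValidationError(
                        f"event at {t} s with duration {dur} s extends past "
                        f"{self.duration_s} s recording"
                    )
        for t, _s, _a, frac in self.stim_schedule:
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"responder fraction {frac} outside [0, 1]")
            if t >= self.duration_s:
                raise ValidationError(f"stimulus at {t} s past end of recording")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class GroundTruth:
    """Planted structure accompanying a simulated recording."""

    events: list[dict] = dc_field(default_factory=list)
    responders: dict[str, np.ndarray] = dc_field(default_factory=dict)
    interneurons: np.ndarray | None = None
    state_labels: np.ndarray | None = None
    stimulus_log: StimulusLog | None = None

    def to_jsonable(self) -> dict:
        return {
            "events": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in e.items()}
                for e in self.events
            ],
            "responders": {k: v.tolist() for k, v in self.responders.items()},
            "interneurons": None if self.interneurons is None else self.interneurons.tolist(),
            "state_labels": None if self.state_labels is None else self.state_labels.tolist(),
        }


def transient_kernel(
    frame_rate: float, rise_s: float, decay_s: float, length_s: float = 10.0
) -> np.ndarray:
    """Difference-of-exponentials transient, normalised to unit peak."""
    t = np.arange(int(round(length_s * frame_rate))) / frame_rate
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValidationError("degenerate kernel (rise >= decay?)")
    return k / peak


def boxcar_response(duration_frames: int, kernel: np.ndarray) -> np.ndarray:
    """Unit-peak dF/F time course of a boxcar drive convolved with the
    indicator kernel; planted amplitudes are expressed on this scale so an
    event of amplitude A peaks at dF/F = A regardless of its duration."""
    r = np.convolve(np.ones(duration_frames), kernel)
    return r / r.max()


def _draw_event_schedule(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float, float, float]]:
    n_events = int(round(cfg.event_rate_per_min * cfg.duration_s / 60.0))
    if n_events == 0:
        return []
    # place events on a jittered regular lattice to respect the minimum
    # separation without rejection sampling
    margin = 10.0
    usable = cfg.duration_s - 2 * margin
    if usable < n_events * cfg.event_min_separation_s:
        n_events = max(1, int(usable / cfg.event_min_separation_s))
    slots = margin + usable * (np.arange(n_events) + rng.uniform(0.2, 0.8, n_events)) / n_events
    schedule = []
    for t in slots:
        is_h = rng.random() < cfg.h_event_fraction
        lo, hi = cfg.h_participation_range if is_h else cfg.l_participation_range
        participation = rng.uniform(lo, hi)
        amplitude = rng.uniform(*cfg.event_amplitude_range)
        duration = rng.uniform(*cfg.event_duration_range_s)
        schedule.append((float(t), float(duration), float(participation), float(amplitude)))
    return schedule


def simulate_recording(cfg: SimConfig) -> tuple[FluorescenceRecording, GroundTruth]:
    """Generate a green-channel recording and its ground truth.

    Identical config (including seed) yields bit-identical output.
    """
    rngs = cfg.rngs()
    n_cells, n_frames = cfg.n_cells, cfg.n_frames
    fr = cfg.frame_rate

    coords = rngs["placement"].uniform(0.0, cfg.fov_um, size=(n_cells, 2))
    f0 = np.clip(
        rngs["placement"].normal(cfg.baseline_mean, cfg.baseline_sd, n_cells),
        cfg.baseline_min,
        None,
    )

    kernel = transient_kernel(fr, cfg.kernel_rise_s, cfg.kernel_decay_s)
    schedule = (
        cfg.event_schedule
        if cfg.event_schedule is not None
        else _draw_event_schedule(cfg, rngs["events"])
    )

    drive_in = np.zeros((n_cells, n_frames))
    truth = GroundTruth()
    for t_s, dur_s, participation, amplitude in schedule:
        onset = int(round(t_s * fr))
        dur = max(1, int(round(dur_s * fr)))
        if onset + dur > n_frames:
            raise ValidationError(f"event at {t_s} s extends past recording end")
        n_part = int(round(participation * n_cells))
        members = rngs["events"].choice(n_cells, size=n_part, replace=False)
        gain = np.convolve(np.ones(dur), kernel).max()
        drive_in[members, onset:onset + dur] += amplitude / gain
        truth.events.append(
            {
                "onset_frame": onset,
                "duration_frames": dur,
                "participants": np.sort(members),
                "participation": n_part / n_cells,
                "amplitude": amplitude,
                "event_class": _truth_class(n_part / n_cells),
            }
        )

    # stimulus responses
    stim_events: list[tuple[int, str]] = []
    for t_s, stim_type, amplitude, responder_fraction in cfg.stim_schedule:
        onset = int(round(t_s * fr))
        stim_events.append((onset, stim_type))
        if stim_type not in truth.responders:
            n_resp = int(round(responder_fraction * n_cells))
            truth.responders[stim_type] = np.sort(
                rngs["stim"].choice(n_cells, size=n_resp, replace=False)
            )
        members = truth.responders[stim_type]
        dur = max(1, int(round(cfg.stim_duration_s * fr)))
        end = min(n_frames, onset + dur)
        gain = np.convolve(np.ones(dur), kernel).max()
        drive_in[members, onset:end] += amplitude / gain

    if np.any(drive_in):
        from scipy.signal import fftconvolve

        drive = fftconvolve(drive_in, kernel[None, :], axes=1)[:, :n_frames]
        drive = np.maximum(drive, 0.0)  # clip FFT ringing below zero
    else:
        drive = drive_in

    # ground-truth peak frame: argmax of the noiseless population-mean drive
    # near each planted event
    pop_drive = drive.mean(axis=0)
    look = int(round(5.0 * fr))
    for ev in truth.events:
        lo = ev["onset_frame"]
        hi = min(n_frames, lo + ev["duration_frames"] + look)
        ev["peak_frame"] = lo + int(np.argmax(pop_drive[lo:hi]))

    noise = rngs["noise"].standard_normal((n_cells, n_frames)) * cfg.noise_sd
    if cfg.shared_noise_sd > 0 and np.isfinite(cfg.spatial_corr_length_um):
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        cov = np.exp(-d / cfg.spatial_corr_length_um)
        cov[np.diag_indices(n_cells)] += 1e-9
        chol = np.linalg.cholesky(cov)
        shared = cfg.shared_noise_sd * (
            chol @ rngs["noise"].standard_normal((n_cells, n_frames))
        )
        noise += shared

    raw = f0[:, None] * (1.0 + drive + noise)
    raw = np.maximum(raw, 1e-6)  # fluorescence is non-negative

    interneurons = np.zeros(n_cells, dtype=bool)
    n_int = int(round(cfg.red_interneuron_fraction * n_cells))
    if n_int:
        interneurons[rngs["red"].choice(n_cells, size=n_int, replace=False)] = True
    truth.interneurons = interneurons

    rec = FluorescenceRecording(
        raw, coords, fr, "green", {"synthetic": "true", "seed": str(cfg.seed)}
    )
    rec.metadata["n_planted_events"] = str(len(truth.events))
    truth.stimulus_log = StimulusLog(sorted(stim_events))
    return rec, truth


def _truth_class(participation: float) -> str:
    if participation > 0.80:
        return "H"
    if participation >= 0.20:
        return "L"
    return "unclassified"


def simulate_red_recording(
    cfg: SimConfig, coords: np.ndarray, interneurons: np.ndarray
) -> FluorescenceRecording:
    """Short structural-channel recording: bright interneurons, dim rest."""
    rng = cfg.rngs()["red_noise"]
    n_frames = int(round(cfg.red_duration_s * cfg.frame_rate))
    mean = np.where(interneurons, cfg.red_bright_mean, cfg.red_dim_mean).astype(float)
    raw = mean[:, None] + rng.standard_normal((cfg.n_cells, n_frames)) * cfg.red_noise_sd
    raw = np.maximum(raw, 1e-6)
    return FluorescenceRecording(raw, coords, cfg.frame_rate, "red")


def simulate_movement(
    cfg: SimConfig,
    bout_plan: list[tuple[str, float]],
    markers: tuple[str, ...] = ("left_forelimb",),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Marker coordinate series realising a planned state sequence.

    ``bout_plan`` is a list of ``(state, duration_s)`` with states in
    {wake, QS, AS}.  Wake is a sustained suprathreshold random walk, QS
    subthreshold jitter, and AS subthreshold jitter punctuated by isolated
    brief twitches at ``twitch_rate_hz``.  Returns a DeepLabCut-style long
    DataFrame (frame, marker, x, y, likelihood) and per-frame ground-truth
    state labels.
    """
    fr = cfg.frame_rate
    rng = cfg.rngs()["movement"]
    step_mags: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for state, dur_s in bout_plan:
        if state not in ("wake", "QS", "AS"):
            raise ValidationError(f"unknown state {state!r}")
        n = int(round(dur_s * fr))
        if state == "wake":
            mags = np.maximum(rng.normal(cfg.wake_step_mean, cfg.wake_step_sd, n), 1.5)
        else:
            mags = np.abs(rng.normal(0.0, cfg.sleep_jitter_sd, n))
            if state == "AS":
                twitch_frames = max(1, int(round(cfg.twitch_duration_s * fr)))
                n_twitch = int(rng.poisson(cfg.twitch_rate_hz * dur_s))
                # cap so twitches stay isolated (>= 2 s apart)
                n_twitch = min(n_twitch, max(1, int(dur_s / 2.0)))
                if n_twitch:
                    # jittered lattice keeps the Poisson count while
                    # guaranteeing isolation, so the nominal rate is realised
                    slot = (n - twitch_frames) / n_twitch
                    starts = (
                        (np.arange(n_twitch) + rng.uniform(0.1, 0.9, n_twitch)) * slot
                    ).astype(int)
                    for s in starts:
                        mags[s:s + twitch_frames] = cfg.twitch_amplitude
        step_mags.append(mags)
        labels.append(np.full(n, state, dtype=object))
    mags = np.concatenate(step_mags)
    state_labels = np.concatenate(labels)
    n_steps = mags.size
    # one extra frame: n_steps displacements need n_steps + 1 coordinates
    state_labels = np.append(state_labels, state_labels[-1])

    rows = []
    for marker in markers:
        angles = rng.uniform(0, 2 * np.pi, n_steps)
        xy = np.zeros((n_steps + 1, 2))
        xy[0] = rng.uniform(100, 200, 2)
        xy[1:, 0] = xy[0, 0] + np.cumsum(mags * np.cos(angles))
        xy[1:, 1] = xy[0, 1] + np.cumsum(mags * np.sin(angles))
        for i in range(n_steps + 1):
            rows.append(
                {"frame": i, "marker": marker, "x": xy[i, 0], "y": xy[i, 1], "likelihood": 1.0}
            )
    return pd.DataFrame(rows), state_labels


def simulate_serotonin(
    cfg: SimConfig,
    state_series: np.ndarray,
    stim_log: StimulusLog | None = None,
    state_offsets: dict[str, float] | None = None,
    stim_amplitude: float = 2.0,
    stim_decay_s: float = 4.0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Single-ROI serotonin-sensor trace.

    Baseline is state-dependent (wake > QS > AS by the configured offsets);
    each stimulus adds a transient of ``stim_amplitude`` with exponential
    decay ``stim_decay_s``.
    """
    if state_offsets is None:
        state_offsets = {"wake": 1.0, "QS": 0.5, "AS": 0.0}
    state_series = np.asarray(state_series)
    n = state_series.size
    trace = np.array([state_offsets[str(s)] for s in state_series], dtype=float)
    if stim_log is not None:
        t = np.arange(int(round(stim_decay_s * 6 * cfg.frame_rate))) / cfg.frame_rate
        kernel = stim_amplitude * np.exp(-t / stim_decay_s)
        for onset, _stim in stim_log.events:
            if onset >= n:
                raise ValidationError(f"stimulus onset {onset} past trace length {n}")
            end = min(n, onset + kernel.size)
            trace[onset:end] += kernel[: end - onset]
    if noise_sd > 0:
        trace = trace + cfg.rngs()["serotonin"].standard_normal(n) * noise_sd
    return trace


def simulate_trial_tensor(
    n_animals: int = 8,
    trials_per_animal: int = 10,
    n_cells: int = 20,
    snippet_s: float = 2.0,
    frame_rate: float = 30.0,
    effect_size: float = 0.0,
    effect_cell_fraction: float = 0.5,
    animal_sd: float = 0.1,
    noise_sd: float = 1.0,
    stimulus_type: str = "airpuff",
    seed: int = 0,
):
    """Post-stimulus trial snippets for condition-decoding experiments.

    Half the animals carry condition "a", half "b".  Each trial is white
    noise plus a per-animal, per-cell random offset (``animal_sd``), so
    trials within an animal are correlated and only subject-wise validation
    is unbiased.  With ``effect_size > 0``, condition "b" trials gain a
    constant shift of ``effect_size * noise_sd`` on a random subset of
    cells.  Returns a :class:`~neodev.decoding.TrialTensor`.
    """
    from .decoding import TrialTensor

    if n_animals < 4 or n_animals % 2:
        raise ValidationError("need an even number of animals >= 4")
    rng = np.random.default_rng(seed)
    n_frames = int(round(snippet_s * frame_rate))
    n_trials = n_animals * trials_per_animal
    animal_ids = np.repeat(np.arange(n_animals), trials_per_animal)
    condition = np.where(animal_ids < n_animals // 2, "a", "b")
    data = rng.standard_normal((n_trials, n_cells, n_frames)) * noise_sd
    offsets = rng.standard_normal((n_animals, n_cells)) * animal_sd
    data += offsets[animal_ids][:, :, None]
    if effect_size > 0:
        n_eff = max(1, int(round(effect_cell_fraction * n_cells)))
        eff_cells = rng.choice(n_cells, size=n_eff, replace=False)
        shift = effect_size * noise_sd
        data[np.ix_(condition == "b", eff_cells)] += shift
    return TrialTensor(
        data=data,
        frame_rate=frame_rate,
        animal_ids=animal_ids,
        condition=condition,
        stimulus_type=np.full(n_trials, stimulus_type),
    )


def simulate_lsps_map(
    layer_rows: dict[str, tuple[int, int]],
    planted_inputs: list[tuple[int, int, float]],
    shape: tuple[int, int] = (11, 17),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Stimulation-grid charge map with planted inputs (row, col, charge_pC)."""
    from .lsps import LSPSMap  # local import to avoid a cycle

    n_rows, n_cols = shape
    grid = np.zeros(shape)
    for r, c, q in planted_inputs:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValidationError(f"planted input ({r}, {c}) outside {shape} grid")
        grid[r, c] += q
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        grid = np.abs(grid + rng.standard_normal(shape) * noise_sd)
    return LSPSMap(grid=grid, layer_rows=dict(layer_rows))


def simulate_psc_sweep(
    amplitude_pa: float,
    onset_ms: float,
    rise_ms: float = 0.5,
    decay_ms: float = 20.0,
    stim_onset_ms: float = 10.0,
    sweep_ms: float = 300.0,
    sample_rate_hz: float = 20_000.0,
    noise_sd_pa: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Double-exponential postsynaptic current sweep.

    ``onset_ms`` is measured from the stimulus onset.  Returns the sweep (pA)
    and the true charge in pC (analytic integral of the planted event).
    """
    n = int(round(sweep_ms / 1000.0 * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz * 1000.0  # ms
    start = stim_onset_ms + onset_ms
    tau_r, tau_d = rise_ms, decay_ms
    shape = np.where(
        t >= start,
        np.exp(-(t - start) / tau_d) - np.exp(-(t - start) / tau_r),
        0.0,
    )
    peak = shape.max() if shape.max() > 0 else 1.0
    sweep = amplitude_pa * shape / peak
    true_charge_pc = amplitude_pa * (tau_d - tau_r) / peak / 1000.0  # pA*ms -> pC
    if noise_sd_pa > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        sweep = sweep + rng.standard_normal(n) * noise_sd_pa
    return sweep, true_charge_pc
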