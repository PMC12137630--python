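"""End-to-end pipeline orchestration with provenance capture.

``run_pipeline`` executes an ordered subset of stages (simulate ->
normalize -> detect-events -> correlations -> responses -> score-sleep),
each reading its predecessors' outputs from disk, and writes a run manifest
recording the configuration snapshot, package version, seeds, SHA-256 of
every output file and per-stage timings.  All randomness derives from one
master seed fanned out per stage, so a manifest pins a bit-reproducible run
for the deterministic stages (which, here, is all of them).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .simulate import SimConfig, simulate_movement, simulate_recording

STAGES = (
    "simulate",
    "normalize",
    "detect-events",
    "correlations",
    "responses",
    "score-sleep",
)

# stage -> input files it requires in the run directory
_DEPS: dict[str, list[str]] = {
    "simulate": [],
    "normalize": ["recording.h5"],
    "detect-events": ["dff.h5"],
    "correlations": ["dff.h5"],
    "responses": ["dff.h5", "stimulus.csv"],
    "score-sleep": ["movement.csv"],
}


class PipelineError(RuntimeError):
    pass


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master_seed: int, stage: str) -> int:
    # documented derivation: low 31 bits of sha256(master_seed:stage)
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(
    out_dir: str | Path,
    stages: list[str] | None = None,
    analysis_config: AnalysisConfig | None = None,
    sim_config: SimConfig | None = None,
    seed: int = 0,
    bout_plan: list[tuple[str, float]] | None = None,
) -> dict:
    """Run the requested stages in a fresh or existing run directory.

    Returns the manifest (also written to ``manifest.json``).  A stage whose
    required inputs are absent raises :class:`PipelineError` naming the
    stage; earlier outputs already on disk satisfy dependencies, so partial
    pipelines can resume.
    """
    from .io import (
        read_recording,
        read_stimulus_log,
        write_recording,
        write_results_table,
        write_stimulus_log,
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    order = {s: i for i, s in enumerate(STAGES)}
    if stages != sorted(stages, key=order.__getitem__):
        raise PipelineError("stages must respect the pipeline order")

    acfg = analysis_config or AnalysisConfig()
    scfg = sim_config
    manifest: dict = {
        "package": "neodev",
        "version": __version__,
        "master_seed": int(seed),
        "stage_seeds": {s: _stage_seed(seed, s) for s in stages},
        "analysis_config": acfg.to_dict(),
        "stages": stages,
        "outputs": {},
        "timings_s": {},
    }

    for stage in stages:
        missing = [f for f in _DEPS[stage] if not (out_dir / f).exists()]
        if missing:
            raise PipelineError(f"stage {stage!r} missing input(s): {missing}")
        t0 = time.perf_counter()
        written: list[Path] = []

        if stage == "simulate":
            import dataclasses

            cfg = dataclasses.replace(scfg or SimConfig(), seed=_stage_seed(seed, stage))
            manifest["sim_config"] = {
                k: v for k, v in cfg.__dict__.items() if not isinstance(v, np.ndarray)
            }
            rec, truth = simulate_recording(cfg)
            written.append(write_recording(rec, out_dir / "recording.h5"))
            written.append(write_stimulus_log(truth.stimulus_log, out_dir / "stimulus.csv"))
            pose, labels = simulate_movement(
                cfg, bout_plan or [("wake", 30.0), ("QS", 60.0), ("AS", 60.0)]
            )
            pose.to_csv(out_dir / "movement.csv", index=False)
            written.append(out_dir / "movement.csv")
            truth.state_labels = labels
            with open(out_dir / "ground_truth.json", "w") as fh:
                json.dump(truth.to_jsonable(), fh)
            written.append(out_dir / "ground_truth.json")

        elif stage == "normalize":
            from .normalize import dff_percentile

            rec = read_recording(out_dir / "recording.h5")
            dff = dff_percentile(rec, acfg.dff_percentile)
            written.append(write_recording(
                type(rec)(dff.dff, rec.coords, rec.frame_rate, rec.channel,
                          {"normalized": "first_percentile"}),
                out_dir / "dff.h5",
            ))

        elif stage == "detect-events":
            from .events import detect_events, events_to_records, summarize_events
            from .normalize import DffRecording

            rec = read_recording(out_dir / "dff.h5")
            dff = DffRecording(rec.raw, rec.frame_rate, rec.coords)
            events = detect_events(
                dff, acfg.event_bin_s, acfg.h_threshold, acfg.l_threshold,
                acfg.event_reference,
            )
            written.append(write_results_table(
                events_to_records(events), out_dir / "events.csv",
                columns=["peak_frame", "start_frame", "end_frame", "duration_s",
                         "amplitude", "participation", "n_participants",
                         "event_class", "truncated"],
            ))
            s = summarize_events(events, dff.duration_s)
            rows = [
                {
                    "event_class": cls,
                    "count": {"H": s.n_h, "L": s.n_l, "unclassified": s.n_unclassified}[cls],
                    "mean_amplitude": s.mean_amplitude[cls],
                    "mean_duration_s": s.mean_duration_s[cls],
                    "frequency_per_min": s.frequency_per_min[cls],
                }
                for cls in ("H", "L", "unclassified")
            ]
            written.append(write_results_table(rows, out_dir / "event_summary.csv"))

        elif stage == "correlations":
            from .metrics import correlation_vs_distance, pairwise_correlations
            from .normalize import DffRecording

            rec = read_recording(out_dir / "dff.h5")
            dff = DffRecording(rec.raw, rec.frame_rate, rec.coords)
            corr = pairwise_correlations(dff)
            cbd = correlation_vs_distance(corr, rec.coords, acfg.distance_bin_um)
            rows = [
                {
                    "bin_lo_um": cbd.bin_edges_um[i],
                    "bin_hi_um": cbd.bin_edges_um[i + 1],
                    "mean_correlation": cbd.mean_correlation[i],
                    "n_pairs": int(cbd.pair_counts[i]),
                }
                for i in range(cbd.mean_correlation.size)
            ]
            written.append(write_results_table(rows, out_dir / "correlation_by_distance.csv"))

        elif stage == "responses":
            from .metrics import responsiveness_test
            from .normalize import DffRecording

            rec = read_recording(out_dir / "dff.h5")
            dff = DffRecording(rec.raw, rec.frame_rate, rec.coords)
            stim = read_stimulus_log(out_dir / "stimulus.csv")
            stim.check_within(dff.n_frames)
            rows = []
            if len(stim):
                for stim_type, res in responsiveness_test(
                    dff, stim,
                    acfg.responsiveness_pre_s, acfg.responsiveness_post_s, acfg.alpha,
                    acfg.response_window_s,
                ).items():
                    for c in range(res.amplitude.size):
                        rows.append(
                            {
                                "stimulus_type": stim_type,
                                "cell": c,
                                "amplitude": res.amplitude[c],
                                "p_raw": res.p_raw[c],
                                "p_adjusted": res.p_adjusted[c],
                                "responsive": bool(res.responsive[c]),
                                "test": res.test_used[c],
                            }
                        )
            written.append(write_results_table(
                rows, out_dir / "responses.csv",
                columns=["stimulus_type", "cell", "amplitude", "p_raw",
                         "p_adjusted", "responsive", "test"],
            ))

        elif stage == "score-sleep":
            from .behavior import bouts_to_records, movement_from_pose, score_sleep_states

            pose = pd.read_csv(out_dir / "movement.csv")
            move = movement_from_pose(pose, acfg.frame_rate,
                                      max_interp_gap_s=acfg.max_interp_gap_s)
            bouts, _ = score_sleep_states(move, "left_forelimb", acfg)
            written.append(write_results_table(
                bouts_to_records(bouts, acfg.frame_rate), out_dir / "sleep_bouts.csv"
            ))

        manifest["timings_s"][stage] = time.perf_counter() - t0
        for p in written:
            manifest["outputs"][p.name] = _hash_file(p)

    acfg.to_yaml(out_dir / "config.yaml")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-execute a run from its manifest in a new directory."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    acfg = AnalysisConfig.from_dict(manifest["analysis_config"])
    scfg = None
    if "sim_config" in manifest:
        d = dict(manifest["sim_config"])
        for key in ("h_participation_range", "l_participation_range",
                    "event_amplitude_range", "event_duration_range_s"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if d.get("event_schedule"):
            d["event_schedule"] = [tuple(e) for e in d["event_schedule"]]
        if d.get("stim_schedule"):
            d["stim_schedule"] = [tuple(e) for e in d["stim_schedule"]]
        scfg = SimConfig(**d)
    return run_pipeline(
        out_dir,
        stages=manifest["stages"],
        analysis_config=acfg,
        sim_config=scfg,
        seed=manifest["master_seed"],
    )
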