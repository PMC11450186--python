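"""Run configuration and pipeline orchestration.

A :class:`RunConfig` (typically loaded from YAML) names the stages to run
and their parameters; :func:`run_pipeline` executes them in dependency order
(stimulus -> scenes / recordings -> models -> analysis), derives every
stage's random substream deterministically from the global seed, and writes
a JSON manifest with seeds and content hashes of all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidSpecError, LumigainError

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("lumigain")

#: execution order; stages not listed in a config are skipped
STAGE_ORDER = ("stimulus", "scene_scan", "circuit", "recording", "analysis")


@dataclass
class RunConfig:
    """Global seed, output directory and per-stage parameter blocks."""

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {"seed", "out_dir", "log_level", "stages"}
        unknown = set(raw) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in self.stages:
            if name not in STAGE_ORDER:
                raise InvalidSpecError(f"unknown stage {name!r}")
        needs_stim = {"recording", "analysis"}
        for name in needs_stim & set(self.stages):
            block = self.stages[name] or {}
            if "stimulus" not in block and "stimulus" not in self.stages:
                raise InvalidSpecError(
                    f"stage {name!r} requires a stimulus stage or an explicit "
                    "'stimulus' file reference"
                )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31) from the global seed."""
    idx = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_stimulus(block: dict, seed: int, out: Path):
    from . import stimuli

    kind = block.get("kind", "grating")
    params = dict(block.get("params", {}))
    params.setdefault("seed", seed)
    screen_params = block.get("screen", {})
    screen = stimuli.ScreenGeometry(**screen_params)
    if kind == "grating":
        movie = stimuli.make_drifting_grating(stimuli.GratingSpec(**params), screen)
    elif kind == "edge":
        movie = stimuli.make_off_edge(stimuli.EdgeSpec(**params), screen)
    elif kind == "noise":
        render = block.get("render", "full")
        movie = stimuli.make_ternary_noise(
            stimuli.WhiteNoiseSpec(**params), screen, render=render
        )
    else:
        raise InvalidSpecError(f"unknown stimulus kind {kind!r}")
    path = out / "stimulus.h5"
    movie.to_hdf5(path)
    return movie, {"stimulus": path}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest: dict = {"seed": config.seed, "stages": {}}
    movie = None
    recording = None

    def run_stage(name, fn):
        nonlocal manifest
        seed = stage_seed(config.seed, name)
        log.info("running stage %s (seed %d)", name, seed)
        try:
            outputs = fn(seed)
        except Exception as exc:
            (out / f"{name}.failed").write_text(str(exc))
            raise LumigainError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "seed": seed,
            "outputs": {k: str(p) for k, p in outputs.items()},
            "sha256": {k: _sha256(Path(p)) for k, p in outputs.items()},
        }

    if "stimulus" in config.stages:
        def stim_stage(seed):
            nonlocal movie
            movie, outputs = _build_stimulus(config.stages["stimulus"] or {}, seed, out)
            return outputs

        run_stage("stimulus", stim_stage)

    if "scene_scan" in config.stages:
        def scan_stage(seed):
            from . import natural_scenes as ns
            from .lmc_model import MembraneParams

            block = config.stages["scene_scan"] or {}
            ens = ns.synthesize_scene_ensemble(
                ns.EnsembleParams(**block.get("ensemble", {})), seed=seed
            )
            result = ns.scan_pooling_sizes(
                ens,
                MembraneParams(**block.get("membrane", {})),
                diameters=tuple(block.get("diameters", (0.5, 2.0, 8.0, 15.0, 32.0))),
                n_trajectories=int(block.get("n_trajectories", 15)),
                seed=seed,
                g_l=float(block.get("g_l", 0.05)),
                background=block.get("background", "response"),
            )
            path = out / "pooling_scan.csv"
            result.to_csv(path)
            return {"pooling_scan": path}

        run_stage("scene_scan", scan_stage)

    if "circuit" in config.stages:
        def circuit_stage(seed):
            from . import circuit_model as cm

            block = config.stages["circuit"] or {}
            g_l = block.get("g_l")
            if g_l is None:
                g_l = cm.calibrate_leak_conductance(
                    float(block.get("pooling_diameter", 15.0))
                )
            params = cm.NormalizationParams(
                g_l=float(g_l),
                p=int(block.get("p", 1)),
                pooling_diameter=float(block.get("pooling_diameter", 15.0)),
            )
            curve = cm.simulate_contrast_curves(
                params, n_traces=int(block.get("n_traces", 1000)), seed=seed
            )
            path = out / "circuit_curve.csv"
            curve.to_csv(path)
            meta = out / "circuit_manifest.json"
            meta.write_text(
                json.dumps(
                    {"g_l": params.g_l, "p": params.p, "slope": curve.slope,
                     "pooling_diameter": params.pooling_diameter,
                     "n_traces": curve.n_traces, "seed": seed}
                )
            )
            return {"curve": path, "meta": meta}

        run_stage("circuit", circuit_stage)

    if "recording" in config.stages:
        def recording_stage(seed):
            nonlocal recording
            from . import synthetic_recordings as sr

            block = config.stages["recording"] or {}
            if movie is None:
                raise InvalidSpecError("recording stage requires the stimulus stage")
            neurons = tuple(
                sr.GroundTruthNeuron(
                    **{**n, "rf_center": tuple(n.get("rf_center", (0.0, 0.0)))}
                )
                for n in block.get("neurons", [{}])
            )
            manifest_obj = sr.RecordingManifest(
                neurons=neurons,
                frame_rate=float(block.get("frame_rate", 12.0)),
                n_trials=int(block.get("n_trials", 3)),
                seed=seed,
            )
            recording, sidecar = sr.generate_recording(manifest_obj, movie)
            rec_path = out / "recording.h5"
            recording.to_hdf5(rec_path)
            sc_path = out / "recording_groundtruth.json"
            sr.save_sidecar(sidecar, sc_path)
            return {"recording": rec_path, "ground_truth": sc_path}

        run_stage("recording", recording_stage)

    if "analysis" in config.stages:
        def analysis_stage(seed):
            import pandas as pd

            from . import imaging_analysis as ia

            if recording is None:
                raise InvalidSpecError("analysis stage requires the recording stage")
            rel = [
                ia.roi_reliability(recording.trials(i))
                for i in range(recording.n_rois)
            ]
            df = pd.DataFrame(
                {
                    "roi": np.arange(recording.n_rois),
                    "reliability": [r[0] for r in rel],
                    "kept": [r[1] for r in rel],
                }
            )
            path = out / "roi_summary.csv"
            df.to_csv(path, index=False)
            return {"roi_summary": path}

        run_stage("analysis", analysis_stage)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
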