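"""End-to-end pipeline: simulate -> register -> angiography -> fusion
-> cohort tallies, with a reproducible run manifest.

A single global seed fans out to per-stage seeds by fixed offsets
(phantom geometry, motion, rendering, registration sampler), so one knob
reproduces the whole run while keeping stages statistically independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import io as aio
from .angiography import AngiographyConfig, perfusion_map
from .cohort import load_cohort, tally_eyes, tally_lesions
from .fusion import (FusionConfig, classify_perfusion, composite_render,
                     ghost_confusion, segment_vessels)
from .phantom import (FrameSequence, MotionModel, PhantomSpec,
                      generate_phantom, render_frames, render_structural)
from .registration import (RegistrationConfig, control_point_spacing_px,
                           register_groupwise)

__all__ = ["PipelineConfig", "StageDependencyError", "run_pipeline",
           "default_config", "ghost_detection_study",
           "registration_recovery_study"]

log = logging.getLogger("aoangio")

_SEED_OFFSETS = {"phantom": 0, "motion": 1009, "render": 2003,
                 "sampler": 3001}


class StageDependencyError(RuntimeError):
    """A stage was enabled without its upstream input."""


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    motion: MotionModel = field(default_factory=MotionModel)
    registration: RegistrationConfig = field(
        default_factory=RegistrationConfig)
    angiography: AngiographyConfig = field(default_factory=AngiographyConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    n_frames: int = 12
    noise_sd: float = 0.02
    flow_on: bool = True
    seed: int = 0
    outdir: str = "aoangio_run"
    stages: tuple[str, ...] = ("simulate", "register", "angio", "fuse",
                               "tally")
    frames_path: Optional[str] = None     # upstream input if simulate is off
    cohort_path: Optional[str] = None     # defaults to the packaged tables

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self,
                       seed=seed,
                       phantom=replace(self.phantom,
                                       seed=seed + _SEED_OFFSETS["phantom"]),
                       motion=replace(self.motion,
                                      seed=seed + _SEED_OFFSETS["motion"]),
                       registration=replace(
                           self.registration,
                           sampler_seed=seed + _SEED_OFFSETS["sampler"]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("phantom", PhantomSpec), ("motion", MotionModel),
                         ("registration", RegistrationConfig),
                         ("angiography", AngiographyConfig),
                         ("fusion", FusionConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = typ(**sub)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the run manifest."""
    cfg = config.with_seed(config.seed)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                      "stages": list(cfg.stages), "outputs": {}}
    stages = set(cfg.stages)
    phantom = None
    frames: Optional[FrameSequence] = None
    structural = None
    perf = None
    seg = None

    if "simulate" in stages:
        phantom = generate_phantom(cfg.phantom)
        frames = render_frames(phantom, cfg.n_frames, cfg.motion,
                               cfg.noise_sd, cfg.flow_on,
                               seed=cfg.seed + _SEED_OFFSETS["render"])
        structural = render_structural(phantom)
        aio.write_frames(outdir / "frames.tif", frames, metadata={
            "seed": cfg.seed, "noise_sd": cfg.noise_sd,
            "flow_on": cfg.flow_on,
            "jitter_amplitude_um": cfg.motion.jitter_amplitude_um,
            "deformation_amplitude_um": cfg.motion.deformation_amplitude_um})
        aio.write_image(outdir / "structural.tif", structural)
        for name in ("vessel_mask", "perfused_mask", "ghost_mask"):
            aio.write_mask(outdir / f"{name}.tif", getattr(phantom, name))
        manifest["outputs"]["simulate"] = {
            "frames": str(outdir / "frames.tif"),
            "structural": str(outdir / "structural.tif"),
            "n_segments": len(phantom.segments),
            "n_ghost_segments": sum(1 for s in phantom.segments
                                    if not s.perfused)}
        log.info("simulate: %d segments, %d frames, pitch %.2f um/px",
                 len(phantom.segments), cfg.n_frames,
                 cfg.phantom.pixel_pitch_um)

    if "register" in stages:
        if frames is None:
            if cfg.frames_path is None:
                raise StageDependencyError(
                    "register: no frames available (enable simulate or set "
                    "frames_path)")
            frames = aio.read_frames(cfg.frames_path)
        spacing_px = control_point_spacing_px(
            cfg.registration.control_point_spacing_um, frames.pixel_pitch_um)
        log.info("register: control-point spacing %.0f um = %d px, "
                 "%d resolutions, %d iterations/level",
                 cfg.registration.control_point_spacing_um, spacing_px,
                 cfg.registration.n_resolutions,
                 cfg.registration.iterations_per_level)
        result = register_groupwise(frames, cfg.registration)
        frames = result.registered
        aio.write_frames(outdir / "registered.tif", frames)
        for i, t in enumerate(result.transforms):
            aio.write_transform(outdir / f"transform_{i:02d}.yaml", t)
        manifest["outputs"]["register"] = {
            "registered": str(outdir / "registered.tif"),
            "cost_trace": [float(c) for c in result.cost_trace],
            "control_point_spacing_px": spacing_px}

    if "angio" in stages:
        if frames is None:
            if cfg.frames_path is None:
                raise StageDependencyError(
                    "angio: no frames available (enable simulate/register or "
                    "set frames_path)")
            frames = aio.read_frames(cfg.frames_path)
        perf = perfusion_map(frames, cfg.angiography)
        aio.write_image(outdir / "perfusion.tif", perf.decorrelation,
                        metadata={"threshold_value": perf.threshold_value,
                                  "n_pairs_used": perf.n_pairs_used,
                                  "pair_policy": cfg.angiography.pair_policy,
                                  "n_frames": frames.n_frames})
        aio.write_image(outdir / "mean_image.tif", perf.mean_image)
        aio.write_mask(outdir / "noise_mask.tif", perf.noise_mask)
        manifest["outputs"]["angio"] = {
            "perfusion": str(outdir / "perfusion.tif"),
            "threshold_value": float(perf.threshold_value),
            "n_pairs_used": int(perf.n_pairs_used)}
        log.info("angio: %d pairs (%s), noise threshold %.4f",
                 perf.n_pairs_used, cfg.angiography.pair_policy,
                 perf.threshold_value)

    if "fuse" in stages:
        if perf is None:
            raise StageDependencyError("fuse: angio stage output missing")
        if structural is None:
            spath = outdir / "structural.tif"
            if not spath.exists():
                raise StageDependencyError(
                    "fuse: structural image missing (enable simulate)")
            structural = aio.read_image(spath)
        fcfg = replace(cfg.fusion,
                       pixel_pitch_um=cfg.phantom.pixel_pitch_um)
        seg = segment_vessels(structural, fcfg)
        labels = classify_perfusion(seg, perf, fcfg)
        composite = composite_render(structural, seg, labels)
        aio.write_image(outdir / "composite.tif", composite)
        rows = [{"segment_id": s.label, "length_um": round(s.length_um, 2),
                 "flow_fraction": round(l.flow_fraction, 4),
                 "status": l.status}
                for s, l in zip(seg.segments, labels.labels)]
        import pandas as pd
        pd.DataFrame(rows, columns=["segment_id", "length_um",
                                    "flow_fraction", "status"]).to_csv(
            outdir / "segments.csv", index=False)
        manifest["outputs"]["fuse"] = {
            "composite": str(outdir / "composite.tif"),
            "segments": str(outdir / "segments.csv"),
            "flow_threshold": float(labels.flow_threshold),
            "n_perfused": labels.n_perfused,
            "n_non_perfused": labels.n_non_perfused}
        if phantom is not None:
            conf = ghost_confusion(seg, labels, phantom.perfused_mask,
                                   phantom.ghost_mask)
            manifest["outputs"]["fuse"]["ghost_confusion"] = conf
        log.info("fuse: %d segments, %d perfused / %d non-perfused, "
                 "flow threshold %.4f", len(seg.segments),
                 labels.n_perfused, labels.n_non_perfused,
                 labels.flow_threshold)

    if "tally" in stages:
        table = load_cohort(cfg.cohort_path)
        lesions = tally_lesions(table)
        eyes = tally_eyes(table)
        tallies = {"patients_with_lesion": lesions.patients_with_lesion,
                   "eyes_by_group": eyes.eyes_by_group,
                   "eyes_by_grade": eyes.eyes_by_grade}
        with open(outdir / "tallies.json", "w") as fh:
            json.dump(tallies, fh, indent=2)
        manifest["outputs"]["tally"] = tallies

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# in-memory study drivers (no disk output), shared by tests and scripts

def ghost_detection_study(seeds, ghost_fraction: float = 0.2,
                          n_frames: int = 12, noise_sd: float = 0.02) -> dict:
    """Full simulate/register/angio/fuse pipeline over several phantoms;
    aggregates the segment-level ghost-detection confusion matrix."""
    seeds = list(seeds)
    tp = fp = tn = fn = unmatched = 0
    for seed in seeds:
        phantom = generate_phantom(PhantomSpec(
            seed=seed + _SEED_OFFSETS["phantom"],
            ghost_fraction=ghost_fraction))
        frames = render_frames(phantom, n_frames,
                               MotionModel(seed=seed + _SEED_OFFSETS["motion"]),
                               noise_sd, True,
                               seed=seed + _SEED_OFFSETS["render"])
        result = register_groupwise(frames, RegistrationConfig(
            sampler_seed=seed + _SEED_OFFSETS["sampler"]))
        perf = perfusion_map(result.registered)
        seg = segment_vessels(render_structural(phantom), FusionConfig())
        labels = classify_perfusion(seg, perf, FusionConfig())
        c = ghost_confusion(seg, labels, phantom.perfused_mask,
                            phantom.ghost_mask)
        tp += c["tp"]
        fp += c["fp"]
        tn += c["tn"]
        fn += c["fn"]
        unmatched += c["unmatched"]
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "unmatched": unmatched,
            "sensitivity": sens, "specificity": spec,
            "balanced_accuracy": 0.5 * (sens + spec),
            "n_seeds": len(seeds)}


def registration_recovery_study(seed: int, field_px: int = 256,
                                n_frames: int = 12,
                                jitter_px: float = 5.0,
                                deformation_px: float = 3.0) -> dict:
    """Noiseless stack under known rigid jitter + smooth warps; returns
    the mean endpoint error of the recovered displacement fields."""
    from .registration import warp_recovery_error
    spec = PhantomSpec(field_width_px=field_px, field_height_px=field_px,
                       seed=seed + _SEED_OFFSETS["phantom"])
    phantom = generate_phantom(spec)
    pitch = spec.pixel_pitch_um
    motion = MotionModel(jitter_amplitude_um=jitter_px * pitch,
                         deformation_amplitude_um=deformation_px * pitch,
                         seed=seed + _SEED_OFFSETS["motion"])
    frames = render_frames(phantom, n_frames, motion, noise_sd=0.0,
                           flow_on=False,
                           seed=seed + _SEED_OFFSETS["render"])
    result = register_groupwise(frames, RegistrationConfig(
        sampler_seed=seed + _SEED_OFFSETS["sampler"]))
    return {"mean_endpoint_error_px": warp_recovery_error(result, frames),
            "cost_trace": [float(c) for c in result.cost_trace],
            "n_frames": n_frames, "field_px": field_px}
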