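"""Config-driven pipeline orchestration with reproducible seeding.

A single YAML/JSON config selects stages and carries their parameter
blocks.  One top-level seed is fanned out to per-stage child seeds via a
counter-based derivation (``SeedSequence([seed, stage_counter])``) so a
stage's realisation does not depend on which other stages run.  Every
run writes a manifest with parameters, output paths and content
checksums; re-running the same config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import io as gio
from .dynamics import run_dynamics
from .geometry import AcquisitionGeometry
from .kinetics import fit_translocation, footprint_mask, intensity_series
from .preprocess import PreprocessParams, preprocess_stack
from .simulate import SimulationConfig, simulate_tirf_movie

__all__ = ["RunConfig", "run", "child_seed"]

_STAGE_COUNTERS = {"simulate": 0, "preprocess": 1, "dynamics": 2,
                   "kinetics": 3, "quantify": 4}


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the run seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_COUNTERS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Block):
    pixel_size: float = 0.1
    frame_interval: float = 0.5
    exposure: float = 0.5
    penetration_depth: float = 110.0
    psf_sigma: float = 2.0


class SimulateBlock(_Block):
    field_size: tuple[int, int] = (128, 128)
    duration_pre: float = 120.0
    duration_post: float = 1500.0
    static_density_pre: float = 4.0
    static_density_post: float = 13.2
    mobile_density_pre: float = 1.0
    mobile_density_post: float = 3.3
    diffusion_coeff: float = 3e-3
    transition_halftime: float = 12.3
    vesicle_brightness: float = 8000.0
    vesicle_z_range: float = 300.0
    background_offset: float = 10.0
    background_amplitude: float = 5.0
    read_noise_sd: float = 1.5
    shot_noise: bool = True


class PreprocessBlock(_Block):
    ball_radius: int = 10
    despeckle_window: int = 3
    outlier_radius: int = 2
    outlier_threshold: float = 10.0
    smooth_window: int = 3
    input: str | None = None  # pre-existing movie TIFF; default: simulate output


class DynamicsBlock(_Block):
    bin_duration: float = 60.0
    n_rois: int = 10
    roi_area_um2: float = 100.0
    input: str | None = None


class KineticsBlock(_Block):
    frames_per_timepoint: int = 10
    use_footprint_mask: bool = False
    input: str | None = None


class RunConfig(_Block):
    """Schema-checked pipeline configuration (unknown keys rejected)."""

    stages: list[str]
    seed: int = 0
    outdir: str = "glut4_run"
    geometry: GeometryBlock = GeometryBlock()
    simulate: SimulateBlock = SimulateBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    dynamics: DynamicsBlock = DynamicsBlock()
    kinetics: KineticsBlock = KineticsBlock()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**data)
        except ValidationError as err:
            raise ValueError(f"invalid run config: {err}") from err


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    known = set(_STAGE_COUNTERS)
    unknown = [s for s in config.stages if s not in known]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    order = [s for s in ("simulate", "preprocess", "dynamics", "kinetics")
             if s in config.stages]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = AcquisitionGeometry(**config.geometry.model_dump())
    outputs: dict[str, str] = {}

    def _resolve_input(block_input, fallback_key, stage):
        if block_input is not None:
            p = Path(block_input)
        elif fallback_key in outputs:
            p = Path(outputs[fallback_key])
        else:
            raise ValueError(
                f"stage {stage!r} needs an input movie: either run an "
                f"earlier stage or set its 'input' path")
        if not p.exists():
            raise FileNotFoundError(f"stage {stage!r} input {p} does not exist")
        return p

    for stage in order:
        if stage == "simulate":
            sim_seed = child_seed(config.seed, "simulate")
            sim_cfg = SimulationConfig(seed=sim_seed,
                                       **config.simulate.model_dump())
            movie, truth = simulate_tirf_movie(sim_cfg, geometry)
            mp = outdir / "movie.tif"
            gio.write_movie(mp, movie, seed=sim_seed)
            truth.to_csv(outdir / "ground_truth.csv")
            outputs["movie"] = str(mp)
            outputs["ground_truth"] = str(outdir / "ground_truth.csv")
        elif stage == "preprocess":
            src = _resolve_input(config.preprocess.input, "movie", stage)
            movie = gio.read_movie(src)
            params = PreprocessParams(**{
                k: v for k, v in config.preprocess.model_dump().items()
                if k != "input"})
            clean = preprocess_stack(movie, params)
            cp = outdir / "clean.tif"
            gio.write_movie(cp, clean, seed=config.seed)
            outputs["clean"] = str(cp)
        elif stage == "dynamics":
            src = _resolve_input(config.dynamics.input, "clean", stage)
            movie = gio.read_movie(src)
            series = run_dynamics(
                movie, bin_duration=config.dynamics.bin_duration,
                n_rois=config.dynamics.n_rois,
                roi_area_um2=config.dynamics.roi_area_um2)
            cp = outdir / "counts.csv"
            series.table.to_csv(cp, index=False)
            outputs["counts"] = str(cp)
        elif stage == "kinetics":
            src = _resolve_input(config.kinetics.input, "clean", stage)
            movie = gio.read_movie(src)
            mask = None
            if config.kinetics.use_footprint_mask:
                ref = movie.frames[:max(movie.insulin_frame, 1)].mean(axis=0)
                mask = footprint_mask(ref, movie.geometry.pixel_size)
            times, series = intensity_series(
                movie, mask, config.kinetics.frames_per_timepoint)
            fit = fit_translocation(times, series)
            fp = outdir / "fit.json"
            fp.write_text(json.dumps({
                "times_min": fit.times.tolist(),
                "normalized_intensity": fit.normalized_intensity.tolist(),
                "fold": fit.fold, "t_half_min": fit.t_half, "rss": fit.rss,
                "final_value": fit.final_value, "converged": fit.converged,
                "mask_area_um2": mask.area_um2 if mask else None,
            }, indent=2))
            outputs["fit"] = str(fp)

    manifest = {
        "seed": config.seed,
        "stages": order,
        "parameters": config.model_dump(),
        "outputs": outputs,
        "checksums": {k: _sha256(Path(v)) for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
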