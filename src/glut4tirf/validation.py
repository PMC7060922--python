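"""Closed-loop validation studies: simulate with known ground truth,
run the full analysis, and recover the generating parameters.

No raw data exist for near-membrane GLUT4 trafficking experiments, so the
pipeline is validated by closed-loop recovery: published summary values
(fold responses, half-times, vesicle densities, penetration depth) are
used as simulator ground truth and the analysis must read them back.

Study problem sizes are chosen to run on a single CPU in minutes: a
256 px (25.6 µm) footprint sampled every 15 s over 3 min pre / 35 min
post insulin for the kinetics studies — intensity time courses need
dense *timepoints* and a window of ~2 half-times, not a high frame
rate — and a 300 px footprint at one frame per 3 s for the
vesicle-counting study, whose 3 x 3 grid of 100 µm² ROIs tiles the
whole footprint.
"""

from __future__ import annotations

import zlib

import numpy as np

from .dynamics import run_dynamics
from .geometry import AcquisitionGeometry
from .kinetics import (
    TranslocationFit,
    estimate_penetration_depth,
    fit_translocation,
    intensity_series,
    translocation_model,
)
from .preprocess import preprocess_stack
from .quantify import ha_gfp_ratio, measure_fields
from .simulate import (
    FieldImageSet,
    SimulationConfig,
    simulate_bead_image,
    simulate_tirf_movie,
    simulate_translocation_fields,
)

__all__ = [
    "child_seeds",
    "translocation_movie_config",
    "recover_translocation_fold",
    "fit_model_series",
    "mobile_density_movie_config",
    "recover_mobile_density",
    "recover_penetration_depth",
    "screen_insulin_ratio",
    "screen_basal_elevation",
]

KINETICS_GEOMETRY = AcquisitionGeometry(pixel_size=0.1, frame_interval=15.0,
                                        exposure=0.5)
DYNAMICS_GEOMETRY = AcquisitionGeometry(pixel_size=0.1, frame_interval=3.0,
                                        exposure=0.5)


def child_seeds(base_seed: int, label: str, n: int) -> list[int]:
    """Derive ``n`` independent seeds (< 2**31) for one study."""
    tag = zlib.crc32(label.encode())  # stable across processes
    ss = np.random.SeedSequence([int(base_seed), tag])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def translocation_movie_config(fold: float, t_half_min: float,
                               seed: int) -> SimulationConfig:
    """Movie whose total vesicle load rises ``fold``-fold after insulin.

    Both pools scale by the same factor so the normalised TIRF-zone
    intensity plateau equals ``fold``; the density relaxation half-time
    is the translocation half-time.
    """
    return SimulationConfig(
        field_size=(256, 256),
        duration_pre=180.0, duration_post=2100.0,
        static_density_pre=4.0, static_density_post=4.0 * fold,
        mobile_density_pre=1.0, mobile_density_post=1.0 * fold,
        transition_halftime=t_half_min, seed=seed)


def recover_translocation_fold(fold: float, t_half_min: float,
                               seeds: list[int],
                               frames_per_timepoint: int = 2) -> list[TranslocationFit]:
    """Simulate, preprocess and fit one movie per seed; return the fits."""
    fits = []
    for seed in seeds:
        config = translocation_movie_config(fold, t_half_min, seed)
        movie, _ = simulate_tirf_movie(config, KINETICS_GEOMETRY)
        clean = preprocess_stack(movie)
        times, series = intensity_series(clean, None, frames_per_timepoint)
        fits.append(fit_translocation(times, series))
    return fits


def fit_model_series(fold: float, t_half_min: float,
                     n_points: int = 50) -> TranslocationFit:
    """Noise-free rise-model series over -2 to 25 min, refitted."""
    t = np.linspace(-2.0, 25.0, n_points)
    return fit_translocation(t, translocation_model(t, fold, t_half_min))


def mobile_density_movie_config(seed: int,
                                mobile_density_post: float = 2.0) -> SimulationConfig:
    """Movie reaching a post-insulin steady-state mobile density.

    The transition half-time is short (1 min) so the final five
    one-minute bins of the 8 min post-insulin window sit on the
    plateau, mirroring the return of mobile-vesicle activity to a steady
    density within minutes of stimulation.
    """
    return SimulationConfig(
        field_size=(300, 300),
        duration_pre=120.0, duration_post=480.0,
        static_density_pre=4.0, static_density_post=4.0,
        mobile_density_pre=1.0, mobile_density_post=mobile_density_post,
        transition_halftime=1.0, seed=seed)


def recover_mobile_density(seeds: list[int],
                           mobile_density_post: float = 2.0,
                           n_rois: int = 9) -> list[float]:
    """Recovered steady-state mobile density (per 100 µm²) per seed,
    averaged over the final five bins and all ROIs."""
    out = []
    for seed in seeds:
        config = mobile_density_movie_config(seed, mobile_density_post)
        movie, _ = simulate_tirf_movie(config, DYNAMICS_GEOMETRY)
        clean = preprocess_stack(movie)
        series = run_dynamics(clean, n_rois=n_rois)
        out.append(series.mean_density_per_100um2("mobile", slice(-5, None)))
    return out


def recover_penetration_depth(depth_nm: float = 110.0,
                              bead_diameter: float = 10.0) -> float:
    """Noise-free bead rendering at the given depth, re-estimated."""
    geometry = AcquisitionGeometry(penetration_depth=depth_nm)
    image = simulate_bead_image(geometry, bead_diameter, brightness=1000.0)
    return estimate_penetration_depth(image, bead_diameter, geometry)


def screen_insulin_ratio(fold: float = 3.0, n_fields: int = 16,
                         seed: int = 0) -> float:
    """Noise-free control screen: normalised insulin HA/GFP ratio."""
    fields = simulate_translocation_fields(n_fields, 0.15, fold=fold,
                                           seed=seed)
    table, _ = ha_gfp_ratio(measure_fields(fields))
    return float(table[table["stimulation"] == "insulin"]
                 ["normalized_ratio"].mean())


def screen_basal_elevation(elevation: float = 2.7, n_fields: int = 16,
                           seed: int = 0) -> float:
    """Knockdown with elevated basal surface reporter and no insulin
    response, read out against the control basal (cross-group
    normalisation)."""
    control = simulate_translocation_fields(
        n_fields, 0.1, fold=3.0, seed=seed, treatment="control")
    knockdown = simulate_translocation_fields(
        n_fields, 0.1 * elevation, fold=1.0, seed=seed + 1,
        treatment="knockdown")
    measurements = measure_fields(
        FieldImageSet(control.fields + knockdown.fields))
    table, _ = ha_gfp_ratio(measurements, normalise_to="control")
    sel = (table["treatment"] == "knockdown") & (table["stimulation"] == "basal")
    return float(table.loc[sel, "normalized_ratio"].mean())
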