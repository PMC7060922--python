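"""Synthetic TIRF movies, calibration beads, and multi-channel cell fields.

The simulator provides ground truth for every downstream analysis stage:

* :func:`simulate_tirf_movie` renders a time-lapse of docked (static) and
  laterally diffusing (mobile) GLUT4-carrier vesicles under evanescent
  illumination.  A vesicle at height ``z`` above the glass appears as a
  Gaussian spot of amplitude ``brightness * exp(-z / d)`` where ``d`` is the
  penetration depth.  Vesicle densities relax from their basal to their
  insulin-stimulated values after the insulin-addition frame with a
  single-exponential time course parameterised by a half-time.
* :func:`simulate_bead_image` renders a large fluorescent bead resting on
  the coverslip; the spherical geometry converts lateral position into
  height, which is how the penetration depth is calibrated in practice.
* :func:`simulate_translocation_fields` and :func:`simulate_coloc_fields`
  emulate fixed-cell multi-channel fields used for surface/total reporter
  ratios and colocalisation, with the generating fractions recorded as
  per-field ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry

__all__ = [
    "SimulationConfig",
    "TIRFMovie",
    "VesicleGroundTruth",
    "FieldImage",
    "FieldImageSet",
    "simulate_tirf_movie",
    "simulate_bead_image",
    "simulate_translocation_fields",
    "simulate_coloc_fields",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic TIRF movie.

    Densities are vesicles per 100 µm² of footprint; ``_pre`` values hold
    before insulin addition and the density relaxes exponentially to the
    ``_post`` value afterwards with half-time ``transition_halftime``
    (minutes).  Defaults describe an adipocyte-like cell: a 3.3-fold
    insulin response of both vesicle pools with a 12.3 min half-time.

    ``diffusion_coeff`` (µm²/s) is the effective lateral diffusion of the
    mobile pool.  Near-membrane GLUT4 carriers are tethered and move in a
    restricted fashion, sub-micrometre over a minute; 3e-3 µm²/s gives
    an rms excursion of ~0.6 µm over 60 s.

    ``vesicle_brightness`` is the photon amplitude of a spot at z = 0;
    ``vesicle_z_range`` (nm) is the span of the uniform height
    distribution.  ``shot_noise`` toggles Poisson photon noise;
    ``read_noise_sd`` adds Gaussian camera noise.
    """

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
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size
        if h <= 0 or w <= 0:
            raise ValueError("field_size must be strictly positive")
        for name in ("static_density_pre", "static_density_post",
                     "mobile_density_pre", "mobile_density_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be non-negative")
        if self.duration_pre < 0 or self.duration_post < 0:
            raise ValueError("durations must be non-negative")
        if self.transition_halftime <= 0:
            raise ValueError("transition_halftime must be positive")
        if self.vesicle_z_range < 0:
            raise ValueError("vesicle_z_range must be non-negative")


@dataclass
class TIRFMovie:
    """A time-ordered stack of intensity rasters plus acquisition metadata.

    ``insulin_frame`` is the index of the first post-insulin frame.
    """

    frames: np.ndarray
    geometry: AcquisitionGeometry
    insulin_frame: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W stack with T >= 1")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if not 0 <= self.insulin_frame <= self.frames.shape[0]:
            raise ValueError("insulin_frame outside [0, T]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_minutes(self) -> np.ndarray:
        """Frame times in minutes relative to insulin addition."""
        idx = np.arange(self.n_frames) - self.insulin_frame
        return idx * self.geometry.frame_interval / 60.0


@dataclass
class VesicleGroundTruth:
    """Per-frame vesicle records exported by the simulator.

    ``records`` has one row per vesicle per frame with columns
    ``vesicle_id, cls, frame, x_px, y_px, z_nm, amplitude``.  Positions may
    lie in the rendering margin just outside the field of view.
    """

    records: pd.DataFrame

    COLUMNS = ("vesicle_id", "cls", "frame", "x_px", "y_px", "z_nm", "amplitude")

    def __post_init__(self) -> None:
        if list(self.records.columns) != list(self.COLUMNS):
            self.records = self.records.reindex(columns=list(self.COLUMNS))
        if len(self.records) and (self.records["z_nm"] < 0).any():
            raise ValueError("z must be non-negative")

    def in_field_counts(self, shape: tuple[int, int], cls: str,
                        n_frames: int | None = None) -> pd.Series:
        """Number of vesicles of class ``cls`` inside the field, per frame.

        Frames with no such vesicle report 0; the frame axis spans
        ``n_frames`` (default: up to the last recorded frame).
        """
        r = self.records
        h, w = shape
        sel = (
            (r["cls"] == cls)
            & (r["x_px"] >= 0) & (r["x_px"] < w)
            & (r["y_px"] >= 0) & (r["y_px"] < h)
        )
        counts = r.loc[sel].groupby("frame").size()
        if n_frames is None:
            n_frames = int(r["frame"].max()) + 1 if len(r) else 0
        return counts.reindex(range(n_frames), fill_value=0)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VesicleGroundTruth":
        return cls(pd.read_csv(path))


def _density_at(config: SimulationConfig, t_rel_s: float, pre: float, post: float) -> float:
    """Vesicle density at time ``t_rel_s`` (seconds relative to insulin)."""
    if t_rel_s < 0:
        return pre
    tau_s = config.transition_halftime * 60.0
    return post + (pre - post) * 2.0 ** (-t_rel_s / tau_s)


def _render_spot(frame: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    """Add a truncated (4 sigma) Gaussian spot in place."""
    h, w = frame.shape
    r = 4.0 * sigma
    x0, x1 = int(math.floor(x - r)), int(math.ceil(x + r))
    y0, y1 = int(math.floor(y - r)), int(math.ceil(y + r))
    x0, x1 = max(x0, 0), min(x1, w - 1)
    y0, y1 = max(y0, 0), min(y1, h - 1)
    if x0 > x1 or y0 > y1:
        return
    xs = np.arange(x0, x1 + 1) - x
    ys = np.arange(y0, y1 + 1) - y
    d2 = ys[:, None] ** 2 + xs[None, :] ** 2
    patch = amp * np.exp(-d2 / (2.0 * sigma * sigma))
    patch[d2 > r * r] = 0.0
    frame[y0:y1 + 1, x0:x1 + 1] += patch


def _uneven_background(shape: tuple[int, int], offset: float, amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Smooth uneven background: low-order polynomial plus broad blobs."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - w / 2) / max(w, 1)
    v = (yy - h / 2) / max(h, 1)
    c = rng.uniform(-1, 1, size=5)
    surface = c[0] * u + c[1] * v + c[2] * u * v + c[3] * u ** 2 + c[4] * v ** 2
    for _ in range(3):
        bx, by = rng.uniform(0, w), rng.uniform(0, h)
        bs = rng.uniform(0.15, 0.3) * max(h, w)
        surface = surface + rng.uniform(0.3, 1.0) * np.exp(
            -((xx - bx) ** 2 + (yy - by) ** 2) / (2 * bs ** 2))
    surface = surface - surface.min()
    if surface.max() > 0:
        surface = surface / surface.max()
    return offset + amplitude * surface


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi) by mirror reflection."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v >= span, 2 * span - v, v)
    return np.clip(v + lo, lo, np.nextafter(hi, lo))


class _Population:
    """Bookkeeping for one vesicle class in the extended (field + margin) region."""

    def __init__(self, rng: np.random.Generator, ext_origin: float, ext_h: float,
                 ext_w: float, z_range: float, id_start: int):
        self.rng = rng
        self.o = ext_origin          # margin size in px (origin offset, same x/y)
        self.h = ext_h
        self.w = ext_w
        self.z_range = z_range
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.z = np.empty(0)
        self.ids = np.empty(0, dtype=int)
        self._next_id = id_start

    @property
    def n(self) -> int:
        return self.x.size

    def spawn(self, k: int) -> None:
        if k <= 0:
            return
        self.x = np.concatenate([self.x, self.rng.uniform(-self.o, self.w - self.o, k)])
        self.y = np.concatenate([self.y, self.rng.uniform(-self.o, self.h - self.o, k)])
        z = (self.rng.uniform(0, self.z_range, k) if self.z_range > 0
             else np.zeros(k))
        self.z = np.concatenate([self.z, z])
        self.ids = np.concatenate([self.ids, np.arange(self._next_id, self._next_id + k)])
        self._next_id += k

    def remove(self, idx: np.ndarray) -> None:
        keep = np.ones(self.n, dtype=bool)
        keep[idx] = False
        self.x, self.y, self.z = self.x[keep], self.y[keep], self.z[keep]
        self.ids = self.ids[keep]

    def match_target(self, target: int) -> None:
        if self.n < target:
            self.spawn(target - self.n)
        elif self.n > target:
            drop = self.rng.choice(self.n, size=self.n - target, replace=False)
            self.remove(drop)

    def diffuse(self, step_px: float) -> None:
        if step_px <= 0 or self.n == 0:
            return
        self.x = self.x + self.rng.normal(0, step_px, self.n)
        self.y = self.y + self.rng.normal(0, step_px, self.n)
        # reflect at the extended-region edge: conserves the population and
        # keeps the equilibrium density uniform (an absorbing edge with
        # uniform respawn would deplete the margin and crowd the interior)
        lo, hi_x, hi_y = -self.o, self.w - self.o, self.h - self.o
        self.x = _reflect(self.x, lo, hi_x)
        self.y = _reflect(self.y, lo, hi_y)


def simulate_tirf_movie(
    config: SimulationConfig,
    geometry: AcquisitionGeometry | None = None,
) -> tuple[TIRFMovie, VesicleGroundTruth]:
    """Render a synthetic TIRF time-lapse with exported per-vesicle truth.

    Static vesicles hold a fixed (x, y, z); mobile vesicles perform lateral
    Brownian motion with the configured diffusion coefficient and may enter
    or leave the field.  Vesicle counts track the (time-dependent) target
    density over an extended region that includes a rendering margin, so
    the density inside the field of view is uniform.  A single uniform
    dither offset per movie removes the integer-rounding bias of the
    target count.

    Returns the movie and a :class:`VesicleGroundTruth` table covering
    every rendered vesicle in every frame.
    """
    geometry = geometry or AcquisitionGeometry()
    h, w = config.field_size
    px = geometry.pixel_size
    psf = geometry.psf_sigma
    d_nm = geometry.penetration_depth

    n_pre = int(round(config.duration_pre / geometry.frame_interval))
    n_post = int(round(config.duration_post / geometry.frame_interval))
    n_frames = n_pre + n_post
    if n_frames < 1:
        raise ValueError("movie must contain at least one frame")
    roi_side_px = 10.0 / px  # one 100 µm² ROI
    if h < roi_side_px or w < roi_side_px:
        raise ValueError(
            "field too small to contain a single 100 µm² region of interest")

    rng = np.random.default_rng(config.seed)

    margin = int(math.ceil(4 * psf)) + int(math.ceil(1.0 / px))
    ext_h, ext_w = h + 2 * margin, w + 2 * margin
    ext_area = ext_h * ext_w * px * px  # µm²

    static = _Population(rng, margin, ext_h, ext_w, config.vesicle_z_range, 0)
    mobile = _Population(rng, margin, ext_h, ext_w, config.vesicle_z_range, 10 ** 7)
    dither_s = rng.uniform()
    dither_m = rng.uniform()
    step_px = math.sqrt(2.0 * config.diffusion_coeff * geometry.frame_interval) / px

    background = _uneven_background((h, w), config.background_offset,
                                    config.background_amplitude, rng)

    frames = np.empty((n_frames, h, w), dtype=np.float64)
    rec_id, rec_cls, rec_frame = [], [], []
    rec_x, rec_y, rec_z, rec_amp = [], [], [], []

    for f in range(n_frames):
        t_rel = (f - n_pre) * geometry.frame_interval
        rho_s = _density_at(config, t_rel, config.static_density_pre,
                            config.static_density_post)
        rho_m = _density_at(config, t_rel, config.mobile_density_pre,
                            config.mobile_density_post)
        static.match_target(int(math.floor(rho_s * ext_area / 100.0 + dither_s)))
        mobile.diffuse(step_px)
        mobile.match_target(int(math.floor(rho_m * ext_area / 100.0 + dither_m)))

        frame = background.copy()
        for pop, cls in ((static, "static"), (mobile, "mobile")):
            if pop.n == 0:
                continue
            amps = config.vesicle_brightness * np.exp(-pop.z / d_nm)
            for i in range(pop.n):
                _render_spot(frame, pop.x[i], pop.y[i], amps[i], psf)
            rec_id.append(pop.ids.copy())
            rec_cls.append(np.full(pop.n, cls))
            rec_frame.append(np.full(pop.n, f))
            rec_x.append(pop.x.copy())
            rec_y.append(pop.y.copy())
            rec_z.append(pop.z.copy())
            rec_amp.append(amps)

        if config.shot_noise:
            frame = rng.poisson(np.maximum(frame, 0.0)).astype(np.float64)
        if config.read_noise_sd > 0:
            frame = frame + rng.normal(0, config.read_noise_sd, frame.shape)
        frames[f] = np.maximum(frame, 0.0)

    if rec_id:
        records = pd.DataFrame({
            "vesicle_id": np.concatenate(rec_id),
            "cls": np.concatenate(rec_cls),
            "frame": np.concatenate(rec_frame).astype(int),
            "x_px": np.concatenate(rec_x),
            "y_px": np.concatenate(rec_y),
            "z_nm": np.concatenate(rec_z),
            "amplitude": np.concatenate(rec_amp),
        })
    else:
        records = pd.DataFrame(
            {c: [] for c in VesicleGroundTruth.COLUMNS})
    movie = TIRFMovie(frames=frames, geometry=geometry, insulin_frame=n_pre)
    return movie, VesicleGroundTruth(records)


def simulate_bead_image(
    geometry: AcquisitionGeometry,
    bead_diameter: float = 10.0,
    brightness: float = 1000.0,
    noise_sd: float = 0.0,
    size: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render a large fluorescent bead resting on the coverslip.

    The bead surface height above the glass at lateral offset ``r`` from
    the contact point is ``z(r) = R - sqrt(R² - r²)`` (``R`` the bead
    radius), so the evanescent excitation maps radius onto an exponential
    intensity fall-off ``brightness * exp(-z(r)/d)``.  Pixels outside the
    bead contact disk are zero.
    """
    if bead_diameter <= 0:
        raise ValueError("bead_diameter must be positive")
    if bead_diameter < geometry.pixel_size:
        raise ValueError("bead_diameter smaller than one pixel")
    R = bead_diameter / 2.0  # µm
    if size is None:
        size = int(math.ceil(bead_diameter / geometry.pixel_size * 1.25))
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - c, yy - c) * geometry.pixel_size
    inside = r <= R
    z_nm = np.zeros_like(r)
    z_nm[inside] = (R - np.sqrt(np.maximum(R * R - r[inside] ** 2, 0.0))) * 1000.0
    img = np.where(inside,
                   brightness * np.exp(-z_nm / geometry.penetration_depth), 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.maximum(img + rng.normal(0, noise_sd, img.shape), 0.0)
    return img


@dataclass
class FieldImage:
    """One multi-channel field of view with its generating ground truth."""

    field_id: str
    channels: dict[str, np.ndarray]
    treatment: str
    stimulation: str
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channels must share one raster shape")


@dataclass
class FieldImageSet:
    """A collection of co-registered multi-channel fields."""

    fields: list[FieldImage]

    def __iter__(self):
        return iter(self.fields)

    def __len__(self) -> int:
        return len(self.fields)


def _cell_blobs(shape: tuple[int, int], n_cells: int, rng: np.random.Generator,
                amplitude: float, cv: float) -> tuple[np.ndarray, np.ndarray, list]:
    """Sum of cell-shaped Gaussian blobs; returns (image, nuclei image, centres)."""
    h, w = shape
    img = np.zeros(shape)
    nuc = np.zeros(shape)
    centres = []
    for _ in range(n_cells):
        cx, cy = rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h)
        s = rng.uniform(0.05, 0.09) * min(h, w)
        amp = amplitude * (max(0.0, 1.0 + cv * rng.standard_normal()) if cv > 0 else 1.0)
        _render_spot(img, cx, cy, amp, s)
        _render_spot(nuc, cx, cy, amp, 0.45 * s)
        centres.append((cx, cy))
    return img, nuc, centres


def simulate_translocation_fields(
    n_fields: int,
    surface_fraction_basal: float = 0.15,
    fold: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    treatment: str = "control",
    shape: tuple[int, int] = (96, 96),
    n_cells: int = 5,
    gfp_level: float = 100.0,
    dapi_level: float = 80.0,
    intensity_cv: float = 0.0,
    gfp_scale: float = 1.0,
) -> FieldImageSet:
    """Simulate basal and insulin-stimulated reporter fields.

    Each field contains cell-shaped blobs.  The GFP channel is
    proportional to total reporter; the surface (HA) channel is the GFP
    channel scaled by the surface-exposed fraction, which is multiplied by
    ``fold`` in the insulin-condition fields.  A DAPI channel marks
    nuclei.  ``gfp_scale`` rescales total reporter expression (emulating
    altered reporter levels).  The generating fractions are recorded in
    each field's ``truth``.
    """
    if fold < 0:
        raise ValueError("fold must be non-negative")
    if not 0 <= surface_fraction_basal <= 1:
        raise ValueError("surface_fraction_basal must lie in [0, 1]")
    if surface_fraction_basal * max(fold, 1.0) > 1:
        raise ValueError("infeasible fold: surface fraction would exceed 1")
    rng = np.random.default_rng(seed)
    out = []
    for stim in ("basal", "insulin"):
        sf = surface_fraction_basal * (fold if stim == "insulin" else 1.0)
        for i in range(n_fields):
            total, nuc, _ = _cell_blobs(shape, n_cells, rng, gfp_level, intensity_cv)
            gfp = gfp_scale * total
            ha = sf * gfp
            dapi = dapi_level / gfp_level * nuc
            chans = {"GFP": gfp, "HA": ha, "DAPI": dapi}
            if noise_sd > 0:
                chans = {k: np.maximum(v + rng.normal(0, noise_sd, v.shape), 0.0)
                         for k, v in chans.items()}
            out.append(FieldImage(
                field_id=f"{treatment}-{stim}-{i:02d}",
                channels=chans, treatment=treatment, stimulation=stim,
                truth={"surface_fraction": sf, "fold": fold,
                       "gfp_scale": gfp_scale}))
    return FieldImageSet(out)


def simulate_coloc_fields(
    n_fields: int,
    overlap_fraction: float,
    seed: int = 0,
    n_structures: int = 150,
    shape: tuple[int, int] = (192, 192),
    amplitude: float = 100.0,
    sigma: float = 2.0,
    noise_sd: float = 0.0,
    treatment: str = "control",
) -> FieldImageSet:
    """Simulate two-channel punctate fields with a configured overlap.

    A binomially drawn fraction of channel-1 puncta is co-placed exactly
    on channel-2 puncta; the remainder is placed disjointly (at least 8
    sigma from every channel-2 punctum, so truncated spots cannot touch).
    The realised co-placed fraction is recorded per field.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    m = 4 * sigma + 1
    out = []
    for i in range(n_fields):
        ch2_xy = np.column_stack([rng.uniform(m, w - m, n_structures),
                                  rng.uniform(m, h - m, n_structures)])
        k = rng.binomial(n_structures, overlap_fraction)
        co_idx = rng.choice(n_structures, size=k, replace=False)
        ch1_xy = [ch2_xy[j] for j in co_idx]
        placed = 0
        while placed < n_structures - k:
            cand = np.array([rng.uniform(m, w - m), rng.uniform(m, h - m)])
            if np.min(np.hypot(*(ch2_xy - cand).T)) >= 8 * sigma:
                ch1_xy.append(cand)
                placed += 1
        ch1 = np.zeros(shape)
        ch2 = np.zeros(shape)
        for x, y in ch1_xy:
            _render_spot(ch1, x, y, amplitude, sigma)
        for x, y in ch2_xy:
            _render_spot(ch2, x, y, amplitude, sigma)
        if noise_sd > 0:
            ch1 = np.maximum(ch1 + rng.normal(0, noise_sd, shape), 0.0)
            ch2 = np.maximum(ch2 + rng.normal(0, noise_sd, shape), 0.0)
        out.append(FieldImage(
            field_id=f"{treatment}-coloc-{i:02d}",
            channels={"GFP": ch1, "marker": ch2},
            treatment=treatment, stimulation="basal",
            truth={"overlap_fraction": overlap_fraction,
                   "realised_overlap": k / n_structures}))
    return FieldImageSet(out)
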