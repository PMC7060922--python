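"""Membrane-footprint fluorescence kinetics and evanescent-field calibration.

The fluorescence within the adherent footprint of a cell, measured in the
TIRF zone, reports the arrival of reporter-carrying vesicles at the
plasma membrane.  After normalising to the pre-insulin baseline, the
insulin response is summarised by a saturating-exponential rise

    R(t) = 1                                      for t < 0
    R(t) = 1 + (A - 1) * (1 - 2^(-t / t_half))    for t >= 0

parameterised directly by the plateau fold-increase ``A`` and the
half-time ``t_half`` (minutes): at ``t = t_half`` the signal has covered
half of the total increase.

The penetration depth of the evanescent field is calibrated from an
image of a large (e.g. 10 µm) fluorescent bead: the spherical surface
converts lateral offset ``r`` into height ``z(r) = R - sqrt(R² - r²)``,
so log-intensity is linear in ``z`` with slope ``-1/d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .geometry import AcquisitionGeometry
from .simulate import TIRFMovie

__all__ = [
    "FootprintMask",
    "TranslocationFit",
    "footprint_mask",
    "intensity_series",
    "translocation_model",
    "fit_translocation",
    "estimate_penetration_depth",
    "TranslocationKinetics",
    "PenetrationDepthEstimator",
]


@dataclass
class FootprintMask:
    """Binary mask of a cell footprint with its physical area."""

    mask: np.ndarray
    area_um2: float
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area_um2 <= 0:
            raise ValueError("mask area must be positive")


@dataclass
class TranslocationFit:
    """Result of fitting the saturating-rise model.

    ``fold`` is the fitted plateau A; ``t_half`` the half-time in
    minutes; ``final_value`` the mean of the last three normalised
    timepoints (an alternative, model-free magnitude readout).
    ``converged`` is False when the optimiser failed or the response is
    flat, in which case ``t_half`` is NaN.
    """

    times: np.ndarray
    normalized_intensity: np.ndarray
    fold: float
    t_half: float
    rss: float
    final_value: float
    converged: bool


def footprint_mask(reference: np.ndarray, pixel_size: float = 0.1) -> FootprintMask:
    """Segment the cell footprint from a reference image.

    Otsu global threshold, hole filling, then the largest connected
    component.  The reference is typically the temporal mean of the
    pre-insulin frames.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 2:
        raise ValueError("footprint_mask expects a 2-D raster")
    if reference.max() <= 0 or np.ptp(reference) < 1e-12:
        raise ValueError("blank or constant reference: no footprint found")
    thr = float(threshold_otsu(reference))
    fg = reference > thr
    if not fg.any():
        raise ValueError("no foreground above the Otsu threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep
    area = float(mask.sum()) * pixel_size ** 2
    return FootprintMask(mask=mask, area_um2=area, threshold=thr)


def intensity_series(
    movie: TIRFMovie,
    mask: FootprintMask | np.ndarray | None = None,
    frames_per_timepoint: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean in-mask intensity per timepoint.

    Timepoints are consecutive groups of ``frames_per_timepoint`` frames
    (a trailing partial group is dropped); the value is the mean over
    the group's frames and the mask pixels; times are group midpoints in
    minutes relative to the insulin frame.
    """
    if mask is None:
        m = np.ones(movie.shape, dtype=bool)
    elif isinstance(mask, FootprintMask):
        m = mask.mask
    else:
        m = np.asarray(mask, dtype=bool)
    if m.shape != movie.shape:
        raise ValueError("mask shape does not match movie frames")
    if frames_per_timepoint < 1:
        raise ValueError("frames_per_timepoint must be >= 1")
    n_groups = movie.n_frames // frames_per_timepoint
    if n_groups < 1:
        raise ValueError("movie shorter than one timepoint group")
    vals = np.empty(n_groups)
    times = np.empty(n_groups)
    for g in range(n_groups):
        a = g * frames_per_timepoint
        z = a + frames_per_timepoint
        vals[g] = movie.frames[a:z][:, m].mean()
        times[g] = ((a + z - 1) / 2.0 - movie.insulin_frame) \
            * movie.geometry.frame_interval / 60.0
    return times, vals


def translocation_model(t: np.ndarray, fold: float, t_half: float) -> np.ndarray:
    """Normalised response: flat 1 before insulin, saturating rise after."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    post = t >= 0
    out[post] = 1.0 + (fold - 1.0) * (1.0 - 2.0 ** (-t[post] / t_half))
    return out


def fit_translocation(
    times: np.ndarray,
    series: np.ndarray,
    insulin_time: float = 0.0,
) -> TranslocationFit:
    """Fit the saturating-rise model to a fluorescence time course.

    The series is first normalised to its pre-insulin mean (so the
    result is invariant to overall intensity scale); the model is then
    fitted by least squares over all timepoints.  Requires at least 3
    pre-insulin and 5 post-insulin timepoints.
    """
    times = np.asarray(times, dtype=float) - insulin_time
    series = np.asarray(series, dtype=float)
    if times.shape != series.shape or times.ndim != 1:
        raise ValueError("times and series must be matching 1-D arrays")
    pre = times < 0
    post = ~pre
    if pre.sum() < 3 or post.sum() < 5:
        raise ValueError("need >= 3 pre-insulin and >= 5 post-insulin points")
    baseline = series[pre].mean()
    if baseline <= 0:
        raise ValueError("non-positive pre-insulin baseline")
    norm = series / baseline

    final_value = float(norm[-3:].mean())
    if np.allclose(norm, 1.0, atol=1e-12):
        # flat response: no kinetic information
        return TranslocationFit(times=times, normalized_intensity=norm,
                                fold=1.0, t_half=float("nan"), rss=0.0,
                                final_value=final_value, converged=False)
    span = float(times[post].max())
    a0 = max(final_value, 1.0 + 1e-6)
    guesses = [(a0, span / 3.0), (a0 * 1.5, span), (a0, span / 10.0)]

    # the plateau is unidentifiable when t_half is far beyond the
    # observation window; bound both parameters to the identifiable range
    upper_a = max(10.0 * max(float(norm.max()), 1.0), 2.0)
    upper_th = 2.0 * span
    best = None
    for a_init, th_init in guesses:
        try:
            popt, _ = optimize.curve_fit(
                translocation_model, times, norm,
                p0=[a_init, min(th_init, upper_th)],
                bounds=([0.0, 1e-6], [upper_a, upper_th]), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((translocation_model(times, *popt) - norm) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return TranslocationFit(times=times, normalized_intensity=norm,
                                fold=float("nan"), t_half=float("nan"),
                                rss=float("nan"), final_value=final_value,
                                converged=False)
    (fold, t_half), rss = best
    if abs(fold - 1.0) < 1e-9:
        # fitted response is flat: half-time undefined
        return TranslocationFit(times=times, normalized_intensity=norm,
                                fold=1.0, t_half=float("nan"), rss=rss,
                                final_value=final_value, converged=False)
    return TranslocationFit(times=times, normalized_intensity=norm,
                            fold=float(fold), t_half=float(t_half),
                            rss=rss, final_value=final_value, converged=True)


def estimate_penetration_depth(
    bead_image: np.ndarray,
    bead_diameter: float,
    geometry: AcquisitionGeometry,
    initial_depth_nm: float = 150.0,
    n_iter: int = 3,
) -> float:
    """Estimate the evanescent penetration depth from a bead image (nm).

    The bead contact point is the centroid of the brightest decile of
    pixels.  Pixel radii are converted to surface heights
    ``z(r) = R - sqrt(R² - r²)``; mean log-intensity is collected in
    1-pixel annuli and fitted linearly against mean height over the
    range ``z <= 3 x`` the current depth estimate (iterated a few times
    from ``initial_depth_nm``); the depth is ``-1/slope``.
    """
    img = np.asarray(bead_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("bead image must be 2-D")
    if img.max() <= 0:
        raise ValueError("blank bead image")
    R_um = bead_diameter / 2.0
    bright = img >= np.quantile(img[img > 0], 0.90)
    ys, xs = np.nonzero(bright)
    weights = img[ys, xs]
    cy = float(np.average(ys, weights=weights))
    cx = float(np.average(xs, weights=weights))

    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    r_um = np.hypot(xx - cx, yy - cy) * geometry.pixel_size
    inside = (r_um < R_um) & (img > 0)
    z_nm = (R_um - np.sqrt(np.maximum(R_um ** 2 - r_um ** 2, 0.0))) * 1000.0

    # 1-px annulus means of height and log-intensity
    ann = np.floor(np.hypot(xx - cx, yy - cy)).astype(int)
    depth = float(initial_depth_nm)
    for _ in range(n_iter):
        sel = inside & (z_nm <= 3.0 * depth)
        if sel.sum() < 10:
            raise ValueError("too few pixels within the fitting range")
        idx = ann[sel]
        zs = np.bincount(idx, weights=z_nm[sel]) / np.maximum(np.bincount(idx), 1)
        ls = np.bincount(idx, weights=np.log(img[sel])) / np.maximum(np.bincount(idx), 1)
        counts = np.bincount(idx)
        ok = counts > 0
        if ok.sum() < 3:
            raise ValueError("too few annuli within the fitting range")
        slope, _ = np.polyfit(zs[ok], ls[ok], 1)
        if slope >= 0 or np.ptp(ls[ok]) < 1e-9:
            raise ValueError("not evanescent: intensity does not decay with height")
        depth = -1.0 / slope
    return float(depth)


class TranslocationKinetics(BaseEstimator):
    """scikit-learn style estimator for the translocation time course.

    ``fit(times, series)`` normalises the series to its pre-insulin
    baseline and fits the saturating-rise model; fitted attributes are
    ``fold_``, ``t_half_``, ``rss_``, ``final_value_`` and the full
    ``result_``.  ``predict(times)`` evaluates the fitted curve.
    """

    def __init__(self, insulin_time: float = 0.0):
        self.insulin_time = insulin_time

    def fit(self, X, y) -> "TranslocationKinetics":
        res = fit_translocation(np.asarray(X).ravel(), np.asarray(y).ravel(),
                                insulin_time=self.insulin_time)
        self.result_ = res
        self.fold_ = res.fold
        self.t_half_ = res.t_half
        self.rss_ = res.rss
        self.final_value_ = res.final_value
        self.converged_ = res.converged
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).ravel() - self.insulin_time
        if not self.converged_:
            return np.ones_like(t)
        return translocation_model(t, self.fold_, self.t_half_)


class PenetrationDepthEstimator(BaseEstimator):
    """scikit-learn style estimator for evanescent-depth calibration.

    ``fit(bead_image)`` exposes the estimate as ``depth_nm_``.
    """

    def __init__(self, bead_diameter: float = 10.0,
                 geometry: AcquisitionGeometry | None = None,
                 initial_depth_nm: float = 150.0):
        self.bead_diameter = bead_diameter
        self.geometry = geometry
        self.initial_depth_nm = initial_depth_nm

    def fit(self, X, y=None) -> "PenetrationDepthEstimator":
        geom = self.geometry or AcquisitionGeometry()
        self.depth_nm_ = estimate_penetration_depth(
            X, self.bead_diameter, geom, self.initial_depth_nm)
        return self
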