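"""Image conditioning chain: rolling-ball background subtraction,
despeckle (median) filtering, and local-outlier removal.

The chain reproduces the classic ImageJ sequence used on TIRF stacks:
an uneven diffuse background is estimated by rolling a ball under the
intensity surface (grayscale opening with a ball-cap structuring
element) and subtracted; shot noise is then suppressed with a 3x3
median; isolated hot pixels are replaced by their local median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import TIRFMovie

__all__ = [
    "PreprocessParams",
    "rolling_ball",
    "despeckle",
    "remove_outliers",
    "preprocess_stack",
    "StackPreprocessor",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the conditioning chain.

    ``smooth_window`` applies a mean presmoothing to the copy of the
    image used for background estimation only (ImageJ's Subtract
    Background does the same by default); the estimated background is
    subtracted from the *unsmoothed* image.  Set 0 to disable.
    """

    ball_radius: int = 10
    despeckle_window: int = 3
    outlier_radius: int = 2
    outlier_threshold: float = 10.0
    smooth_window: int = 3

    def __post_init__(self) -> None:
        if self.ball_radius < 1:
            raise ValueError("ball_radius must be >= 1")
        if self.despeckle_window < 3 or self.despeckle_window % 2 == 0:
            raise ValueError("despeckle_window must be odd and >= 3")
        if self.outlier_radius < 1:
            raise ValueError("outlier_radius must be >= 1")
        if self.outlier_threshold < 0:
            raise ValueError("outlier_threshold must be >= 0")


def _ball_structure(radius: int) -> np.ndarray:
    """Ball-cap heights over a disk footprint; -inf outside the disk."""
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = xx ** 2 + yy ** 2
    ball = np.where(d2 <= r * r, np.sqrt(np.maximum(r * r - d2, 0.0)), -np.inf)
    return ball


def _disk_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return xx ** 2 + yy ** 2 <= r * r


def rolling_ball(image: np.ndarray, ball_radius: int = 10,
                 smooth_window: int = 0) -> np.ndarray:
    """Subtract the rolling-ball background from a 2-D image.

    The background is the grayscale opening of the image by a ball of
    the given radius (erosion then dilation with the ball-cap heights).
    With ``smooth_window > 0`` the background is estimated on a
    mean-filtered copy (noise robustness) and capped at the original
    image so the result stays non-negative.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("rolling_ball expects a 2-D raster")
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1")
    ball = _ball_structure(ball_radius)
    target = image
    if smooth_window and smooth_window > 1:
        target = ndimage.uniform_filter(image, size=smooth_window, mode="reflect")
    background = ndimage.grey_opening(target, structure=ball, mode="reflect")
    background = np.minimum(background, image)
    return image - background


def despeckle(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median-filter the image (reflective padding at the edges)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("despeckle expects a 2-D raster")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    return ndimage.median_filter(image, size=window, mode="reflect")


def remove_outliers(image: np.ndarray, radius: int = 2,
                    threshold: float = 10.0) -> np.ndarray:
    """Replace pixels deviating from their local disk median by that median.

    A pixel is an outlier when ``|value - median|`` over the disk
    neighbourhood of the given radius exceeds ``threshold``; all other
    pixels are untouched.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("remove_outliers expects a 2-D raster")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    med = ndimage.median_filter(image, footprint=_disk_footprint(radius),
                                mode="reflect")
    out = image.copy()
    mask = np.abs(image - med) > threshold
    out[mask] = med[mask]
    return out


def preprocess_stack(movie: TIRFMovie, params: PreprocessParams | None = None) -> TIRFMovie:
    """Apply rolling-ball, despeckle and outlier removal to every frame.

    Geometry and insulin frame index are preserved.
    """
    params = params or PreprocessParams()
    out = np.empty_like(movie.frames)
    for i, frame in enumerate(movie.frames):
        clean = rolling_ball(frame, params.ball_radius, params.smooth_window)
        clean = despeckle(clean, params.despeckle_window)
        clean = remove_outliers(clean, params.outlier_radius,
                                params.outlier_threshold)
        out[i] = clean
    return TIRFMovie(frames=out, geometry=movie.geometry,
                     insulin_frame=movie.insulin_frame)


class StackPreprocessor(TransformerMixin, BaseEstimator):
    """scikit-learn style transformer wrapping :func:`preprocess_stack`.

    ``transform`` accepts a :class:`TIRFMovie` or a T x H x W array and
    returns the same type.  Stateless: ``fit`` only validates parameters.
    """

    def __init__(self, ball_radius: int = 10, despeckle_window: int = 3,
                 outlier_radius: int = 2, outlier_threshold: float = 10.0,
                 smooth_window: int = 3):
        self.ball_radius = ball_radius
        self.despeckle_window = despeckle_window
        self.outlier_radius = outlier_radius
        self.outlier_threshold = outlier_threshold
        self.smooth_window = smooth_window

    def _params(self) -> PreprocessParams:
        return PreprocessParams(
            ball_radius=self.ball_radius,
            despeckle_window=self.despeckle_window,
            outlier_radius=self.outlier_radius,
            outlier_threshold=self.outlier_threshold,
            smooth_window=self.smooth_window,
        )

    def fit(self, X=None, y=None) -> "StackPreprocessor":
        self._params()  # validates
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        params = self._params()
        if isinstance(X, TIRFMovie):
            return preprocess_stack(X, params)
        frames = np.asarray(X, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        out = np.empty_like(frames)
        for i, frame in enumerate(frames):
            clean = rolling_ball(frame, params.ball_radius, params.smooth_window)
            clean = despeckle(clean, params.despeckle_window)
            out[i] = remove_outliers(clean, params.outlier_radius,
                                     params.outlier_threshold)
        return out
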