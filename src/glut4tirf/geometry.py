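"""Acquisition geometry of an objective-type TIRF microscope.

The evanescent excitation field decays exponentially with height ``z``
above the coverslip, ``I(z) = I0 * exp(-z / d)``, where ``d`` is the
penetration depth.  Everything downstream (simulation, bead calibration,
vesicle rendering) shares this geometry object.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical acquisition parameters of a TIRF movie.

    Parameters
    ----------
    pixel_size : float
        Lateral sampling, micrometres per pixel.  The default 0.1 µm/px
        corresponds to an EMCCD with 16 µm pixels behind a 100x/1.45 NA
        objective with a 1.6x expansion lens.
    frame_interval : float
        Seconds between consecutive frames (default 0.5 s, i.e. 2 Hz).
    exposure : float
        Integration time per frame, seconds.
    penetration_depth : float
        Evanescent-field decay length ``d`` in nanometres.
    psf_sigma : float
        Gaussian sigma of a rendered diffraction-limited spot, in pixels.
        Vesicles are extended objects, so the effective spot width is the
        convolution of vesicle size and optical PSF; 2 px (~200 nm) is a
        realistic effective width.
    """

    pixel_size: float = 0.1
    frame_interval: float = 0.5
    exposure: float = 0.5
    penetration_depth: float = 110.0
    psf_sigma: float = 2.0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "exposure",
                     "penetration_depth", "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.frame_interval < self.exposure:
            raise ValueError("frame_interval must be >= exposure")

    @property
    def frame_rate(self) -> float:
        """Frames per second."""
        return 1.0 / self.frame_interval
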