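"""Reading and writing movies and results in standard formats.

Movies travel as ImageJ-compatible multi-page grayscale TIFF with a
sidecar JSON holding the acquisition geometry, the insulin-addition
frame index and the seed; ground truth as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import AcquisitionGeometry
from .simulate import TIRFMovie, VesicleGroundTruth


def sidecar_path(tiff_path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + ".json")


def write_movie(path, movie: TIRFMovie, seed: int | None = None,
                extra: dict | None = None) -> None:
    """Write a movie as multi-page TIFF plus a metadata sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), imagej=True,
                     metadata={"axes": "TYX"})
    meta = {
        "geometry": dataclasses.asdict(movie.geometry),
        "insulin_frame": int(movie.insulin_frame),
        "seed": seed,
    }
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_movie(path) -> TIRFMovie:
    """Read a movie written by :func:`write_movie` (sidecar required)."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"metadata sidecar {side} not found; frame interval and "
            "insulin frame are required")
    meta = json.loads(side.read_text())
    geometry = AcquisitionGeometry(**meta["geometry"])
    return TIRFMovie(frames=frames, geometry=geometry,
                     insulin_frame=int(meta["insulin_frame"]))


def write_ground_truth(path, truth: VesicleGroundTruth) -> None:
    truth.to_csv(path)


def read_ground_truth(path) -> VesicleGroundTruth:
    return VesicleGroundTruth.from_csv(path)
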