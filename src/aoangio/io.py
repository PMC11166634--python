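"""TIFF and sidecar I/O for frame sequences, masks, and transforms.

Frame sequences are stored as multi-page float32 TIFF (one page per
frame, page order = frame order) with a YAML sidecar carrying the pixel
pitch and provenance (seeds, motion parameters).  Binary masks are
single-page 8-bit TIFF.  B-spline transforms serialize to a YAML file
holding the grid spacing and the displacement lattice, so registrations
are replayable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile
import yaml

from .phantom import FrameSequence
from .registration import BsplineTransform

PathLike = Union[str, Path]


def _sidecar(path: PathLike) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".yaml")


def write_frames(path: PathLike, seq: FrameSequence,
                 metadata: Optional[dict] = None) -> None:
    tifffile.imwrite(str(path), seq.frames.astype(np.float32))
    meta = {"pixel_pitch_um": float(seq.pixel_pitch_um),
            "n_frames": int(seq.n_frames),
            "registered": bool(seq.registered)}
    if metadata:
        meta.update(metadata)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    if seq.validity_mask is not None:
        write_mask(Path(path).with_name(Path(path).stem + "_validity.tif"),
                   seq.validity_mask)


def read_frames(path: PathLike) -> FrameSequence:
    frames = np.asarray(tifffile.imread(str(path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    side = _sidecar(path)
    pitch = 1.5
    registered = False
    if side.exists():
        with open(side) as fh:
            meta = yaml.safe_load(fh) or {}
        pitch = float(meta.get("pixel_pitch_um", pitch))
        registered = bool(meta.get("registered", False))
    validity = None
    vpath = Path(path).with_name(Path(path).stem + "_validity.tif")
    if vpath.exists():
        validity = read_mask(vpath)
    return FrameSequence(frames=frames, pixel_pitch_um=pitch,
                         validity_mask=validity, registered=registered)


def write_image(path: PathLike, image: np.ndarray,
                metadata: Optional[dict] = None) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
    if metadata:
        with open(_sidecar(path), "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=True)


def read_image(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_mask(path: PathLike, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path))) > 0


def write_transform(path: PathLike, t: BsplineTransform) -> None:
    doc = {"grid_spacing_um": float(t.grid_spacing_um),
           "pixel_pitch_um": float(t.pixel_pitch_um),
           "shape": [int(s) for s in t.shape],
           "grid_dx_um": t.grid_dx_um.tolist(),
           "grid_dy_um": t.grid_dy_um.tolist()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_transform(path: PathLike) -> BsplineTransform:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return BsplineTransform(
        grid_dx_um=np.asarray(doc["grid_dx_um"], dtype=float),
        grid_dy_um=np.asarray(doc["grid_dy_um"], dtype=float),
        grid_spacing_um=float(doc["grid_spacing_um"]),
        pixel_pitch_um=float(doc["pixel_pitch_um"]),
        shape=tuple(doc["shape"]))
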