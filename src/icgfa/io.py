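"""File formats: scene videos (multi-page TIFF), annotations (JSON),
reports (CSV/JSON).

TIFF is used for video because it is lossless and trivially inspectable;
annotations use pixel coordinates (0-based, x right / y down) and half-open
grid-module intervals, matching the in-memory conventions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import FramePairSequence, GroundTruthAnnotation

__all__ = ["write_scene", "read_scene", "write_annotation",
           "read_annotation"]


def write_scene(seq: FramePairSequence, directory) -> None:
    """Write white/NIR (or display) stacks as multi-page TIFFs plus a JSON
    sidecar with times, mode and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "white.tif",
                     np.asarray(seq.white, dtype=np.uint8))
    if seq.nir is not None:
        tifffile.imwrite(directory / "nir.tif",
                         np.clip(seq.nir, 0, 255).astype(np.uint8))
    if seq.display is not None:
        tifffile.imwrite(directory / "display.tif",
                         np.clip(seq.display, 0, 255).astype(np.uint8))
    meta = {"times": [float(t) for t in seq.times], "mode": seq.mode,
            "seed": seq.meta.get("seed"),
            "perfusion": seq.meta.get("perfusion")}
    with open(directory / "scene.json", "w") as fh:
        json.dump(meta, fh)


def read_scene(directory) -> FramePairSequence:
    directory = Path(directory)
    with open(directory / "scene.json") as fh:
        meta = json.load(fh)
    white = tifffile.imread(directory / "white.tif")
    nir = display = None
    if (directory / "nir.tif").exists():
        nir = tifffile.imread(directory / "nir.tif")
    if (directory / "display.tif").exists():
        display = tifffile.imread(directory / "display.tif")
    return FramePairSequence(white=white, nir=nir, display=display,
                             times=np.array(meta["times"]),
                             mode=meta["mode"],
                             meta={"seed": meta.get("seed"),
                                   "perfusion": meta.get("perfusion")})


def write_annotation(annotation: GroundTruthAnnotation, path) -> None:
    data = {
        "line": [[float(x), float(y)] for x, y in annotation.line],
        "labels": [int(v) for v in annotation.labels],
        "stapler_center": annotation.stapler_center,
        "stapler_band": None if annotation.stapler_band is None
        else list(annotation.stapler_band),
        "boundary_col": annotation.boundary_col,
        "line_cols": None if annotation.line_cols is None
        else [int(c) for c in annotation.line_cols],
        "expert_id": annotation.expert_id,
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_annotation(path) -> GroundTruthAnnotation:
    with open(path) as fh:
        data = json.load(fh)
    return GroundTruthAnnotation(
        line=np.array(data["line"], dtype=float),
        labels=np.array(data["labels"], dtype=np.int64),
        stapler_center=data["stapler_center"],
        stapler_band=None if data["stapler_band"] is None
        else tuple(data["stapler_band"]),
        boundary_col=data.get("boundary_col"),
        line_cols=None if data.get("line_cols") is None
        else np.array(data["line_cols"], dtype=np.int64),
        expert_id=data.get("expert_id", 0))
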