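"""Plain-text and TIFF I/O for recordings and calcium movies.

Recordings travel as tab-separated columnar tables (``time_s`` plus one
column per channel role) with a YAML sidecar carrying the sampling rate and
event annotations.  Movies travel as multi-page 16-bit TIFF stacks with a
JSON sidecar carrying the frame rate, landmarks and the intensity scale used
on write.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ROLES, CalciumMovie, Recording

PathLike = Union[str, Path]


def write_recording(rec: Recording, tsv_path: PathLike,
                    meta_path: Optional[PathLike] = None) -> None:
    tsv_path = Path(tsv_path)
    cols = {"time_s": rec.time}
    for role in ROLES:
        if role in rec.channels:
            cols[role] = rec.channels[role]
    pd.DataFrame(cols).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    meta = {"fs_hz": float(rec.fs),
            "annotations": {k: float(v) for k, v in rec.annotations.items()}}
    meta_path = tsv_path.with_suffix(".yaml") if meta_path is None else Path(meta_path)
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_recording(tsv_path: PathLike, meta_path: Optional[PathLike] = None,
                   ) -> Recording:
    tsv_path = Path(tsv_path)
    meta_path = tsv_path.with_suffix(".yaml") if meta_path is None else Path(meta_path)
    meta = yaml.safe_load(meta_path.read_text())
    df = pd.read_csv(tsv_path, sep="\t")
    channels = {role: df[role].to_numpy() for role in ROLES if role in df.columns}
    return Recording(fs=float(meta["fs_hz"]), channels=channels,
                     annotations=dict(meta.get("annotations", {})))


def write_movie(movie: CalciumMovie, tif_path: PathLike,
                sidecar_path: Optional[PathLike] = None) -> None:
    """Write frames as 16-bit TIFF pages; the scale used to fit the dynamic
    range is recorded in the JSON sidecar so reads invert it."""
    tif_path = Path(tif_path)
    frames = np.asarray(movie.frames, dtype=float)
    lo = float(frames.min())
    hi = float(frames.max())
    scale = (65535.0 / (hi - lo)) if hi > lo else 1.0
    data = np.round((frames - lo) * scale).astype(np.uint16)
    tifffile.imwrite(tif_path, data, photometric="minisblack")
    sidecar = {
        "fs_hz": float(movie.fs),
        "normalized": bool(movie.normalized),
        "landmarks": {k: float(v) for k, v in movie.landmarks.items()},
        "intensity_offset": lo,
        "intensity_scale": scale,
    }
    sidecar_path = tif_path.with_suffix(".json") if sidecar_path is None else Path(sidecar_path)
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_movie(tif_path: PathLike, sidecar_path: Optional[PathLike] = None,
               ) -> CalciumMovie:
    tif_path = Path(tif_path)
    sidecar_path = tif_path.with_suffix(".json") if sidecar_path is None else Path(sidecar_path)
    sidecar = json.loads(Path(sidecar_path).read_text())
    data = tifffile.imread(tif_path).astype(np.float32)
    frames = data / sidecar["intensity_scale"] + sidecar["intensity_offset"]
    return CalciumMovie(frames=frames, fs=float(sidecar["fs_hz"]),
                        landmarks=dict(sidecar["landmarks"]),
                        normalized=bool(sidecar["normalized"]))
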