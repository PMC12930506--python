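"""Reading and writing the package's on-disk formats.

Mimic-record tables are plain CSV (``mimic_id, x_mm, y_mm, diameter_um,
label, load, t0, t15, ...``); image stacks are multi-page TIFF, one file
per channel, with a JSON metadata sidecar carrying the seed, pixel size and
config hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_records",
    "read_records",
    "write_image_stacks",
    "read_image_stacks",
]


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_image_stacks(
    channels: dict,
    directory: str | Path,
    pixel_size_um: float,
    metadata: dict | None = None,
    prefix: str = "sample",
) -> dict:
    """Write one multi-page TIFF per channel plus a JSON sidecar.

    Returns a mapping of channel name to file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, stack in channels.items():
        arr = np.asarray(stack)
        if arr.ndim == 2:
            arr = arr[None]
        p = directory / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32))
        paths[name] = p
    sidecar = {"pixel_size_um": pixel_size_um, "channels": {k: str(v.name) for k, v in paths.items()}}
    sidecar.update(metadata or {})
    (directory / f"{prefix}_meta.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths


def read_image_stacks(directory: str | Path, prefix: str = "sample"):
    """Read the stacks and sidecar written by :func:`write_image_stacks`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{prefix}_meta.json").read_text())
    channels = {
        name: tifffile.imread(directory / fname)
        for name, fname in meta["channels"].items()
    }
    return channels, meta
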