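"""Readers and writers for the pipeline's interchange formats.

Cell tables are CSV with ``object_id, centroid_x_um, centroid_y_um`` and
``{marker}_{compartment}_mean`` columns (QuPath-export dialect); layer
boundaries are a two-column CSV of (boundary_name, depth_um); images are
multichannel TIFF with channel names in the metadata; manifests are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import BOUNDARY_NAMES, LayerModel, boundary_table


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"object_id", "centroid_x_um", "centroid_y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table {path} lacks columns: {sorted(missing)}")
    return df


def write_layer_boundaries(model: LayerModel, path) -> None:
    pd.DataFrame(
        boundary_table(model), columns=["boundary_name", "depth_um"]
    ).to_csv(path, index=False)


def read_layer_boundaries(
    path, roi_width: float = 400.0, wm_sample_depth: float = 100.0, **kwargs
) -> LayerModel:
    df = pd.read_csv(path)
    depths = dict(zip(df["boundary_name"], df["depth_um"]))
    try:
        boundaries = tuple(float(depths[n]) for n in BOUNDARY_NAMES)
    except KeyError as e:
        raise ValueError(f"layer-boundary file {path} lacks boundary {e}") from e
    return LayerModel(
        boundaries, wm_sample_depth=wm_sample_depth, roi_width=roi_width, **kwargs
    )


def write_image(image: dict[str, np.ndarray], path, pixel_size: float) -> None:
    """Multichannel TIFF, one page per channel, names in ImageJ metadata."""
    names = list(image)
    stack = np.stack([image[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        metadata={
            "axes": "CYX",
            "Labels": names,
            "pixel_size_um": pixel_size,
        },
    )


def read_image(path) -> tuple[dict[str, np.ndarray], float]:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    names = meta.get("Labels") or [f"ch{i}" for i in range(stack.shape[0])]
    px = float(meta.get("pixel_size_um", 1.0))
    return {n: stack[i] for i, n in enumerate(names)}, px


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
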