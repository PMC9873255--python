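"""File I/O: multi-page TIFF sections with channel-role descriptors,
ground-truth JSON sidecars, and cohort CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError
from .sections import GroundTruth
from .segmentation import SectionImage

__all__ = [
    "write_section",
    "read_section",
    "write_ground_truth",
    "write_cohort",
    "read_cohort",
]


def write_section(image: SectionImage, path: str | Path) -> Path:
    """Write a section as multi-page TIFF plus a JSON channel descriptor.

    The descriptor ``<stem>.channels.json`` records page order
    (channel roles) and the pixel size in um/px.
    """
    path = Path(path)
    roles = list(image.channels)
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(path, stack)
    descriptor = {"channels": roles, "pixel_size_um": image.pixel_size}
    path.with_suffix(".channels.json").write_text(json.dumps(descriptor, indent=2))
    return path


def read_section(path: str | Path, descriptor: str | Path | None = None) -> SectionImage:
    """Read a multi-page TIFF with its channel-role descriptor (JSON or YAML)."""
    path = Path(path)
    if descriptor is None:
        descriptor = path.with_suffix(".channels.json")
    descriptor = Path(descriptor)
    if not descriptor.exists():
        raise ConfigurationError(f"channel descriptor not found: {descriptor}")
    text = descriptor.read_text()
    meta = json.loads(text) if descriptor.suffix == ".json" else yaml.safe_load(text)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    roles = meta["channels"]
    if len(roles) != stack.shape[0]:
        raise ConfigurationError(
            f"descriptor lists {len(roles)} channels, TIFF has {stack.shape[0]} pages"
        )
    channels = {role: stack[i].astype(np.float64) for i, role in enumerate(roles)}
    return SectionImage(channels=channels, pixel_size=float(meta["pixel_size_um"]))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write the ground truth as a JSON sidecar (polygons as vertex lists)."""
    path = Path(path)
    payload = {
        "pixel_size_um": truth.pixel_size,
        "n_fibers": truth.n_fibers,
        "areas_um2": truth.areas_um2.tolist(),
        "types": truth.types,
        "central_nucleus": truth.central_nucleus.tolist(),
        "puncta": truth.puncta.tolist(),
        "polygons_xy": [
            np.asarray(p.exterior.coords).tolist() for p in truth.polygons
        ],
        "nucleus_centroids": [
            {"row": r, "col": c, "kind": k} for r, c, k in truth.nucleus_centroids
        ],
        "cell_centroids": [
            {"row": r, "col": c, "compartment": k} for r, c, k in truth.cell_centroids
        ],
        "red_fraction_of_tissue": float(
            truth.red_mask.sum() / truth.tissue_mask.sum()
        ),
    }
    path.write_text(json.dumps(payload))
    return path


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
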