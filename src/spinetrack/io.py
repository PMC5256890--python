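"""Disk formats: multi-page TIFF stacks, benchmark manifests, ROI JSON.

Stacks are 16-bit grayscale multi-page TIFFs; a benchmark dataset on
disk is a directory of stacks plus a CSV manifest with one row per
stack (filename, annotated target slice, optional ROI). Session plans
round-trip through JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import RectROI, ZStack
from .quantify import QuantROI
from .timeline import SessionPlan

__all__ = [
    "read_stack",
    "write_stack",
    "read_manifest",
    "write_manifest",
    "read_rois",
    "write_rois",
    "load_plan",
    "save_plan",
]

MANIFEST_COLUMNS = ["filename", "target_slice_index",
                    "roi_row0", "roi_col0", "roi_height", "roi_width"]


def write_stack(path, stack: ZStack, scale_to_uint16: bool = True) -> None:
    """Write a stack as a multi-page TIFF (16-bit by default).

    Z spacing is stored in the image description so the stack
    round-trips with its axial geometry.
    """
    data = stack.slices
    if scale_to_uint16:
        peak = data.max()
        scale = 65535.0 / peak if peak > 0 else 1.0
        data = np.round(data * scale).astype(np.uint16)
    meta = {"z_start_um": float(stack.z_positions[0]),
            "z_step_um": stack.step_um}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_stack(path) -> ZStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Falls back to unit Z spacing when no geometry metadata is present.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        desc = tf.pages[0].description or ""
    if data.ndim == 2:
        data = data[None]
    z0, dz = 0.0, 1.0
    try:
        meta = json.loads(desc)
        z0 = float(meta["z_start_um"])
        dz = float(meta["z_step_um"])
    except (json.JSONDecodeError, KeyError, TypeError):
        pass
    z = z0 + np.arange(data.shape[0]) * dz
    return ZStack(slices=data, z_positions=z)


def write_manifest(path, entries) -> None:
    """Write a benchmark manifest CSV.

    ``entries`` is a sequence of (filename, target_index, roi-or-None).
    """
    rows = []
    for fname, target, roi in entries:
        if roi is None:
            rows.append((fname, target, "", "", "", ""))
        else:
            rows.append((fname, target, roi.row0, roi.col0,
                         roi.height, roi.width))
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path):
    """Load a manifest CSV and its stacks as (ZStack, target, roi) triples."""
    base = Path(path).parent
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    dataset = []
    for _, row in df.iterrows():
        stack = read_stack(base / str(row["filename"]))
        roi = None
        if "roi_row0" in df.columns and not pd.isna(row["roi_row0"]) \
                and str(row["roi_row0"]) != "":
            roi = RectROI(int(row["roi_row0"]), int(row["roi_col0"]),
                          int(row["roi_height"]), int(row["roi_width"]))
        dataset.append((stack, int(row["target_slice_index"]), roi))
    return dataset


def write_rois(path, rois: list[QuantROI]) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in rois], indent=1))


def read_rois(path) -> list[QuantROI]:
    return [QuantROI.from_dict(d) for d in json.loads(Path(path).read_text())]


def save_plan(path, plan: SessionPlan) -> None:
    """Serialize a session plan as YAML (or JSON when path ends in .json)."""
    d = plan.to_dict()
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d))


def load_plan(path) -> SessionPlan:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SessionPlan.from_dict(d)
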