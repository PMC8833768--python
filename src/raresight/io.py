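"""File formats: multi-page TIFF frames with YAML channel maps, event
tables as CSV with run-length-encoded mask sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .categories import ROLES
from .detection import ChannelStack, EventRecord, Mask

__all__ = [
    "write_frame",
    "read_frame",
    "events_to_frame",
    "write_events",
    "read_events",
    "encode_rle",
    "decode_rle",
]


def write_frame(stack: ChannelStack, tiff_path, yaml_path=None) -> None:
    """One TIFF page per channel plus a sidecar YAML channel map."""
    tiff_path = Path(tiff_path)
    yaml_path = Path(yaml_path) if yaml_path else tiff_path.with_suffix(".yaml")
    tifffile.imwrite(
        tiff_path, stack.images.astype(np.float32), photometric="minisblack"
    )
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(
            {"frame_id": stack.frame_id, "channel_roles": dict(stack.channel_roles)},
            fh,
        )


def read_frame(tiff_path, yaml_path=None) -> ChannelStack:
    tiff_path = Path(tiff_path)
    yaml_path = Path(yaml_path) if yaml_path else tiff_path.with_suffix(".yaml")
    images = tifffile.imread(tiff_path)
    with open(yaml_path) as fh:
        meta = yaml.safe_load(fh)
    return ChannelStack(
        frame_id=meta["frame_id"],
        images=np.asarray(images, dtype=float),
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
    )


def encode_rle(mask: Mask) -> dict:
    """Run-length encode a mask's boolean grid (starts-false runs)."""
    flat = mask.grid.ravel()
    if flat.size == 0:
        return {"offset": list(mask.offset), "shape": [0, 0], "runs": []}
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate([[0], changes + 1, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:  # runs alternate starting with a False run
        runs = [0] + runs
    return {
        "offset": [int(v) for v in mask.offset],
        "shape": list(mask.grid.shape),
        "runs": [int(r) for r in runs],
    }


def decode_rle(payload: dict) -> Mask:
    shape = tuple(payload["shape"])
    n = shape[0] * shape[1]
    flat = np.zeros(n, dtype=bool)
    pos, value = 0, False
    for run in payload["runs"]:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return Mask(tuple(payload["offset"]), flat.reshape(shape))


def events_to_frame(records: list[EventRecord]) -> pd.DataFrame:
    """Tabular view of event records (masks referenced by event_id)."""
    rows = []
    for e in records:
        row = {
            "event_id": e.event_id,
            "frame_id": e.frame_id,
            "row": e.centroid[0],
            "col": e.centroid[1],
            "cell_area": e.cell_area,
            "nucleus_area": e.nucleus_area,
            "cell_eccentricity": e.cell_eccentricity,
            "nucleus_eccentricity": e.nucleus_eccentricity,
            "is_dapi_positive": e.is_dapi_positive,
            "attached_flag": e.attached_flag,
            "solidity": e.solidity,
            "annularity": e.annularity,
            "label": e.label,
            "is_rare": e.is_rare,
        }
        for role in ROLES:
            row[f"median_{role}"] = e.median_intensity.get(role, np.nan)
            row[f"positive_{role}"] = e.positivity.get(role)
        rows.append(row)
    return pd.DataFrame(rows)


def write_events(records: list[EventRecord], csv_path, masks_path=None) -> None:
    """Event table as CSV, masks as an RLE JSON sidecar."""
    csv_path = Path(csv_path)
    events_to_frame(records).to_csv(csv_path, index=False)
    masks_path = Path(masks_path) if masks_path else csv_path.with_suffix(".masks.json")
    payload = {
        str(e.event_id): {
            "cell": encode_rle(e.cell_mask),
            "nucleus": encode_rle(e.nucleus_mask),
        }
        for e in records
    }
    masks_path.write_text(json.dumps(payload))


def read_events(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
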