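"""Stack, config and results I/O.

Canonical on-disk layout is one multi-page TIFF per channel (pages are
sections), mirroring per-antibody acquisition; a single multi-channel file
is accepted when a channel order is supplied. Calibration is never
guessed: readers require explicit pixel size and section thickness.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stacks import ChannelStack, StackShapeError

__all__ = [
    "read_stack", "write_stack", "read_multichannel_stack",
    "load_config", "config_hash", "write_results",
]


def write_stack(stack: ChannelStack, out_dir) -> dict[str, str]:
    """Write one multi-page TIFF per channel; returns name → path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, arr in stack.channels.items():
        path = out_dir / f"{name}.tif"
        tifffile.imwrite(path, arr, photometric="minisblack", metadata=None)
        written[name] = str(path)
    meta = {
        "pixel_size_xy_um": stack.pixel_size_xy,
        "section_thickness_um": stack.section_thickness,
        "provenance": stack.provenance,
        "channels": list(stack.channels),
    }
    (out_dir / "calibration.json").write_text(json.dumps(meta, indent=2))
    return written


def read_stack(
    paths: dict[str, "str | Path"],
    pixel_size_xy: float | None = None,
    section_thickness: float | None = None,
) -> ChannelStack:
    """Read a channel-per-file stack.

    ``paths`` maps channel name → TIFF path. Calibration must be given
    explicitly, or a ``calibration.json`` sidecar (as written by
    :func:`write_stack`) must sit beside the first file — it is never
    silently assumed.
    """
    if not paths:
        raise ValueError("no channel files given")
    first_dir = Path(next(iter(paths.values()))).parent
    sidecar = first_dir / "calibration.json"
    if (pixel_size_xy is None or section_thickness is None) and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size_xy = pixel_size_xy or meta["pixel_size_xy_um"]
        section_thickness = section_thickness or meta["section_thickness_um"]
    if pixel_size_xy is None or section_thickness is None:
        raise ValueError(
            "calibration (pixel_size_xy, section_thickness) is required and "
            "no calibration.json sidecar was found"
        )
    channels = {}
    ref_name = None
    for name, path in paths.items():
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if ref_name is None:
            ref_name = name
        elif arr.shape != channels[ref_name].shape:
            raise StackShapeError(
                f"channel {name!r} ({Path(path).name}) has shape {arr.shape} "
                f"but {ref_name!r} has {channels[ref_name].shape}"
            )
        channels[name] = arr
    return ChannelStack(channels=channels, pixel_size_xy=pixel_size_xy,
                        section_thickness=section_thickness,
                        provenance=f"read from {first_dir}")


def read_multichannel_stack(
    path,
    channel_order: list[str],
    pixel_size_xy: float,
    section_thickness: float,
    channel_axis: int = 1,
) -> ChannelStack:
    """Read a single multi-channel TIFF given an explicit channel order."""
    arr = tifffile.imread(path)
    if arr.ndim != 4:
        raise StackShapeError(f"expected a 4D multi-channel stack, got {arr.shape}")
    arr = np.moveaxis(arr, channel_axis, 0)
    if arr.shape[0] != len(channel_order):
        raise StackShapeError(
            f"file has {arr.shape[0]} channels but {len(channel_order)} names given"
        )
    return ChannelStack(
        channels={name: arr[i] for i, name in enumerate(channel_order)},
        pixel_size_xy=pixel_size_xy, section_thickness=section_thickness,
        provenance=f"read from {path}")


# ---------------------------------------------------------------------------
# Config and results
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable hash of a config: any parameter change changes the hash."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write one CSV per table plus a JSON manifest; returns the manifest."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for stage, table in tables.items():
        path = out_dir / f"{stage}.csv"
        table.to_csv(path, index=False)
        files[stage] = path.name
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "tables": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
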