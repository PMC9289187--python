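"""Reading and writing stacks, truth tables, and configuration.

Stacks are multi-page TIFF, one file per microtissue, channel-first page
order (all Z planes of channel 0, then channel 1, ...), with channel
names and voxel sizes recorded in the image description metadata.
Ground truth and functional records are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from isletmt.errors import ConfigError
from isletmt.grid import VoxelGrid
from isletmt.synthetic import CHANNELS, LAYOUT_COLUMNS, validate_layout


def write_stack_tiff(path, stacks: dict[str, VoxelGrid], ome: bool = False) -> None:
    """Write a multi-channel stack as multi-page TIFF (channel-first).

    With ``ome=True`` the file is written as OME-TIFF with channel names
    and voxel sizes in the OME metadata; otherwise a plain multi-page
    TIFF with a JSON image description carrying the same information.
    """
    path = Path(path)
    channels = list(stacks)
    first = stacks[channels[0]]
    data = np.stack([stacks[ch].data for ch in channels]).astype(np.float32)
    if ome:
        dz, dy, dx = first.voxel_size
        tifffile.imwrite(
            path, data, photometric="minisblack", ome=True,
            metadata={"axes": "CZYX", "Channel": {"Name": channels},
                      "PhysicalSizeZ": dz, "PhysicalSizeY": dy,
                      "PhysicalSizeX": dx},
        )
        return
    meta = {
        "channels": channels,
        "voxel_size_zyx_um": list(first.voxel_size),
    }
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))


def read_stack_tiff(path, channel_map: dict[str, int | str] | None = None,
                    voxel_size: tuple[float, float, float] | None = None
                    ) -> dict[str, VoxelGrid]:
    """Read a multi-channel TIFF stack back into per-channel grids.

    ``channel_map`` assigns channel keys to page-block indices (or, when
    the file carries channel names in its metadata, to those names). With
    no map and no metadata, channels default to the canonical
    DAPI/NKX6.1/EdU order.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (ValueError, TypeError):
            meta = {}

    if data.ndim == 3:
        data = data[np.newaxis]
    if data.ndim != 4:
        raise ConfigError(f"{path.name}: expected a (C, Z, Y, X) stack, got shape {data.shape}")

    names = meta.get("channels")
    vs = voxel_size or tuple(meta.get("voxel_size_zyx_um", (3.0, 0.5, 0.5)))
    if channel_map is None:
        if names is None:
            names = list(CHANNELS[: data.shape[0]])
        channel_map = {name: i for i, name in enumerate(names)}

    out: dict[str, VoxelGrid] = {}
    for key, ref in channel_map.items():
        if isinstance(ref, str):
            if names is None or ref not in names:
                raise ConfigError(f"{path.name}: channel name {ref!r} not in metadata {names}")
            idx = names.index(ref)
        else:
            idx = int(ref)
        if not 0 <= idx < data.shape[0]:
            raise ConfigError(f"{path.name}: channel index {idx} out of range "
                              f"for {data.shape[0]} channels")
        out[key] = VoxelGrid(data=np.asarray(data[idx], dtype=np.float64),
                             voxel_size=tuple(vs), channel_name=key)
    return out


def write_truth_csv(truth_frame: pd.DataFrame, path) -> None:
    truth_frame.to_csv(path, index=False)


def read_layout_csv(path) -> pd.DataFrame:
    layout = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ConfigError(f"layout {path}: missing columns {missing}")
    return validate_layout(layout)


def write_layout_csv(layout: pd.DataFrame, path) -> None:
    validate_layout(layout).to_csv(path, index=False)


def read_functional_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"mt_id", "dose_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"functional CSV {path}: missing columns {sorted(missing)}")
    for col in df.columns:
        if df[col].dtype.kind in "fi" and col not in ("duration_days",):
            if (df[col].dropna() < 0).any():
                raise ConfigError(f"functional CSV {path}: negative values in {col}")
    return df
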