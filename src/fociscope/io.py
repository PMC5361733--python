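"""File I/O: multi-channel TIFF stacks and per-cell CSV tables.

Stacks are written as a single 4D TIFF, channel-first (C, Z, Y, X) with the
channel order nuclear/foci/edu and the voxel spacing recorded as JSON in the
ImageDescription tag.  All CSVs are comma-separated UTF-8 with a header row;
coordinates are 0-based voxel indices in z-y-x order, spacing in nm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .simulate import ChannelStack

CHANNEL_ORDER = ("nuclear", "foci", "edu")


class StackReadError(IOError):
    """Unreadable or malformed stack file."""


class MissingChannelError(StackReadError):
    """Stack does not resolve all three channels."""


class SpacingRequiredError(StackReadError):
    """No voxel spacing in the file metadata and none supplied."""


def write_stack(path: str | Path, stack: ChannelStack) -> None:
    data = np.stack([stack.nuclear, stack.foci, stack.edu]).astype(np.float32)
    meta = {"channels": list(CHANNEL_ORDER),
            "spacing_zyx_nm": list(stack.spacing_zyx)}
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_stack(path: str | Path,
               spacing_zyx: Optional[Sequence[float]] = None) -> ChannelStack:
    """Read a 4D channel-first TIFF back into a :class:`ChannelStack`.

    Spacing is taken from the embedded JSON metadata, or from the
    ``spacing_zyx`` argument; having neither is an error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackReadError(f"cannot read stack {path}: {exc}") from exc
    if data.ndim == 3:
        raise MissingChannelError(
            f"{path} holds a single 3D volume; expected 3 channels")
    if data.ndim != 4 or data.shape[0] != 3:
        raise MissingChannelError(
            f"{path} has shape {data.shape}; expected (3, Z, Y, X) "
            f"with channels {CHANNEL_ORDER}")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if "channels" in meta and tuple(meta["channels"]) != CHANNEL_ORDER:
        raise MissingChannelError(
            f"{path} channel order {meta['channels']} != {CHANNEL_ORDER}")
    spacing = meta.get("spacing_zyx_nm", spacing_zyx)
    if spacing is None:
        raise SpacingRequiredError(
            f"{path} carries no voxel spacing; pass spacing_zyx explicitly")
    return ChannelStack(nuclear=data[0], foci=data[1], edu=data[2],
                        spacing_zyx=tuple(float(s) for s in spacing))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


_CSV_HEADER = ("# coordinates are 0-based voxel indices, z-y-x order; "
               "spacing in nm\n")


def write_table(path: str | Path, frame: pd.DataFrame,
                comment: str = _CSV_HEADER) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if comment:
            fh.write(comment)
        frame.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
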