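"""Reading and writing of the pipeline's on-disk formats.

Stacks travel as multi-page TIFF with a JSON sidecar carrying the voxel
spacing (``{"spacing_um": [x, y, z], "channels": [...]}``); masks as 8-bit
0/255 TIFF; label images as 16-bit TIFF; ROIs as JSON polygon lists in
pixel coordinates; recordings as an HDF5 container with datasets ``/lfp``
(channels x samples x trials) and ``/onsets`` plus the ``fs_hz`` attribute
and an optional ``/spikes`` (unit, trial, t_s) table; tables as CSV with
one header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .ephys import TrialRecording
from .imaging import ImageStack


def write_stack(path, stack: ImageStack, meta_path=None) -> None:
    """Write an ImageStack as a (channel, z, y, x) TIFF plus JSON sidecar."""
    path = Path(path)
    names = list(stack.channels)
    arr = np.stack([stack.channels[n] for n in names])
    tifffile.imwrite(path, arr.astype(np.float32))
    sz, sy, sx = stack.spacing
    meta = {"spacing_um": [sx, sy, sz], "channels": names}
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=1))


def read_stack(path, meta_path=None) -> ImageStack:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    arr = tifffile.imread(path)
    names = meta["channels"]
    if arr.ndim == 3 and len(names) == 1:
        arr = arr[None]
    if arr.ndim == 2 and len(names) == 1:
        arr = arr[None, None]
    sx, sy, sz = meta["spacing_um"]
    return ImageStack(
        channels={n: arr[i] for i, n in enumerate(names)}, spacing=(sz, sy, sx)
    )


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def read_rois(path) -> list[np.ndarray]:
    """ROI polygons from JSON: a list of [[x, y], ...] vertex lists."""
    data = json.loads(Path(path).read_text())
    return [np.asarray(poly, dtype=float) for poly in data]


def write_recording(path, recording: TrialRecording, spikes: pd.DataFrame | None = None) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("lfp", data=recording.data)
        f.create_dataset("onsets", data=recording.onsets)
        f.attrs["fs_hz"] = recording.fs
        if spikes is not None:
            g = f.create_group("spikes")
            g.create_dataset("unit", data=spikes["unit"].to_numpy(dtype=np.int64))
            g.create_dataset("trial", data=spikes["trial"].to_numpy(dtype=np.int64))
            g.create_dataset("t_s", data=spikes["t_s"].to_numpy(dtype=float))


def read_recording(path) -> tuple[TrialRecording, pd.DataFrame | None]:
    with h5py.File(Path(path), "r") as f:
        rec = TrialRecording(
            data=f["lfp"][()], fs=float(f.attrs["fs_hz"]), onsets=f["onsets"][()]
        )
        spikes = None
        if "spikes" in f:
            g = f["spikes"]
            spikes = pd.DataFrame(
                {"unit": g["unit"][()], "trial": g["trial"][()], "t_s": g["t_s"][()]}
            )
    return rec, spikes


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def read_trace(path) -> pd.DataFrame:
    """Behavior trace CSV with columns t_s, state [, condition]."""
    return pd.read_csv(Path(path))
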