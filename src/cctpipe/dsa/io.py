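"""Disk round-trip for DSA sequences and ROI masks.

A sequence is stored as a directory of 16-bit grayscale PNG frames plus a JSON
sidecar carrying the frame times, the mask-frame index, and the affine scaling
used to quantise float intensities into the PNG range.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .timing import DsaSequence, RoiMask

_SIDECAR = "sequence.json"
_U16_MAX = 65535


def write_sequence(seq: DsaSequence, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo = float(seq.frames.min())
    hi = float(seq.frames.max())
    scale = (hi - lo) / _U16_MAX if hi > lo else 1.0
    names = []
    for t in range(seq.n_frames):
        q = np.round((seq.frames[t] - lo) / scale).astype(np.uint16)
        name = f"frame_{t:04d}.png"
        iio.imwrite(directory / name, q)
        names.append(name)
    sidecar = {
        "frame_times_s": [float(t) for t in seq.frame_times_s],
        "frame_rate_hz": 1.0 / seq.frame_interval_s,
        "mask_frame_index": int(seq.mask_frame_index),
        "intensity_offset": lo,
        "intensity_scale": scale,
        "frames": names,
    }
    (directory / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return directory


def read_sequence(directory: str | Path) -> DsaSequence:
    directory = Path(directory)
    sidecar = json.loads((directory / _SIDECAR).read_text())
    frames = np.stack(
        [iio.imread(directory / name).astype(np.float64) for name in sidecar["frames"]]
    )
    frames = frames * sidecar["intensity_scale"] + sidecar["intensity_offset"]
    return DsaSequence(
        frames=frames,
        frame_times_s=np.asarray(sidecar["frame_times_s"], dtype=float),
        mask_frame_index=sidecar["mask_frame_index"],
    )


def write_roi(roi: RoiMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (roi.mask.astype(np.uint8) * 255))
    return path


def read_roi(path: str | Path, label: str = "other") -> RoiMask:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse any colour channels
        img = img.max(axis=-1)
    return RoiMask(mask=img > 0, label=label)
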