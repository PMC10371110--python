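"""Image and report I/O: frame streams as numbered PNGs with a JSON sidecar."""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DataError
from .scene import Frame, FrameStream

log = logging.getLogger(__name__)

SIDECAR_NAME = "stream.json"


def seed_for(base_seed: int, module_name: str) -> np.random.SeedSequence:
    """Fork the experiment seed into a stable per-module substream.

    The fork uses a stable hash (CRC-32) of the module name, so adding a
    module never perturbs another module's draws.
    """
    return np.random.SeedSequence([int(base_seed), zlib.crc32(module_name.encode())])


def write_stream(stream: FrameStream, directory, bit_depth: int = 8) -> Path:
    """Write frames as numbered grayscale PNGs plus a metadata sidecar.

    Intensities already quantized to ``bit_depth`` levels survive the
    round trip bit-exactly.
    """
    if bit_depth not in (8, 16):
        raise DataError("PNG streams support 8- or 16-bit depth")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    levels = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    for i, fr in enumerate(stream.frames):
        iio.imwrite(
            directory / f"frame_{i:05d}.png",
            np.round(fr.data * levels).astype(dtype),
        )
    sidecar = {
        "fps": stream.fps,
        "period_ms": stream.period_ms,
        "bit_depth": bit_depth,
        "timestamps_ms": [fr.timestamp_ms for fr in stream.frames],
        "laser_states": [fr.laser_state for fr in stream.frames],
        "channels": [fr.channel for fr in stream.frames],
    }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return directory


def read_stream(directory) -> FrameStream:
    """Read a numbered-PNG stream back; warns if the sidecar is missing
    (laser states then unknown and must come from parity detection)."""
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise DataError(f"no frames found under {directory}")
    images = [iio.imread(p) for p in paths]
    dtypes = {im.dtype for im in images}
    if len(dtypes) != 1:
        raise DataError("mixed bit depths in stream directory")
    levels = float(np.iinfo(images[0].dtype).max)
    sidecar_path = directory / SIDECAR_NAME
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        timestamps = meta["timestamps_ms"]
        states = meta["laser_states"]
        channels = meta.get("channels", ["nir"] * len(images))
        period, fps = meta["period_ms"], meta["fps"]
    else:
        warnings.warn(
            "stream sidecar missing: laser states unknown (use parity detection)",
            stacklevel=2,
        )
        period, fps = 33.0, 1000.0 / 33.0
        timestamps = [i * period for i in range(len(images))]
        states = [None] * len(images)
        channels = ["nir"] * len(images)
    frames = [
        Frame(np.asarray(im, float) / levels, t, s, c)
        for im, t, s, c in zip(images, timestamps, states, channels)
    ]
    return FrameStream(frames, period_ms=period, fps=fps)
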