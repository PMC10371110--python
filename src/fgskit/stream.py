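"""Processing of laser-synchronized frame streams.

With the excitation laser toggled on every other frame, the absolute
difference of consecutive frames removes every static contribution
(ambient NIR room light, dark level) and preserves the excitation-driven
signal, yielding a background-subtracted stream at the full input rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, ParityAmbiguityError
from .scene import FrameStream

log = logging.getLogger(__name__)


@dataclass
class LaserSchedule:
    """Timing of the frame-synchronized excitation trigger (all ms)."""

    frame_period: float
    trigger_period: float
    on_duration: float
    duty: float

    def __post_init__(self):
        if abs(self.trigger_period - 2 * self.frame_period) > 1e-9:
            raise ConfigError("trigger period must equal twice the frame period")
        if not (0 < self.on_duration <= self.frame_period):
            raise ConfigError("on-duration must lie in (0, frame period]")


def make_schedule(fps: float, duty: float = 0.7) -> LaserSchedule:
    """Schedule for a given frame rate: 30 fps -> 33 ms frames, 66 ms trigger."""
    if fps <= 0:
        raise ConfigError("fps must be positive")
    if not (0 < duty <= 1):
        raise ConfigError("duty must lie in (0, 1]")
    period = round(1000.0 / fps)
    return LaserSchedule(
        frame_period=period, trigger_period=2 * period, on_duration=duty * period, duty=duty
    )


@dataclass
class SubtractedStream:
    """Sliding consecutive-frame absolute differences |F_n - F_{n-1}|."""

    frames: np.ndarray  # (N-1, H, W), non-negative
    fps: float
    source: FrameStream | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if np.any(self.frames < 0):
            raise DataError("difference frames must be non-negative")

    def __len__(self) -> int:
        return len(self.frames)


def background_subtract(stream: FrameStream) -> SubtractedStream:
    """Sliding background subtraction: one output frame per input after the
    first, at the full input rate.

    Differences are computed in float, so integer wraparound cannot occur
    regardless of the source bit depth.
    """
    if len(stream) < 2:
        raise DataError("background subtraction needs at least 2 frames")
    shapes = {f.data.shape for f in stream.frames}
    if len(shapes) != 1:
        raise DataError("all frames must share one shape")
    data = stream.intensities()
    diffs = np.abs(np.diff(data.astype(float), axis=0))
    return SubtractedStream(diffs, fps=stream.fps, source=stream)


@dataclass(frozen=True)
class ParityResult:
    parity: str  # "even-on" | "odd-on"
    margin: float  # relative mean-intensity difference between parities


def detect_laser_parity(stream: FrameStream, min_margin: float = 0.01) -> ParityResult:
    """Decide which frame parity carries the excitation from mean intensities.

    The parity with the larger mean is laser-on; the relative margin must
    exceed ``min_margin`` or the decision is refused as ambiguous.
    """
    if len(stream) < 4:
        raise DataError("parity detection needs at least 4 frames")
    data = stream.intensities()
    m_even = float(data[0::2].mean())
    m_odd = float(data[1::2].mean())
    base = 0.5 * (m_even + m_odd)
    margin = abs(m_even - m_odd) / base if base > 0 else 0.0
    if margin < min_margin:
        raise ParityAmbiguityError(
            f"laser parity ambiguous: relative margin {margin:.2e} < {min_margin:.2e}"
        )
    return ParityResult("even-on" if m_even > m_odd else "odd-on", margin)


def pair_on_off(stream: FrameStream, parity: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pair each laser-on frame with the adjacent preceding/following off frame.

    Consecutive frames are grouped in twos from the first complete pair; an
    odd leftover frame is dropped with a logged warning.
    """
    if parity not in ("even-on", "odd-on"):
        raise DataError("parity must be 'even-on' or 'odd-on'")
    data = stream.intensities()
    pairs = []
    n = len(data)
    for i in range(0, n - 1, 2):
        a, b = data[i], data[i + 1]
        if parity == "even-on":
            pairs.append((a, b))
        else:
            pairs.append((b, a))
    if n % 2 == 1:
        log.warning("odd leftover frame %d dropped from on/off pairing", n - 1)
    return pairs
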