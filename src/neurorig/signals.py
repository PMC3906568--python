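"""Core in-memory containers: uniformly sampled traces and positioned images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trace:
    """A uniformly sampled analog signal.

    Parameters
    ----------
    samples : ndarray
        Sample values.
    rate : float
        Sample rate in Hz (> 0).
    t0 : float
        Time of the first sample, seconds.
    units : str
        Physical units of the samples (SI: "V", "A", ...).
    channel : str
        Name of the originating channel or device.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""
    channel: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def time_slice(self, start: float, stop: float) -> "Trace":
        """Return the sub-trace with times in [start, stop)."""
        i0 = max(0, int(np.ceil((start - self.t0) * self.rate - 1e-9)))
        i1 = min(self.n, int(np.ceil((stop - self.t0) * self.rate - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"window [{start}, {stop}) outside trace span")
        return Trace(self.samples[i0:i1], self.rate, self.t0 + i0 / self.rate,
                     self.units, self.channel)

    def copy(self) -> "Trace":
        return Trace(self.samples.copy(), self.rate, self.t0, self.units,
                     self.channel)


@dataclass
class Frame:
    """A single image with its pixel-to-global transform.

    ``transform`` maps homogeneous pixel coordinates (x=column, y=row,
    0-based, pixel centers at integers) to global sample coordinates in
    meters.
    """

    pixels: np.ndarray
    transform: "np.ndarray | object" = None  # Transform3D; kept loose to avoid cycle
    objective: str = ""
    t_start: float = 0.0
    exposure: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2D array")


@dataclass
class FrameSeries:
    """An ordered list of frames sharing a shape, with per-frame start times."""

    frames: list = field(default_factory=list)

    def __post_init__(self):
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have inconsistent shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t_start for f in self.frames])

    def stack(self) -> np.ndarray:
        """All frames as one (n, rows, cols) array."""
        return np.stack([f.pixels for f in self.frames])
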