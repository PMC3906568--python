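"""Scan-mirror voltage calibration, scan pattern generation, laser dosimetry.

The galvanometric mirror pair steers the laser: for a target (x, y) in the
global sample frame the command voltages follow a quadratic map

    Vx = A·x² + B·y² + C·x + D·y + E
    Vy = F·x² + G·y² + H·x + I·y + J

whose coefficients are fitted from observed (spot position, voltage) pairs,
once per (laser, objective) combination.  The model is linear in its
coefficients, so ordinary linear least squares reaches the same optimum as
an iterative least-squares solver and is used here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScannerCalibration",
    "CalibrationStore",
    "ScanPattern",
    "LaserState",
    "fit_voltage_map",
    "position_to_voltage",
    "generate_scan_pattern",
    "estimate_field_shift",
    "laser_energy_calc",
]


@dataclass
class ScannerCalibration:
    """Fitted voltage-map coefficients for one (laser, objective) pair."""

    vx_coef: np.ndarray  # A, B, C, D, E
    vy_coef: np.ndarray  # F, G, H, I, J
    laser: str = ""
    objective: str = ""
    fit_residual: float = 0.0  # RMS position-model residual, volts

    def __post_init__(self):
        self.vx_coef = np.asarray(self.vx_coef, dtype=float)
        self.vy_coef = np.asarray(self.vy_coef, dtype=float)
        if self.vx_coef.shape != (5,) or self.vy_coef.shape != (5,):
            raise ValueError("each coefficient set must have exactly 5 entries")
        if not np.isfinite(self.fit_residual):
            raise ValueError("fit residual must be finite")

    @property
    def key(self) -> str:
        return f"{self.laser}/{self.objective}"


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x ** 2, y ** 2, x, y, np.ones_like(x)])


def fit_voltage_map(samples, laser: str = "", objective: str = "") -> ScannerCalibration:
    """Least-squares fit of the quadratic voltage map.

    ``samples`` is an iterable of (x, y, Vx, Vy) with positions in meters and
    voltages in volts.  Requires at least 5 samples spanning a non-degenerate
    geometry (the design matrix [x², y², x, y, 1] must be full rank).  On
    noise-free data generated from the model the fit recovers the
    coefficients to machine precision.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("samples must be (x, y, Vx, Vy) quadruples")
    if len(arr) < 5:
        raise ValueError(f"need at least 5 samples, got {len(arr)}")
    x, y, vx, vy = arr.T
    # solve in unit-scaled coordinates: meter-scale positions make the raw
    # design badly conditioned (x^2 ~ 1e-8 vs 1), costing ~7 digits
    sx = float(np.max(np.abs(x))) or 1.0
    sy = float(np.max(np.abs(y))) or 1.0
    A = _design(x / sx, y / sy)
    if np.linalg.matrix_rank(A) < 5:
        raise ValueError("degenerate sample geometry: design matrix rank-deficient "
                         "(are the points collinear?)")
    rescale = np.array([1 / sx ** 2, 1 / sy ** 2, 1 / sx, 1 / sy, 1.0])
    cx, resx, *_ = np.linalg.lstsq(A, vx, rcond=None)
    cy, resy, *_ = np.linalg.lstsq(A, vy, rcond=None)
    cx = cx * rescale
    cy = cy * rescale
    A = _design(x, y)
    rss = float(np.sum((A @ cx - vx) ** 2) + np.sum((A @ cy - vy) ** 2))
    rms = np.sqrt(rss / (2 * len(arr)))
    return ScannerCalibration(cx, cy, laser=laser, objective=objective,
                              fit_residual=rms)


def position_to_voltage(cal: ScannerCalibration, x: float, y: float):
    """Evaluate the calibrated map at a global (x, y) position (meters)."""
    a = _design(np.atleast_1d(np.asarray(x, float)),
                np.atleast_1d(np.asarray(y, float)))
    vx = a @ cal.vx_coef
    vy = a @ cal.vy_coef
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(vx[0]), float(vy[0])
    return vx, vy


class CalibrationStore:
    """Calibrations keyed by (laser, objective), JSON-serializable."""

    def __init__(self):
        self._store: dict[str, ScannerCalibration] = {}

    def add(self, cal: ScannerCalibration):
        self._store[cal.key] = cal

    def get(self, laser: str, objective: str) -> ScannerCalibration:
        key = f"{laser}/{objective}"
        if key not in self._store:
            raise KeyError(
                f"no scanner calibration stored for laser={laser!r}, "
                f"objective={objective!r}")
        return self._store[key]

    def save(self, path):
        doc = {k: {"vx_coef": list(c.vx_coef), "vy_coef": list(c.vy_coef),
                   "laser": c.laser, "objective": c.objective,
                   "fit_residual": c.fit_residual}
               for k, c in self._store.items()}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def load(cls, path) -> "CalibrationStore":
        with open(path) as fh:
            doc = json.load(fh)
        store = cls()
        for rec in doc.values():
            store.add(ScannerCalibration(**rec))
        return store


# ---------------------------------------------------------------------------
# scan patterns


@dataclass
class ScanPattern:
    """Geometry of one scan: raster | line | circle | spiral | points.

    raster: ``extent`` (x0, y0, width, height), ``rows``, ``cols``,
    ``overscan`` fraction added to both ends of every line, ``bidirectional``
    with an optional ``field_shift`` in samples applied to reversed rows.
    line: ``start``/``stop`` endpoints and ``n_points`` (inclusive).
    circle: ``center``, ``radius``, ``n_points`` at constant angular speed.
    spiral: Archimedean r = pitch·theta/(2π), ``turns`` and ``n_points``.
    points: explicit ``points`` list, passed through.
    """

    kind: str
    extent: tuple | None = None
    rows: int = 0
    cols: int = 0
    start: tuple | None = None
    stop: tuple | None = None
    n_points: int = 0
    center: tuple = (0.0, 0.0)
    radius: float = 0.0
    pitch: float = 0.0
    turns: float = 1.0
    overscan: float = 0.0
    bidirectional: bool = False
    field_shift: int = 0
    points: list = field(default_factory=list)


def generate_scan_pattern(pattern: ScanPattern, sample_rate: float):
    """Expand a scan pattern to a timed position series.

    Returns ``(xy, keep)``: an (n, 2) array of positions in meters sampled
    at ``sample_rate`` and a boolean mask flagging samples to keep at image
    reconstruction (overscan turnaround samples are flagged False).
    """
    if sample_rate <= 0:
        raise ValueError("sample rate must be positive")
    if pattern.overscan < 0:
        raise ValueError("overscan fraction cannot be negative")
    kind = pattern.kind
    if kind == "raster":
        return _raster(pattern)
    if kind == "line":
        p0, p1 = np.asarray(pattern.start, float), np.asarray(pattern.stop, float)
        f = np.linspace(0.0, 1.0, pattern.n_points)[:, None]
        return p0 + f * (p1 - p0), np.ones(pattern.n_points, bool)
    if kind == "circle":
        th = np.linspace(0.0, 2 * np.pi, pattern.n_points, endpoint=False)
        xy = np.column_stack([pattern.center[0] + pattern.radius * np.cos(th),
                              pattern.center[1] + pattern.radius * np.sin(th)])
        return xy, np.ones(pattern.n_points, bool)
    if kind == "spiral":
        th = np.linspace(0.0, 2 * np.pi * pattern.turns, pattern.n_points)
        r = pattern.pitch * th / (2 * np.pi)
        xy = np.column_stack([pattern.center[0] + r * np.cos(th),
                              pattern.center[1] + r * np.sin(th)])
        return xy, np.ones(pattern.n_points, bool)
    if kind == "points":
        xy = np.asarray(pattern.points, float).reshape(-1, 2)
        return xy, np.ones(len(xy), bool)
    raise ValueError(f"unknown scan pattern kind {pattern.kind!r}")


def _raster(pattern: ScanPattern):
    x0, y0, w, h = pattern.extent
    rows, cols = pattern.rows, pattern.cols
    if rows < 1 or cols < 1 or w <= 0 or h <= 0:
        raise ValueError("raster needs positive extent and at least 1 row/col")
    n_over = int(round(cols * pattern.overscan))
    dx = w / cols
    # core column centers plus overscan extension on both ends of the line
    ci = np.arange(-n_over, cols + n_over)
    xs = x0 + (ci + 0.5) * dx
    keep_line = (ci >= 0) & (ci < cols)
    ys = y0 + (np.arange(rows) + 0.5) * (h / rows)
    xy_rows, keep_rows = [], []
    for r in range(rows):
        x_line, k_line = xs, keep_line
        if pattern.bidirectional and r % 2 == 1:
            x_line, k_line = xs[::-1], keep_line[::-1]
            if pattern.field_shift:
                x_line = np.roll(x_line, pattern.field_shift)
                k_line = np.roll(k_line, pattern.field_shift)
        xy_rows.append(np.column_stack([x_line, np.full(len(xs), ys[r])]))
        keep_rows.append(k_line)
    return np.vstack(xy_rows), np.concatenate(keep_rows)


def estimate_field_shift(even_row: np.ndarray, odd_row: np.ndarray,
                         max_shift: int = 10) -> int:
    """Estimate the bidirectional comb shift maximizing row cross-correlation.

    ``odd_row`` is the reversed-direction line; the returned integer shift,
    applied via ``np.roll`` to the odd rows, best aligns them with the even
    rows.  Provided as a convenience; the default pipeline uses an explicit
    user-supplied shift.
    """
    even = even_row - even_row.mean()
    odd = odd_row[::-1] - odd_row.mean()
    best, best_c = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        c = float(np.dot(even, np.roll(odd, s)))
        if c > best_c:
            best, best_c = s, c
    return best


# ---------------------------------------------------------------------------
# laser power / energy


@dataclass
class LaserState:
    """Current laser output power and per-optical-configuration attenuation."""

    output_power: float  # watts, at the source
    attenuation: float = 1.0  # fraction reaching the sample plane

    def __post_init__(self):
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError(f"attenuation must be in [0, 1], got {self.attenuation}")

    @property
    def expected_sample_power(self) -> float:
        """Expected power at the sample plane, watts."""
        return self.output_power * self.attenuation


def laser_energy_calc(state: LaserState, requested_energy: float) -> float:
    """Pulse duration (s) delivering ``requested_energy`` (J) at the sample."""
    if requested_energy < 0:
        raise ValueError("requested energy cannot be negative")
    power = state.expected_sample_power
    if power <= 0:
        raise ValueError(f"expected sample power must be positive, got {power}")
    return requested_energy / power
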