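"""Simulated rig hardware: clamp amplifier, camera, scan mirrors, reservation.

Every simulator is a pure function of its parameters plus an explicit seed,
so acquisitions are bit-reproducible.  The clamp model is a passive RC cell
(pipette access resistance Ra in series with the membrane Rm || Cm); an
optional leaky integrate-and-fire mode generates spike trains for
current-clamp excitability protocols.  Simulators deliberately omit
amplifier filtering, capacitance compensation and camera readout noise.
"""

from __future__ import annotations

import threading
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from neurorig.signals import Frame, FrameSeries, Trace

__all__ = [
    "CellModel",
    "DeviceRegistry",
    "Reservation",
    "ReservationTimeout",
    "sim_clamp_response",
    "sim_lif_response",
    "sim_camera_acquire",
    "sim_scanner_observe",
]


# ---------------------------------------------------------------------------
# cell model


@dataclass
class CellModel:
    """Passive RC cell seen through a patch pipette.

    Ra: access (series) resistance, ohms.  Rm: membrane resistance, ohms.
    Cm: membrane capacitance, farads.  Vrest: resting potential, volts.
    holding_current: steady pipette current at the holding potential, amps.
    noise_sd: white Gaussian noise sd in the recorded units (A in VC, V in IC).
    """

    Ra: float = 10e6
    Rm: float = 100e6
    Cm: float = 30e-12
    Vrest: float = -65e-3
    holding_current: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if min(self.Ra, self.Rm, self.Cm) <= 0:
            raise ValueError("Ra, Rm, Cm must all be positive")

    @property
    def tau_vc(self) -> float:
        """Voltage-clamp charging time constant Cm·(Ra·Rm)/(Ra+Rm)."""
        return self.Cm * self.Ra * self.Rm / (self.Ra + self.Rm)

    @property
    def tau_ic(self) -> float:
        """Current-clamp membrane time constant Rm·Cm."""
        return self.Rm * self.Cm


# ---------------------------------------------------------------------------
# clamp amplifier


def _step_changes(samples: np.ndarray):
    """Yield (index, delta) for each level change in a piecewise-constant array."""
    d = np.diff(samples)
    idx = np.nonzero(d)[0]
    return [(int(i) + 1, float(d[i])) for i in idx]


def sim_clamp_response(cell: CellModel, command: Trace, mode: str,
                       rate: float | None = None, seed: int = 0) -> Trace:
    """Response of the RC cell to a piecewise-constant clamp command.

    In voltage clamp a command step dV produces the classic capacitive
    transient: I(t) = Ihold + dV/(Ra+Rm) + (dV/Ra - dV/(Ra+Rm))·exp(-t/tau)
    with tau = Cm·Ra·Rm/(Ra+Rm).  In current clamp a step dI charges the
    membrane, V(t) = Vrest + dI·Rm·(1-exp(-t/(Rm·Cm))) + dI·Ra, the Ra drop
    being instantaneous.  Arbitrary piecewise-constant commands are handled
    by superposition (the circuit is linear).  ``i0`` mode records the free
    membrane potential.
    """
    if rate is None:
        rate = command.rate
    if rate <= 0:
        raise ValueError("rate must be positive")
    if mode not in ("vc", "ic", "i0"):
        raise ValueError(f"mode must be vc|ic|i0, got {mode!r}")
    expected_units = {"vc": "V", "ic": "A", "i0": "A"}[mode]
    if command.units and command.units != expected_units:
        raise ValueError(
            f"command units {command.units!r} do not match mode {mode!r} "
            f"(expected {expected_units!r})")

    n = command.n
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    if mode == "vc":
        tau = cell.tau_vc
        out = np.full(n, cell.holding_current)
        Iss_per_V = 1.0 / (cell.Ra + cell.Rm)
        Ipk_per_V = 1.0 / cell.Ra
        for i, dv in _step_changes(command.samples):
            tt = t[i:] - t[i]
            out[i:] += dv * Iss_per_V + dv * (Ipk_per_V - Iss_per_V) * np.exp(-tt / tau)
        units = "A"
    elif mode == "ic":
        tau = cell.tau_ic
        out = np.full(n, cell.Vrest)
        for i, di in _step_changes(command.samples):
            tt = t[i:] - t[i]
            out[i:] += di * cell.Rm * (1.0 - np.exp(-tt / tau)) + di * cell.Ra
        units = "V"
    else:  # i0: free membrane potential, no command applied
        out = np.full(n, cell.Vrest)
        units = "V"

    if cell.noise_sd > 0:
        out = out + rng.normal(0.0, cell.noise_sd, n)
    return Trace(out, rate, t0=command.t0, units=units, channel="primary")


def sim_lif_response(cell: CellModel, command: Trace, rate: float | None = None,
                     seed: int = 0, threshold: float = -40e-3,
                     reset: float = -65e-3, refractory: float = 2e-3,
                     spike_peak: float = 30e-3) -> Trace:
    """Leaky integrate-and-fire current-clamp response (synthetic spiking).

    Forward-Euler integration of dV/dt = (Vrest - V)/(Rm·Cm) + I/Cm with a
    hard threshold, reset and absolute refractory period.  The threshold
    crossing sample is painted at ``spike_peak`` so that spikes register as
    upward crossings of conventional detection thresholds.  This mechanism
    is synthetic -- it exists to exercise spike-train metrics, not to model
    channel dynamics.
    """
    if rate is None:
        rate = command.rate
    dt = 1.0 / rate
    n = command.n
    rng = np.random.default_rng(seed)
    I = command.samples
    V = np.empty(n)
    v = cell.Vrest
    refr_until = -1.0
    tau = cell.tau_ic
    for i in range(n):
        ti = i * dt
        if ti < refr_until:
            v = reset
            V[i] = v + I[i] * cell.Ra
            continue
        v = v + dt * ((cell.Vrest - v) / tau + I[i] / cell.Cm)
        if v >= threshold:
            V[i] = spike_peak
            v = reset
            refr_until = ti + refractory
        else:
            V[i] = v + I[i] * cell.Ra
    if cell.noise_sd > 0:
        V = V + rng.normal(0.0, cell.noise_sd, n)
    return Trace(V, rate, t0=command.t0, units="V", channel="primary")


# ---------------------------------------------------------------------------
# device reservation


class ReservationTimeout(TimeoutError):
    """A reservation request waited longer than its timeout."""


@dataclass
class Reservation:
    devices: frozenset
    owner: str
    _registry: "DeviceRegistry" = None

    def release(self):
        if self._registry is not None:
            self._registry._release(self)
            self._registry = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.release()
        return False


class DeviceRegistry:
    """Tracks which devices are claimed by which task.

    Reservations claim all requested devices atomically under one lock, so a
    task never holds some devices while waiting on others (no hold-and-wait,
    hence no deadlock).  Waiting requests are granted first-come
    first-served.
    """

    def __init__(self, device_names):
        self._all = set(device_names)
        self._held: dict[str, str] = {}  # device -> owner
        self._cond = threading.Condition()
        self._queue: deque = deque()
        self.claim_log: list[tuple[str, str, frozenset]] = []  # (event, owner, devices)

    def reserve(self, devices, owner: str = "task", timeout: float = 30.0) -> Reservation:
        devset = frozenset(devices)
        unknown = devset - self._all
        if unknown:
            raise KeyError(f"unknown devices: {sorted(unknown)}")
        ticket = object()
        with self._cond:
            self._queue.append(ticket)
            ok = self._cond.wait_for(
                lambda: self._queue[0] is ticket
                and not any(d in self._held for d in devset),
                timeout=timeout)
            if not ok:
                self._queue.remove(ticket)
                self._cond.notify_all()
                raise ReservationTimeout(
                    f"timed out waiting for {sorted(devset)} (owner {owner!r})")
            self._queue.popleft()
            for d in devset:
                self._held[d] = owner
            self.claim_log.append(("claim", owner, devset))
            self._cond.notify_all()
        return Reservation(devset, owner, self)

    def _release(self, res: Reservation):
        with self._cond:
            for d in res.devices:
                self._held.pop(d, None)
            self.claim_log.append(("release", res.owner, res.devices))
            self._cond.notify_all()

    def held(self) -> dict:
        with self._cond:
            return dict(self._held)


# ---------------------------------------------------------------------------
# camera


def sim_camera_acquire(rig, camera: str, n_frames: int, exposure: float,
                       interval: float, trigger_mode: str = "normal",
                       scene=None, seed: int = 0, trigger_time: float = 0.0,
                       ttl_rate: float = 40e3, ttl_duration: float | None = None):
    """Acquire frames by sampling a scene through the camera's global transform.

    Returns ``(FrameSeries, ttl)`` where the TTL trace is high during each
    exposure and frame start times equal its rising-edge times exactly.  In
    triggered mode the first exposure begins at ``trigger_time``.  The scene
    is a callable mapping global (x, y) meter coordinate arrays to intensity.
    """
    if exposure > interval:
        raise ValueError(f"exposure {exposure} exceeds frame interval {interval}")
    dev = rig.device(camera)
    if dev.kind != "camera":
        raise ValueError(f"{camera!r} is not a camera")
    shape = tuple(dev.config.get("sensor_shape", (32, 32)))
    noise_sd = float(dev.config.get("noise_sd", 0.0))
    rng = np.random.default_rng(seed)
    tr = rig.global_transform(camera)

    cols, rows = np.meshgrid(np.arange(shape[1]), np.arange(shape[0]))
    pix = np.column_stack([cols.ravel(), rows.ravel(), np.zeros(cols.size)])
    gpts = tr.map(pix)

    t_first = trigger_time if trigger_mode == "triggered" else 0.0
    dt = 1.0 / ttl_rate
    frames = []
    starts = []
    for k in range(n_frames):
        # quantize to the TTL sample grid so edge times are exact
        start = round((t_first + k * interval) / dt) * dt
        starts.append(start)
        if scene is None:
            img = np.zeros(shape)
        else:
            vals = np.asarray(scene(gpts[:, 0], gpts[:, 1]), dtype=float)
            # constant scenes may return a scalar; broadcast to the sensor
            img = np.broadcast_to(vals, (gpts.shape[0],)).reshape(shape).copy()
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, shape)
        frames.append(Frame(pixels=img, transform=tr,
                            objective=_active_objective_of(rig, camera),
                            t_start=start, exposure=exposure))

    if ttl_duration is None:
        ttl_duration = starts[-1] + interval
    n_ttl = int(round(ttl_duration * ttl_rate))
    ttl = np.zeros(n_ttl)
    for start in starts:
        i0 = int(round(start * ttl_rate))
        i1 = min(n_ttl, i0 + max(1, int(round(exposure * ttl_rate))))
        ttl[i0:i1] = 5.0  # TTL high level, volts
    return (FrameSeries(frames),
            Trace(ttl, ttl_rate, t0=0.0, units="V", channel=f"{camera}.exposure"))


def _active_objective_of(rig, camera: str) -> str:
    for anc in rig.parent_chain(camera):
        if rig.devices[anc].kind == "microscope":
            return rig.active_objective(anc) or ""
    return ""


# ---------------------------------------------------------------------------
# scan mirrors


def _quad_eval(coef, x, y):
    a, b, c, d, e = coef
    return a * x ** 2 + b * y ** 2 + c * x + d * y + e


def sim_scanner_observe(true_map, Vx: float, Vy: float,
                        noise_sd: float = 0.0, seed: int = 0):
    """Spot position produced by mirror voltages under a ground-truth map.

    ``true_map`` is a pair of 5-coefficient tuples ((A..E), (F..J)) for the
    quadratic voltage model Vx = A·x² + B·y² + C·x + D·y + E (and likewise
    Vy).  The returned (x, y) position is the model inverse at (Vx, Vy),
    found numerically from a linear-part initial guess, plus Gaussian
    position noise.  Used to generate scanner calibration datasets.
    """
    cx, cy = np.asarray(true_map[0], float), np.asarray(true_map[1], float)
    # linear initial guess: [C D; H I] [x y]' = [Vx-E, Vy-J]'
    M = np.array([[cx[2], cx[3]], [cy[2], cy[3]]])
    if abs(np.linalg.det(M)) < 1e-15:
        raise ValueError("ground-truth map has singular linear part")
    guess = np.linalg.solve(M, [Vx - cx[4], Vy - cy[4]])

    def resid(p):
        return [_quad_eval(cx, p[0], p[1]) - Vx, _quad_eval(cy, p[0], p[1]) - Vy]

    sol = optimize.root(resid, guess, tol=1e-12)
    pos = sol.x
    # Newton polish with the analytic Jacobian down to machine precision
    for _ in range(5):
        r = np.asarray(resid(pos))
        if np.max(np.abs(r)) < 1e-15:
            break
        x, y = pos
        J = np.array([[2 * cx[0] * x + cx[2], 2 * cx[1] * y + cx[3]],
                      [2 * cy[0] * x + cy[2], 2 * cy[1] * y + cy[3]]])
        pos = pos - np.linalg.solve(J, r)
    if np.max(np.abs(resid(pos))) > 1e-9:
        raise ValueError(
            f"voltages ({Vx}, {Vy}) outside the invertible range of the map")
    if noise_sd > 0:
        pos = pos + np.random.default_rng(seed).normal(0.0, noise_sd, 2)
    return float(pos[0]), float(pos[1])
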