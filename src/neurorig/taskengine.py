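"""Declarative task specification, validation, ordering and execution.

A task describes one synchronized episodic acquisition as a mapping with a
``protocol`` block (duration, storeData, continuous) plus one block per
participating device, e.g.::

    protocol: {duration: 0.1, storeData: false, continuous: false}
    DAQ:     {rate: 40e3, numPts: 4e3, triggerDevice: Camera}
    Clamp1:  {mode: 'I=0', primary: {record: true}}
    Camera:  {record: true, triggerMode: 'Normal',
              channels: {exposure: {record: true}}}

The engine only interprets the protocol block; each device interprets its
own command block.  Execution reserves all participating devices
atomically, configures them in an order satisfying declared
configure-before preferences (ties broken by descending trigger-arming
latency, so slow-arming devices are configured early), then starts them so
that every device waiting on a hardware trigger is armed before its trigger
source starts.  Results come back keyed by device name.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml

from neurorig.rig import RigConfig
from neurorig.signals import Trace
from neurorig.simdevices import (CellModel, DeviceRegistry, sim_camera_acquire,
                                 sim_clamp_response, sim_lif_response)

__all__ = [
    "TaskError",
    "TaskSpec",
    "SequenceSpec",
    "TaskResult",
    "Manager",
    "build_waveform",
    "validate_task",
    "plan_orders",
    "load_task_spec",
]


class TaskError(ValueError):
    """Invalid task specification or execution failure."""


class SimulatedDeviceFailure(RuntimeError):
    """Raised by a device scripted (via ``fail_at`` config) to fail."""


# ---------------------------------------------------------------------------
# waveform descriptors


def build_waveform(desc, rate: float, n: int) -> np.ndarray:
    """Expand a waveform descriptor into a sample array of length ``n``.

    Descriptors are mappings with a ``type`` of ``square`` (pulse train:
    start, duration, amplitude, period, n_pulses, offset), ``ramp`` (start,
    duration, slope or amplitude, offset), ``sine`` (frequency, amplitude,
    phase_deg, offset) or ``array`` (explicit ``samples``).  A bare list or
    array is treated as explicit samples.
    """
    if isinstance(desc, (list, tuple, np.ndarray)):
        arr = np.asarray(desc, dtype=float)
        if len(arr) != n:
            raise TaskError(f"waveform length {len(arr)} != expected {n} samples")
        return arr
    kind = desc.get("type")
    t = np.arange(n) / rate
    offset = float(desc.get("offset", 0.0))
    if kind == "square":
        out = np.full(n, offset)
        start = float(desc.get("start", 0.0))
        dur = float(desc["duration"])
        amp = float(desc["amplitude"])
        period = float(desc.get("period", 0.0))
        npulse = int(desc.get("n_pulses", 1))
        for k in range(npulse):
            s = start + k * period
            out[(t >= s) & (t < s + dur)] += amp
        return out
    if kind == "ramp":
        start = float(desc.get("start", 0.0))
        dur = float(desc["duration"])
        amp = float(desc["amplitude"])
        out = np.full(n, offset)
        m = (t >= start) & (t < start + dur)
        out[m] += amp * (t[m] - start) / dur
        return out
    if kind == "sine":
        f = float(desc["frequency"])
        amp = float(desc["amplitude"])
        ph = np.radians(float(desc.get("phase_deg", 0.0)))
        return offset + amp * np.sin(2 * np.pi * f * t + ph)
    if kind == "array":
        return build_waveform(desc["samples"], rate, n)
    raise TaskError(f"unknown waveform type {kind!r}")


# ---------------------------------------------------------------------------
# specs


@dataclass
class TaskSpec:
    """Validated task: protocol plus per-device command blocks."""

    protocol: dict
    devices: dict  # name -> command block

    @property
    def duration(self) -> float:
        return float(self.protocol["duration"])


@dataclass
class SequenceSpec:
    """A base task plus ordered parameter axes (first axis outermost)."""

    base: dict
    axes: list  # of (device, parameter path (list of keys), list of values)


@dataclass
class TaskResult:
    data: dict = field(default_factory=dict)  # device -> result payload
    status: str = "completed"  # completed | aborted | failed
    error: str | None = None
    timing: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]


def load_task_spec(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# validation and ordering


def _trigger_edges(device_blocks: dict):
    """Edges (triggered_device -> trigger_source): triggered starts first."""
    edges = []
    for name, block in device_blocks.items():
        trig = block.get("triggerDevice") if isinstance(block, dict) else None
        if trig is not None:
            edges.append((name, trig))
    return edges


def validate_task(rig: RigConfig, spec: dict) -> TaskSpec:
    """Check a raw task mapping against the rig and normalize it.

    Resolves device names, fills DAQ rate/numPts defaults from the protocol
    duration, reconciles waveform lengths, and rejects trigger cycles and
    continuous acquisition (only short episodic tasks are supported).
    """
    if "protocol" not in spec:
        raise TaskError("task spec has no 'protocol' block")
    protocol = dict(spec["protocol"])
    duration = float(protocol.get("duration", 0.0))
    if duration <= 0:
        raise TaskError(f"protocol duration must be positive, got {duration}")
    if protocol.get("continuous"):
        raise TaskError("continuous acquisition is not supported "
                        "(episodic tasks only)")
    protocol.setdefault("storeData", False)
    protocol.setdefault("continuous", False)

    blocks = {}
    for name, block in spec.items():
        if name == "protocol":
            continue
        if name not in rig.devices:
            raise TaskError(f"task references unknown device {name!r}")
        blocks[name] = copy.deepcopy(block) if isinstance(block, dict) else {}

    # trigger references and cycles
    for name, block in blocks.items():
        trig = block.get("triggerDevice")
        if trig is not None and trig not in blocks:
            raise TaskError(f"device {name!r}: trigger source {trig!r} "
                            "not in task")
    _toposort(list(blocks), _trigger_edges(blocks), what="trigger")

    # DAQ defaults and waveform reconciliation
    for name, block in blocks.items():
        if rig.devices[name].kind == "daq":
            rate = float(block.get("rate",
                                   rig.devices[name].config.get("rate", 40e3)))
            npts = int(float(block.get("numPts", round(rate * duration))))
            if abs(npts - rate * duration) > 0.5:
                raise TaskError(
                    f"DAQ {name!r}: numPts {npts} inconsistent with rate "
                    f"{rate} Hz x duration {duration} s = {rate * duration:g}")
            block["rate"], block["numPts"] = rate, npts
    rate = _task_rate(rig, blocks, duration)
    n = int(round(rate * duration))
    for name, block in blocks.items():
        cmd = block.get("command")
        if isinstance(cmd, (list, tuple, np.ndarray)) and len(cmd) != n:
            raise TaskError(f"device {name!r}: command waveform length "
                            f"{len(cmd)} != {n} samples")
    return TaskSpec(protocol=protocol, devices=blocks)


def _task_rate(rig, blocks, duration) -> float:
    for name, block in blocks.items():
        if rig.devices[name].kind == "daq":
            return float(block["rate"])
    return 40e3


def _toposort(nodes, edges, what="ordering", priority=None):
    """Kahn topological sort of ``nodes`` under (before, after) ``edges``.

    ``priority(node)`` orders ready nodes (higher first); ties break by name
    for determinism.
    """
    succ = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for a, b in edges:
        succ[a].append(b)
        indeg[b] += 1
    ready = [n for n in nodes if indeg[n] == 0]
    order = []
    while ready:
        if priority:
            ready.sort(key=lambda n: (-priority(n), n))
        else:
            ready.sort()
        node = ready.pop(0)
        order.append(node)
        for nxt in succ[node]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                ready.append(nxt)
    if len(order) != len(nodes):
        cyclic = sorted(n for n in nodes if indeg[n] > 0)
        raise TaskError(f"{what} cycle involving {cyclic}")
    return order


def plan_orders(spec: TaskSpec, rig: RigConfig | None = None):
    """Compute (configure order, start order) for a validated task.

    Configure order: topological order of declared ``configure_before``
    preferences (rig device config), ties broken by descending declared
    ``arming_latency`` so slow-arming devices are configured earliest.
    Start order: every triggered device starts (arms) before its trigger
    source; free-running trigger masters start last.
    """
    names = list(spec.devices)

    def latency(n):
        if rig is not None and n in rig.devices:
            return float(rig.devices[n].config.get("arming_latency", 0.0))
        return 0.0

    cfg_edges = []
    if rig is not None:
        for n in names:
            for before in rig.devices[n].config.get("configure_before", []):
                if before in names:
                    cfg_edges.append((n, before))
    configure_order = _toposort(names, cfg_edges, what="configure preference",
                                priority=latency)

    trig_edges = _trigger_edges(spec.devices)
    sources = {b for _, b in trig_edges}
    start_order = _toposort(names, trig_edges, what="trigger",
                            priority=lambda n: 0 if n in sources else 1)
    return configure_order, start_order


# ---------------------------------------------------------------------------
# execution


class Manager:
    """Owns the rig, the device reservation registry, and task execution."""

    def __init__(self, rig: RigConfig, seed: int = 0, session=None,
                 scene=None):
        self.rig = rig
        self.registry = DeviceRegistry(rig.devices)
        self.seed = seed
        self.session = session  # datastore DirHandle for storeData tasks
        self.scene = scene  # default camera scene callable
        self._task_counter = 0
        self.clamp_mode: dict[str, str] = {}  # per-clamp current mode
        self.mode_log: dict[str, list] = {}  # per-clamp mode transition history

    # -- clamp mode safety ---------------------------------------------------
    def _switch_clamp_mode(self, name: str, new_mode: str):
        """Switch clamp mode, always passing through I=0 with zeroed holding."""
        cur = self.clamp_mode.get(name, "i0")
        log = self.mode_log.setdefault(name, [])
        if new_mode == cur:
            return
        if cur != "i0" and new_mode != "i0":
            log.append((cur, "i0", "holding zeroed"))
            cur = "i0"
        log.append((cur, new_mode, ""))
        self.clamp_mode[name] = new_mode

    def cell_model(self, clamp: str) -> CellModel:
        cfg = self.rig.devices[clamp].config.get("cell", {})
        return CellModel(
            Ra=float(cfg.get("Ra", 10e6)), Rm=float(cfg.get("Rm", 100e6)),
            Cm=float(cfg.get("Cm", 30e-12)),
            Vrest=float(cfg.get("Vrest", -65e-3)),
            holding_current=float(cfg.get("holding_current", 0.0)),
            noise_sd=float(cfg.get("noise_sd", 0.0)))

    # -- task API --------------------------------------------------------------
    def create_task(self, spec: dict) -> "Task":
        self._task_counter += 1
        return Task(self, validate_task(self.rig, spec),
                    task_id=f"task-{self._task_counter}")

    def execute_task(self, spec: dict, seed: int | None = None) -> TaskResult:
        """Validate, reserve, configure, start, run to completion, release."""
        task = self.create_task(spec)
        task.execute(seed=seed)
        while not task.is_done():
            pass
        return task.get_results()

    def run_sequence(self, seq: SequenceSpec, halt_on_error: bool = False):
        """Execute the base task at every point of the parameter grid.

        Returns an object array shaped by the axis lengths (first axis
        outermost); each cell is a TaskResult whose timing metadata records
        the parameter values applied at that point.
        """
        if not seq.axes:
            raise TaskError("sequence has no parameter axes")
        shape = tuple(len(vals) for _, _, vals in seq.axes)
        out = np.empty(shape, dtype=object)
        for idx in itertools.product(*(range(s) for s in shape)):
            spec = copy.deepcopy(seq.base)
            point_params = {}
            for (device, path, values), i in zip(seq.axes, idx):
                _set_path(spec, [device, *path], values[i])
                point_params[f"{device}." + ".".join(map(str, path))] = values[i]
            spec.setdefault("protocol", {})["parameters"] = point_params
            lin = int(np.ravel_multi_index(idx, shape))
            try:
                res = self.execute_task(spec, seed=self.seed + lin)
            except Exception as exc:  # record and continue unless halting
                if halt_on_error:
                    raise
                res = TaskResult(status="failed", error=str(exc))
            res.timing["sequence_index"] = idx
            res.timing["parameters"] = point_params
            out[idx] = res
        return out


def _set_path(d: dict, path, value):
    node = d
    for key in path[:-1]:
        if key not in node or not isinstance(node[key], dict):
            node[key] = {}
        node = node[key]
    node[path[-1]] = value


class Task:
    """One reserved, configured, runnable acquisition.

    Mirrors the poll/abort contract: ``execute()`` reserves and starts,
    ``is_done()`` advances a simulated clock by the 10 ms polling interval,
    ``stop(abort=True)`` aborts (devices stopped in reverse start order) and
    ``get_results()`` returns the per-device payload.
    """

    POLL_INTERVAL = 0.010  # seconds of simulated time per poll

    def __init__(self, manager: Manager, spec: TaskSpec, task_id: str):
        self.manager = manager
        self.spec = spec
        self.task_id = task_id
        self.configure_order, self.start_order = plan_orders(spec, manager.rig)
        self.start_log: list[str] = []
        self.stop_log: list[str] = []
        self._reservation = None
        self._clock = 0.0
        self._result: TaskResult | None = None
        self._started = False
        self.timeout = float(spec.protocol.get(
            "timeout", 10.0 * spec.duration + 5.0))

    # -- lifecycle -----------------------------------------------------------
    def execute(self, seed: int | None = None):
        seed = self.manager.seed if seed is None else seed
        mgr = self.manager
        self._reservation = mgr.registry.reserve(
            self.spec.devices, owner=self.task_id,
            timeout=self.spec.protocol.get("reserve_timeout", 30.0))
        try:
            for name in self.configure_order:
                self._check_scripted_failure(name, "configure")
            for name in self.start_order:
                self._check_scripted_failure(name, "start")
                self.start_log.append(name)
            self._results_payload = self._run_devices(seed)
            self._started = True
        except Exception as exc:
            self.stop_log = list(reversed(self.start_log))
            self._result = TaskResult(status="failed", error=str(exc),
                                      timing={"start_order": self.start_log})
            self._release()

    def _check_scripted_failure(self, name, stage):
        if self.manager.rig.devices[name].config.get("fail_at") == stage:
            raise SimulatedDeviceFailure(f"device {name!r} failed at {stage}")

    def is_done(self) -> bool:
        if self._result is not None:
            return True
        self._clock += self.POLL_INTERVAL
        if self._clock > self.timeout:
            self.stop_log = list(reversed(self.start_log))
            self._result = TaskResult(status="failed", error="completion timeout")
            self._release()
            return True
        if self._clock >= self.spec.duration:
            self._finish()
            return True
        return False

    def stop(self, abort: bool = False):
        if self._result is not None:
            return
        if abort:
            self.stop_log = list(reversed(self.start_log))
            self._result = TaskResult(
                status="aborted",
                timing={"start_order": self.start_log,
                        "stop_order": self.stop_log})
            self._release()
        else:
            self._finish()

    def get_results(self) -> TaskResult:
        if self._result is None:
            self._finish()
        return self._result

    def _finish(self):
        if self._result is not None:
            return
        self._result = TaskResult(
            data=self._results_payload, status="completed",
            timing={"configure_order": self.configure_order,
                    "start_order": self.start_order,
                    "duration": self.spec.duration})
        if self.spec.protocol.get("storeData") and self.manager.session is not None:
            from neurorig.datastore import store_task_result
            store_task_result(self.manager.session, self.spec, self._result)
        self._release()

    def _release(self):
        if self._reservation is not None:
            self._reservation.release()
            self._reservation = None

    # -- simulated acquisition -------------------------------------------------
    def _run_devices(self, seed: int) -> dict:
        mgr = self.manager
        rig = mgr.rig
        duration = self.spec.duration
        rate = _task_rate(rig, self.spec.devices, duration)
        n = int(round(rate * duration))
        payload: dict = {}
        for name, block in self.spec.devices.items():
            kind = rig.devices[name].kind
            dev_seed = (seed + hash(name) % 10007) % (2 ** 31)
            if kind == "daq":
                payload[name] = {"rate": rate, "numPts": n,
                                 "triggerDevice": block.get("triggerDevice")}
            elif kind == "clamp":
                payload[name] = self._run_clamp(name, block, rate, n, dev_seed)
            elif kind == "camera":
                payload[name] = self._run_camera(name, block, duration,
                                                 rate, dev_seed)
            elif kind in ("daqgeneric", "laser", "scanner"):
                out = {}
                if "command" in block:
                    out["command"] = Trace(
                        build_waveform(block["command"], rate, n), rate,
                        units=block.get("units", ""), channel=name)
                if kind == "scanner" and "position" in block:
                    out["position"] = tuple(block["position"])
                payload[name] = out
            else:
                payload[name] = {}
        return payload

    def _run_clamp(self, name, block, rate, n, seed) -> dict:
        mgr = self.manager
        mode = str(block.get("mode", "i0")).lower().replace(" ", "")
        mode = {"i=0": "i0"}.get(mode, mode)
        if mode not in ("vc", "ic", "i0"):
            raise TaskError(f"clamp {name!r}: unknown mode {block.get('mode')!r}")
        mgr._switch_clamp_mode(name, mode)
        cell = mgr.cell_model(name)
        units = {"vc": "V", "ic": "A", "i0": "A"}[mode]
        cmd_desc = block.get("command")
        if cmd_desc is None:
            cmd = np.full(n, float(block.get("holding", 0.0)))
        else:
            cmd = build_waveform(cmd_desc, rate, n)
        cmd_trace = Trace(cmd, rate, units=units, channel=f"{name}.command")
        if mode == "ic" and block.get("spiking"):
            primary = sim_lif_response(cell, cmd_trace, rate, seed=seed)
        else:
            primary = sim_clamp_response(cell, cmd_trace, mode, rate, seed=seed)
        out = {"mode": mode}
        prim_block = block.get("primary", {})
        if not isinstance(prim_block, dict) or prim_block.get("record", True):
            out["primary"] = primary
        if block.get("record_command", False):
            out["command"] = cmd_trace
        return out

    def _run_camera(self, name, block, duration, rate, seed) -> dict:
        mgr = self.manager
        cfg = mgr.rig.devices[name].config
        interval = float(block.get("interval", cfg.get("interval", 0.020)))
        exposure = float(block.get("exposure", cfg.get("exposure",
                                                       0.8 * interval)))
        n_frames = int(block.get("n_frames", max(1, int(duration / interval))))
        tmode = str(block.get("triggerMode", "Normal")).lower()
        frames, ttl = sim_camera_acquire(
            mgr.rig, name, n_frames=n_frames, exposure=exposure,
            interval=interval,
            trigger_mode="triggered" if tmode == "triggered" else "normal",
            scene=block.get("scene", mgr.scene), seed=seed,
            ttl_rate=rate, ttl_duration=duration)
        out = {}
        if block.get("record", True):
            out["frames"] = frames
        channels = block.get("channels", {})
        if channels.get("exposure", {}).get("record"):
            out["exposure"] = ttl
        return out
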