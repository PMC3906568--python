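"""Rig configuration and the optomechanical coordinate hierarchy.

Every device on the rig (stage, microscope, camera, scanner, ...) owns an
affine transform relating its local coordinate frame to its parent's frame.
Chaining transforms up the hierarchy yields the mapping between any device
and the global sample frame, so that images, photostimulation sites and
stage positions can all be expressed in common physical coordinates
(meters).  Conventions: 4x4 homogeneous matrices, column vectors, transform
applied on the left; camera pixels are 0-based (x=column, y=row) with pixel
centers at integer coordinates; a microscope objective contributes
``translate(offset) @ scale`` (offset expressed post-scale, in meters).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Transform3D",
    "DeviceNode",
    "Objective",
    "RigConfig",
    "RigConfigError",
    "load_rig_config",
    "parse_quantity",
]


class RigConfigError(ValueError):
    """Raised for invalid rig configurations (cycles, bad references...)."""


# ---------------------------------------------------------------------------
# unit handling

_UNIT_SCALE = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6,
    "V": 1.0, "mV": 1e-3, "uV": 1e-6,
    "A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9, "pA": 1e-12,
    "Ohm": 1.0, "kOhm": 1e3, "MOhm": 1e6, "GOhm": 1e9,
    "F": 1.0, "uF": 1e-6, "nF": 1e-9, "pF": 1e-12,
    "W": 1.0, "mW": 1e-3, "uW": 1e-6,
    "J": 1.0, "mJ": 1e-3, "uJ": 1e-6,
    "Hz": 1.0, "kHz": 1e3, "MHz": 1e6,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ]+)?\s*$")


def parse_quantity(value) -> float:
    """Normalize a config scalar to SI units.

    Accepts plain numbers or strings like ``"100 um"``, ``"10 MOhm"``,
    ``"40 kHz"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        m = _QUANTITY_RE.match(value)
        if m:
            num, unit = m.groups()
            try:
                x = float(num)
            except ValueError:
                raise RigConfigError(f"cannot parse quantity {value!r}") from None
            if unit is None:
                return x
            if unit not in _UNIT_SCALE:
                raise RigConfigError(f"unknown unit {unit!r} in {value!r}")
            return x * _UNIT_SCALE[unit]
    raise RigConfigError(f"cannot parse quantity {value!r}")


# ---------------------------------------------------------------------------
# transforms


class Transform3D:
    """An invertible 3D affine transform stored as a 4x4 homogeneous matrix."""

    def __init__(self, matrix=None):
        if matrix is None:
            matrix = np.eye(4)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got shape {matrix.shape}")
        # scale-relative singularity test: micron-per-pixel transforms have
        # tiny absolute determinants but are perfectly well conditioned
        if not np.all(np.isfinite(matrix)):
            raise ValueError("transform matrix must be finite")
        sv = np.linalg.svd(matrix[:3, :3], compute_uv=False)
        if sv[-1] <= 1e-12 * sv[0]:
            raise ValueError("linear part of transform is singular")
        self.matrix = matrix

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "Transform3D":
        return cls()

    @classmethod
    def from_parts(cls, offset=(0, 0, 0), scale=(1, 1, 1), angle_deg=0.0) -> "Transform3D":
        """translate(offset) @ rotate_z(angle) @ scale -- offset post-scale."""
        sx, sy, sz = scale
        m = np.eye(4)
        c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
        m[:3, :3] = np.array([[c * sx, -s * sy, 0.0],
                              [s * sx, c * sy, 0.0],
                              [0.0, 0.0, sz]])
        m[:3, 3] = offset
        return cls(m)

    @classmethod
    def translation(cls, offset) -> "Transform3D":
        m = np.eye(4)
        m[:3, 3] = offset
        return cls(m)

    # -- algebra -----------------------------------------------------------
    def compose(self, other: "Transform3D") -> "Transform3D":
        """self after other: (self @ other)(p) = self(other(p))."""
        return Transform3D(self.matrix @ other.matrix)

    __matmul__ = compose

    def inverse(self) -> "Transform3D":
        return Transform3D(np.linalg.inv(self.matrix))

    def map(self, point) -> np.ndarray:
        """Apply the transform to a 3-vector (or (n, 3) array of points)."""
        p = np.asarray(point, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite coordinates")
        single = p.ndim == 1
        p = np.atleast_2d(p)
        ph = np.hstack([p, np.ones((len(p), 1))])
        out = (self.matrix @ ph.T).T[:, :3]
        return out[0] if single else out

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()

    def __repr__(self):
        return f"Transform3D(offset={self.offset}, det={np.linalg.det(self.matrix[:3, :3]):.3g})"


# ---------------------------------------------------------------------------
# devices

DEVICE_KINDS = {"daq", "clamp", "camera", "scanner", "laser", "stage",
                "microscope", "daqgeneric"}


@dataclass
class Objective:
    """One objective lens: per-slot optical scale (m/px) and offset (m)."""

    name: str
    slot: int
    scale: tuple  # (sx, sy) meters per pixel
    offset: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not all(s > 0 for s in self.scale):
            raise RigConfigError(f"objective {self.name!r}: scale must be positive")

    def transform(self) -> Transform3D:
        sx, sy = self.scale
        return Transform3D.from_parts(offset=self.offset, scale=(sx, sy, 1.0))


@dataclass
class DeviceNode:
    """One device in the optomechanical hierarchy."""

    name: str
    kind: str
    parent: str | None = None
    local_transform: Transform3D = field(default_factory=Transform3D.identity)
    connections: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)  # kind-specific settings

    def __post_init__(self):
        if self.kind not in DEVICE_KINDS:
            raise RigConfigError(f"device {self.name!r}: unknown kind {self.kind!r}")


class RigConfig:
    """The validated rig: device forest plus per-kind settings.

    Mutating operations (:meth:`move_stage`, :meth:`set_objective`) update a
    device's local transform in place; global transforms are always computed
    on demand from the current state.
    """

    def __init__(self, devices: list[DeviceNode]):
        self.devices: dict[str, DeviceNode] = {}
        for dev in devices:
            if dev.name in self.devices:
                raise RigConfigError(f"duplicate device name {dev.name!r}")
            self.devices[dev.name] = dev
        self._objectives: dict[str, dict[int, dict[str, Objective]]] = {}
        self._active_slot: dict[str, int] = {}
        self._active_objective: dict[str, str] = {}
        self._listeners: list = []
        self._validate()

    # -- validation --------------------------------------------------------
    def _validate(self):
        for dev in self.devices.values():
            if dev.parent is not None and dev.parent not in self.devices:
                raise RigConfigError(
                    f"device {dev.name!r}: unknown parent {dev.parent!r}")
        # forest check: walk each chain with a visited set
        for dev in self.devices.values():
            seen = set()
            node = dev
            while node.parent is not None:
                if node.name in seen:
                    raise RigConfigError(
                        f"cycle in device hierarchy at {node.name!r}")
                seen.add(node.name)
                node = self.devices[node.parent]
        # connection references must name existing DAQ devices
        daqs = {n for n, d in self.devices.items() if d.kind == "daq"}
        for dev in self.devices.values():
            for ch, conn in dev.connections.items():
                if conn.get("daq") not in daqs:
                    raise RigConfigError(
                        f"device {dev.name!r} channel {ch!r}: dangling DAQ "
                        f"reference {conn.get('daq')!r}")

    # -- lookup ------------------------------------------------------------
    def device(self, name: str) -> DeviceNode:
        try:
            return self.devices[name]
        except KeyError:
            raise RigConfigError(f"unknown device {name!r}") from None

    def parent_chain(self, name: str) -> list[str]:
        """Ancestors of *name*, nearest first."""
        chain = []
        node = self.device(name)
        while node.parent is not None:
            chain.append(node.parent)
            node = self.devices[node.parent]
        return chain

    def descendants(self, name: str) -> set[str]:
        self.device(name)
        out = set()
        frontier = {name}
        while frontier:
            frontier = {d.name for d in self.devices.values()
                        if d.parent in frontier}
            out |= frontier
        return out

    # -- coordinate mapping -------------------------------------------------
    def global_transform(self, name: str) -> Transform3D:
        """Local-to-global transform: product of local transforms up to root."""
        dev = self.device(name)
        t = dev.local_transform
        for anc in self.parent_chain(name):
            t = self.devices[anc].local_transform @ t
        return t

    def map_point(self, name: str, point, direction: str = "to_global") -> np.ndarray:
        t = self.global_transform(name)
        if direction == "to_global":
            return t.map(point)
        elif direction == "to_local":
            return t.inverse().map(point)
        raise ValueError(f"direction must be to_global|to_local, got {direction!r}")

    # -- state changes -------------------------------------------------------
    def register_objectives(self, microscope: str, objectives: list[Objective]):
        dev = self.device(microscope)
        if dev.kind != "microscope":
            raise RigConfigError(f"{microscope!r} is not a microscope")
        table = self._objectives.setdefault(microscope, {})
        for obj in objectives:
            table.setdefault(obj.slot, {})[obj.name] = obj

    def set_objective(self, microscope: str, slot: int, objective: str):
        """Switch the active objective; updates the microscope transform."""
        table = self._objectives.get(microscope)
        if not table or slot not in table:
            raise RigConfigError(f"{microscope!r}: unknown objective slot {slot}")
        if objective not in table[slot]:
            raise RigConfigError(
                f"{microscope!r} slot {slot}: unknown objective {objective!r}")
        obj = table[slot][objective]
        self.device(microscope).local_transform = obj.transform()
        self._active_slot[microscope] = slot
        self._active_objective[microscope] = objective
        for fn in self._listeners:
            fn("objective_changed", microscope, objective)

    def active_objective(self, microscope: str) -> str | None:
        return self._active_objective.get(microscope)

    def move_stage(self, stage: str, position):
        """Set the stage's local translation (meters, absolute)."""
        dev = self.device(stage)
        if dev.kind != "stage":
            raise RigConfigError(f"{stage!r} is not a stage device")
        position = np.asarray(position, dtype=float)
        if position.shape != (3,) or not np.all(np.isfinite(position)):
            raise ValueError("stage position must be a finite 3-vector")
        m = dev.local_transform.matrix.copy()
        m[:3, 3] = position
        dev.local_transform = Transform3D(m)
        for fn in self._listeners:
            fn("stage_moved", stage, tuple(position))

    def stage_position(self, stage: str) -> np.ndarray:
        return self.device(stage).local_transform.offset

    def add_listener(self, fn):
        """Register a callback(event, device, detail) for state changes."""
        self._listeners.append(fn)


# ---------------------------------------------------------------------------
# config file loading


def _parse_transform(block: dict | None) -> Transform3D:
    if not block:
        return Transform3D.identity()
    offset = [parse_quantity(v) for v in block.get("offset", [0, 0, 0])]
    scale = [parse_quantity(v) for v in block.get("scale", [1, 1, 1])]
    if len(offset) == 2:
        offset = [*offset, 0.0]
    if len(scale) == 2:
        scale = [*scale, 1.0]
    angle = float(block.get("angle_deg", 0.0))
    return Transform3D.from_parts(offset=offset, scale=scale, angle_deg=angle)


def load_rig_config(path) -> RigConfig:
    """Load and validate a rig configuration from a YAML (or JSON) file.

    The file holds a top-level ``devices:`` list; each entry gives ``name``,
    ``kind``, optional ``parent``, ``transform`` (offset/scale/angle_deg),
    ``connections`` mapping channel names to DAQ ports, and kind-specific
    blocks (``objectives:`` for microscopes, simulation parameters for
    simulated devices).
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise RigConfigError(f"cannot parse rig config {path}: {exc}") from exc
    return rig_from_dict(doc, source=str(path))


def rig_from_dict(doc: dict, source: str = "<dict>") -> RigConfig:
    if not isinstance(doc, dict) or "devices" not in doc:
        raise RigConfigError(f"{source}: expected a mapping with a 'devices' list")
    nodes = []
    objective_blocks = {}
    for entry in doc["devices"]:
        name = entry.get("name")
        if not name:
            raise RigConfigError(f"{source}: device entry missing 'name'")
        if entry.get("parent") == name:
            raise RigConfigError(f"cycle in device hierarchy at {name!r}")
        kind = entry.get("kind", "")
        node = DeviceNode(
            name=name,
            kind=kind,
            parent=entry.get("parent"),
            local_transform=_parse_transform(entry.get("transform")),
            connections=entry.get("connections", {}) or {},
            config={k: v for k, v in entry.items()
                    if k not in {"name", "kind", "parent", "transform",
                                 "connections", "objectives"}},
        )
        nodes.append(node)
        if "objectives" in entry:
            objective_blocks[name] = entry["objectives"]
    rig = RigConfig(nodes)
    for mic, objs in objective_blocks.items():
        parsed = []
        for o in objs:
            scale = [parse_quantity(v) for v in o["scale"]]
            offset = [parse_quantity(v) for v in o.get("offset", [0, 0, 0])]
            if len(offset) == 2:
                offset = [*offset, 0.0]
            parsed.append(Objective(name=o["name"], slot=int(o.get("slot", 0)),
                                    scale=tuple(scale), offset=tuple(offset)))
        rig.register_objectives(mic, parsed)
        active = [o for o in objs if o.get("active")]
        if active:
            rig.set_objective(mic, int(active[0].get("slot", 0)), active[0]["name"])
    return rig
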