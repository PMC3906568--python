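"""A self-contained demonstration rig and example tasks.

The demo hierarchy mirrors a typical patch-clamp + imaging setup:
stage -> microscope -> {camera, scanner}, with a DAQ, a clamp amplifier
channel connected to a simulated passive cell, and a photostimulation
laser.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from neurorig.rig import RigConfig, load_rig_config, rig_from_dict

__all__ = ["demo_rig_dict", "example_task_dict", "test_pulse_task_dict",
           "build_demo_rig", "gaussian_scene"]

DEMO_TRUE_SCANNER_MAP = (
    # ground-truth quadratic voltage map, positions in meters
    (2.0e4, -1.0e4, 3.0e3, 5.0e2, -1.2),
    (1.5e4, 2.5e4, 4.0e2, 2.8e3, 0.7),
)


def demo_rig_dict(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    cell = {
        "Ra": float(rng.uniform(8e6, 15e6)),
        "Rm": float(rng.uniform(80e6, 200e6)),
        "Cm": float(rng.uniform(20e-12, 50e-12)),
        "Vrest": -65e-3,
        "noise_sd": 0.0,
    }
    return {
        "devices": [
            {"name": "Stage", "kind": "stage",
             "transform": {"offset": [0, 0, 0]}},
            {"name": "Scope", "kind": "microscope", "parent": "Stage",
             "objectives": [
                 {"name": "5x", "slot": 0, "scale": ["2 um", "2 um"],
                  "offset": [0, 0], "active": True},
                 {"name": "63x", "slot": 1,
                  "scale": ["0.159 um", "0.159 um"], "offset": [0, 0]},
             ]},
            {"name": "Camera", "kind": "camera", "parent": "Scope",
             "sensor_shape": [32, 32], "interval": 0.020, "exposure": 0.015,
             "arming_latency": 0.05,
             "connections": {"exposure": {"daq": "DAQ", "port": "di0",
                                          "type": "di"}}},
            {"name": "Scanner", "kind": "scanner", "parent": "Scope",
             "true_map": [list(DEMO_TRUE_SCANNER_MAP[0]),
                          list(DEMO_TRUE_SCANNER_MAP[1])],
             "connections": {"vx": {"daq": "DAQ", "port": "ao2", "type": "ao"},
                             "vy": {"daq": "DAQ", "port": "ao3", "type": "ao"}}},
            {"name": "DAQ", "kind": "daq", "rate": 40e3},
            {"name": "Clamp1", "kind": "clamp", "cell": cell,
             "connections": {
                 "primary": {"daq": "DAQ", "port": "ai0", "type": "ai"},
                 "command": {"daq": "DAQ", "port": "ao0", "type": "ao"}}},
            {"name": "Laser", "kind": "laser", "output_power": 0.020,
             "attenuation": {"5x": 0.5, "63x": 0.1}},
        ]
    }


def example_task_dict() -> dict:
    """100 ms simultaneous clamp + camera recording, camera as trigger master."""
    return {
        "protocol": {"storeData": False, "continuous": False, "duration": 0.1},
        "DAQ": {"rate": 40e3, "numPts": 4e3, "triggerDevice": "Camera"},
        "Clamp1": {"mode": "I=0", "primary": {"mode": "MembranePotential",
                                              "record": True}},
        "Camera": {"record": True, "triggerMode": "Normal",
                   "channels": {"exposure": {"record": True}}},
    }


def test_pulse_task_dict(amplitude: float = -10e-3, duration: float = 0.2,
                         pulse_start: float = 0.05,
                         pulse_len: float = 0.1) -> dict:
    """A voltage-clamp test pulse for membrane-property estimation."""
    return {
        "protocol": {"storeData": True, "continuous": False,
                     "duration": duration},
        "DAQ": {"rate": 100e3},
        "Clamp1": {"mode": "vc", "record_command": True,
                   "command": {"type": "square", "start": pulse_start,
                               "duration": pulse_len,
                               "amplitude": amplitude, "offset": 0.0},
                   "primary": {"record": True}},
    }


def gaussian_scene(center=(20e-6, 20e-6), sigma: float = 10e-6,
                   amplitude: float = 100.0, background: float = 10.0):
    """An analytic scene: one Gaussian fluorescent spot in global coordinates."""
    cx, cy = center

    def scene(x, y):
        return background + amplitude * np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2))

    return scene


def build_demo_rig(out_dir, seed: int = 0) -> RigConfig:
    """Write the demo rig and example task specs, return the loaded rig."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rig_doc = demo_rig_dict(seed)
    with open(out / "rig.yaml", "w") as fh:
        yaml.safe_dump(rig_doc, fh, sort_keys=False)
    with open(out / "example_task.yaml", "w") as fh:
        yaml.safe_dump(example_task_dict(), fh, sort_keys=False)
    with open(out / "test_pulse_task.yaml", "w") as fh:
        yaml.safe_dump(test_pulse_task_dict(), fh, sort_keys=False)
    return load_rig_config(out / "rig.yaml")


def demo_rig(seed: int = 0) -> RigConfig:
    """The demo rig as an in-memory object (no files written)."""
    return rig_from_dict(demo_rig_dict(seed))
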