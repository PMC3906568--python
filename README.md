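# neurorig

A simulation-backed engine for multi-device neurophysiology experiments:
coordinate-aware rig modeling, synchronized task execution against simulated
hardware, scanner calibration, and the standard analyses of patch-clamp and
imaging data — with no hardware required.

## The problem

A patch-clamp / imaging rig is a hierarchy of devices — stage, microscope,
objectives, camera, scan mirrors, amplifiers, DAQ — that must agree on three
hard things:

1. **Where everything is.** Every pixel and every scan-mirror voltage must map
   to the same physical coordinate system, through a chain of transforms that
   changes whenever the stage moves or the objective is switched.
2. **When everything happens.** A single recording involves several devices
   that must start in an order compatible with their hardware trigger wiring,
   hold exclusive access to shared hardware, and produce synchronized,
   timestamped data.
3. **What the data mean.** Raw traces and frames only become results through
   quantitative analysis: access/membrane resistance and capacitance from test
   pulses, synaptic event detection, ΔF/F, photostimulation map statistics.

`neurorig` implements all three layers against *simulated* devices with known
ground truth — an RC-circuit cell model, a scene-rendering camera, a scanner
with a hidden quadratic voltage map — so every part of the acquisition and
analysis chain can be tested quantitatively, end to end.

## Worked example

Generate a demo rig (stage → microscope → {camera, scanner}, DAQ, patch
amplifier with a randomized cell, laser) and run the bundled example task —
a 100 ms recording in which the DAQ is hardware-triggered by the camera while
the amplifier records in I=0 mode:

```bash
$ neurorig --seed 0 demo --out rig
$ neurorig --seed 0 task run rig/example_task.yaml --rig rig/rig.yaml
{
  "status": "completed",
  "devices": [
    "Camera",
    "Clamp1",
    "DAQ"
  ],
  "start_order": [
    "Clamp1",
    "DAQ",
    "Camera"
  ],
  "Clamp1.primary": "trace: 4000 samples @ 40000 Hz (0.1 s, V)",
  "Camera.frames": "frames: 5 x (32, 32)",
  "Camera.exposure": "trace: 4000 samples @ 40000 Hz (0.1 s, V)"
}
```

Note the start order: the DAQ is triggered by the camera, so it is armed
*before* the camera starts — the engine derives this from the task's trigger
declarations.

Run a voltage-clamp test pulse, store it in a session, and recover the cell's
electrical properties from the stored data:

```bash
$ neurorig --seed 0 task run rig/test_pulse_task.yaml --rig rig/rig.yaml --out session
$ neurorig analyze patch session/run
{
  "Rin": 124833137.4629146,
  "Raccess": 12458731.81125007,
  "Rm": 112374405.65166453,
  "Cm": 2.122920571808604e-11,
  "tau": 0.00023809216527952045,
  "holding_current": 0.0,
  "fit_residual": 2.133137208645797e-25
}
```

The demo rig's ground-truth cell (written into `rig/rig.yaml`) is
Ra = 12458731.811 Ω, Rm = 112374405.652 Ω, Cm = 21.229 pF — the analysis
recovers all three to ~12 significant digits from the simulated recording.

Calibrate the scan mirrors against the simulator's hidden quadratic voltage
map (noise-free, then with 1 µm spot-observation noise):

```bash
$ neurorig --seed 0 calibrate scanner --rig rig/rig.yaml --grid 5 --out cal.json
{
  "key": "Laser/5x",
  "fit_residual_V": 4.053454519487839e-16,
  "n_samples": 25
}
$ neurorig --seed 0 calibrate scanner --rig rig/rig.yaml --grid 5 --noise 1e-6 --out cal_noisy.json
{
  "key": "Laser/5x",
  "fit_residual_V": 0.002989672641849547,
  "n_samples": 25
}
```

Other entry points: `task sequence` (parameter grids), `analyze iv`,
`analyze events`, `analyze map`, `analyze calcium`, `mosaic compose`. The same
functionality is available as a library (`neurorig.rig`, `.taskengine`,
`.scanner`, `.ephys`, `.imaging`, `.datastore`); see `docs/methods.md` for the
models and numerical methods.

## Reproduction

All randomness flows from a single seed. To reproduce the acceptance
quantities:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This executes the worked-example task, scanner-calibration recovery (noise-free
and noisy), membrane-property recovery over 200 random cells, event-detection
operating characteristics at SNR 10, map-classifier calibration over 500 null
maps, trigger-ordering and transform round-trip sweeps (1000 random cases
each), frame-timing recovery and a datastore consistency check, and writes the
resulting quantities as JSON. Rerunning with the same `--seed` reproduces every
value exactly; the full run takes a few seconds.

The test suite (`pytest -q tests/`) covers the same ground plus per-module
unit and property-based tests; `tests/test_acceptance.py` asserts the
quantitative tolerances.
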