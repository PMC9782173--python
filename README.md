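# insolekit

Simulation and analysis toolkit for a 16-sensor capacitive smart insole.

The package models the full measurement chain in software:

* **`sensor_model`** — physics/signal model of one capacitive pressure
  sensor: two-layer series-dielectric capacitance, linear pressure →
  relative-capacitance transduction (1.19 MPa⁻¹ bare, 0.55 MPa⁻¹ in-insole)
  with a hysteretic unloading branch (DH = 9.8%), asymmetric first-order
  response dynamics (142 ms rise / 160 ms recovery at the 10–90% criterion)
  and seeded measurement noise.
* **`rig_simulator`** — loading-rig protocols: the 15-level calibration
  staircase (41.5–872.4 kPa in 59.35 kPa steps), constant-pressure square
  waves at 30–70 steps/min, long durability runs and quasi-static
  triangular hysteresis ramps.
* **`gait_simulator`** — synthetic 16-channel plantar-pressure frames over
  repeated gait cycles with ground-truth phase labels (heel strike → foot
  flat → midstance → heel off → toe off → swing) and a shipped sensor
  layout on a 250 mm × 85 mm (EU 39) outline.
* **`characterization`** — staircase cycle amplitudes, OLS sensitivity and
  linearity, degree of hysteresis (trapezoidal loop areas), 10–90% /
  90–10% threshold-crossing response/recovery times, loading-frequency
  invariance and baseline/peak drift.
* **`gait_pipeline`** — capacitance → pressure calibration with LoD
  flagging, center-of-pressure trajectories, the 227-cell display grid with
  its ten-level 0–450 kPa color scale, rule-based gait-phase segmentation
  and per-zone peak summaries.
* **`io_cli` / `cli`** — CSV/JSON readers and writers plus the command-line
  interface.

## Command line

A single entry point `insolekit` exposes five subcommands:

```bash
# simulated rig recording (capacitance CSV + sidecar, protocol JSON)
insolekit simulate-rig --protocol staircase --out trace.csv --protocol-out proto.json

# characterization report from a trace/protocol pair
insolekit characterize --trace trace.csv --protocol proto.json --out report.json

# synthetic gait recording (wide frames CSV with ground-truth labels)
insolekit simulate-gait --out frames.csv --n-cycles 3

# segmentation + CoP + zone summary + heatmap snapshot
insolekit analyze-gait --frames frames.csv --out-dir analysis/

# full default pipeline, one JSON of headline metrics
insolekit report --seed 0 --out report.json
```

Formats: trace CSV is `time_s,value` with a JSON metadata sidecar of the
same stem; frames CSV is `time_s,T1,…,H3[,phase]`; layouts, protocols,
gait specs and reports are versioned JSON.

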