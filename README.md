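# funkam

Functional joint calibration and external knee adduction moment estimation
for robotic leg-press training, in pure scientific Python.

## The problem

The external knee adduction moment (EAM) — the frontal-plane component of
the intersegmental knee moment, adduction-positive — is the standard
surrogate for medial-compartment knee load and the quantity a knee-loading
training device must estimate online. It is notoriously sensitive to the
orientation of the knee's adduction–abduction axis: the frontal-plane lever
arms are small, so a joint axis misaligned by a few degrees leaks a slice of
the large sagittal (flexion) moment into the frontal plane, easily changing
the EAM's magnitude and even its sign.

`funkam` implements a full marker-based pipeline for leg-press exercise
that addresses this with *functionally* determined joint parameters:

* **OCST** — optimal common shape technique: alternating Procrustes
  estimation of each marker cluster's rigid common shape, suppressing
  soft-tissue artifact before any joint fitting;
* **SCoRE** — the hip joint center as the point simultaneously fixed in the
  pelvis and thigh frames, solved as one stacked linear least-squares system
  over a StarArc reference movement;
* **SARA** — the knee/ankle flexion axes as the near-null singular direction
  of the same stacked system over active flexion sweeps;
* joint coordinate systems built from the functional axis `z` and the
  segment line (knee: `x = ẑ×û`, `û` from KJC to HJC; `y = ẑ×x̂`);
* a generic **7-segment / 18-DOF** unilateral lower-extremity model
  (pelvis, torso, thigh, shank, talus, calcaneus, toes; 6-DOF pelvis, ball
  hips/torso, 3-rotation knee, hinge ankle/subtalar/toe joints), scaled to
  the subject from the functional joint centers;
* three ways of using the calibration: **CON** (conventional scaling,
  generic axis orientations), **FUN 1** (reorient only the proximal
  femur/tibia joint frames to the functional axes) and **FUN 2** (reorient
  proximal and distal frames), all evaluated against **REF**, a model-free
  standard that computes moments directly from the transferred functional
  frames;
* weighted Gauss–Newton **inverse kinematics** on an analytic marker
  Jacobian, zero-lag 4th-order Butterworth filtering (6 Hz), and recursive
  **Newton–Euler inverse dynamics** with the plate wrench applied at its
  center of pressure; moments are reported in N·m and normalized to %BWHt
  (100·M / m·g·h);
* a frame-by-frame **real-time mode** (warm-started IK → EMA filter with
  α = 0.1525 → backward differences → one ID evaluation) with deadline
  accounting against the 8 ms robot-control step;
* a seedable **synthetic-data generator** that renders reference movements
  and leg-press trials from a subject with fully known model, axis tilts and
  ground-truth moments — the oracle behind the entire test suite.

## Worked example

Simulate a subject whose true knee flexion axis is tilted 10° from the
generic medio-lateral direction, calibrate, build models, run ID, compare:

```sh
funkam simulate --out-dir demo --seed 7 --knee-tilt-deg 10 --rate 50
funkam calibrate --stararc demo/stararc.trc --knee demo/knee_ref.trc \
    --ankle demo/ankle_ref.trc --static demo/static.trc --out demo/cal.json
funkam scale --cal demo/cal.json --static demo/static.trc \
    --mass 64.01 --height 1.7555 --variant FUN2 --out demo/fun2.json
funkam id --model demo/fun2.json --trial demo/trial.trc --wrench demo/trial.mot \
    --mass 64.01 --height 1.7555 --static demo/static.trc --out demo/fun2_moments.sto
funkam metrics --candidate demo/fun2_moments.sto --reference demo/truth_moments.sto
```

With the both-frame functional model (FUN 2) the pipeline reproduces the
generator's ground-truth EAM essentially exactly:

```json
{"frames": 150, "mean_eam_bwht": 0.8759302749863609}
{"rmse_bwht": 7.598245407844521e-08, "sign_agreement_percent": 100.0}
```

Repeating with `--variant CON` (conventional scaling, generic axes) on the
same trial gives

```json
{"frames": 150, "mean_eam_bwht": -0.35826748130364233}
{"rmse_bwht": 1.2714763684400114, "sign_agreement_percent": 3.3333333333333335}
```

— the 10° axis error does not just distort the EAM (RMSE 1.27 %BWHt), it
flips its sign: the conventionally scaled model reports an *abduction*
moment where the knee actually experiences an adduction moment. That is the
failure mode functional axis integration exists to remove.

## Layout

| module | contents |
| --- | --- |
| `funkam.rigid` | rigid-transform algebra, weighted SVD pose estimation |
| `funkam.markers` | trajectory container, gap fill, virtual markers, OCST |
| `funkam.calibration` | SCoRE, SARA, JCS construction, calibrate/transfer |
| `funkam.anthropometry` | generic parameter tables and the marker layout |
| `funkam.model` | model tree, scaling (CON), FUN 1 / FUN 2 integration |
| `funkam.kinematics` | forward kinematics, velocities, analytic Jacobian |
| `funkam.ik` | damped Gauss–Newton inverse kinematics |
| `funkam.dynamics` | Newton–Euler ID, %BWHt, REF pipeline, wrench I/O types |
| `funkam.signals` | zero-lag Butterworth, EMA, differentiation |
| `funkam.outcomes` | EAM metrics, marker-set sensitivity (S1–S8) |
| `funkam.realtime` | streaming IK→EMA→ID with deadline accounting |
| `funkam.synthetic` | ground-truth subject and trial generator |
| `funkam.io_files`, `funkam.cli` | TRC/MOT/STO + serialization, `funkam` CLI |

See `docs/methods.md` for the model conventions, parameter choices and
known limitations.
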