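# gaitbalance

Modeling and identification of the human walking balance controller, built
on the COM-ZMP inverted-pendulum framework used in humanoid robotics.

Wearable motion-assist devices need to know whether their wearer is about
to lose balance. A practical route is to model the wearer the way a
humanoid robot models itself: the whole-body center of mass (COM) behaves
like an inverted pendulum pivoting about the zero moment point (ZMP), and a
balance controller places the ZMP so that each step lands the *capture
point* — the spot where planting the ZMP would bring the COM to rest — on
the next footfall. `gaitbalance` implements that whole stack for human gait
recordings and, because real motion-capture/force-plate recordings of this
kind are rarely shareable, ships a closed-loop synthetic gait generator
that stands in for the hardware.

## The model

Along the travel axis, with COM position `x` and ZMP `x_Z`, the dynamics
admit an *asymmetric* eigenstructure (recovery and collapse are not mirror
motions):

```
ẍ = ζ₁ζ₂ (x − x_Z) + (ζ₁ − ζ₂) ẋ
```

with a divergent mode `+ζ₁` and a convergent mode `−ζ₂` (1/s). The capture
point is `x_C = x + ẋ/ζ₂`. During one stepping window (support foot at
`x_P`, target footfall `x_Sd`, landing time `T`), minimizing the ZMP's
squared excursion about the axle subject to the terminal condition
`x(T) + ẋ(T)/ζ₂ = x_Sd` gives the state-feedback law

```
x_ZMP = x_P + 2 (x_CP − e^{−ζ₁(T−t)} x_SP) / (1 − e^{−2ζ₁(T−t)}),
x_CP = x + ẋ/ζ₂ − x_P,   x_SP = x_Sd − x_P,
```

saturated to the support area. Continuous walking alternates left/right
windows from each toe-off to the opposite toe-off; each window splits at
heel contact into sections with their own axle. Identification fits
`(ζ₁, ζ₂)` — optionally under the product constraint `ζ₁ζ₂ = 8.67 1/s²`
used in the stepping/braking studies — plus one axle per section, against
the sensor-side ZMP computed by moment balance over four shoe-mounted
force plates.

The package provides:

- `anthropometry` — 15-segment body model scaled from height/mass; whole-body COM.
- `dynamics` — the pendulum model: eigenstructure, closed-form solutions, capture point, ZMP from kinematics with angular-momentum correction.
- `controller` — the capture-point MPC law and bilateral switching.
- `zmp_estimation` — four-plate moment-balance ZMP and the insole foot-shape model.
- `gait_phase` — rule-based detection of the seven Perry phases per leg (force rules primary, kinematic rules as fallback) and gait-cycle statistics.
- `identification` — `ControllerIdentifier` (scikit-learn-style estimator), window segmentation, and the trunk-heading local frame for turning walks.
- `synthetic_data` — the closed-loop walker + sensor synthesizer (stepping, straight, 90°-turn scenarios) with ground-truth phase timelines.
- `io` / `cli` — CSV/YAML formats and the `gaitbalance` command-line tool.

## Worked example

Simulate a noiseless stepping-and-braking trial and identify the
controller under the eigenvalue-product constraint:

```sh
$ gaitbalance simulate --kind stepping --n-steps 1 --noise-level 0 \
      --seed 0 --out step.csv --truth step_truth.csv
wrote step.csv (165 samples)
$ gaitbalance identify --input step.csv --phases step_truth.csv \
      --constraint 8.67 --seed 0 --out fit.json
zeta1=4.000 zeta2=2.168 rmse=0.0000 m
```

`fit.json` then contains

```json
{
  "zeta1": 3.9999999851496346,
  "zeta2": 2.1675000080470417,
  "zeta_product": 8.67,
  "x_p": [-3.34e-09, 0.29999999957],
  "rmse_m": 9.73e-10
}
```

i.e. the fit recovers the generating eigenvalues (divergent mode
ζ₁ = 4 1/s, convergent mode ζ₂ = 2.17 1/s) and the two axle positions —
the support ankle at 0 m before heel contact and the landing position at
0.30 m after it — with sub-nanometre residual, because the noiseless trial
lies exactly in the model class.

Phase detection on a default six-step walk at the standard sensor-noise
level:

```sh
$ gaitbalance simulate --kind straight_walk --n-steps 6 --noise-level 1 \
      --seed 2 --out walk.csv
$ gaitbalance detect --input walk.csv --out phases.csv
stance 60.6 % / swing 39.4 %
```

The detected stance share of the gait cycle sits near the 62 % of normal
gait (sampling at 60 Hz quantizes each heel contact by up to one frame,
which trims ~1.4 percentage points from the detected stance).

The same pipeline runs end to end with `gaitbalance report`, and turning
walks are handled by fitting in the trunk-heading local frame
(`--frame local`).

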