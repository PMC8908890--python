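# Methods

This note records the model, the algorithmic choices, and the rationale
behind defaults, in enough detail to reproduce or challenge any of them.

## 1. COM-ZMP pendulum with asymmetric eigenvalues

The controlled variable is the horizontal COM coordinate `x` along the
travel axis; the control variable is the ZMP `x_Z`. With COM height `z`
near-constant (`z̈ ≈ 0`, the standard flat-COM approximation) and the
change of whole-body angular momentum neglected, the linearized dynamics
are a saddle: a divergent mode and a convergent mode. The symmetric
pendulum has both at `ζ = √(g/z)`; human recovery (converging) and
collapse (diverging) motions have different asymptote slopes in the phase
plane, so the model carries two magnitudes, eigenvalues `(+ζ₁, −ζ₂)`:

    ẍ = ζ₁ζ₂ (x − x_Z) + (ζ₁ − ζ₂) ẋ

Note the velocity coupling term: it is required for the eigenvalues of the
companion matrix `[[0,1],[ζ₁ζ₂, ζ₁−ζ₂]]` to be exactly `(ζ₁, −ζ₂)`, and —
more importantly — it is what makes the capture-point coordinate
`ξ = x + ẋ/ζ₂ − x_P` obey the clean first-order law `ξ̇ = ζ₁(ξ − u)` under
a ZMP offset `u = x_Z − x_P`. Every closed-form result below (and the
closed-loop simulator) uses this full asymmetric equation; the
symmetric-limit forms are recovered exactly at `ζ₁ = ζ₂`.

Under constant ZMP the exact solution is the two-exponential

    x(t) = A e^{ζ₁t} + B e^{−ζ₂t} + x_Z,
    A = (χ₀ + ẋ₀/ζ₂)/(1 + ζ₁/ζ₂),  B = (χ₀ − ẋ₀/ζ₁)/(1 + ζ₂/ζ₁),

whose velocity is `ẋ(t) = Aζ₁e^{ζ₁t} − Bζ₂e^{−ζ₂t}` (differentiation adds
the `ζ` factors; the coefficients alone do not reproduce `ẋ₀`). The
implementation is validated against fixed-step RK4 at 1 ms to 1e-8 m.

Sensor-side, the ZMP comes from the moment balance over the four
shoe-mounted plates (toe and heel per foot),

    x_ZMP = Σᵢ(−n_iy − (z_i − z_ZMP) f_ix + x_i f_iz) / Σᵢ f_iz ,

with ground height `z_ZMP = 0` and a contact threshold of 3 % body weight
on the total vertical force (below it the foot is airborne and no ZMP is
reported). The kinematic ZMP with angular-momentum correction is
`x_ZMP = (x(g+z̈) − ẍz)/(g+z̈) − L̇_Gy/(M(g+z̈))`; the correction
coefficient is negative, consistent with the momentum-based definition
(the ZMP shifts backwards while pitch angular momentum builds after
landing).

## 2. Capture-point MPC law and window logic

One stepping window is parameterized by the support-foot (axle) position
`x_P`, the target footfall `x_Sd` and the landing time `T`. Minimizing
`∫ (x_ZMP − x_P)² dt` subject to the terminal condition
`x(T) + ẋ(T)/ζ₂ = x_Sd` yields

    u*(t) = 2 (ξ − e^{−ζ₁(T−t)} S) / (1 − e^{−2ζ₁(T−t)}),   S = x_Sd − x_P,

with `x_ZMP = x_P + u*` (the law's natural frame is foot-relative; the
axle anchors it). Two numerical facts shape the implementation:

- **Horizon floor.** As `t → T` the denominator vanishes; the horizon is
  clamped at ε = 0.5 ms. The clamp leaves a terminal-condition residual
  that scales as `S·ζ₁·ε/e` (in the clamped zone the law closes a fixed
  `1 − 1/e` of the remaining gap per time constant); 0.5 ms keeps the
  residual below ~5×10⁻⁴ m across physiologic tasks (ζ₁ ≤ 6, S ≤ 0.5 m),
  comfortably under the 1 mm at which we assert the terminal condition.
  A 10 ms floor — the sample-period scale — would leave ~4 mm.
- **All solutions converge onto the target.** The homogeneous solutions of
  the closed loop decay like `sinh(ζ₁(T−t))`, so the terminal condition is
  met from any initial state; the law, not the initial condition, owns the
  landing.

**Window switching.** Windows run from each toe-off to the opposite
toe-off and are split at the intervening heel contact, each section with
its own axle:

- *Before heel contact* (single support): the window's own task drives,
  saturated to the support foot's area (`x_P − 0.05 m` to `x_P + 0.13 m`,
  the insole extent about the ankle).
- *After heel contact* (double support): the landed foot is the new axle
  and the **next** window's task takes over. This is essential for
  continuous walking: pinning the capture point on the landing target
  through double support would strand the next step outside its
  reachable set — the step requires
  `(ξ₀ + b_heel)e^{ζ₁T_swing} − b_heel ≥ stride`, and with ζ₁ = 4,
  stride 0.30 m, swing 0.418 s, the capture point must already lead the
  new axle at toe-off. Rolling the COM forward through double support
  provides exactly that lead; the simulated ZMP rides the landed foot's
  heel-side bound through most of double support, which matches how the
  ZMP enters at the heel after heel strike.
- *The last window* has no successor and ends in the infinite-horizon
  braking limit `u = 2ξ` anchored on the final landing position, which
  pins the capture point there and brings the COM to rest — this one-window
  case *is* the stepping-and-braking motion.

Walk start is handled by beginning closed-loop control at the
destabilization onset (~0.32 cycles before the first toe-off): the first
task's law then produces the anticipatory backward ZMP shift of gait
initiation, without which the first step is unreachable from quiet
standing.

## 3. Gait-phase detection

The seven phases per leg (Loading Response, Mid-Stance, Terminal Stance,
Pre-Swing; Initial, Mid, Terminal Swing) are delimited by a forward-only
state machine. Each boundary has a force rule and a kinematic rule; the
force rule is primary when plate channels exist, the kinematic rule is the
fallback and a cross-check (disagreements beyond 5 samples are logged):

| boundary | force rule | kinematic rule |
|---|---|---|
| Initial Contact | heel `F_z` rises through threshold | foot-outline lowest point reaches floor |
| LR → MSt | toe `F_z` rises | outline highest point falls below flat threshold |
| MSt → TSt | heel `F_z` falls | highest point exceeds flat threshold (heel rise) |
| TSt → PSw | opposite foot's Initial Contact | same, kinematic |
| PSw → ISw | toe `F_z` falls (toe-off) | lowest point exceeds clearance |
| ISw → MSw | — | swing ankle passes support ankle (travel axis) |
| MSw → TSw | — | knee–ankle horizontal offset within tolerance (vertical shank) |

Defaults (configurable, recorded in every report): floor contact 10 mm,
foot flat 25 mm, clearance 20 mm, force threshold 3 % body weight,
knee–ankle alignment 20 mm, debounce 3 samples. The debounce is
retroactive — a transition commits only after 3 consistent samples but is
time-stamped at the first of them — so clean transitions keep their exact
onset sample. Zero-duration phases are legal and occur at walk start
(no Terminal-Stance/Pre-Swing boundary; Initial and Mid Swing activate
together when the feet start side by side).

Cycle statistics normalize each heel-contact-to-heel-contact cycle to
100 %; stance = LR+MSt+TSt+PSw. The earliest-starting and latest-ending
cycles of a bout cover the start and braking transients and are excluded
by default (the trimming is bout-level, not per-leg, so a six-step walk
retains one steady cycle per leg). Detection quantizes events to the
60 Hz grid: heel contacts are found at the first frame at/after the true
crossing, which shortens detected stance by up to one frame (~1.4
percentage points at a 1.1 s cycle) — the detected split on the default
walk is 60.6/39.4 against the constructed 62/38.

## 4. Identification

The fit is teacher-forced: the window law is evaluated along the
*measured* COM position and velocity and compared to the *measured*
(four-plate) ZMP; nothing is re-simulated inside the optimizer. Fitted
parameters: ζ₁ (with ζ₂ = C/ζ₁ under an optional product constraint C, or
ζ₂ free) and one axle `x_P` per section. Landing targets `x_Sd` and all
event times come from the phase timeline (detected or ground truth) and
the ankle channels; they are not co-estimated.

Numerical structure and the reasons for it:

- **Nested optimization.** For fixed eigenvalues the law is linear in
  `x_P`, so each section's axle is an inner 1-D problem (coarse 41-point
  grid bracket + bounded Brent, search radius ±0.10 m around the measured
  support ankle). The outer problem (1-D constrained or 2-D free) runs
  multi-start Nelder–Mead (8 starts seeded from the fit seed, bounds
  ζ ∈ [1, 10] 1/s); the fit is deterministic given the seed.
- **Near-landing exclusion.** Samples within 30 ms of the landing are
  excluded from the objective: there the law's gain diverges like
  `1/(ζ₁(T−t))` and a single sample would dominate the fit with
  near-singular sensitivity. The reported trace still covers them.
- **Saturation handling.** The *plant* saturates; the fitted model clips
  only in double-support sections, where the measured ZMP genuinely rides
  the landed foot's heel bound and the plateau pins the axle. In
  single-support sections the command stays interior, and including a
  saturated branch in the model lets least squares park noisy samples on
  the noise-free clip bound — a variance-clamping artifact that biased the
  axle by +2.5 cm and attenuated ζ₁ before it was removed.
- **Known limitation — errors-in-variables.** The model input states are
  measured, so their noise is amplified by the law's gain. Under the
  product constraint the braking/capture-point sections anchor ζ₂ and the
  bias is negligible (median ζ₁ ≈ 4.01 at the default noise). The fully
  unconstrained fit on noisy data is attenuation-prone (it can drift
  toward the low-gain bound); use the constraint on noisy recordings, as
  the stepping/braking studies do.
- **Event-timing sensitivity.** A one-frame (16.7 ms) shift of the landing
  time scales the law's exponential by `e^{ζ₁Δt} ≈ 1.07`, which moves the
  fitted ζ₁ by ~5 %. Fits from detected (grid-quantized) timelines
  therefore sit a few percent from fits using exact event times; the
  recovery benchmarks use exact times.

Quality is reported as the RMSE between model and measured ZMP over the
fitted samples. For display, `model_zmp_trace(..., continuous=True)`
renders the conventional continuous model trace: the rendering horizon is
clamped at the 30 ms floor and each boundary jump is absorbed by a linear
taper over the following section; RMSE is always computed on the raw
trace.

## 5. Trunk-heading local frame (turning walks)

Only the forward axis is modeled, so non-straight walking is first
expressed in a frame aligned with the trunk: X along the chest's forward
heading (yaw only), anchored at the waist's ground projection. A naive
per-sample waist-centered origin fails structurally — the support foot's
local coordinate drifts as the origin walks away, so no constant
per-section axle exists. The frame therefore rectifies the forward
coordinate to arc length:

    x_loc = s(t) + R(ψ)ᵀ(p − waist)·e_x,   y_loc = R(ψ)ᵀ(p − waist)·e_y,

where `s(t)` is the waist's cumulative forward progress along its own
heading. Ground-fixed points then stay stationary in the local frame, and
on a straight walk the transform reduces to the global frame up to a
constant. Velocity, force and torque *vectors* are rotated into the local
axes (the forward COM velocity is the physical speed along the heading;
all model quantities are position differences, so the moving origin
cancels). The applied yaw, origin and arc length are stored as columns,
making the inverse exact. The heading can be low-pass filtered
(2nd-order Butterworth, 1 Hz default) to keep step-cycle wobble out of
the frame of real recordings; the synthetic chest heading is wobble-free,
so filtered and raw give near-identical fits on generated data.

## 6. Synthetic gait generator

The generator's defaults are the study conditions; they emulate 60 Hz
recordings of a lean 1.65 m / 57 kg subject:

| parameter | default | basis |
|---|---|---|
| eigenvalues ζ₁, ζ₂ | 4.0, 2.1675 1/s | identified stepping values; product 8.67 |
| stride (per-step advance) | 0.30 m | middle of the measured 0.1–0.6 m range |
| step duration | 0.55 s (1.1 s cycle) | normal self-selected gait |
| phase template (% of cycle) | LR 10, MSt 20, TSt 20, PSw 12, ISw 13, MSw 13, TSw 12 | realizes the 62/38 stance/swing split; per-leg override for asymmetric gait |
| COM height | 0.57 × height, constant | flat-COM approximation |
| noise (1 σ) | 2 mm positions, 10 mm/s velocities, 2 N forces, 0.1 N·m torques | plausible IMU-mocap/plate noise; no published characterization exists |
| lateral sway | ±3 cm toward the support foot | realism only; carries no controller semantics |

The COM is integrated in closed loop (exact propagation on
piecewise-constant ZMP at 10× the output rate) under the bilateral law of
§2; step feasibility is checked (an unreachable capture-point target
raises an error naming the step). Foot kinematics and plate forces are
then synthesized *backwards from the ground-truth timeline* so that every
detection rule of §3 crosses its threshold at the true event time: heel
pivot through Loading Response (15° toe-up at contact), flat foot in
Mid-Stance, heel rise about the toe from the Mid-/Terminal-Stance
boundary, swing clearance of 5 cm, ankle crossing and shank verticality at
their template times. Per-foot vertical force follows a two-peak profile —
0 at contact, 120 % body weight at the end of Loading Response, ~100 %
through mid-stance, a second peak in Terminal Stance, 0 at toe-off — with
the heel plate leading at contact and the toe plate after Mid-Stance; the
interior profile knots carry a solved additive correction so one steady
stance integrates to half a cycle of body weight (total force averages
body weight to <2 %). Plate pitch torques are solved per sample so the
moment-balance ZMP of the synthesized plates equals the simulator's ZMP
exactly (ankle torque is a real degree of freedom of an instrumented
shoe).

Turning trials are generated in the trunk-heading local frame and mapped
to the global frame as the exact inverse of §5's transform: the heading
smoothsteps through the turn over ~3.5 step lengths (a natural
curved-walking radius of ~0.7 m), the waist path integrates
heading-rotated local increments, and all channels are carried rigidly per
sample.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue artifact and marker dropout;
joint-level kinematics (the ankle/knee channels are idealized trajectories
anchored at event times, not a rigid linkage with the foot body);
three-dimensional angular-momentum dynamics (the pitch-momentum ZMP
correction is available but the walker's lateral motion is decorative);
inter-stride variability of timing and foot placement (every cycle follows
the template exactly); and, for turns, strict foot stationarity in the
global frame (a planted foot drifts by a few centimetres while the heading
changes, the price of holding the trunk-relative geometry exact).

## 7. Degenerate inputs and tie-breaks

Flight (total vertical force below threshold) yields "no ZMP", not an
error; `g + z̈ ≤ 0` in the kinematic ZMP raises (true flight). Standing
records produce no segments and empty statistics raise informatively.
Non-unit foot quaternions are normalized with a warning. The detector's
state machine only moves forward through the cycle; at walk start it may
emit zero-duration Pre-Swing/Initial-Swing entries at the toe-off sample.
Identification flags (rather than crashes on) non-convergence, and the
eigenvalue-product constraint is enforced exactly by construction
(ζ₂ = C/ζ₁).

## 8. Problem sizes

All shipped analyses run at desk scale: stepping trials are ~2.7 s
(165 samples), walks 5.5–6.5 s (330–390 samples), and the recovery studies
use 20 seeded trials; a full test run plus the acceptance script completes
in a few minutes on one core.
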