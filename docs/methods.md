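# Models and methods

`saurogait` contains two models of bipedal lizard running built on the
morphometrics of *Callisaurus draconoides* (≈10 g, 192 mm snout to tail
tip).  This note records the science each model implements, the defaults
chosen where the source measurement tables are silent, the numerical
choices, and what the implementation does and does not capture.

## The planar three-link model

The trunk is idealized as three rigid links in the horizontal plane —
anterior body (66 mm, 4 g), posterior body (42 mm, 4 g), tail (84 mm, 2 g) —
joined by two frictionless yaw joints (waist, tail base).  Roll, pitch and
the vertical ground reaction are excluded: at high speed the animal's trunk
moves almost entirely in yaw.  Yaw inertias use the homogeneous solid
cylinder of length *l* and radius *w*/2 about a transverse axis,
`i = m(l²/12 + (w/2)²/4)`.

Dynamics are formulated per link: Newton equations for the link centres of
mass with pin-joint constraint forces, the twice-differentiated chain
closure `C x = (L/2)cos q`, `C y = (L/2)sin q` eliminating the internal
forces, and the per-link moment balance assembled into an implicit linear
system in the angular accelerations (internal forces depend on those
accelerations).  The forward dynamics are verified against an independent
Euler–Lagrange oracle built only from the chain geometry and kinetic
energy.  Integration is fixed-step fourth-order Runge–Kutta, default step
T_p/1000 with gait period T_p = 0.092 s.

External inputs per stride, all exposed in the configuration:

* **GRF**: fore-aft full sine per stance (braking then propulsion; zero net
  impulse analytically) and lateral half sine always directed toward the
  midline.  Amplitudes are not published; default 0.1 N for both, about one
  body weight, a typical peak for small sprinting lizards.
* **Stance schedule**: one stance per half period, right foot first, window
  of half the half-period centred within it; the foot is placed 38 mm from
  the posterior-body COM at ±45° off the running direction and is anchored
  (no slip) for the whole stance.
* **GRM**: the yaw moment the stance foot must transmit so that the
  posterior body tracks the pelvic reference 20° sin(2πt/T_p).  It is
  realized as a critically damped servo (natural frequency six times the
  gait frequency) solved exactly through the rotational dynamics at every
  step, active only while a foot is on the ground.
* **PD controller**: waist and tail track their reference sines with
  default gains kp = 0.25 N·m/rad, kd = 1.5 mN·m·s/rad, chosen so a 20°
  reference sine at T_p is tracked within a few percent of its amplitude.

### Undulation optimization

Design vector (a₁, b₁, a₂, b₂): amplitude and phase of the waist and tail
reference sines.  Objective: squared waist plus tail torque integrated over
the final simulated period, plus a quadratic penalty on the peak |GRM|
above a bound (default 0.03 N·m, near the smallest peak any undulation can
achieve for the default model — a non-undulating trunk needs nearly three
times more).  The search is SLSQP from starts in the in-phase/antiphase
quadrants, followed by a restart from the incumbent; the restart matters
because the penalized objective has a narrow curved valley that a single
SQP working set descends poorly.  The torque-minimal solution always drives
the waist and tail in opposition — the S-shaped lateral undulation — and
this result is robust across the five published morphometric variants.

## The 15-link biomechanical model

Fifteen links (three trunk segments and four three-segment legs), 33
coordinates: two world translations and the body yaw (unactuated "virtual"
coordinates) plus 30 rotations — waist and tail-base yaw, and per leg a
3-DOF shoulder/hip, 1-DOF elbow/knee and 3-DOF wrist/ankle.  The body is
held at a constant height, so the tree is planar-suspended and all vertical
motion comes from the legs.  Link inertias use the same cylinder rule about
each link's long axis.

All motion is prescribed.  Body and hind-leg joints follow one sine per
stride period (default 0.03 s); fore legs are frozen in a tucked posture;
the right leg repeats the left half a period later with the printed mirror
sign rules.  The virtual yaw carries the pelvic-rotation sine
20° sin(2πt/T), so the pelvis itself swings as that sine plus the waist
joint: a larger waist amplitude sweeps the hips further and lengthens the
stride, which is the mechanism behind the stride-versus-amplitude
relationship this model family exhibits.  (Placing the 20° sine on the
pelvis absolute angle instead makes the hip kinematics identical at every
body amplitude and the stride flat — that reading is inconsistent with the
model's reported behaviour.)

**Ankles.** The foot always faces the running direction at a fixed
downward pitch; the three ankle angles are solved in closed form (z-x-y
Euler decomposition of the chain orientation, unwrapped along the
trajectory so differencing is meaningful).  The pitch value is not
published and a flat foot degenerates the contact rule, so it is identified
from the model family's own contact kinematics: with the ground at the
foot-center minimum, the stance depth is (l_foot/2)·sin(pitch), and the
reported duty factor (≈26%) together with the small vertical extent of the
tiptoe path (≈9 mm) imply a pitch near 14–15°.  Default 15°.

**Ground and contact.** The ground plane sits at the minimum over one
cycle of the swing foot-center height (between the tiptoe and ankle
minima).  A foot is in stance while its nominal tiptoe is below the plane;
during stance the ankle pitch bends (closed-form solve, solution nearest
the nominal) so the foot end lies exactly on the plane, and the tiptoe's
world position is pinned at its touchdown point — the virtual translations
follow linearly.  Between stances the model's COM translates at its liftoff
velocity.  After one transient stride the gait is exactly periodic.

**Inverse dynamics.** Mass matrix from per-link geometric Jacobians
(`A = Σ m JᵥᵀJᵥ + JωᵀI Jω`), bias and gravity from a recursive
Newton–Euler pass, verified against kinetic-energy and power-balance
oracles.  With a foot fixed, the operational-space quantities Λ_c, μ_c,
p_c, J̄_cᵀ are formed at the tiptoe (three linear rows by default — a point
foot transmits no moment; wrench rows are available behind a flag) and the
implicit torque equation has a singular projector as system matrix: contact
makes actuation redundant.  The default resolution zeroes the
virtual-translation torques (the floating base cannot push the animal) and
is minimum-norm in the remaining freedom; the residual virtual-yaw torque
plays the role of the ground-reaction moment.  A plain minimum-norm
resolution is available but under-prices stance by letting fictitious base
forces assist the legs.  Joint rates and accelerations along a gait come
from differencing the joint trace, as in the source method; the anchoring
velocity jump at touchdown therefore contributes finite, sampling-dependent
impact terms, so torque costs are always quoted at the standard sampling of
120 steps per period inside the optimizer (an option excludes fixed windows
around the contact transitions to obtain the resolution-independent smooth
part).

### Gait cost and optimization

The cost is the squared torque of the 30 actuated joints integrated over
one period of the fixed-period trace.  The 4 m/s running-speed requirement
enters twice, in different roles:

* **Reporting**: the simulated trace's time axis is rescaled so the mean
  forward speed is exactly 4 m/s.  Stride length, width, duty factor and
  hip height are invariant under this rescale; stride duration and
  frequency scale with it (duration ≈ stride length / 4 mm/ms).
* **Objective**: a soft anchor `0.05 · (v_raw/4 − 1)²` is added to the
  torque integral.  Without it the fixed-period objective is minimized by
  gaits that barely advance; costing a fully speed-rescaled trace instead
  makes stride maximization always optimal and drives every amplitude to
  its bound.  The weight makes a ~15% speed deviation comparable to the
  torque-cost differences between candidate running gaits.

Nine design parameters: waist and tail amplitude and phase, hip-swing
(retraction) amplitude and offset, and the amplitudes of hip depression,
femoral long-axis rotation and knee flexion.  Remaining sine parameters are
fixed model assumptions chosen once for a sprawled runner: stance centred
at quarter period, depression offset 40°, knee offset −35° (crouch depth
giving a hip height near the real animal's ≈28 mm), small femoral rotation
and large horizontal sweep.  Amplitude bounds are per-joint ranges of
motion (retraction 50°, depression 45°, femoral rotation 45°, knee 60°;
body joints 80°) rather than one generic bound, under which the femoral
rotation otherwise always saturates.  The optimizer is Powell's
derivative-free direction-set search (default four outer sweeps): contact
windows are resolved on a finite grid, so the objective is piecewise
discontinuous in the design and finite-difference SQP gradients are
unreliable; SLSQP remains selectable.  The body-amplitude sweep fixes waist
= tail amplitude (phases at the package defaults, which keep the pelvic
swing near 20° at every amplitude), re-optimizes the five leg parameters at
each point and warm-starts from the previous amplitude.

### Problem sizes

Defaults used by the test suite and the reproduction script: gait traces of
5 strides at 300 steps per period for metrics, 3 strides at 120 steps per
period inside the optimizer; Powell with 4 outer sweeps, single start
(warm-started along the sweep); planar undulation optimization at 150–400
steps per period with 2–4 starts.  All randomized pieces (extra optimizer
starts) are seed-controlled; with a single start the whole pipeline is
deterministic.

## What passing tests do and do not show

The test suite verifies the mechanics exactly (chain closure, momentum
conservation, Lagrangian/Newton–Euler/KKT cross-checks at 1e-6–1e-10), the
contracts of every operation, and the qualitative science: the S-shaped
undulation emerges from torque minimization for all published morphometric
variants, body undulation reduces the squared joint torque, the waist axis
dominates the cost landscape, and the stride lengthens with body amplitude
at fixed legs.  The quantitative gait statistics, however, depend on
reconstruction choices the source tables do not pin down — leg phase
conventions, attachment offsets, ranges of motion, the contact-redundancy
resolution and the optimizer's local basin.  Under this package's
documented choices, the torque-minimal gait uses more vertical limb motion
than the published one (duty factor ≈13–20% rather than ≈26%, larger
vertical tiptoe extent), and the stride-length endpoints sit 10–25% from
the published values; the reproduction script reports whatever the pipeline
actually computes.  These comparisons gauge the reconstruction, not the
correctness of the mechanics, which the property tests establish
independently.

## Known limitations

* No roll/pitch/vertical trunk dynamics in either model (by design).
* The planar model's GRF amplitudes and stance fraction are calibrated
  conventions, not measurements.
* Contact is a single anchored point per foot with no slip, no compliance
  and no friction cone; touchdown velocity jumps are impulsive.
* The 33-coordinate model is never forward-simulated under torque control;
  torques are extracted from prescribed kinematics (inverse dynamics), as
  in the source method.
* Gait optima are local by construction; different initializations can
  land in different basins, which is the dominant uncertainty in the
  quantitative gait statistics.
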