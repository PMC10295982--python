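# Methods

`wristkin` studies whether the wrist rotations needed in a shelf
pick-and-place task — wrist flexion/extension (F/E), wrist
abduction/adduction (A/A) and forearm pronation/supination (P/S) — can
be predicted from the kinematics of the more proximal arm joints
(elbow F/E and A/A, plus the three shoulder angles).  Because no
subject recordings ship with the package, every stage is exercised
against a synthetic motion-capture generator with exact ground truth.
This note records the models, the defaults and the reasoning behind
the genuinely open design choices.

## The synthetic study

**Design.** Five subjects transport two standardized grasp objects (a
power-grip cylinder and a spherical object) between four shelf slots
(UL, UR, DL, DR); all 12 ordered origin–destination pairs are
performed, three repetitions each, giving 5 × 2 × 12 × 3 = 360 trials
of nominally 5 s sampled at 60 Hz.  Four pose sensors (hand, forearm,
arm, trunk) report position plus an intrinsic Z–Y′–X″ Euler triple
(azimuth, elevation, roll) in a fixed transmitter frame whose x axis
points to the subject's right, y toward the subject and z down;
orientation channels are stored wrapped to [−180°, +180°], so the
wrap-removal step of the pipeline is exercised for real.

**Arm model.** A rigid chain trunk → shoulder → elbow → wrist with
segment lengths 28/26/9 cm, each joint parameterized by the same
F/E → A/A → P/S rotation sequence used in extraction (F/E about the
proximal z, A/A about the intermediate y, axial rotation last, about
the distal x).  Sensors carry fixed, slightly tilted mounting
rotations so that mounting-frame removal is a real operation rather
than an identity.

**Trajectories.** Per trial, the arm moves through three phases
(reach, transport, return; nominal split 0.35/0.30/0.35, each phase
duration jittered ±10 % per repetition).  Each phase follows a
joint-space polyline through posture via-points, traversed with a
minimum-jerk time profile (zero end velocity and acceleration).
Grasp/release postures are authored per (slot, object): the cylinder
is gripped from the side with a pronated forearm, the sphere from the
top supinated, upper slots demand wrist abduction and more shoulder
flexion, lower slots the opposite — reproducing the qualitative
structure in which P/S spans the largest range and A/A the smallest.

Two numerical calibrations keep the simulation physically coherent:

* **Shelf-plane calibration.** All slots sit on one shelf plane, so
  every grasp/release posture is solved (1-D root find on the
  shoulder-flexion channel, restricted to the near branch of the
  reach envelope) to put the hand sensor at a common depth of
  6 cm from the transmitter.  Subject-specific posture perturbations
  (σ = 3° per channel, drawn once per subject and slot/object) are
  re-calibrated the same way — different subjects grasp differently
  but reach the same shelf.
* **Clearance scheduling.** Between events the hand must stay behind
  the shelf plane (it cannot pass through the shelf).  Via-points are
  pulled to scheduled clearances; the schedule grows like the cube
  root of path fraction near the grasp/release instants, which
  cancels the cubic dwell of the minimum-jerk profile so the hand-y
  coordinate rises *linearly in time* away from each event.  This is
  what makes the pick/place minima crisp enough to detect to ±2 grid
  steps under noise.

**Noise and motor variability.** Measurement noise is i.i.d. Gaussian
on every sensor channel, σ = 0.1 cm on positions and σ = 0.5° on
orientation angles — enough to exercise the filtering and
synchronization stages without burying the signal.  On top of that the
generator models *motor* variability, without which repetitions would
be identical up to sensor noise and an instant-wise predictor would be
unrealistically flattered: each repetition realizes slightly different
grasp/release postures (keyframe wobble σ = 1.0° per channel,
re-solved to the fixed shelf plane, so the variability lives in the
posture null-space of the object position) and a slightly different
approach path (interior via-points wobble with σ = 2.0°, while the
event postures stay pinned to the object).  The posture wobble scale
is bounded above by the pipeline's own detectability requirement —
pick/place events must remain recoverable to ±2 normalized steps in at
least 95 % of trials — and 1.0° is the default consistent with that
requirement.  Because a top grasp reconfigures the whole arm, the two
objects also differ in the proximal channels (sphere: elbow lifted
~8°, shoulder rolled ~6°), not only at the wrist; this is what makes
the grip mode partially, but not perfectly, inferable from elbow and
shoulder angles, mirroring the real-data pattern in which adding
explicit object information improves the correlation.
All randomness derives from `numpy` `SeedSequence`s spawned from one
master seed; identical (design, seed) reproduces the study exactly.

**What the generator does not emulate:** soft-tissue artifact, sensor
drop-out, magnetic distortion of the tracker, muscle dynamics, or the
fine structure of individual human wrist trajectories.  Passing tests
therefore demonstrate that the *pipeline* is correct and that the
qualitative findings hold on a realizable data-generating process of
the same shape — not that the numeric results transfer to any real
subject.

## Angle extraction

Per sample and joint, the relative rotation between the two flanking
sensors (mounting frames removed) is decomposed as
R = R\_FE(z) · R\_AA(y) · R\_PS(x), with A/A confined to [−90°, 90°].
Gimbal lock (|cos A/A| < 1e−6) is flagged, not raised: F/E absorbs the
coupled rotation and P/S reports zero; trials with more than 1 % of
flagged samples emit a warning.  The wrist pair additionally yields an
axial residual (`wrist_PS_res`) that is stored but excluded from
modelling, since hand pronation/supination physically happens in the
forearm.  Output series are unwrapped to be continuous.

For real recordings without known mounting frames a static-calibration
option estimates them from the mean sensor rotation over an initial
rest window (projected back to SO(3) by SVD), relying on all segment
frames coinciding with the trunk base frame in the anatomical posture.

## Preprocessing

* **Synchronization.** The three repetitions of a condition are
  aligned by dynamic time warping on the 3-D hand trajectory
  (Euclidean metric, steps {(1,0),(0,1),(1,1)}, ties preferring the
  diagonal), repetition 1 serving as the reference; query samples
  mapped to one reference index are averaged, and ground-truth event
  indices are mapped through the warping path.  The DP implementation
  is verified against exhaustive path enumeration.
* **Filtering.** 3rd-order Butterworth low-pass, default cutoff 5 Hz
  (standard for reach kinematics; the harness makes it configurable),
  zero-phase by default so event timing is unbiased.  Edges are
  handled by reflection padding several filter time-constants long,
  and the single-pass variant starts from steady-state initial
  conditions, giving unit DC gain to 1e−9.  The filter is applied to
  the extracted angle series and hand positions — the quantities
  actually modelled — rather than to raw pose channels; the noise-free
  round trip (< 0.5° RMS distortion) bounds the difference.
* **Normalization.** Linear interpolation onto 101 samples at
  normalized time steps of 0.01 (≈ 50 ms at the ~5 s trial length).
* **Centering.** Every angle is re-expressed as the deviation from its
  per-subject mean over all of that subject's samples, cancelling
  systematic sensor-placement differences; offsets are kept for the
  inverse transform.

## Events and datasets

Pick (PK) and place (PL) are the minima of the hand-sensor y
coordinate in the first ([0, 50]) and second ([51, 100]) half of the
normalized record — the trial protocol is symmetric, so the halves
segmentation is exact on the normalized clock; a local-minima detector
is available for non-centred transports.  The feed-forward dataset has
two rows per trial (inputs sampled an anticipation of 0.1–0.75 s ahead
of each event, targets at the event; optional one-hot extensions for
object, subject and task), 720 rows for the default study, split
85/15.  The time-delay dataset concatenates whole trials (15 % of
trials held out, balanced across objects) after multiplying each by a
Tukey window whose cosine ramps span the first and last five samples
(ratio 0.1), so trials meet at zero; the first max(delay) samples of
each concatenation are masked, trial boundaries are not (the taper
handles them).

## Networks and training

One hidden layer of hyperbolic-tangent units (5–20 in the study grid),
linear output, per-feature min–max scaling of inputs and targets to
[−1, 1] frozen before training, Nguyen–Widrow-style seeded
initialization.  The reference trainer is Levenberg–Marquardt with
Bayesian regularization: damped Gauss–Newton steps

    dw = −(β JᵀJ + (α + μ) I)⁻¹ (β Jᵀe + α w)

on the objective β·Σe² + α·Σw², with μ adapted ×0.1 / ×10 on
accepted/rejected steps (μ ∈ [1e−10, 1e10]); after each accepted step
the effective number of parameters γ = N_w − α·tr((β JᵀJ + α I)⁻¹)
re-estimates α ← γ/Σw² and β ← (N − γ)/(2Σe²).  γ is bounded in
[0, N_w] by construction.  Convergence is judged on the relative
decrease of the objective *under the hyperparameters the step was
taken with* — after re-estimation the objective equals N/2 identically
and carries no signal.  The Jacobian is exact (backpropagation per
output), which is what makes LM practical at the study's sizes
(≈ 2 × 10⁴ samples × ≈ 800 weights for the largest time-delay nets).
Plain LM (α = 0, 15 % validation split, patience 6) and Møller's
scaled conjugate gradient are provided for the trainer comparison; the
Bayesian variant needs no validation set, matching its toolbox
semantics.

The time-delay regressor embeds the five input channels at delays
d ∈ {a..b} (e.g. 1:10 ≈ 0.5 s of context; 11:12 = a 0.5 s-anticipated
two-tap window) and trains one single-output network per wrist angle.

**Epoch caps.** The experiment harness defaults to 100 epochs for the
feed-forward grid and 30 for the time-delay grid; training loss on
this data stabilizes well before these caps (the per-epoch logs are
kept on every fitted model), and the caps keep a full five-session
grid tractable on one CPU.

## Evaluation

Per-angle MAE (feed-forward) or RMSE (time-delay) in degrees, plus a
Pearson correlation: pooled over all test outputs for the three-output
feed-forward network, the mean of per-angle coefficients for the
time-delay family (whose tables report a mean CC).  Correlations are
computed on the centered scale the networks are trained on; MAE/RMSE
are identical on either scale because centering shifts targets and
predictions alike.  Each configuration is averaged over five training
sessions with derived seeds (seed + 0 … seed + 4), reported as
mean ± SD.  The linear baseline fits one ordinary-least-squares model
per target angle on all 101-sample rows of every trial stacked
vertically.

## Design choices where the design was open

* Euler axis assignment: the rotation *order* (F/E → A/A → P/S) is
  fixed by the method; the axes are chosen as z/y/x with x the distal
  long axis, making axial rotation the final rotation about the long
  axis — the standard convention for pronation/supination.
* DTW alignment signal: the 3-D hand trajectory, because the events
  of interest are defined on it; reference = repetition 1.
* Raw sampling rate 60 Hz × 5 s: only the normalized 101-point grid
  (≈ 50 ms steps) is contractual; 60 Hz is typical of multiplexed
  electromagnetic trackers.
* Feed-forward inputs and targets are both subject-centered, and the
  time-delay pipeline uses the same centering for consistency;
  predictions can be reported on the raw scale via the stored offsets.
* The evaluation's correlation is computed on centered angles (the
  scale of the trained mapping); both pooled and per-angle-mean modes
  are exposed.

## Known limitations

* The generator's posture keyframes are authored, not measured; the
  wrist-angle ranges and correlations it produces are of realistic
  magnitude but are not calibrated to any individual.
* Gimbal lock is flagged but the affected Euler triples remain
  degenerate; the default postures stay away from A/A = ±90°.
* The linear-solve depth calibration assumes the shelf plane is
  reachable on the near branch of the shoulder-flexion envelope;
  extreme custom geometries fall back to the closest approach.
* Training is dense-matrix LM: fine up to a few thousand weights,
  not intended for deep or convolutional extensions.
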