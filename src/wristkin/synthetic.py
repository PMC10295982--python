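"""Synthetic pick-and-place motion-capture studies with known ground truth.

The generator emulates a shelf-transport protocol: a standing subject,
four pose sensors (hand, forearm, arm, trunk), two standardized grasp
objects (cylinder, sphere) and four shelf slots (UL, UR, DL, DR).  Each
trial runs anatomical rest -> grasp at the origin slot -> transport ->
release at the destination slot -> anatomical rest, as a joint-space
minimum-jerk trajectory through authored posture keyframes, so the
ground-truth joint angles are known exactly at every sample.

Transmitter frame convention (tracker on the shelf top, back-left
corner): x points to the subject's right, y toward the subject, z
downwards.  The subject works entirely in the x > 0 hemisphere, and the
hand's y coordinate dips to a minimum exactly when the hand is at the
shelf — the property the pick/place detector relies on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import (
    ANGLE_NAMES,
    SENSORS,
    compose_joint,
    euler_to_matrix,
    matrix_to_euler,
    wrap_angles,
)

#: Trunk base frame: segment x-axis toward the ground (transmitter +z),
#: y-axis toward the shelf (transmitter -y), z-axis to the subject's
#: right (transmitter +x).  Columns are the segment axes in the
#: transmitter frame.
TRUNK_BASE_ROTATION = np.array(
    [
        [0.0, 0.0, 1.0],
        [0.0, -1.0, 0.0],
        [1.0, 0.0, 0.0],
    ]
)

_EX = np.array([1.0, 0.0, 0.0])

SLOTS = ("DL", "DR", "UL", "UR")
OBJECTS = ("cylinder", "sphere")

#: Nominal phase split of a trial: reach, transport, return.  The grasp
#: sits at cumulative fraction 0.35 and the release at 0.65.
_PHASE_FRACTIONS = (0.35, 0.30, 0.35)


class DesignError(ValueError):
    """Raised for invalid study designs."""


class ConfigError(ValueError):
    """Raised for invalid generator configuration values."""


@dataclass(frozen=True)
class TrialMeta:
    subject: int
    object: str
    origin: str
    destination: str
    repetition: int

    def key(self):
        return (self.subject, self.object, self.origin, self.destination, self.repetition)

    def group_key(self):
        """All metadata except the repetition index (the sync group)."""
        return (self.subject, self.object, self.origin, self.destination)


@dataclass
class ArmModel:
    """Kinematic chain geometry, sensor mounting frames and posture keyframes.

    Lengths are centimetres; keyframes are 9-vectors in degrees following
    :data:`wristkin.kinematics.ANGLE_NAMES` order, indexed by
    ``(slot, object, phase)`` with phase in {"grasp", "release"} plus a
    single ``"anatomical"`` entry.
    """

    upper_arm: float = 28.0
    forearm: float = 26.0
    hand: float = 9.0
    shoulder_position: np.ndarray = field(
        default_factory=lambda: np.array([30.0, 52.0, 38.0])
    )
    trunk_sensor_offset: np.ndarray = field(
        default_factory=lambda: np.array([-12.0, 3.0, -6.0])
    )
    sensor_fractions: dict = field(
        default_factory=lambda: {"arm": 0.55, "forearm": 0.5, "hand": 0.5}
    )
    mounts: dict = field(default_factory=lambda: default_mounts())
    keyframes: dict | None = None
    shelf_depth_cm: float = 6.0
    perturb_scale: float = 3.0
    keyframe_perturbations: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, L in (("upper_arm", self.upper_arm), ("forearm", self.forearm),
                        ("hand", self.hand)):
            if L <= 0:
                raise ConfigError(f"segment length {name} must be positive")
        self.shoulder_position = np.asarray(self.shoulder_position, dtype=float)
        self.trunk_sensor_offset = np.asarray(self.trunk_sensor_offset, dtype=float)
        if self.keyframes is None:
            self.keyframes = calibrated_keyframes(self)
        for key, q in self.keyframes.items():
            q = np.asarray(q, dtype=float)
            if q.shape != (9,):
                raise ConfigError(f"keyframe {key} must have 9 angles")
            if key == "anatomical":
                continue
            if abs(q[0]) > 70 or abs(q[1]) > 40 or not (-90 <= q[5] <= 90):
                raise ConfigError(f"keyframe {key} violates anatomical wrist ranges")

    def keyframe(self, slot: str, obj: str, phase: str) -> np.ndarray:
        if phase == "anatomical":
            return np.asarray(self.keyframes["anatomical"], dtype=float).copy()
        return np.asarray(self.keyframes[(slot, obj, phase)], dtype=float).copy()


@dataclass
class StudyDesign:
    """Factors and noise model of a synthetic study."""

    n_subjects: int = 5
    objects: tuple = OBJECTS
    slots: tuple = SLOTS
    n_repetitions: int = 3
    rate_hz: float = 60.0
    duration_s: float = 5.0
    pos_noise_cm: float = 0.1
    angle_noise_deg: float = 0.5
    timing_jitter: float = 0.1
    repetition_noise_deg: float = 1.0
    path_noise_deg: float = 2.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise DesignError("need at least one subject")
        if self.n_repetitions < 1:
            raise DesignError("need at least one repetition")
        if self.rate_hz * self.duration_s < 101:
            raise DesignError("sampling rate x duration must cover >= 101 samples")
        if (self.pos_noise_cm < 0 or self.angle_noise_deg < 0
                or self.repetition_noise_deg < 0 or self.path_noise_deg < 0):
            raise ConfigError("noise sigmas must be non-negative")
        if not (0 <= self.timing_jitter < 1):
            raise ConfigError("timing jitter must be a fraction in [0, 1)")


@dataclass
class TrialRecord:
    """Raw per-sensor pose series plus (synthetic-only) ground truth.

    Each sensor array has columns (x, y, z, azimuth, elevation, roll);
    positions in cm in the transmitter frame, orientation angles in
    degrees wrapped to [-180, 180).
    """

    meta: TrialMeta
    t: np.ndarray
    sensors: dict
    mounts: dict | None = None
    truth_angles: np.ndarray | None = None
    grasp_index: int | None = None
    release_index: int | None = None
    seed: int | None = None


def default_mounts() -> dict:
    """Fixed, slightly tilted sensor mounting rotations (segment -> sensor)."""
    return {
        "hand": euler_to_matrix(5.0, -4.0, 7.0),
        "forearm": euler_to_matrix(-6.0, 3.0, -2.0),
        "arm": euler_to_matrix(4.0, 2.0, -5.0),
        "trunk": euler_to_matrix(-3.0, 5.0, 2.0),
    }


def _grasp_posture(slot: str, obj: str) -> np.ndarray:
    """Authored grasp posture for one shelf slot and object.

    Upper slots demand more shoulder flexion and wrist abduction; lower
    slots more elbow flexion and wrist adduction.  The cylinder is
    approached from the side with a pronated forearm, the sphere from
    the top with a supinated forearm, which also flips the wrist F/E
    pattern — giving the study-wide range ordering P/S > F/E > A/A.
    The shoulder flexion authored here is only a starting guess: the
    calibration step re-solves it so the hand reaches the common shelf
    plane (equal hand-y) at every slot.
    """
    up = slot[0] == "U"
    left = slot[1] == "L"
    cyl = obj == "cylinder"
    q = np.zeros(9)
    # wrist F/E: object-driven pattern with a slot modulation
    q[0] = (14.0 if cyl else -10.0) + (5.0 if up else -3.0)
    # wrist A/A: abducted at the upper shelf, adducted at the lower
    q[1] = (8.0 if up else -8.0) + (2.0 if left else -2.0)
    q[2] = 0.0  # axial rotation of the hand happens in the forearm
    # elbow: shelf row sets flexion; the top-grasped sphere lifts the
    # elbow and rolls the shoulder compared to the side-grasped cylinder,
    # so the proximal chain carries the grip mode too
    q[3] = (38.0 if up else 52.0) + (0.0 if cyl else 8.0)
    q[4] = (4.0 if left else 2.0) + (0.0 if cyl else 3.0)
    # forearm P/S: object grip mode plus a lateral component
    q[5] = (-38.0 if cyl else 30.0) + (16.0 if left else -16.0) + (4.0 if up else -4.0)
    # shoulder: row sets flexion, column sets ab/adduction
    q[6] = 58.0 if up else 40.0
    q[7] = (20.0 if left else -14.0) + (0.0 if cyl else 3.0)
    q[8] = (8.0 if left else -6.0) + (0.0 if cyl else -6.0)
    return q


def hand_y(model: ArmModel, q: np.ndarray) -> float:
    """Hand-sensor y coordinate (cm) for a single posture."""
    pos, _ = forward_kinematics(model, q)["hand"]
    return float(pos[0, 1])


def _solve_reach_depth(model: ArmModel, q: np.ndarray, target_y: float) -> np.ndarray:
    """Adjust shoulder flexion so the hand reaches the shelf plane (y = target).

    The shelf sits at a fixed depth, so every grasp/release posture
    must put the hand-mounted sensor at the same y; a 1-D solve on the
    shoulder flexion channel enforces that while the authored elbow and
    wrist channels keep the per-slot posture structure.
    """
    from scipy.optimize import brentq

    q = q.copy()

    def f(s):
        qq = q.copy()
        qq[6] = s
        return hand_y(model, qq) - target_y

    grid = np.linspace(15.0, 68.0, 36)
    vals = np.array([f(s) for s in grid])
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    if idx.size == 0:  # no crossing: keep the closest approach
        q[6] = float(grid[np.argmin(np.abs(vals))])
        return q
    # pick the crossing nearest the authored shoulder angle
    cand = [brentq(f, grid[i], grid[i + 1]) for i in idx]
    q[6] = float(min(cand, key=lambda s: abs(s - q[6])))
    return q


def _posture_at_depth(model: ArmModel, q: np.ndarray, target_y: float,
                      iterations: int = 5) -> np.ndarray:
    """Posture near ``q`` with the hand placed at absolute depth ``target_y``.

    Moves only the elbow and shoulder flexion channels along the local
    gradient of hand y, which keeps the wrist pattern of the base
    posture intact.  Used for approach / retraction via-points.
    """
    channels = (3, 6)
    out = q.copy()
    for _ in range(iterations):
        y0 = hand_y(model, out)
        if abs(y0 - target_y) < 0.05:
            break
        g = np.zeros(len(channels))
        for i, c in enumerate(channels):
            qp = out.copy()
            qp[c] += 0.5
            g[i] = (hand_y(model, qp) - y0) / 0.5
        gg = float(g @ g)
        if gg < 1e-6:  # degenerate gradient: plain shoulder extension
            out[6] -= 8.0
            continue
        step = g * (target_y - y0) / gg
        step = np.clip(step, -15.0, 15.0)
        for i, c in enumerate(channels):
            out[c] += step[i]
        # stay on the near-branch of the reach envelope: beyond ~70 deg of
        # shoulder flexion the hand sweeps back through the shelf plane
        out[6] = float(np.clip(out[6], 0.0, 68.0))
        out[3] = float(np.clip(out[3], 0.0, 115.0))
    return out


def calibrated_keyframes(model: ArmModel) -> dict:
    """Keyframe table with every grasp/release depth-calibrated."""
    kf = {"anatomical": np.zeros(9)}
    release_delta = np.zeros(9)
    release_delta[0] = 2.0  # slight wrist tilt when letting go
    for slot in SLOTS:
        for obj in OBJECTS:
            g = _solve_reach_depth(model, _grasp_posture(slot, obj),
                                   model.shelf_depth_cm)
            r = _solve_reach_depth(model, g + release_delta, model.shelf_depth_cm)
            kf[(slot, obj, "grasp")] = g
            kf[(slot, obj, "release")] = r
    return kf


def enumerate_transports(slots) -> list:
    """Every ordered (origin, destination) pair, lexicographically sorted."""
    unique = sorted(set(slots))
    if len(unique) < 2:
        raise DesignError("need at least two distinct shelf slots")
    return [p for p in itertools.permutations(unique, 2)]


def minimum_jerk_path(q_start, q_end, duration: float, t):
    """Quintic minimum-jerk interpolation between two joint postures.

    q(t) = q_start + (q_end - q_start) * (10 tau^3 - 15 tau^4 + 6 tau^5)
    with tau = t / duration; endpoint velocity and acceleration vanish.
    ``t`` may be scalar or an array; all values must lie in [0, duration].
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > duration):
        raise ValueError("t outside [0, duration]")
    tau = t / duration
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    q_start = np.asarray(q_start, dtype=float)
    q_end = np.asarray(q_end, dtype=float)
    if t.ndim == 0:
        return q_start + (q_end - q_start) * s
    return q_start + (q_end - q_start) * s[:, None]


def forward_kinematics(model: ArmModel, q: np.ndarray) -> dict:
    """Sensor poses (position + rotation matrix) for joint angles ``q``.

    ``q`` is (9,) or (n, 9) in :data:`ANGLE_NAMES` order.  Returns a dict
    sensor -> (pos, R) with pos (n, 3) cm and R (n, 3, 3); the rotation
    composition mirrors the extraction chain exactly, so
    ``extract_joint_angles(forward_kinematics(q)) == q`` away from
    gimbal lock.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[1] != 9:
        raise ValueError("q must have 9 angle columns")
    R_trunk = np.broadcast_to(TRUNK_BASE_ROTATION, (q.shape[0], 3, 3))
    R_arm = R_trunk @ compose_joint(q[:, 6], q[:, 7], q[:, 8])
    R_fore = R_arm @ compose_joint(q[:, 3], q[:, 4], q[:, 5])
    R_hand = R_fore @ compose_joint(q[:, 0], q[:, 1], q[:, 2])

    p_sh = model.shoulder_position
    p_elbow = p_sh + R_arm @ _EX * model.upper_arm
    p_wrist = p_elbow + R_fore @ _EX * model.forearm

    f = model.sensor_fractions
    poses = {
        "trunk": (
            np.broadcast_to(p_sh + TRUNK_BASE_ROTATION @ model.trunk_sensor_offset,
                            (q.shape[0], 3)).copy(),
            R_trunk @ model.mounts["trunk"],
        ),
        "arm": (
            p_sh + R_arm @ _EX * (f["arm"] * model.upper_arm),
            R_arm @ model.mounts["arm"],
        ),
        "forearm": (
            p_elbow + R_fore @ _EX * (f["forearm"] * model.forearm),
            R_fore @ model.mounts["forearm"],
        ),
        "hand": (
            p_wrist + R_hand @ _EX * (f["hand"] * model.hand),
            R_hand @ model.mounts["hand"],
        ),
    }
    return poses


def _minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Scalar minimum-jerk progress 0 -> 1 with vanishing end velocities."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _sample_polyline(vias, s: np.ndarray) -> np.ndarray:
    """Sample a joint-space polyline at normalized arc lengths ``s``."""
    pts = np.asarray(vias, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return np.repeat(pts[:1], len(s), axis=0)
    cs = np.concatenate([[0.0], np.cumsum(seg)]) / total
    out = np.empty((len(s), pts.shape[1]))
    for c in range(pts.shape[1]):
        out[:, c] = np.interp(s, cs, pts[:, c])
    return out


def _trial_phases(model: ArmModel, meta: TrialMeta,
                  g: np.ndarray | None = None, r: np.ndarray | None = None,
                  rng: np.random.Generator | None = None,
                  path_noise_deg: float = 0.0):
    """Via-point polylines for the reach, transport and return phases.

    Every via-point is pulled to a controlled clearance behind the
    shelf plane, and the transport path is densified so the polyline
    never sweeps through the plane between vias — the hand cannot pass
    through a physical shelf, so the hand-y minima coincide with the
    grasp and release events.  ``g``/``r`` optionally override the
    grasp and release keyframes (per-repetition motor variability).
    """
    anat = model.keyframe(None, None, "anatomical")
    if g is None:
        g = model.keyframe(meta.origin, meta.object, "grasp")
    if r is None:
        r = model.keyframe(meta.destination, meta.object, "release")
    shelf = model.shelf_depth_cm
    y_rest = hand_y(model, anat)

    def scheduled(q_from, q_to, depths):
        """Dense polyline from q_from to q_to following a depth schedule."""
        ws = np.linspace(0.0, 1.0, len(depths) + 2)[1:-1]
        vias = [
            _posture_at_depth(model, (1.0 - w) * q_from + w * q_to, d)
            for w, d in zip(ws, depths)
        ]
        return [q_from] + vias + [q_to]

    # Cube-root clearance profiles: the minimum-jerk time profile dwells
    # cubically at the phase boundaries, so a depth that grows like the
    # cube root of path fraction makes hand-y rise linearly in time away
    # from the grasp/release instants — a crisp, detectable touch.
    ws8 = np.linspace(0.0, 1.0, 10)[1:-1]
    reach = scheduled(anat, g, shelf + (y_rest - shelf) * (1.0 - ws8) ** (1.0 / 3.0))
    transport = scheduled(g, r, shelf + 8.0 * np.sin(np.pi * ws8) ** (1.0 / 3.0))
    ret = scheduled(r, anat, shelf + (y_rest - shelf) * ws8 ** (1.0 / 3.0))
    phases = [reach, transport, ret]
    if rng is not None and path_noise_deg > 0:
        # motor variability of the approach: the interior of the path
        # wanders from repetition to repetition while the grasp/release
        # postures stay pinned to the object
        for phase in phases:
            for via in phase[1:-1]:
                d = rng.normal(0.0, path_noise_deg, 9)
                d[2] = 0.0
                via += d
    return phases


def generate_trial(model: ArmModel, design: StudyDesign, meta: TrialMeta,
                   seed: int | np.random.SeedSequence,
                   phases: list | None = None) -> TrialRecord:
    """Simulate one transport trial.

    Joint-space minimum-jerk segments pass through the keyframes
    anatomical -> grasp(origin) -> retract -> release(destination) ->
    anatomical, with per-repetition jittered segment durations.  Sensor
    poses come from forward kinematics plus i.i.d. Gaussian noise on
    positions and orientation angles; orientations are wrapped to
    [-180, 180).  Fully reproducible from the seed.
    """
    if meta.origin == meta.destination:
        raise DesignError("origin and destination slots must differ")
    rng = np.random.default_rng(seed)
    if design.repetition_noise_deg > 0 or design.path_noise_deg > 0:
        # motor variability: every repetition realizes slightly different
        # grasp/release postures (re-calibrated to the fixed shelf plane)
        # and a slightly different approach path
        g = model.keyframe(meta.origin, meta.object, "grasp")
        r = model.keyframe(meta.destination, meta.object, "release")
        if design.repetition_noise_deg > 0:
            wg = rng.normal(0.0, design.repetition_noise_deg, 9)
            wr = rng.normal(0.0, design.repetition_noise_deg, 9)
            wg[2] = wr[2] = 0.0
            g = _solve_reach_depth(model, g + wg, model.shelf_depth_cm)
            r = _solve_reach_depth(model, r + wr, model.shelf_depth_cm)
        phases = _trial_phases(model, meta, g=g, r=r, rng=rng,
                               path_noise_deg=design.path_noise_deg)
    elif phases is None:
        phases = _trial_phases(model, meta)

    n_phase = len(_PHASE_FRACTIONS)
    durations = np.array(_PHASE_FRACTIONS) * design.duration_s
    if design.timing_jitter > 0:
        durations = durations * (
            1.0 + rng.uniform(-design.timing_jitter, design.timing_jitter, size=n_phase)
        )
    bounds = np.concatenate([[0.0], np.cumsum(durations)])
    total = bounds[-1]
    n = int(round(total * design.rate_hz)) + 1
    t = np.arange(n) / design.rate_hz
    t[-1] = min(t[-1], total)

    q = np.empty((n, 9))
    for k in range(n_phase):
        lo, hi = bounds[k], bounds[k + 1]
        sel = (t >= lo) & (t <= hi) if k == n_phase - 1 else (t >= lo) & (t < hi)
        tau = (t[sel] - lo) / (hi - lo)
        q[sel] = _sample_polyline(phases[k], _minimum_jerk_profile(tau))

    grasp_index = int(np.argmin(np.abs(t - bounds[1])))
    release_index = int(np.argmin(np.abs(t - bounds[2])))

    poses = forward_kinematics(model, q)
    sensors = {}
    for sensor in SENSORS:
        pos, R = poses[sensor]
        pos = np.asarray(pos, dtype=float).copy()
        az, el, roll, _ = matrix_to_euler(R)
        euler = np.column_stack([az, el, roll])
        if design.pos_noise_cm > 0:
            pos = pos + rng.normal(0.0, design.pos_noise_cm, size=pos.shape)
        if design.angle_noise_deg > 0:
            euler = euler + rng.normal(0.0, design.angle_noise_deg, size=euler.shape)
        sensors[sensor] = np.column_stack([pos, wrap_angles(euler)])

    return TrialRecord(
        meta=meta,
        t=t,
        sensors=sensors,
        mounts={k: v.copy() for k, v in model.mounts.items()},
        truth_angles=q,
        grasp_index=grasp_index,
        release_index=release_index,
        seed=None if isinstance(seed, np.random.SeedSequence) else int(seed),
    )


def subject_models(model: ArmModel, design: StudyDesign, seed: int) -> dict:
    """Per-subject arm models with keyframes perturbed once per subject.

    One Gaussian perturbation vector (scale ``model.perturb_scale``) is
    drawn per (slot, object) and applied to both the grasp and release
    keyframes; the anatomical rest posture and the wrist axial-rotation
    channel stay untouched.  Perturbations are recorded on the returned
    models in ``keyframe_perturbations``.
    """
    out = {}
    root = np.random.SeedSequence(seed)
    for s in range(design.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, s)))
        kf = {"anatomical": np.zeros(9)}
        perts = {}
        for slot in design.slots:
            for obj in design.objects:
                d = rng.normal(0.0, model.perturb_scale, size=9)
                d[2] = 0.0
                perts[(slot, obj)] = d
                # perturbed postures still reach the same physical shelf
                kf[(slot, obj, "grasp")] = _solve_reach_depth(
                    model, model.keyframe(slot, obj, "grasp") + d, model.shelf_depth_cm
                )
                kf[(slot, obj, "release")] = _solve_reach_depth(
                    model, model.keyframe(slot, obj, "release") + d, model.shelf_depth_cm
                )
        out[s] = replace(
            model,
            keyframes=kf,
            keyframe_perturbations=perts,
        )
    return out


def _trial_seed_sequence(seed: int, meta: TrialMeta, design: StudyDesign):
    oi = list(design.objects).index(meta.object)
    si = sorted(set(design.slots)).index(meta.origin)
    di = sorted(set(design.slots)).index(meta.destination)
    return np.random.SeedSequence(
        seed, spawn_key=(1, meta.subject, oi, si, di, meta.repetition)
    )


def generate_study(design: StudyDesign, seed: int,
                   model: ArmModel | None = None) -> list:
    """Generate one trial per (subject, object, transport, repetition).

    Trial count = n_subjects x n_objects x |transports| x n_repetitions
    (360 for the default design).  Deterministic per (design, seed).
    """
    if model is None:
        model = ArmModel()
    models = subject_models(model, design, seed)
    transports = enumerate_transports(design.slots)
    trials = []
    for s in range(design.n_subjects):
        for obj in design.objects:
            for origin, dest in transports:
                # cache polylines when repetitions share exact postures
                phases = (
                    None
                    if design.repetition_noise_deg > 0
                    else _trial_phases(models[s], TrialMeta(s, obj, origin, dest, 1))
                )
                for rep in range(1, design.n_repetitions + 1):
                    meta = TrialMeta(s, obj, origin, dest, rep)
                    trials.append(
                        generate_trial(models[s], design, meta,
                                       _trial_seed_sequence(seed, meta, design),
                                       phases=phases)
                    )
    return trials
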