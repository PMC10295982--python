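"""Rigid-body joint-angle extraction from body-mounted sensor poses.

Each tracker sensor reports its position and an intrinsic Z-Y'-X'' Euler
orientation (azimuth, elevation, roll) relative to a fixed transmitter.
Joint angles are obtained per sample from the relative rotation between
the sensors on the two segments flanking the joint, decomposed in the
order flexion/extension (about z), abduction/adduction (about y'),
pronation/supination (about x''), with x the distal long axis of the
proximal segment so that axial rotation comes last.

Sensor pairs and the angle triples they yield:

========  =================  ==========================================
joint     sensor pair        decomposed triple
========  =================  ==========================================
wrist     forearm -> hand    wrist_FE, wrist_AA, wrist_PS_res
elbow     arm -> forearm     elbow_FE, elbow_AA, forearm_PS
shoulder  trunk -> arm       shoulder_FE, shoulder_AA, shoulder_PS
========  =================  ==========================================

The wrist axial residual is computed and stored but excluded from
modelling (hand pronation/supination happens in the forearm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical channel order used by every (n, 9) angle array in the package.
ANGLE_NAMES = (
    "wrist_FE",
    "wrist_AA",
    "wrist_PS_res",
    "elbow_FE",
    "elbow_AA",
    "forearm_PS",
    "shoulder_FE",
    "shoulder_AA",
    "shoulder_PS",
)

#: Input channels for the wrist-angle regressors (elbow + shoulder).
INPUT_ANGLES = ("elbow_FE", "elbow_AA", "shoulder_FE", "shoulder_AA", "shoulder_PS")
#: Target channels (wrist flexion/extension, abduction/adduction and
#: forearm pronation/supination).
TARGET_ANGLES = ("wrist_FE", "wrist_AA", "forearm_PS")

INPUT_IDX = tuple(ANGLE_NAMES.index(a) for a in INPUT_ANGLES)
TARGET_IDX = tuple(ANGLE_NAMES.index(a) for a in TARGET_ANGLES)

SENSORS = ("hand", "forearm", "arm", "trunk")

_ORTHO_TOL = 1e-6
_GIMBAL_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a rotation input fails orthonormality checks."""


def euler_to_matrix(azimuth, elevation, roll, degrees: bool = True) -> np.ndarray:
    """Rotation matrix for an intrinsic Z-Y'-X'' Euler triple.

    Broadcasts over array inputs; scalar inputs give a single (3, 3)
    matrix, shape (n,) inputs give (n, 3, 3).
    """
    a, e, r = np.broadcast_arrays(
        np.asarray(azimuth, dtype=float),
        np.asarray(elevation, dtype=float),
        np.asarray(roll, dtype=float),
    )
    if degrees:
        a, e, r = np.radians(a), np.radians(e), np.radians(r)
    ca, sa = np.cos(a), np.sin(a)
    ce, se = np.cos(e), np.sin(e)
    cr, sr = np.cos(r), np.sin(r)
    R = np.empty(a.shape + (3, 3))
    R[..., 0, 0] = ca * ce
    R[..., 0, 1] = ca * se * sr - sa * cr
    R[..., 0, 2] = ca * se * cr + sa * sr
    R[..., 1, 0] = sa * ce
    R[..., 1, 1] = sa * se * sr + ca * cr
    R[..., 1, 2] = sa * se * cr - ca * sr
    R[..., 2, 0] = -se
    R[..., 2, 1] = ce * sr
    R[..., 2, 2] = ce * cr
    return R


def compose_joint(fe, aa, ps, degrees: bool = True) -> np.ndarray:
    """R = R_FE(z) @ R_AA(y) @ R_PS(x) — same algebra as ``euler_to_matrix``."""
    return euler_to_matrix(fe, aa, ps, degrees=degrees)


def matrix_to_euler(R: np.ndarray, degrees: bool = True):
    """Invert the intrinsic Z-Y'-X'' composition.

    Returns (azimuth, elevation, roll, gimbal_flag).  At gimbal lock
    (|elevation| = 90 deg) only the sum/difference of the outer angles
    is defined; the roll is reported as zero and the azimuth carries the
    whole residual rotation.
    """
    R = np.asarray(R, dtype=float)
    se = -R[..., 2, 0]
    se = np.clip(se, -1.0, 1.0)
    elevation = np.arcsin(se)
    ce = np.cos(elevation)
    gimbal = np.abs(ce) < _GIMBAL_TOL

    azimuth = np.where(gimbal, 0.0, np.arctan2(R[..., 1, 0], R[..., 0, 0]))
    roll = np.where(gimbal, 0.0, np.arctan2(R[..., 2, 1], R[..., 2, 2]))
    if np.any(gimbal):
        # At the poles only az -/+ roll is defined; with roll pinned to 0:
        # elevation=+90: R[0,1] = -sin(az), R[0,2] =  cos(az)
        # elevation=-90: R[0,1] = -sin(az), R[0,2] = -cos(az)
        az_lock = np.arctan2(-R[..., 0, 1], np.where(se < 0, -1.0, 1.0) * R[..., 0, 2])
        azimuth = np.where(gimbal, az_lock, azimuth)
    if degrees:
        azimuth, elevation, roll = map(np.degrees, (azimuth, elevation, roll))
    return azimuth, elevation, roll, gimbal


def _check_orthonormal(R: np.ndarray, tol: float = _ORTHO_TOL, name: str = "rotation"):
    R = np.asarray(R, dtype=float)
    eye = np.eye(3)
    err = np.abs(np.swapaxes(R, -1, -2) @ R - eye).max()
    if err > tol:
        raise ValidationError(f"{name} is not orthonormal (max |R'R - I| = {err:.3g})")
    det = np.linalg.det(R)
    if np.any(np.abs(det - 1.0) > max(tol, 1e-6)):
        raise ValidationError(f"{name} is not a proper rotation (det != +1)")
    return R


def relative_rotation(proximal: np.ndarray, distal: np.ndarray) -> np.ndarray:
    """Distal segment expressed in the proximal frame: proximal^T @ distal."""
    proximal = _check_orthonormal(proximal, name="proximal")
    distal = _check_orthonormal(distal, name="distal")
    return np.swapaxes(proximal, -1, -2) @ distal


def decompose_joint(R: np.ndarray, degrees: bool = True):
    """Factor a joint rotation as R_FE(z) @ R_AA(y) @ R_PS(x).

    Returns (FE, AA, PS, gimbal_flag) with AA in [-90, 90] deg.  The
    gimbal flag marks samples where |cos AA| < 1e-6; there FE absorbs
    the coupled rotation and PS is reported as zero.
    """
    return matrix_to_euler(R, degrees=degrees)


def unwrap_series(wrapped, period: float = 360.0, axis: int = 0) -> np.ndarray:
    """Remove +/-360 deg jumps from an angle series stored in [-180, 180].

    The first sample is unchanged; consecutive differences are brought
    into (-period/2, period/2] by adding multiples of the period.
    """
    return np.unwrap(np.asarray(wrapped, dtype=float), period=period, axis=axis)


def wrap_angles(angles, period: float = 360.0) -> np.ndarray:
    """Wrap angles into [-period/2, period/2)."""
    a = np.asarray(angles, dtype=float)
    half = period / 2.0
    return (a + half) % period - half


@dataclass
class TrialSeries:
    """Per-trial joint-angle series plus the hand trajectory.

    ``angles`` follows :data:`ANGLE_NAMES` column order, in degrees,
    continuous (unwrapped).  ``provenance`` accumulates processing flags
    (raw / synchronized / filtered / normalized / centered).
    """

    meta: "object"
    t: np.ndarray
    angles: np.ndarray
    hand_pos: np.ndarray
    truth_angles: np.ndarray | None = None
    grasp_index: int | None = None
    release_index: int | None = None
    provenance: tuple = ("raw",)
    gimbal_fraction: float = 0.0

    def copy_with(self, **kw) -> "TrialSeries":
        return replace(self, **kw)


def _segment_rotations(trial, mounting: str | dict = "attached",
                       calibration_window_s: float = 0.5) -> dict:
    """Per-sensor segment rotation matrices with mounting frames removed."""
    from .synthetic import TrialRecord  # local import to avoid a cycle

    if isinstance(mounting, dict):
        mounts = mounting
    elif mounting == "attached":
        if trial.mounts is None:
            raise ValueError("trial carries no mounting frames; use mounting='calibrate'")
        mounts = trial.mounts
    elif mounting == "calibrate":
        mounts = estimate_mounts_static(trial, window_s=calibration_window_s)
    else:
        raise ValueError(f"unknown mounting option {mounting!r}")

    segs = {}
    for sensor in SENSORS:
        pose = trial.sensors.get(sensor)
        if pose is None:
            raise ValueError(f"trial is missing the {sensor!r} sensor")
        R_sensor = euler_to_matrix(pose[:, 3], pose[:, 4], pose[:, 5])
        segs[sensor] = R_sensor @ mounts[sensor].T
    return segs


def estimate_mounts_static(trial, window_s: float = 0.5) -> dict:
    """Static-calibration mounting frames from an anatomical-rest window.

    At anatomical rest every segment frame coincides with the trunk
    base frame, so the mean sensor rotation over the window, projected
    back onto SO(3), gives the mounting rotation directly.
    """
    from .synthetic import TRUNK_BASE_ROTATION

    n = max(2, int(round(window_s / max(np.diff(trial.t).mean(), 1e-9))))
    mounts = {}
    for sensor in SENSORS:
        pose = trial.sensors[sensor]
        R = euler_to_matrix(pose[:n, 3], pose[:n, 4], pose[:n, 5]).mean(axis=0)
        R = TRUNK_BASE_ROTATION.T @ R
        U, _, Vt = np.linalg.svd(R)
        M = U @ Vt
        if np.linalg.det(M) < 0:
            U[:, -1] *= -1
            M = U @ Vt
        mounts[sensor] = M
    return mounts


def extract_joint_angles(trial, mounting: str | dict = "attached",
                         gimbal_warn_fraction: float = 0.01) -> TrialSeries:
    """Compute the nine inter-segment angles for one trial.

    Per sample the three sensor-pair relative rotations are decomposed
    with :func:`decompose_joint`; outputs are unwrapped to continuous
    degree series.  A warning is issued when more than
    ``gimbal_warn_fraction`` of samples sit at gimbal lock.
    """
    segs = _segment_rotations(trial, mounting)
    pairs = (
        ("forearm", "hand"),     # -> wrist triple
        ("arm", "forearm"),      # -> elbow FE/AA + forearm PS
        ("trunk", "arm"),        # -> shoulder triple
    )
    n = trial.t.shape[0]
    angles = np.empty((n, 9))
    gimbal_total = 0
    for k, (prox, dist) in enumerate(pairs):
        R_rel = np.swapaxes(segs[prox], -1, -2) @ segs[dist]
        fe, aa, ps, gimbal = decompose_joint(R_rel)
        angles[:, 3 * k + 0] = fe
        angles[:, 3 * k + 1] = aa
        angles[:, 3 * k + 2] = ps
        gimbal_total += int(np.count_nonzero(gimbal))
    frac = gimbal_total / (3 * n)
    if frac > gimbal_warn_fraction:
        warnings.warn(
            f"{100 * frac:.1f}% of samples are gimbal-locked; "
            "the affected Euler triples are degenerate",
            RuntimeWarning,
        )
    angles = unwrap_series(angles, axis=0)
    return TrialSeries(
        meta=trial.meta,
        t=trial.t.copy(),
        angles=angles,
        hand_pos=trial.sensors["hand"][:, :3].copy(),
        truth_angles=None if trial.truth_angles is None else trial.truth_angles.copy(),
        grasp_index=trial.grasp_index,
        release_index=trial.release_index,
        provenance=("raw",),
        gimbal_fraction=frac,
    )
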