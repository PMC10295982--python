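"""Repetition synchronization, filtering and time normalization.

The processing chain per trial group (one subject, object, origin,
destination — three repetitions):

1. synchronize the repetitions onto the first repetition's time base by
   dynamic time warping of the 3-D hand trajectory;
2. low-pass filter every channel (3rd-order Butterworth, zero-phase by
   default);
3. linearly resample onto the normalized 101-point grid (time step 0.01);
4. optionally re-express every angle as the deviation from its
   per-subject mean (sensor-placement differences cancel out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .kinematics import ANGLE_NAMES, TrialSeries
from .synthetic import ConfigError, TrialMeta

N_NORMALIZED = 101

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


class DataError(ValueError):
    """Raised for structurally invalid series inputs."""


@dataclass
class NormalizedTrial:
    """One trial on the normalized 101-sample grid.

    ``angles`` is (101, 9) degrees; ``hand_pos`` is (101, 3) cm.  The
    pick (PK) and place (PL) indices are filled in by the event
    detector; ``offsets`` holds per-subject centering offsets (deg, one
    per angle channel) once centering has been applied.
    """

    meta: TrialMeta
    tau: np.ndarray
    angles: np.ndarray
    hand_pos: np.ndarray
    truth_angles: np.ndarray | None = None
    true_pk: int | None = None
    true_pl: int | None = None
    pk: int | None = None
    pl: int | None = None
    offsets: np.ndarray | None = None
    provenance: tuple = ()

    def __post_init__(self):
        if self.angles.shape[0] != N_NORMALIZED:
            raise DataError("normalized trials must have exactly 101 samples")

    @property
    def centered(self) -> bool:
        return self.offsets is not None


# ---------------------------------------------------------------------------
# dynamic time warping

def _dtw_tables(C: np.ndarray):
    n, m = C.shape
    D = np.full((n, m), np.inf)
    P = np.zeros((n, m), dtype=np.int8)  # 0 diag, 1 up (i-1), 2 left (j-1)
    D[0, 0] = C[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + C[0, j]
        P[0, j] = 2
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        P[i, 0] = 1
        for j in range(1, m):
            diag = D[i - 1, j - 1]
            up = D[i - 1, j]
            left = D[i, j - 1]
            best, move = diag, 0
            if up < best:
                best, move = up, 1
            if left < best:
                best, move = left, 2
            D[i, j] = C[i, j] + best
            P[i, j] = move
    return D, P


if _HAVE_NUMBA:
    _dtw_tables_jit = njit(cache=True)(_dtw_tables)
else:  # pragma: no cover
    _dtw_tables_jit = _dtw_tables


def dtw(reference: np.ndarray, query: np.ndarray, metric: str = "euclidean"):
    """Globally optimal monotone alignment of two multichannel series.

    Steps are {(1,0), (0,1), (1,1)}; the cumulative cost is the sum of
    local distances along the path.  Ties prefer the diagonal step.
    Returns ``(cost, path)`` with the path a list of (i, j) index pairs
    from (0, 0) to (n-1, m-1).
    """
    a = np.atleast_2d(np.asarray(reference, dtype=float))
    b = np.atleast_2d(np.asarray(query, dtype=float))
    if a.shape[0] == 1 and a.shape[1] > 1 and np.ndim(reference) == 1:
        a = a.T
    if b.shape[0] == 1 and b.shape[1] > 1 and np.ndim(query) == 1:
        b = b.T
    if a.size == 0 or b.size == 0:
        raise DataError("cannot align empty series")
    if a.shape[1] != b.shape[1]:
        raise DataError("reference and query must share the channel count")
    from scipy.spatial.distance import cdist

    C = cdist(a, b, metric=metric)
    D, P = _dtw_tables_jit(np.ascontiguousarray(C))
    i, j = C.shape[0] - 1, C.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        move = P[i, j]
        if move == 0:
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return float(D[-1, -1]), path


def warp_onto_reference(path, values: np.ndarray, n_ref: int) -> np.ndarray:
    """Average query samples mapped to each reference index by a DTW path."""
    out = np.zeros((n_ref,) + values.shape[1:])
    counts = np.zeros(n_ref)
    for i, j in path:
        out[i] += values[j]
        counts[i] += 1
    return out / counts.reshape((n_ref,) + (1,) * (values.ndim - 1))


def map_index_through_path(path, query_index: int) -> int:
    """Reference index a query sample lands on after warping (median pair)."""
    refs = [i for i, j in path if j == query_index]
    if not refs:
        raise DataError("query index not covered by the warping path")
    return int(refs[len(refs) // 2])


def synchronize_repetitions(group: list[TrialSeries]) -> list[TrialSeries]:
    """Warp repetitions 2..n of a trial group onto repetition 1's time base.

    The alignment signal is the 3-D hand trajectory (Euclidean metric);
    the resulting path re-times every angle channel, the hand position,
    the ground-truth angles and the true event indices.  With fewer
    than two repetitions the input is passed through with a warning.
    """
    if len(group) < 2:
        warnings.warn("fewer than 2 repetitions; nothing to synchronize", RuntimeWarning)
        return [g.copy_with(provenance=g.provenance + ("synchronized",)) for g in group]
    group = sorted(group, key=lambda ts: ts.meta.repetition)
    ref = group[0]
    n_ref = len(ref.t)
    out = [ref.copy_with(provenance=ref.provenance + ("synchronized",))]
    for ts in group[1:]:
        _, path = dtw(ref.hand_pos, ts.hand_pos)
        angles = warp_onto_reference(path, ts.angles, n_ref)
        hand = warp_onto_reference(path, ts.hand_pos, n_ref)
        truth = (
            None
            if ts.truth_angles is None
            else warp_onto_reference(path, ts.truth_angles, n_ref)
        )
        out.append(
            ts.copy_with(
                t=ref.t.copy(),
                angles=angles,
                hand_pos=hand,
                truth_angles=truth,
                grasp_index=(
                    None
                    if ts.grasp_index is None
                    else map_index_through_path(path, ts.grasp_index)
                ),
                release_index=(
                    None
                    if ts.release_index is None
                    else map_index_through_path(path, ts.release_index)
                ),
                provenance=ts.provenance + ("synchronized",),
            )
        )
    return out


# ---------------------------------------------------------------------------
# filtering and resampling

def butterworth_lowpass(series: np.ndarray, cutoff_hz: float, rate_hz: float,
                        order: int = 3, zero_phase: bool = True) -> np.ndarray:
    """3rd-order Butterworth low-pass with reflection-padded edges.

    ``zero_phase`` applies the filter forward and backward (no lag,
    squared magnitude response: gain 0.5 at the cutoff instead of
    1/sqrt(2)).
    """
    if not 0 < cutoff_hz < rate_hz / 2:
        raise ConfigError("cutoff must lie in (0, Nyquist)")
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    # reflection padding well beyond 3x the filter order so edge
    # transients decay inside the padding
    pad = min(x.shape[0] - 1, max(3 * order, int(3 * rate_hz / cutoff_hz)))
    if zero_phase:
        y = signal.sosfiltfilt(sos, x, axis=0, padtype="even", padlen=pad)
    else:
        xp = np.pad(x, ((pad, 0), (0, 0)), mode="reflect") if pad else x
        zi = signal.sosfilt_zi(sos)  # steady-state unit-step conditions
        y = np.empty_like(xp)
        for c in range(xp.shape[1]):
            y[:, c], _ = signal.sosfilt(sos, xp[:, c], zi=zi * xp[0, c])
        y = y[pad:] if pad else y
    return y[:, 0] if one_d else y


def resample_normalized(series: np.ndarray, n: int = N_NORMALIZED) -> np.ndarray:
    """Linear interpolation onto the normalized grid {0, 1/(n-1), ..., 1}."""
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 2:
        raise DataError("need at least two samples to resample")
    src = np.linspace(0.0, 1.0, x.shape[0])
    dst = np.linspace(0.0, 1.0, n)
    if x.ndim == 1:
        return np.interp(dst, src, x)
    out = np.empty((n,) + x.shape[1:])
    for c in np.ndindex(x.shape[1:]):
        out[(slice(None),) + c] = np.interp(dst, src, x[(slice(None),) + c])
    return out


def normalize_trial(ts: TrialSeries, cutoff_hz: float = 5.0, rate_hz: float | None = None,
                    zero_phase: bool = True) -> NormalizedTrial:
    """Filter a (synchronized) trial and resample it to 101 points."""
    if rate_hz is None:
        rate_hz = 1.0 / float(np.mean(np.diff(ts.t)))
    angles = butterworth_lowpass(ts.angles, cutoff_hz, rate_hz, zero_phase=zero_phase)
    hand = butterworth_lowpass(ts.hand_pos, cutoff_hz, rate_hz, zero_phase=zero_phase)
    n_raw = angles.shape[0]

    def to_grid(idx):
        return None if idx is None else int(round(idx * (N_NORMALIZED - 1) / (n_raw - 1)))

    return NormalizedTrial(
        meta=ts.meta,
        tau=np.round(np.linspace(0.0, 1.0, N_NORMALIZED), 2),
        angles=resample_normalized(angles),
        hand_pos=resample_normalized(hand),
        truth_angles=(
            None if ts.truth_angles is None else resample_normalized(ts.truth_angles)
        ),
        true_pk=to_grid(ts.grasp_index),
        true_pl=to_grid(ts.release_index),
        provenance=ts.provenance + ("filtered", "normalized"),
    )


def preprocess_study(extracted: list[TrialSeries], cutoff_hz: float = 5.0,
                     zero_phase: bool = True,
                     synchronize: bool = True) -> list[NormalizedTrial]:
    """Full per-group preprocessing of an extracted study."""
    groups: dict = {}
    for ts in extracted:
        groups.setdefault(ts.meta.group_key(), []).append(ts)
    out = []
    for key in sorted(groups):
        group = groups[key]
        if synchronize and len(group) >= 2:
            group = synchronize_repetitions(group)
        for ts in group:
            out.append(normalize_trial(ts, cutoff_hz=cutoff_hz, zero_phase=zero_phase))
    return out


# ---------------------------------------------------------------------------
# per-subject centering

def center_by_subject(trials: list[NormalizedTrial]):
    """Re-express every angle as its deviation from the subject mean.

    The offset per (subject, channel) is the mean over all of that
    subject's normalized samples across all their trials, mirroring the
    sensor-placement correction applied before network training.
    Returns ``(centered_trials, offsets)`` with offsets a dict
    subject -> (9,) array for the inverse transform.
    """
    per_subject: dict = {}
    for nt in trials:
        per_subject.setdefault(nt.meta.subject, []).append(nt)
    offsets = {
        s: np.vstack([nt.angles for nt in group]).mean(axis=0)
        for s, group in per_subject.items()
    }
    centered = []
    for nt in trials:
        if nt.centered:  # idempotent: already deviations from the mean
            centered.append(nt)
            continue
        off = offsets[nt.meta.subject]
        centered.append(
            NormalizedTrial(
                meta=nt.meta,
                tau=nt.tau,
                angles=nt.angles - off,
                hand_pos=nt.hand_pos,
                truth_angles=nt.truth_angles,
                true_pk=nt.true_pk,
                true_pl=nt.true_pl,
                pk=nt.pk,
                pl=nt.pl,
                offsets=off.copy(),
                provenance=nt.provenance + ("centered",),
            )
        )
    return centered, offsets


def uncenter(trials: list[NormalizedTrial]) -> list[NormalizedTrial]:
    """Inverse of :func:`center_by_subject`."""
    out = []
    for nt in trials:
        if not nt.centered:
            out.append(nt)
            continue
        out.append(
            NormalizedTrial(
                meta=nt.meta,
                tau=nt.tau,
                angles=nt.angles + nt.offsets,
                hand_pos=nt.hand_pos,
                truth_angles=nt.truth_angles,
                true_pk=nt.true_pk,
                true_pl=nt.true_pl,
                pk=nt.pk,
                pl=nt.pl,
                offsets=None,
                provenance=nt.provenance + ("uncentered",),
            )
        )
    return out


# ---------------------------------------------------------------------------
# tapered concatenation

def tukey_window(n: int = N_NORMALIZED, taper_len: int = 5) -> np.ndarray:
    """Tukey window whose cosine ramps span exactly ``taper_len`` samples."""
    if taper_len >= (n - 1) // 2:  # alpha would reach 1: no flat centre left
        raise ConfigError("taper length must leave the central samples unaltered")
    return signal.windows.tukey(n, alpha=2.0 * taper_len / (n - 1))


def taper_concatenate(trials: list[NormalizedTrial], taper_len: int = 5,
                      order_seed: int | None = None):
    """Concatenate trials into one long multichannel series.

    Each trial's channels are multiplied by a Tukey window that brings
    the first and last ``taper_len`` samples to zero at the trial
    edges, so consecutive trials meet without jumps; the central
    samples are unaltered.  Returns ``(angles, hand, boundaries,
    order)`` where boundaries[k] is the start row of trial k in the
    (seeded, recorded) concatenation order.
    """
    if not trials:
        raise DataError("no trials to concatenate")
    order = np.arange(len(trials))
    if order_seed is not None:
        order = np.random.default_rng(order_seed).permutation(len(trials))
    w = tukey_window(N_NORMALIZED, taper_len)[:, None]
    angle_parts, hand_parts, boundaries = [], [], []
    row = 0
    for k in order:
        nt = trials[k]
        boundaries.append(row)
        angle_parts.append(nt.angles * w)
        hand_parts.append(nt.hand_pos * w)
        row += N_NORMALIZED
    return (
        np.vstack(angle_parts),
        np.vstack(hand_parts),
        boundaries,
        [int(k) for k in order],
    )
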