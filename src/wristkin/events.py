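"""Pick/place event detection, anticipation, and dataset assembly.

The pick (PK) and place (PL) instants are the two minima of the hand
sensor's y coordinate — the hand is deepest toward the shelf exactly
when the object is grasped and released.  On the normalized 101-point
grid the first half of the record holds the reach (PK), the second the
return (PL).

Two dataset layouts feed the two network families:

* an instant-wise case table (two rows per trial, one per event) for
  the feed-forward network, with inputs sampled an anticipation ahead
  of the event and targets at the event itself;
* a delay-embedded concatenated series for the time-delay network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import INPUT_ANGLES, INPUT_IDX, TARGET_ANGLES, TARGET_IDX
from .preprocessing import DataError, N_NORMALIZED, NormalizedTrial
from .synthetic import ConfigError

logger = logging.getLogger(__name__)

#: Case-table column names.
INPUT_COLS = [f"in_{a}" for a in INPUT_ANGLES]
TARGET_COLS = [f"out_{a}" for a in TARGET_ANGLES]
META_COLS = ["subject", "object", "origin", "destination", "repetition", "event"]


class DetectionError(ValueError):
    """Raised when the hand trajectory carries no usable depth minimum."""


@dataclass(frozen=True)
class EventPair:
    """PK and PL indices on the normalized grid."""

    pk: int
    pl: int

    def __post_init__(self):
        if not 0 <= self.pk < self.pl <= N_NORMALIZED - 1:
            raise ValueError("event indices must satisfy 0 <= pk < pl <= 100")


@dataclass(frozen=True)
class DelaySpec:
    """Delays (in normalized steps) applied to the input channels.

    The label follows the inclusive "a:b" convention, e.g. "1:10" for
    the previous ten instants (about 0.5 s) and "11:12" for two
    instants anticipated half a second ahead of the prediction.
    """

    delays: tuple
    label: str

    def __post_init__(self):
        d = self.delays
        if not d or any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ConfigError("delays must be strictly positive and increasing")

    @classmethod
    def parse(cls, label: str) -> "DelaySpec":
        a, b = (int(x) for x in label.split(":"))
        return cls(delays=tuple(range(a, b + 1)), label=label)

    @property
    def max_delay(self) -> int:
        return max(self.delays)

    @property
    def n_features(self) -> int:
        return len(INPUT_ANGLES) * len(self.delays)


def detect_pick_place(trial: NormalizedTrial, min_range_cm: float = 0.1,
                      mode: str = "halves") -> EventPair:
    """Locate PK and PL from the hand-y minima of a normalized trial.

    ``halves`` mode takes the argmin over indices [0, 50] (PK) and
    [51, 100] (PL), ties resolved to the earliest index.  The
    ``local_minima`` mode instead picks the two most prominent local
    minima (first = PK) — useful when the transport is not centred.
    """
    y = trial.hand_pos[:, 1]
    if np.ptp(y) < min_range_cm:
        raise DetectionError("hand y range below 0.1 cm; no transport detected")
    if mode == "halves":
        half = (N_NORMALIZED - 1) // 2
        pk = int(np.argmin(y[: half + 1]))
        pl = half + 1 + int(np.argmin(y[half + 1:]))
    elif mode == "local_minima":
        from scipy.signal import find_peaks

        idx, props = find_peaks(-y, prominence=min_range_cm)
        if len(idx) < 2:
            raise DetectionError("fewer than two prominent hand-y minima")
        best = idx[np.argsort(props["prominences"])[-2:]]
        pk, pl = int(best.min()), int(best.max())
    else:
        raise ConfigError(f"unknown detection mode {mode!r}")
    return EventPair(pk=pk, pl=pl)


def detect_events(trials: list[NormalizedTrial], mode: str = "halves"):
    """Detect and attach events for every trial (in place); returns trials."""
    for nt in trials:
        pair = detect_pick_place(nt, mode=mode)
        nt.pk, nt.pl = pair.pk, pair.pl
    return trials


def anticipation_to_steps(anticipation_s: float, step_duration_s: float = 0.05) -> int:
    """Convert a time anticipation to normalized grid steps (0.5 s -> 10)."""
    if anticipation_s < 0:
        raise ConfigError("anticipation must be non-negative")
    return int(round(anticipation_s / step_duration_s))


def assemble_ffnn_cases(trials: list[NormalizedTrial], anticipation_steps: int,
                        extensions: frozenset | set = frozenset()) -> pd.DataFrame:
    """Instant-wise case table: two rows per trial (PK and PL).

    Inputs are the five elbow/shoulder angles sampled
    ``anticipation_steps`` before the event; targets are the three
    wrist angles at the event.  Optional one-hot extensions append the
    manipulated object (1 unit), the subject identity (one unit per
    subject) and the task type PK/PL (1 unit).  Trials whose PK
    precedes the anticipation are skipped with a warning.
    """
    unknown = set(extensions) - {"object", "subject", "task"}
    if unknown:
        raise ConfigError(f"unknown case-table extensions {sorted(unknown)}")
    subjects = sorted({nt.meta.subject for nt in trials})
    objects = sorted({nt.meta.object for nt in trials})
    rows = []
    for nt in trials:
        if nt.pk is None or nt.pl is None:
            raise DataError("events not detected; run detect_events first")
        for event_name, event_idx in (("PK", nt.pk), ("PL", nt.pl)):
            t_in = event_idx - anticipation_steps
            if t_in < 0:
                logger.warning(
                    "trial %s: anticipation exceeds %s index; row skipped",
                    nt.meta, event_name,
                )
                continue
            row = dict(zip(INPUT_COLS, nt.angles[t_in, list(INPUT_IDX)]))
            row.update(zip(TARGET_COLS, nt.angles[event_idx, list(TARGET_IDX)]))
            if "object" in extensions:
                row["ext_object"] = float(objects.index(nt.meta.object))
            if "subject" in extensions:
                for s in subjects:
                    row[f"ext_subject_{s}"] = float(nt.meta.subject == s)
            if "task" in extensions:
                row["ext_task"] = float(event_name == "PL")
            row.update(
                subject=nt.meta.subject,
                object=nt.meta.object,
                origin=nt.meta.origin,
                destination=nt.meta.destination,
                repetition=nt.meta.repetition,
                event=event_name,
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    ext_cols = [c for c in df.columns if c.startswith("ext_")]
    return df[INPUT_COLS + ext_cols + TARGET_COLS + META_COLS]


def feature_columns(table: pd.DataFrame) -> list:
    """Input + extension columns of a case table."""
    return INPUT_COLS + [c for c in table.columns if c.startswith("ext_")]


def split_cases(table: pd.DataFrame, test_fraction: float = 0.15,
                stratify: str | None = None, seed: int | None = None):
    """Seeded random train/test split of a case table.

    With ``stratify='object'`` the test rows are balanced across the
    two objects (plus/minus one row).  Returns ``(train, test)`` as
    disjoint, exhaustive row subsets.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError("test fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_test = int(round(n * test_fraction))
    if stratify is None:
        test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    elif stratify == "object":
        test_parts = []
        values = sorted(table["object"].unique())
        quota = np.full(len(values), n_test // len(values))
        quota[: n_test % len(values)] += 1
        for v, k in zip(values, quota):
            pool = np.flatnonzero((table["object"] == v).to_numpy())
            test_parts.append(rng.choice(pool, size=min(int(k), len(pool)),
                                         replace=False))
        test_idx = np.sort(np.concatenate(test_parts))
    else:
        raise ConfigError(f"unknown stratification {stratify!r}")
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return table.iloc[~mask].copy(), table.iloc[mask].copy()


def split_manifest(table: pd.DataFrame, test_fraction: float = 0.15,
                   stratify: str | None = None, seed: int | None = None) -> dict:
    """Reproducible record of a case split: seed plus row indices."""
    train, test = split_cases(table, test_fraction, stratify, seed)
    return {
        "seed": seed,
        "test_fraction": test_fraction,
        "stratify": stratify,
        "train_rows": [int(i) for i in train.index],
        "test_rows": [int(i) for i in test.index],
    }


def split_trials(trials: list[NormalizedTrial], test_fraction: float = 0.15,
                 seed: int | None = None):
    """Trial-level stratified split for the time-delay pipeline.

    Fifteen percent of trials by default, half per object (the
    delay-embedded series must not mix train and test samples within a
    trial).
    """
    rng = np.random.default_rng(seed)
    by_object: dict = {}
    for k, nt in enumerate(trials):
        by_object.setdefault(nt.meta.object, []).append(k)
    n_test = int(round(len(trials) * test_fraction))
    values = sorted(by_object)
    quota = np.full(len(values), n_test // len(values))
    quota[: n_test % len(values)] += 1
    test_set = set()
    for v, k in zip(values, quota):
        pool = np.array(by_object[v])
        test_set |= set(rng.choice(pool, size=min(int(k), len(pool)), replace=False))
    train = [nt for i, nt in enumerate(trials) if i not in test_set]
    test = [nt for i, nt in enumerate(trials) if i in test_set]
    return train, test


def delay_embed(X: np.ndarray, delays) -> tuple:
    """Tapped-delay-line embedding of an arbitrary series.

    Row t of the output holds the channels of ``X`` at t-d for every
    delay d (channel count x n_delays features, zero-padded before the
    series start); ``valid`` masks the first max(delays) rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T = X.shape[0]
    maxd = max(delays)
    if T <= maxd:
        raise DataError("series shorter than the maximum delay")
    blocks = []
    for d in delays:
        shifted = np.zeros_like(X)
        shifted[d:] = X[:-d]
        blocks.append(shifted)
    valid = np.zeros(T, dtype=bool)
    valid[maxd:] = True
    return np.hstack(blocks), valid


def embed_delays(angles: np.ndarray, spec: DelaySpec):
    """Delay-embed a concatenated angle series for the time-delay network.

    Returns ``(X, Y, valid)``: X has one row per sample with the five
    input channels at t-d for every delay d (5 x n_delays features), Y
    the three wrist-angle targets at t, and ``valid`` masks out the
    first ``max_delay`` samples of the concatenation.  Trial
    boundaries are deliberately not masked — the Tukey taper already
    brings the series to zero there.
    """
    a = np.asarray(angles, dtype=float)
    X, valid = delay_embed(a[:, list(INPUT_IDX)], spec.delays)
    Y = a[:, list(TARGET_IDX)]
    return X, Y, valid
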