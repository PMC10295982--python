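"""Metrics and the experiment harness.

Reports mirror the study's comparison tables: per-wrist-angle error
(MAE for the instant-wise network, RMSE for the time-delay network),
plus a correlation coefficient — pooled Pearson over all test outputs
for the three-output feed-forward network, the mean of the three
per-angle Pearson coefficients for the single-output time-delay
networks.  Every configuration is averaged over several independent
training sessions (distinct test splits and initializations).

Correlations and errors are computed on the subject-centered angle
scale (deviations from each subject's mean posture), which is the
scale the networks are trained on; MAE/RMSE are identical on the
centered and raw scales because centering shifts targets and
predictions alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import (
    DelaySpec,
    TARGET_COLS,
    anticipation_to_steps,
    assemble_ffnn_cases,
    feature_columns,
    split_cases,
    split_trials,
)
from .kinematics import INPUT_IDX, TARGET_ANGLES, TARGET_IDX
from .preprocessing import NormalizedTrial, taper_concatenate
from .regressors import ShallowNetRegressor, TimeDelayNetRegressor, fit_linear
from .synthetic import ConfigError


# ---------------------------------------------------------------------------
# metrics

def mae(actual, predicted) -> float:
    """Mean absolute error, degrees."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def rmse(actual, predicted) -> float:
    """Root-mean-square error, degrees."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def _paired(actual, predicted):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must have equal, nonzero shape")
    return a, p


def correlation(actual, predicted, mode: str = "pooled") -> float:
    """Pearson correlation between targets and predictions.

    ``pooled`` concatenates all channels into one pair of vectors;
    ``per_angle_mean`` averages the per-channel coefficients.
    """
    a = np.atleast_2d(np.asarray(actual, dtype=float).T).T
    p = np.atleast_2d(np.asarray(predicted, dtype=float).T).T
    if a.shape != p.shape or a.shape[0] < 2:
        raise ValueError("need >= 2 paired samples")
    if mode == "pooled":
        return _pearson(a.ravel(), p.ravel())
    if mode == "per_angle_mean":
        return float(np.mean([_pearson(a[:, k], p[:, k]) for k in range(a.shape[1])]))
    raise ConfigError(f"unknown correlation mode {mode!r}")


def _pearson(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# helpers

def restrict_trials(trials, obj: str | None = None, subject: int | None = None):
    """Subset a study to one object and/or one subject."""
    out = [
        nt
        for nt in trials
        if (obj is None or nt.meta.object == obj)
        and (subject is None or nt.meta.subject == subject)
    ]
    if not out:
        raise ConfigError("restriction leaves no trials")
    return out


def stack_trials(trials: list[NormalizedTrial]):
    """Vertically stack all normalized samples: (X 5-angle, Y 3-angle)."""
    A = np.vstack([nt.angles for nt in trials])
    return A[:, list(INPUT_IDX)], A[:, list(TARGET_IDX)]


def _session_seed(seed: int, offset: int) -> int:
    return int((seed + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# experiments

def run_ffnn_experiment(trials: list[NormalizedTrial], neurons=(10,),
                        anticipations_s=(0.5,), extensions=(frozenset(),),
                        trainers=("bayes-lm",), sessions: int = 5,
                        seed: int = 0, test_fraction: float = 0.15,
                        max_epochs: int = 100,
                        label: str = "") -> pd.DataFrame:
    """Instant-wise network over a (neurons x anticipation x extensions x
    trainer) grid, averaged over training sessions.

    Each session draws its own 15 % test split and initialization from
    the derived seed ``seed + s``.  Returns one row per grid cell with
    mean and SD of the per-angle MAE and of the pooled correlation.
    """
    grid = [
        (h, ant, frozenset(ext), tr)
        for h in neurons
        for ant in anticipations_s
        for ext in extensions
        for tr in trainers
    ]
    if not grid or sessions < 1:
        raise ConfigError("empty experiment grid")
    rows = []
    for h, ant, ext, trainer in grid:
        steps = anticipation_to_steps(ant)
        table = assemble_ffnn_cases(trials, steps, ext)
        feats = feature_columns(table)
        per_session = []
        for s in range(sessions):
            s_seed = _session_seed(seed, s)
            train, test = split_cases(table, test_fraction, seed=s_seed)
            model = ShallowNetRegressor(
                hidden_units=h, solver=trainer, max_epochs=max_epochs,
                random_state=s_seed,
            ).fit(train[feats].to_numpy(), train[TARGET_COLS].to_numpy())
            pred = model.predict(test[feats].to_numpy())
            actual = test[TARGET_COLS].to_numpy()
            per_session.append(
                [mae(actual[:, k], pred[:, k]) for k in range(3)]
                + [correlation(actual, pred, mode="pooled")]
            )
        arr = np.array(per_session)
        rows.append(
            {
                "label": label,
                "trainer": trainer,
                "anticipation_s": ant,
                "neurons": h,
                "extensions": "+".join(sorted(ext)) if ext else "none",
                "sessions": sessions,
                "fe_err": arr[:, 0].mean(), "fe_err_sd": arr[:, 0].std(ddof=0),
                "aa_err": arr[:, 1].mean(), "aa_err_sd": arr[:, 1].std(ddof=0),
                "ps_err": arr[:, 2].mean(), "ps_err_sd": arr[:, 2].std(ddof=0),
                "cc": arr[:, 3].mean(), "cc_sd": arr[:, 3].std(ddof=0),
                "cc_sessions": list(arr[:, 3]),
            }
        )
    return pd.DataFrame(rows)


def run_tdnn_experiment(trials: list[NormalizedTrial], neurons=(10,),
                        delay_specs=("1:10",), trainers=("bayes-lm",),
                        sessions: int = 5, seed: int = 0,
                        test_fraction: float = 0.15, max_epochs: int = 30,
                        taper_len: int = 5, label: str = "") -> pd.DataFrame:
    """Time-delay networks (one per wrist angle) over a grid.

    Each session draws a trial-level stratified 15 % test split (half
    per object), taper-concatenates the train and test groups
    separately, and trains three single-output networks.  Reports the
    per-angle RMSE and the mean per-angle correlation.
    """
    specs = [
        DelaySpec.parse(sp) if isinstance(sp, str) else sp for sp in delay_specs
    ]
    if not specs or sessions < 1:
        raise ConfigError("empty experiment grid")
    rows = []
    for h in neurons:
        for spec in specs:
            for trainer in trainers:
                per_session = []
                for s in range(sessions):
                    s_seed = _session_seed(seed, s)
                    train, test = split_trials(trials, test_fraction, seed=s_seed)
                    ang_tr, _, _, _ = taper_concatenate(train, taper_len, s_seed)
                    ang_te, _, _, _ = taper_concatenate(test, taper_len, s_seed)
                    Xtr = ang_tr[:, list(INPUT_IDX)]
                    Xte = ang_te[:, list(INPUT_IDX)]
                    ccs, errs = [], []
                    for k in range(3):
                        ytr = ang_tr[:, TARGET_IDX[k]]
                        model = TimeDelayNetRegressor(
                            delays=spec.label, hidden_units=h, solver=trainer,
                            max_epochs=max_epochs, random_state=s_seed + 7 * k,
                        ).fit(Xtr, ytr)
                        pred = model.predict(Xte)
                        valid = ~np.isnan(pred)
                        actual = ang_te[valid, TARGET_IDX[k]]
                        errs.append(rmse(actual, pred[valid]))
                        ccs.append(_pearson(actual, pred[valid]))
                    per_session.append(errs + [float(np.mean(ccs))])
                arr = np.array(per_session)
                rows.append(
                    {
                        "label": label,
                        "trainer": trainer,
                        "delays": spec.label,
                        "neurons": h,
                        "sessions": sessions,
                        "fe_err": arr[:, 0].mean(), "fe_err_sd": arr[:, 0].std(ddof=0),
                        "aa_err": arr[:, 1].mean(), "aa_err_sd": arr[:, 1].std(ddof=0),
                        "ps_err": arr[:, 2].mean(), "ps_err_sd": arr[:, 2].std(ddof=0),
                        "cc": arr[:, 3].mean(), "cc_sd": arr[:, 3].std(ddof=0),
                        "cc_sessions": list(arr[:, 3]),
                    }
                )
    return pd.DataFrame(rows)


def run_linear_baseline(trials: list[NormalizedTrial]) -> pd.DataFrame:
    """Per-angle linear models on the vertically stacked study samples."""
    X, Y = stack_trials(trials)
    models = fit_linear(X, Y, targets=list(TARGET_ANGLES))
    return pd.DataFrame(
        [
            {"target": m.target, "mae": m.mae, "cc": m.cc,
             "rank_deficient": m.rank_deficient}
            for m in models
        ]
    )
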