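"""Shallow network regressors with Bayesian-regularized LM training.

The workhorse is a single-hidden-layer network (hyperbolic-tangent
hidden units, linear output, min-max input/output scaling to [-1, 1])
trained by Levenberg-Marquardt with Bayesian regularization: the
objective

    F = beta * E_D + alpha * E_W,
    E_D = sum of squared scaled errors,  E_W = 1/2 * sum of squared weights,

is minimized by damped Gauss-Newton steps

    dw = -(beta J'J + (alpha + mu) I)^-1 (beta J'e + alpha w),

and after every accepted step the hyperparameters are re-estimated from
the evidence framework via the effective number of parameters

    gamma = N_w - alpha * tr((beta J'J + alpha I)^-1),
    alpha <- gamma / (2 E_W),    beta <- (N - gamma) / (2 E_D),

which trades data fit against weight decay without a validation set.
Plain Levenberg-Marquardt (alpha = 0, early stopping) and Moller's
scaled conjugate gradient are provided for the trainer comparison.

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``) so they compose with pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

TRAINERS = ("bayes-lm", "lm", "scg")

_MU_MIN, _MU_MAX = 1e-10, 1e10


class TrainingError(RuntimeError):
    """Raised when training encounters non-finite losses."""


# ---------------------------------------------------------------------------
# scaling

@dataclass
class MinMaxScaler1:
    """Per-feature affine map onto [-1, 1] (frozen after fitting)."""

    lo: np.ndarray = None
    hi: np.ndarray = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler1":
        X = np.asarray(X, dtype=float)
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        return self

    def _span(self):
        span = self.hi - self.lo
        return np.where(span == 0, 1.0, span)

    def transform(self, X):
        return 2.0 * (np.asarray(X, dtype=float) - self.lo) / self._span() - 1.0

    def inverse_transform(self, Xs):
        return (np.asarray(Xs, dtype=float) + 1.0) / 2.0 * self._span() + self.lo


# ---------------------------------------------------------------------------
# network container

@dataclass
class ShallowNet:
    """Weights of a one-hidden-layer tanh network with linear output.

    ``hidden == 0`` degenerates to a plain affine map (used by the
    linear-regime checks of the trainer).  ``alpha``, ``beta`` and
    ``gamma`` hold the Bayesian-regularization state after training;
    ``log`` collects per-epoch mean squared errors.
    """

    W1: np.ndarray | None
    b1: np.ndarray | None
    W2: np.ndarray
    b2: np.ndarray
    activation: str = "tanh"
    x_scaler: MinMaxScaler1 | None = None
    y_scaler: MinMaxScaler1 | None = None
    alpha: float = 0.0
    beta: float = 1.0
    gamma: float = np.nan
    log: list = field(default_factory=list)

    @property
    def hidden(self) -> int:
        return 0 if self.W1 is None else self.W1.shape[0]

    @property
    def n_in(self) -> int:
        return self.W2.shape[1] if self.W1 is None else self.W1.shape[1]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]

    @property
    def n_weights(self) -> int:
        return pack(self).size

    def _act(self, z):
        return np.tanh(z) if self.activation == "tanh" else z

    def _dact(self, h, z):
        return 1.0 - h**2 if self.activation == "tanh" else np.ones_like(z)

    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """Network output in the scaled domain."""
        if self.W1 is None:
            return Xs @ self.W2.T + self.b2
        H = self._act(Xs @ self.W1.T + self.b1)
        return H @ self.W2.T + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = X if self.x_scaler is None else self.x_scaler.transform(X)
        Ys = self.forward_scaled(np.asarray(Xs, dtype=float))
        return Ys if self.y_scaler is None else self.y_scaler.inverse_transform(Ys)


def pack(net: ShallowNet) -> np.ndarray:
    parts = [net.W2.ravel(), net.b2.ravel()]
    if net.W1 is not None:
        parts = [net.W1.ravel(), net.b1.ravel()] + parts
    return np.concatenate(parts)


def unpack(net: ShallowNet, w: np.ndarray) -> None:
    k = 0
    if net.W1 is not None:
        n = net.W1.size
        net.W1 = w[k:k + n].reshape(net.W1.shape)
        k += n
        n = net.b1.size
        net.b1 = w[k:k + n].copy()
        k += n
    n = net.W2.size
    net.W2 = w[k:k + n].reshape(net.W2.shape)
    k += n
    net.b2 = w[k:].copy()


def init_network(n_in: int, hidden: int, n_out: int, seed=None,
                 activation: str = "tanh") -> ShallowNet:
    """Seeded Nguyen-Widrow-style initialization.

    Hidden rows are random directions scaled to 0.7 * h**(1/n_in) so
    the active regions of the tanh units partition the input hypercube;
    hidden biases spread uniformly across the same range.  Output
    weights start small and the output bias at zero.
    """
    if n_in < 1 or n_out < 1 or hidden < 0:
        raise ValueError("invalid network widths")
    rng = np.random.default_rng(seed)
    if hidden == 0:
        W1 = b1 = None
        W2 = rng.uniform(-0.5, 0.5, size=(n_out, n_in)) / np.sqrt(n_in)
    else:
        scale = 0.7 * hidden ** (1.0 / n_in)
        W1 = rng.standard_normal((hidden, n_in))
        W1 *= scale / np.linalg.norm(W1, axis=1, keepdims=True)
        b1 = rng.uniform(-scale, scale, size=hidden)
        W2 = rng.uniform(-0.5, 0.5, size=(n_out, hidden)) / np.sqrt(hidden)
    b2 = np.zeros(n_out)
    return ShallowNet(W1=W1, b1=b1, W2=W2, b2=b2, activation=activation)


# ---------------------------------------------------------------------------
# derivatives

def _residuals(net: ShallowNet, Xs, Ys):
    """Scaled residual vector e = (yhat - y) flattened row-major."""
    return (net.forward_scaled(Xs) - Ys).ravel()


def _jacobian(net: ShallowNet, Xs) -> np.ndarray:
    """Exact Jacobian of the residuals with respect to the packed weights.

    Shape (m * n_out, N_w); computed by backpropagation per output
    unit (the residual de/dw equals dyhat/dw).
    """
    m = Xs.shape[0]
    k = net.n_out
    # single precision for large Jacobians: the Gauss-Newton normal
    # matrix is damped by mu, so the reduced precision only perturbs
    # the step, not the accepted objective (which stays float64)
    large = m * k * (net.n_weights) > 2e7
    dtype = np.float32 if large else np.float64
    if net.W1 is None:
        n_in = net.n_in
        J = np.zeros((m * k, k * n_in + k), dtype=dtype)
        for o in range(k):
            J[o::k, o * n_in:(o + 1) * n_in] = Xs
            J[o::k, k * n_in + o] = 1.0
        return J
    h = net.hidden
    n_in = net.n_in
    Z = Xs @ net.W1.T + net.b1
    H = net._act(Z)
    dH = net._dact(H, Z)
    if large:
        Xs32, H, dH = Xs.astype(dtype), H.astype(dtype), dH.astype(dtype)
        W2 = net.W2.astype(dtype)
    else:
        Xs32, W2 = Xs, net.W2
    # dyhat_o / dW1[j,i] = W2[o,j] * dH[:,j] * Xs[:,i]
    JW1 = np.einsum("oj,mj,mi->moji", W2, dH, Xs32).reshape(m * k, h * n_in)
    Jb1 = np.einsum("oj,mj->moj", W2, dH).reshape(m * k, h)
    JW2 = np.zeros((m * k, k * h), dtype=dtype)
    Jb2 = np.zeros((m * k, k), dtype=dtype)
    for o in range(k):
        JW2[o::k, o * h:(o + 1) * h] = H
        Jb2[o::k, o] = 1.0
    return np.hstack([JW1, Jb1, JW2, Jb2])


def _gradient(net: ShallowNet, Xs, Ys) -> np.ndarray:
    """Gradient J'e of half the scaled SSE, without forming J."""
    E = net.forward_scaled(Xs) - Ys  # (m, k)
    if net.W1 is None:
        gW2 = E.T @ Xs
        gb2 = E.sum(axis=0)
        return np.concatenate([gW2.ravel(), gb2])
    Z = Xs @ net.W1.T + net.b1
    H = net._act(Z)
    dH = net._dact(H, Z)
    gW2 = E.T @ H
    gb2 = E.sum(axis=0)
    D1 = (E @ net.W2) * dH
    gW1 = D1.T @ Xs
    gb1 = D1.sum(axis=0)
    return np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])


# ---------------------------------------------------------------------------
# trainers

def _mse(net, Xs, Ys):
    e = _residuals(net, Xs, Ys)
    return float(e @ e) / e.size


def train_bayes_lm(net: ShallowNet, Xs: np.ndarray, Ys: np.ndarray,
                   max_epochs: int = 300, tol: float = 1e-9,
                   mu_init: float = 5e-3,
                   monitor: tuple | None = None) -> ShallowNet:
    """Bayesian-regularized Levenberg-Marquardt on scaled data.

    ``monitor`` optionally supplies a held-out (Xs, Ys) pair whose MSE
    is logged per epoch (it never influences training).  The log rows
    are dicts with epoch, train_mse, test_mse, F, alpha, beta, gamma.
    """
    Xs = np.asarray(Xs, dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    if Ys.ndim == 1:
        Ys = Ys[:, None]
    if Xs.shape[0] < 2:
        raise TrainingError("need at least two training rows")
    w = pack(net)
    N_w = w.size
    N = Ys.size
    alpha, beta = 0.0, 1.0
    mu = mu_init
    I = np.eye(N_w)

    e = _residuals(net, Xs, Ys)
    J = _jacobian(net, Xs)
    JtJ = (J.T @ J).astype(np.float64)
    for epoch in range(max_epochs):
        g = beta * (J.T @ e.astype(J.dtype)).astype(np.float64) + alpha * w
        E_D = float(e @ e)
        SSW = float(w @ w)
        # the step direction is half the gradient of this objective
        F = beta * E_D + alpha * SSW
        if not np.isfinite(F):
            raise TrainingError("non-finite loss during training")

        accepted = False
        while mu <= _MU_MAX:
            A = beta * JtJ + (alpha + mu) * I
            try:
                dw = -np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_new = w + dw
            unpack(net, w_new)
            e_new = _residuals(net, Xs, Ys)
            E_D_new = float(e_new @ e_new)
            F_new = beta * E_D_new + alpha * float(w_new @ w_new)
            if np.isfinite(F_new) and F_new < F:
                accepted = True
                mu = max(mu * 0.1, _MU_MIN)
                break
            unpack(net, w)
            mu *= 10.0
        if not accepted:
            break  # mu overflow: cannot improve further

        w, e = w_new, e_new
        E_D = E_D_new
        E_W = 0.5 * float(w @ w)  # half-sum convention for the updates

        # evidence-framework re-estimation of alpha, beta via the
        # effective number of parameters (Jacobian at the new weights,
        # reused for the next LM step)
        J = _jacobian(net, Xs)
        JtJ = (J.T @ J).astype(np.float64)
        H_half = beta * JtJ + max(alpha, 1e-12) * I
        try:
            tr_inv = float(np.trace(np.linalg.inv(H_half)))
        except np.linalg.LinAlgError:
            tr_inv = float(np.trace(np.linalg.pinv(H_half)))
        gamma = N_w - max(alpha, 1e-12) * tr_inv
        gamma = float(np.clip(gamma, 0.0, N_w))
        alpha = gamma / max(2.0 * E_W, 1e-12)
        beta = max(N - gamma, 1e-3) / max(2.0 * E_D, 1e-12)

        row = {
            "epoch": epoch,
            "train_mse": E_D / N,
            "F": F_new,
            "alpha": alpha,
            "beta": beta,
            "gamma": gamma,
        }
        if monitor is not None:
            row["test_mse"] = _mse(net, *monitor)
        net.log.append(row)
        net.alpha, net.beta, net.gamma = alpha, beta, gamma

        # convergence is judged on the step's decrease of F under the
        # hyperparameters it was taken with (after re-estimation F is
        # N/2 by construction, so that value carries no signal)
        if (F - F_new) / max(F, 1e-300) < tol:
            break
    return net


def _val_split(Xs, Ys, fraction, rng):
    n = Xs.shape[0]
    n_val = max(1, int(round(n * fraction))) if fraction > 0 else 0
    idx = rng.permutation(n)
    val, tr = idx[:n_val], idx[n_val:]
    return Xs[tr], Ys[tr], Xs[val], Ys[val]


def train_lm(net: ShallowNet, Xs: np.ndarray, Ys: np.ndarray,
             max_epochs: int = 300, tol: float = 1e-9, mu_init: float = 1e-3,
             val_fraction: float = 0.15, patience: int = 6,
             seed=None, monitor: tuple | None = None) -> ShallowNet:
    """Plain Levenberg-Marquardt (no weight penalty) with early stopping.

    A seeded ``val_fraction`` share of the training rows forms the
    early-stopping set (patience 6), mirroring toolbox defaults for
    unregularized trainers.
    """
    Xs = np.asarray(Xs, dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    if Ys.ndim == 1:
        Ys = Ys[:, None]
    rng = np.random.default_rng(seed)
    Xt, Yt, Xv, Yv = _val_split(Xs, Ys, val_fraction, rng)
    if Xt.shape[0] < 2:
        Xt, Yt = Xs, Ys
        Xv = None
    w = pack(net)
    I = np.eye(w.size)
    mu = mu_init
    e = _residuals(net, Xt, Yt)
    best_val = np.inf
    best_w = w.copy()
    bad = 0
    for epoch in range(max_epochs):
        J = _jacobian(net, Xt)
        JtJ = (J.T @ J).astype(np.float64)
        g = (J.T @ e.astype(J.dtype)).astype(np.float64)
        F = float(e @ e)
        if not np.isfinite(F):
            raise TrainingError("non-finite loss during training")
        accepted = False
        while mu <= _MU_MAX:
            try:
                dw = -np.linalg.solve(JtJ + mu * I, g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            unpack(net, w + dw)
            e_new = _residuals(net, Xt, Yt)
            F_new = float(e_new @ e_new)
            if np.isfinite(F_new) and F_new < F:
                accepted = True
                mu = max(mu * 0.1, _MU_MIN)
                break
            unpack(net, w)
            mu *= 10.0
        if not accepted:
            break
        w = w + dw
        e = e_new
        row = {"epoch": epoch, "train_mse": F_new / Yt.size}
        if Xv is not None and Xv.shape[0]:
            val_mse = _mse(net, Xv, Yv)
            row["val_mse"] = val_mse
            if val_mse < best_val - 1e-15:
                best_val, best_w, bad = val_mse, w.copy(), 0
            else:
                bad += 1
        if monitor is not None:
            row["test_mse"] = _mse(net, *monitor)
        net.log.append(row)
        if Xv is not None and bad > patience:
            unpack(net, best_w)
            break
        if abs(F - F_new) / max(F, 1e-300) < tol:
            break
    net.alpha, net.beta, net.gamma = 0.0, 1.0, np.nan
    return net


def train_scg(net: ShallowNet, Xs: np.ndarray, Ys: np.ndarray,
              max_epochs: int = 600, tol: float = 1e-10,
              val_fraction: float = 0.15, patience: int = 6,
              seed=None, monitor: tuple | None = None) -> ShallowNet:
    """Moller's scaled conjugate gradient on the scaled SSE."""
    Xs = np.asarray(Xs, dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    if Ys.ndim == 1:
        Ys = Ys[:, None]
    rng = np.random.default_rng(seed)
    Xt, Yt, Xv, Yv = _val_split(Xs, Ys, val_fraction, rng)
    if Xt.shape[0] < 2:
        Xt, Yt = Xs, Ys
        Xv = None

    def loss_grad(w):
        unpack(net, w)
        e = _residuals(net, Xt, Yt)
        return float(e @ e), 2.0 * _gradient(net, Xt, Yt)

    w = pack(net)
    sigma0, lam, lam_bar = 1e-5, 5e-7, 0.0
    f, g = loss_grad(w)
    p = -g
    r = -g
    success = True
    best_val, best_w, bad = np.inf, w.copy(), 0
    for epoch in range(max_epochs):
        if success:
            p2 = float(p @ p)
            if p2 < 1e-300:
                break
            sigma = sigma0 / np.sqrt(p2)
            _, g_plus = loss_grad(w + sigma * p)
            s = (g_plus - g) / sigma
            delta = float(p @ s)
        delta_reg = delta + (lam - lam_bar) * p2
        if delta_reg <= 0:
            lam_bar = 2.0 * (lam - delta_reg / p2)
            delta_reg = -delta_reg + lam * p2
            lam = lam_bar
        mu_step = float(p @ r)
        alpha_step = mu_step / delta_reg
        f_new, _ = loss_grad(w + alpha_step * p)
        Delta = 2.0 * delta_reg * (f - f_new) / mu_step**2
        if Delta >= 0:
            w = w + alpha_step * p
            f, g_old = f_new, g
            _, g = loss_grad(w)
            r_new = -g
            lam_bar = 0.0
            success = True
            if (epoch + 1) % w.size == 0:
                p = r_new  # restart
            else:
                beta_cg = (float(r_new @ r_new) - float(r_new @ r)) / mu_step
                p = r_new + beta_cg * p
            r = r_new
            if Delta >= 0.75:
                lam = max(lam * 0.25, 1e-15)
            row = {"epoch": epoch, "train_mse": f / Yt.size}
            if Xv is not None and Xv.shape[0]:
                unpack(net, w)
                val_mse = _mse(net, Xv, Yv)
                row["val_mse"] = val_mse
                if val_mse < best_val - 1e-15:
                    best_val, best_w, bad = val_mse, w.copy(), 0
                else:
                    bad += 1
                if bad > patience:
                    net.log.append(row)
                    w = best_w
                    break
            if monitor is not None:
                unpack(net, w)
                row["test_mse"] = _mse(net, *monitor)
            net.log.append(row)
            if f > 0 and abs(row["train_mse"]) < tol:
                break
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = lam + delta_reg * (1 - Delta) / p2
        if lam > 1e20:
            break
    unpack(net, w)
    net.alpha, net.beta, net.gamma = 0.0, 1.0, np.nan
    return net


_TRAIN_FUNCS = {"bayes-lm": train_bayes_lm, "lm": train_lm, "scg": train_scg}


# ---------------------------------------------------------------------------
# scikit-learn estimators

class ShallowNetRegressor(RegressorMixin, BaseEstimator):
    """Single-hidden-layer regressor for instant-wise wrist prediction.

    Parameters
    ----------
    hidden_units : int, default 20
        Hidden-layer width (the study grid spans 5-20).
    solver : {"bayes-lm", "lm", "scg"}
        Training function: Bayesian-regularized Levenberg-Marquardt
        (default, no validation set needed), plain LM or scaled
        conjugate gradient (both with early stopping).
    max_epochs : int
        Epoch cap; training also stops on relative loss change below
        ``tol`` or on damping overflow.
    random_state : int or None
        Seeds the Nguyen-Widrow initialization and any validation split.

    Attributes
    ----------
    net_ : ShallowNet          fitted network (weights and scalers)
    alpha_, beta_, gamma_ :    Bayesian-regularization state
    loss_curve_ : list[dict]   per-epoch training log
    """

    def __init__(self, hidden_units: int = 20, solver: str = "bayes-lm",
                 max_epochs: int = 300, tol: float = 1e-9,
                 activation: str = "tanh", val_fraction: float = 0.15,
                 patience: int = 6, random_state: int | None = None):
        self.hidden_units = hidden_units
        self.solver = solver
        self.max_epochs = max_epochs
        self.tol = tol
        self.activation = activation
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y, monitor: tuple | None = None):
        X, y = check_X_y(X, y, multi_output=True, y_numeric=True)
        Y = y[:, None] if y.ndim == 1 else y
        if self.solver not in TRAINERS:
            raise ValueError(f"solver must be one of {TRAINERS}")
        ss = np.random.SeedSequence(self.random_state)
        init_seed, split_seed = ss.spawn(2)
        net = init_network(X.shape[1], self.hidden_units, Y.shape[1],
                           seed=init_seed, activation=self.activation)
        net.x_scaler = MinMaxScaler1().fit(X)
        net.y_scaler = MinMaxScaler1().fit(Y)
        Xs = net.x_scaler.transform(X)
        Ys = net.y_scaler.transform(Y)
        mon = None
        if monitor is not None:
            mon = (net.x_scaler.transform(monitor[0]),
                   net.y_scaler.transform(
                       monitor[1][:, None] if np.ndim(monitor[1]) == 1
                       else monitor[1]))
        if self.solver == "bayes-lm":
            train_bayes_lm(net, Xs, Ys, max_epochs=self.max_epochs,
                           tol=self.tol, monitor=mon)
        elif self.solver == "lm":
            train_lm(net, Xs, Ys, max_epochs=self.max_epochs, tol=self.tol,
                     val_fraction=self.val_fraction, patience=self.patience,
                     seed=split_seed, monitor=mon)
        else:
            train_scg(net, Xs, Ys, max_epochs=max(self.max_epochs, 600),
                      val_fraction=self.val_fraction, patience=self.patience,
                      seed=split_seed, monitor=mon)
        self.net_ = net
        self.alpha_, self.beta_, self.gamma_ = net.alpha, net.beta, net.gamma
        self.loss_curve_ = net.log
        self.n_features_in_ = X.shape[1]
        self._y_1d = y.ndim == 1
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X)
        Y = self.net_.predict(X)
        return Y[:, 0] if self._y_1d else Y


class TimeDelayNetRegressor(RegressorMixin, BaseEstimator):
    """Tapped-delay-line network for instant-by-instant wrist prediction.

    ``X`` is a multichannel input series (T, n_channels) — typically
    the tapered concatenation of many trials — and ``y`` the target
    angle series.  Each sample t is predicted from the input channels
    at t-d for every delay d; the first max(delay) samples are masked.

    The ``delays`` parameter accepts an inclusive "a:b" string (e.g.
    "1:10" = the previous ten instants, roughly half a second) or an
    explicit tuple of positive delays.
    """

    def __init__(self, delays="1:10", hidden_units: int = 10,
                 solver: str = "bayes-lm", max_epochs: int = 100,
                 tol: float = 1e-9, val_fraction: float = 0.15,
                 patience: int = 6, random_state: int | None = None):
        self.delays = delays
        self.hidden_units = hidden_units
        self.solver = solver
        self.max_epochs = max_epochs
        self.tol = tol
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    def _delay_tuple(self):
        from .events import DelaySpec

        if isinstance(self.delays, str):
            return DelaySpec.parse(self.delays).delays
        return tuple(self.delays)

    def fit(self, X, y, monitor: tuple | None = None):
        from .events import delay_embed

        X, y = check_X_y(X, y, multi_output=True, y_numeric=True)
        delays = self._delay_tuple()
        Xe, valid = delay_embed(X, delays)
        mon = None
        if monitor is not None:
            Xm, vm = delay_embed(np.asarray(monitor[0], dtype=float), delays)
            mon = (Xm[vm], np.asarray(monitor[1], dtype=float)[vm])
        self._core = ShallowNetRegressor(
            hidden_units=self.hidden_units, solver=self.solver,
            max_epochs=self.max_epochs, tol=self.tol,
            val_fraction=self.val_fraction, patience=self.patience,
            random_state=self.random_state,
        ).fit(Xe[valid], y[valid], monitor=mon)
        self.net_ = self._core.net_
        self.loss_curve_ = self._core.loss_curve_
        self.alpha_, self.beta_, self.gamma_ = (
            self._core.alpha_, self._core.beta_, self._core.gamma_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Predict the target series; masked leading samples are NaN."""
        from .events import delay_embed

        check_is_fitted(self, "net_")
        X = check_array(X)
        Xe, valid = delay_embed(X, self._delay_tuple())
        out = np.full(X.shape[0], np.nan)
        out[valid] = self._core.predict(Xe[valid])
        return out


# ---------------------------------------------------------------------------
# linear baseline

@dataclass
class LinearModel:
    """Per-target linear fit: intercept + one coefficient per predictor."""

    target: str
    intercept: float
    coef: np.ndarray
    mae: float
    cc: float
    rank_deficient: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def fit_linear(X: np.ndarray, Y: np.ndarray, targets=None) -> list:
    """Ordinary least squares per target angle on the stacked samples.

    Returns one :class:`LinearModel` per target with its in-sample MAE
    and Pearson correlation.  Rank-deficient predictor matrices are
    flagged and solved in the minimum-norm sense.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least n_predictors + 1 rows")
    if targets is None:
        targets = [f"target_{k}" for k in range(Y.shape[1])]
    A = np.column_stack([np.ones(X.shape[0]), X])
    coefs, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    deficient = rank < A.shape[1]
    models = []
    for k, name in enumerate(targets):
        pred = A @ coefs[:, k]
        resid = Y[:, k] - pred
        cc = float(np.corrcoef(Y[:, k], pred)[0, 1]) if np.ptp(pred) > 0 else np.nan
        models.append(
            LinearModel(
                target=name,
                intercept=float(coefs[0, k]),
                coef=coefs[1:, k].copy(),
                mae=float(np.abs(resid).mean()),
                cc=cc,
                rank_deficient=deficient,
            )
        )
    return models


def predict_tdnn(models: list, X: np.ndarray) -> np.ndarray:
    """Stack per-angle time-delay predictions into a (T, n_angles) array."""
    return np.column_stack([m.predict(X) for m in models])
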