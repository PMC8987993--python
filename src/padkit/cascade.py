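"""Cascade-forward neural-network regressor.

A cascade-forward network is a layered feed-forward regressor in which
every hidden layer receives the *original* inputs concatenated with the
outputs of all preceding hidden layers, and the single linear output unit
sees the inputs plus every hidden layer.  With tanh hidden units the
architecture trivially contains the pure linear model (through the
input-to-output skip connection), which is why it behaves well on
feature panels whose age signal is largely linear.

Training minimizes mean squared error (plus an optional small L2 penalty
on the weights) with full-batch L-BFGS-B and analytic gradients; a seeded
validation split provides early stopping by keeping the parameters with
the best validation loss seen during the optimization path.  Everything
is deterministic given ``random_state``.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class CascadeForwardRegressor(RegressorMixin, BaseEstimator):
    """Cascade-forward network with standardized inputs and a linear output.

    Parameters
    ----------
    n_layers : int, default=12
        Number of hidden layers.
    width : int, default=16
        Units per hidden layer.
    alpha : float, default=1e-3
        L2 penalty on weights (not biases), in squared-target units.
    max_iter : int, default=500
        Maximum L-BFGS iterations.
    tol : float, default=1e-6
        Optimizer tolerance (ftol).
    validation_fraction : float, default=0.1
        Fraction of the training set held out for early stopping; 0 disables.
    random_state : int, default=0
        Seeds weight initialization and the validation split.

    Attributes
    ----------
    coefs_ : list of ndarray
        Hidden-layer weight matrices; layer k has shape
        (n_features + k * width, width).
    intercepts_ : list of ndarray
        Hidden-layer biases.
    output_coef_ : ndarray, output_intercept_ : float
        Linear read-out over [inputs, all hidden activations].
    x_mean_, x_scale_ : ndarray
        Per-feature standardization learned on the training data.
    loss_curve_ : list of float
        Training MSE at each optimizer iteration.
    """

    def __init__(
        self,
        n_layers: int = 12,
        width: int = 16,
        alpha: float = 1e-3,
        max_iter: int = 500,
        tol: float = 1e-6,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.width = width
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ---- parameter vector packing -------------------------------------
    def _shapes(self, d: int) -> List[Tuple[int, int]]:
        return [(d + k * self.width, self.width) for k in range(self.n_layers)]

    def _init_params(self, d: int, rng, Xs=None, ys=None) -> np.ndarray:
        parts = []
        Ws, bs = [], []
        for din, dout in self._shapes(d):
            bound = np.sqrt(6.0 / (din + dout))
            W = rng.uniform(-bound, bound, (din, dout))
            Ws.append(W)
            bs.append(np.zeros(dout))
            parts.append(W.ravel())
            parts.append(bs[-1])
        dout_in = d + self.n_layers * self.width
        w = rng.uniform(-0.05, 0.05, dout_in)
        b = 0.0
        if Xs is not None and len(Xs):
            # warm-start the linear read-out with a ridge solve over
            # [inputs, hidden activations]; the cascade then only needs to
            # refine the nonlinear part.
            _, A, _ = self._forward(Xs, Ws, bs, w, b)
            Ac = np.column_stack([A, np.ones(len(A))])
            G = Ac.T @ Ac + 1e-6 * np.eye(Ac.shape[1])
            beta = np.linalg.solve(G, Ac.T @ ys)
            w, b = beta[:-1], float(beta[-1])
        parts.append(w)
        parts.append(np.array([b]))
        return np.concatenate(parts)

    def _unpack(self, theta: np.ndarray, d: int):
        Ws, bs, pos = [], [], 0
        for din, dout in self._shapes(d):
            Ws.append(theta[pos : pos + din * dout].reshape(din, dout))
            pos += din * dout
            bs.append(theta[pos : pos + dout])
            pos += dout
        dout_in = d + self.n_layers * self.width
        w = theta[pos : pos + dout_in]
        b = theta[pos + dout_in]
        return Ws, bs, w, b

    # ---- forward / backward -------------------------------------------
    def _forward(self, A0: np.ndarray, Ws, bs, w, b):
        A = A0
        acts = []
        for W, bias in zip(Ws, bs):
            H = np.tanh(A @ W + bias)
            acts.append(H)
            A = np.concatenate([A, H], axis=1)
        return A @ w + b, A, acts

    def _loss_grad(self, theta: np.ndarray, A0: np.ndarray, y: np.ndarray, d: int):
        n = len(y)
        Ws, bs, w, b = self._unpack(theta, d)
        yhat, A, acts = self._forward(A0, Ws, bs, w, b)
        resid = yhat - y
        mse = float(resid @ resid) / n
        dy = 2.0 * resid / n
        gw = A.T @ dy
        gb = np.array([dy.sum()])
        dA = np.outer(dy, w)
        gWs: List[np.ndarray] = [None] * self.n_layers  # type: ignore
        gbs: List[np.ndarray] = [None] * self.n_layers  # type: ignore
        for k in range(self.n_layers - 1, -1, -1):
            din = d + k * self.width
            dz = dA[:, din : din + self.width] * (1.0 - acts[k] ** 2)
            gWs[k] = A[:, :din].T @ dz
            gbs[k] = dz.sum(axis=0)
            dA = dA[:, :din]
            dA += dz @ Ws[k].T
        penalty = 0.0
        if self.alpha:
            penalty = self.alpha * (sum(float((W**2).sum()) for W in Ws) + float(w @ w))
            for k in range(self.n_layers):
                gWs[k] = gWs[k] + 2.0 * self.alpha * Ws[k]
            gw = gw + 2.0 * self.alpha * w
        parts = []
        for k in range(self.n_layers):
            parts.append(gWs[k].ravel())
            parts.append(gbs[k])
        parts.append(gw)
        parts.append(gb)
        return mse + penalty, np.concatenate(parts)

    # ---- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in training data")
        n, d = X.shape
        if n < 2 or len(np.unique(y)) < 2:
            raise ValueError("need at least 2 samples with distinct targets")
        self.n_features_in_ = d
        self.x_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.x_scale_ = scale
        Xs = (X - self.x_mean_) / self.x_scale_
        self.y_mean_ = float(y.mean())
        y_scale = float(y.std())
        self.y_scale_ = y_scale if y_scale > 0 else 1.0
        ys = (y - self.y_mean_) / self.y_scale_

        rng = np.random.default_rng(self.random_state)

        if 0 < self.validation_fraction < 1 and n >= 10:
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx, tr_idx = np.array([], dtype=int), np.arange(n)
        Xtr, ytr = Xs[tr_idx], ys[tr_idx]
        Xval, yval = Xs[val_idx], ys[val_idx]

        theta0 = self._init_params(d, rng, Xtr, ytr)

        self.loss_curve_: List[float] = []
        best = {"val": np.inf, "theta": theta0.copy()}

        def callback(theta):
            mse, _ = self._loss_grad(theta, Xtr, ytr, d)
            self.loss_curve_.append(mse)
            if len(val_idx):
                Ws, bs, w, b = self._unpack(theta, d)
                pred, _, _ = self._forward(Xval, Ws, bs, w, b)
                vmse = float(np.mean((pred - yval) ** 2))
                if vmse < best["val"]:
                    best["val"] = vmse
                    best["theta"] = theta.copy()

        res = minimize(
            self._loss_grad,
            theta0,
            args=(Xtr, ytr, d),
            jac=True,
            method="L-BFGS-B",
            callback=callback,
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-9},
        )
        theta = best["theta"] if len(val_idx) and np.isfinite(best["val"]) else res.x
        if not len(val_idx):
            theta = res.x
        self.coefs_, self.intercepts_, self.output_coef_, b = self._unpack(theta, d)
        self.output_intercept_ = float(b)
        self.n_iter_ = int(res.nit)
        self.optimizer_result_ = {"status": int(res.status), "message": str(res.message)}
        return self

    def predict(self, X):
        check_is_fitted(self, "output_coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        Xs = (X - self.x_mean_) / self.x_scale_
        yhat, _, _ = self._forward(
            Xs, self.coefs_, self.intercepts_, self.output_coef_, self.output_intercept_
        )
        return yhat * self.y_scale_ + self.y_mean_
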