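"""Single-hidden-layer regression network trained by resilient backprop.

The regressor has one hidden layer with logistic activation and a single
linear output node.  Targets are min-max scaled to [0, 1] on the training
split and predictions mapped back to original units.  Training uses
Rprop+ (resilient backpropagation with weight backtracking): each weight
carries its own step size, grown by ``eta_plus`` while the gradient sign
is stable and shrunk by ``eta_minus`` (with the last step undone) when it
flips.  Only gradient signs matter, which makes the method robust to the
scale of the summed-squared-error surface.

The default hidden-layer width follows the ``N/3 + 2`` rule (rounded
half-up), where N is the number of input covariates — a deliberately
small hidden layer that limits overfitting on feature sets of a few
dozen correlated covariates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["hidden_nodes", "RpropRegressor"]


def hidden_nodes(n_inputs: int) -> int:
    """Hidden-layer width from the N/3 + 2 rule, rounded half-up."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    return int(np.floor(n_inputs / 3.0 + 2.0 + 0.5))


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class RpropRegressor(RegressorMixin, BaseEstimator):
    """Feed-forward regressor trained by Rprop+ on summed squared error.

    Parameters
    ----------
    n_hidden : int or None
        Hidden-layer width; ``None`` applies the N/3 + 2 rule.
    eta_plus, eta_minus : float
        Step-size growth/shrink factors (1.2 and 0.5).
    delta_init, delta_min, delta_max : float
        Initial, minimum and maximum per-weight step sizes.
    gradient_threshold : float
        Stop when the largest absolute error gradient falls below this.
    max_epochs : int
        Epoch budget; hitting it without reaching the gradient threshold
        sets ``converged_ = False`` (flagged, not fatal).
    random_state : int
        Seed of the uniform(-0.5, 0.5) weight initialization.

    Attributes
    ----------
    w1_ : ndarray of shape (n_inputs + 1, n_hidden)
        Input-to-hidden weights, bias in the last row.
    w2_ : ndarray of shape (n_hidden + 1, 1)
        Hidden-to-output weights, bias in the last row.
    error_trace_ : ndarray
        Summed-squared-error after each epoch (may oscillate; the final
        value never exceeds the initial one).
    """

    def __init__(
        self,
        n_hidden: int | None = None,
        eta_plus: float = 1.2,
        eta_minus: float = 0.5,
        delta_init: float = 0.1,
        delta_min: float = 1e-6,
        delta_max: float = 50.0,
        gradient_threshold: float = 0.01,
        max_epochs: int = 10000,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.eta_plus = eta_plus
        self.eta_minus = eta_minus
        self.delta_init = delta_init
        self.delta_min = delta_min
        self.delta_max = delta_max
        self.gradient_threshold = gradient_threshold
        self.max_epochs = max_epochs
        self.random_state = random_state

    # -- forward/backward ---------------------------------------------------

    @staticmethod
    def _forward(w1: np.ndarray, w2: np.ndarray, X: np.ndarray):
        xb = np.hstack([X, np.ones((X.shape[0], 1))])
        h = _logistic(xb @ w1)
        hb = np.hstack([h, np.ones((h.shape[0], 1))])
        return xb, h, hb, (hb @ w2).ravel()

    @classmethod
    def _gradients(cls, w1: np.ndarray, w2: np.ndarray, X: np.ndarray, t: np.ndarray):
        """Analytic gradients of E = 0.5 * sum((out - t)^2)."""
        xb, h, hb, out = cls._forward(w1, w2, X)
        err = out - t
        g2 = hb.T @ err[:, None]
        dh = (err[:, None] * w2[:-1, :].T) * h * (1.0 - h)
        g1 = xb.T @ dh
        return g1, g2, float(0.5 * np.dot(err, err))

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per target value")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        n, p = X.shape
        nh = self.n_hidden if self.n_hidden is not None else hidden_nodes(p)

        self.y_min_ = float(y.min())
        self.y_max_ = float(y.max())
        span = self.y_max_ - self.y_min_
        self.y_scale_ = span if span > 0 else 1.0
        t = (y - self.y_min_) / self.y_scale_

        rng = np.random.default_rng(self.random_state)
        w1 = rng.uniform(-0.5, 0.5, size=(p + 1, nh))
        w2 = rng.uniform(-0.5, 0.5, size=(nh + 1, 1))

        deltas = [np.full_like(w1, self.delta_init), np.full_like(w2, self.delta_init)]
        prev_g = [np.zeros_like(w1), np.zeros_like(w2)]
        prev_step = [np.zeros_like(w1), np.zeros_like(w2)]
        weights = [w1, w2]

        trace = []
        converged = False
        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            g1, g2, err = self._gradients(weights[0], weights[1], X, t)
            trace.append(err)
            grads = [g1, g2]
            if max(np.abs(g1).max(), np.abs(g2).max()) < self.gradient_threshold:
                converged = True
                break
            for w, g, d, pg, ps in zip(weights, grads, deltas, prev_g, prev_step):
                sign = pg * g
                grow = sign > 0
                shrink = sign < 0
                d[grow] = np.minimum(d[grow] * self.eta_plus, self.delta_max)
                d[shrink] = np.maximum(d[shrink] * self.eta_minus, self.delta_min)
                step = -np.sign(g) * d
                # backtrack where the gradient flipped, and skip the sign
                # comparison there next epoch (Rprop+)
                step[shrink] = -ps[shrink]
                g = g.copy()
                g[shrink] = 0.0
                w += step
                ps[:] = step
                pg[:] = g
        self.w1_, self.w2_ = weights
        self.n_hidden_ = nh
        self.n_features_in_ = p
        self.converged_ = converged
        self.n_epochs_ = epoch
        self.error_trace_ = np.asarray(trace)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "w1_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}"
            )
        *_, out = self._forward(self.w1_, self.w2_, X)
        return out * self.y_scale_ + self.y_min_

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "w1_")
        state = {
            "params": self.get_params(),
            "w1": self.w1_.tolist(),
            "w2": self.w2_.tolist(),
            "y_min": self.y_min_,
            "y_max": self.y_max_,
            "y_scale": self.y_scale_,
            "n_hidden": self.n_hidden_,
            "n_features_in": self.n_features_in_,
            "converged": self.converged_,
            "n_epochs": self.n_epochs_,
        }
        return json.dumps(state)

    @classmethod
    def from_json(cls, payload: str | Path) -> "RpropRegressor":
        if isinstance(payload, Path):
            payload = payload.read_text()
        state = json.loads(payload)
        est = cls(**state["params"])
        est.w1_ = np.asarray(state["w1"], dtype=float)
        est.w2_ = np.asarray(state["w2"], dtype=float)
        est.y_min_ = state["y_min"]
        est.y_max_ = state["y_max"]
        est.y_scale_ = state["y_scale"]
        est.n_hidden_ = state["n_hidden"]
        est.n_features_in_ = state["n_features_in"]
        est.converged_ = state["converged"]
        est.n_epochs_ = state["n_epochs"]
        est.error_trace_ = np.asarray([])
        return est
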