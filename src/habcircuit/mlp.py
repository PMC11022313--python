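"""The 6-2-1 ReLU perceptron mapping habenula subtype activity to raphe output.

The network has six input nodes (one per habenula subtype), two hidden nodes
(H1, H2) and one output node (R), with ReLU activations on hidden and output
layers — 17 free parameters in total.  It is deliberately implemented natively
in numpy: the model is tiny, full-batch training is deterministic given a
seed, and the subgradient convention at the ReLU kink (derivative 0 at 0) is
explicit rather than framework-dependent.

``CircuitMLP`` is a scikit-learn style regressor (``fit`` / ``predict`` /
``get_params``); ``fit_design`` is a thin functional wrapper returning a
:class:`FitResult` with per-condition RMSEs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .naming import SUBTYPES

__all__ = [
    "MLPParams", "FitResult", "forward", "rmse", "CircuitMLP", "fit_design",
    "predict_ablation", "DeadNetworkError",
]


class DeadNetworkError(RuntimeError):
    """Every restart converged to the all-zero output on a nonzero target."""


@dataclass
class MLPParams:
    """Weights and biases of the 6-2-1 network.

    W1 : (6, 2) input→hidden weights; b1 : (2,) hidden biases;
    W2 : (2,) hidden→output weights; b2 : float output bias.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.W2 = np.asarray(self.W2, dtype=float).ravel()
        self.b2 = float(np.asarray(self.b2).ravel()[0])
        h = self.b1.shape[0]
        if self.W1.ndim != 2 or self.W1.shape[1] != h or self.W2.shape[0] != h:
            raise ValueError(f"inconsistent parameter shapes: W1 {self.W1.shape}, "
                             f"b1 {self.b1.shape}, W2 {self.W2.shape}")
        if not (np.all(np.isfinite(self.W1)) and np.all(np.isfinite(self.b1))
                and np.all(np.isfinite(self.W2)) and np.isfinite(self.b2)):
            raise ValueError("parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + 1

    def copy(self) -> "MLPParams":
        return MLPParams(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2)

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2, [self.b2]])

    # 17 stable parameter ids, used by the sensitivity scan and reports.
    def param_ids(self, input_names=SUBTYPES) -> list:
        ids = []
        for j in range(self.n_hidden):
            for i, name in enumerate(input_names):
                ids.append(f"W1:{name}->H{j + 1}")
        ids += [f"b1:H{j + 1}" for j in range(self.n_hidden)]
        ids += [f"W2:H{j + 1}->R" for j in range(self.n_hidden)]
        ids.append("b2:R")
        return ids

    def get_param(self, pid: str, input_names=SUBTYPES) -> float:
        W1, b1, W2 = self.W1, self.b1, self.W2
        kind, _, rest = pid.partition(":")
        if kind == "W1":
            src, _, dst = rest.partition("->")
            return W1[list(input_names).index(src), int(dst[1:]) - 1]
        if kind == "b1":
            return b1[int(rest[1:]) - 1]
        if kind == "W2":
            return W2[int(rest[1:rest.index("->")]) - 1]
        if kind == "b2":
            return self.b2
        raise KeyError(pid)

    def set_param(self, pid: str, value: float, input_names=SUBTYPES) -> None:
        kind, _, rest = pid.partition(":")
        if kind == "W1":
            src, _, dst = rest.partition("->")
            self.W1[list(input_names).index(src), int(dst[1:]) - 1] = value
        elif kind == "b1":
            self.b1[int(rest[1:]) - 1] = value
        elif kind == "W2":
            self.W2[int(rest[1:rest.index("->")]) - 1] = value
        elif kind == "b2":
            self.b2 = value
        else:
            raise KeyError(pid)

    def to_dict(self) -> dict:
        return {
            "format": "habcircuit-mlp/1",
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "activation": "relu",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPParams":
        return cls(np.array(d["W1"]), np.array(d["b1"]), np.array(d["W2"]), d["b2"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MLPParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def forward(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Forward pass: h = ReLU(x W1 + b1); y = ReLU(h · W2 + b2).

    ``x`` may be a single 6-vector or an (n, 6) matrix; returns a scalar or an
    (n,) vector.  Output is always >= 0 (output ReLU).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.n_inputs:
        raise ValueError(f"expected {params.n_inputs} input columns, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    h = np.maximum(X @ params.W1 + params.b1, 0.0)
    y = np.maximum(h @ params.W2 + params.b2, 0.0)
    return float(y[0]) if single else y


def hidden_activations(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Hidden-layer activations, (n, n_hidden)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.maximum(X @ params.W1 + params.b1, 0.0)


def rmse(yhat: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error between two equal-length vectors."""
    yhat = np.asarray(yhat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if yhat.size == 0 or y.size == 0:
        raise ValueError("rmse of empty input")
    if yhat.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


@dataclass
class FitResult:
    """Outcome of a training run, with provenance."""

    params: MLPParams
    rmse_overall: float
    rmse_per_condition: dict
    training_log: list = field(default_factory=list)
    seed: int | None = None
    restarts: int = 0
    epochs_run: int = 0

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rmse_overall": self.rmse_overall,
            "rmse_per_condition": self.rmse_per_condition,
            "seed": self.seed,
            "restarts": self.restarts,
            "epochs_run": self.epochs_run,
        }


class CircuitMLP(RegressorMixin, BaseEstimator):
    """Scikit-learn style regressor for the 6-2-1 ReLU circuit model.

    Training minimises mean-squared error by full-batch Adam (lr 1e-3 by
    default), running ``n_restarts`` random initialisations simultaneously and
    keeping the best by final loss.  A restart stops early when its loss
    plateaus (relative change < ``plateau_tol`` over ``plateau_epochs``) or
    drops below ``target_loss``; the whole fit stops once the best restart has
    converged below ``target_loss``.  Deterministic given ``random_state``.

    Parameters
    ----------
    hidden_units : int, default 2
        Hidden-layer width.  The scientific model uses 2 (a 1-node hidden
        layer was found insufficient); other widths are accepted for
        exploration only.
    learning_rate : float, default 1e-3
    max_epochs : int, default 20000
    n_restarts : int, default 10
    init_scale : float, default 0.5
        Weights start uniform(-init_scale, init_scale); biases start at 0.1
        (small positive, to reduce dead-ReLU initialisations).
    target_loss : float, default 1e-6
        MSE below which a restart is considered converged.
    plateau_epochs / plateau_tol : plateau early-stop window and tolerance.
    dtype : numpy dtype, default float32
        Working precision of the training loop (ample for the convergence
        tolerance; roughly halves the fit time).  Returned parameters and
        reported RMSEs are float64.
    random_state : int, default 0

    Attributes
    ----------
    params_ : MLPParams — best parameters found.
    loss_curve_ : list of float — best-restart loss at each checkpoint.
    rmse_ : float — overall training RMSE of the returned model.
    n_epochs_ : int — epochs actually run.
    """

    def __init__(self, hidden_units: int = 2, learning_rate: float = 1e-3,
                 max_epochs: int = 20000, n_restarts: int = 10,
                 init_scale: float = 0.5, init_bias: float = 0.1,
                 target_loss: float = 1e-6, plateau_epochs: int = 500,
                 plateau_tol: float = 1e-9, dtype=np.float32,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.n_restarts = n_restarts
        self.init_scale = init_scale
        self.init_bias = init_bias
        self.target_loss = target_loss
        self.plateau_epochs = plateau_epochs
        self.plateau_tol = plateau_tol
        self.dtype = dtype
        self.random_state = random_state

    # ------------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_inputs)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on n_samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")

        n, d = X.shape
        h = int(self.hidden_units)
        R = int(self.n_restarts)
        rng = np.random.default_rng(self.random_state)
        dt = np.dtype(self.dtype)

        # Stacked-restart layout: layer-1 weights concatenated column-wise so
        # one dgemm serves all restarts.
        W1 = rng.uniform(-self.init_scale, self.init_scale, size=(d, R * h)).astype(dt)
        b1 = np.full(R * h, self.init_bias, dtype=dt)
        W2 = rng.uniform(-self.init_scale, self.init_scale, size=(R, h)).astype(dt)
        b2 = np.full(R, self.init_bias, dtype=dt)
        Xw = np.ascontiguousarray(X, dtype=dt)
        yb = np.ascontiguousarray(y, dtype=dt)[:, None]

        mW1 = np.zeros_like(W1); vW1 = np.zeros_like(W1)
        mb1 = np.zeros_like(b1); vb1 = np.zeros_like(b1)
        mW2 = np.zeros_like(W2); vW2 = np.zeros_like(W2)
        mb2 = np.zeros_like(b2); vb2 = np.zeros_like(b2)
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        active = np.ones(R, dtype=bool)
        best_loss = np.full(R, np.inf)
        bW1 = W1.copy(); bb1 = b1.copy(); bW2 = W2.copy(); bb2 = b2.copy()
        last_check = np.full(R, np.inf)
        log = []
        check_every = 50
        epoch = 0

        for epoch in range(1, int(self.max_epochs) + 1):
            Z1 = Xw @ W1 + b1                      # (n, R*h)
            H = np.maximum(Z1, 0.0)
            Hr = H.reshape(n, R, h)
            Z2 = np.einsum("nrh,rh->nr", Hr, W2) + b2
            out = np.maximum(Z2, 0.0)
            err = out - yb
            loss = np.mean(err * err, axis=0, dtype=np.float64)  # (R,)

            dead = ~np.isfinite(loss)
            if np.any(dead & active):
                active &= ~dead                    # NaN loss: abandon restart

            improved = (loss < best_loss) & active & ~dead
            if np.any(improved):
                best_loss[improved] = loss[improved]
                cols = np.repeat(improved, h)
                bW1[:, cols] = W1[:, cols]
                bb1[cols] = b1[cols]
                bW2[improved] = W2[improved]
                bb2[improved] = b2[improved]

            if epoch % check_every == 0 or epoch == self.max_epochs:
                log.append(float(np.min(best_loss)))
            if np.min(best_loss) < self.target_loss:
                break
            if epoch % self.plateau_epochs == 0:
                with np.errstate(invalid="ignore"):
                    rel = (last_check - best_loss) / np.maximum(last_check, 1e-300)
                rel = np.where(np.isnan(rel), np.inf, rel)
                plateaued = rel < self.plateau_tol
                converged = best_loss < self.target_loss
                active &= ~(plateaued | converged)
                last_check = best_loss.copy()
                if not np.any(active):
                    break

            # backward (subgradient 0 at ReLU kinks)
            dZ2 = (2.0 / n) * err * (Z2 > 0)       # (n, R)
            gW2 = np.einsum("nrh,nr->rh", Hr, dZ2)
            gb2 = dZ2.sum(axis=0)
            dH = dZ2[:, :, None] * W2[None, :, :]  # (n, R, h)
            dZ1 = (dH.reshape(n, R * h)) * (Z1 > 0)
            gW1 = Xw.T @ dZ1
            gb1 = dZ1.sum(axis=0)

            t = epoch
            bc1 = 1.0 - beta1 ** t
            bc2 = 1.0 - beta2 ** t
            lr = self.learning_rate
            amask = np.repeat(active.astype(float), h)

            mW1 = beta1 * mW1 + (1 - beta1) * gW1
            vW1 = beta2 * vW1 + (1 - beta2) * gW1 * gW1
            W1 -= lr * amask * (mW1 / bc1) / (np.sqrt(vW1 / bc2) + eps)
            mb1 = beta1 * mb1 + (1 - beta1) * gb1
            vb1 = beta2 * vb1 + (1 - beta2) * gb1 * gb1
            b1 -= lr * amask * (mb1 / bc1) / (np.sqrt(vb1 / bc2) + eps)

            am = active.astype(float)
            mW2 = beta1 * mW2 + (1 - beta1) * gW2
            vW2 = beta2 * vW2 + (1 - beta2) * gW2 * gW2
            W2 -= lr * am[:, None] * (mW2 / bc1) / (np.sqrt(vW2 / bc2) + eps)
            mb2 = beta1 * mb2 + (1 - beta1) * gb2
            vb2 = beta2 * vb2 + (1 - beta2) * gb2 * gb2
            b2 -= lr * am * (mb2 / bc1) / (np.sqrt(vb2 / bc2) + eps)

        if not np.any(np.isfinite(best_loss)):
            raise DeadNetworkError("all restarts diverged (non-finite loss)")

        best = int(np.argmin(best_loss))
        params = MLPParams(
            bW1[:, best * h:(best + 1) * h].copy(),
            bb1[best * h:(best + 1) * h].copy(),
            bW2[best].copy(),
            bb2[best],
        )
        yhat = forward(params, X)
        if np.all(yhat == 0.0) and np.any(y != 0.0):
            # the best restart is a dead network; check whether any restart is alive
            raise DeadNetworkError(
                "best fit predicts identically zero on a nonzero target; "
                "try more restarts or a different seed")
        self.params_ = params
        self.loss_curve_ = log
        self.rmse_ = rmse(yhat, y)
        self.n_epochs_ = epoch
        self.n_features_in_ = d
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise AttributeError("CircuitMLP is not fitted yet")
        return forward(self.params_, np.asarray(X, dtype=float))


def fit_design(design, epochs: int = 20000, learning_rate: float = 1e-3,
               restarts: int = 10, seed: int = 0, **kwargs) -> FitResult:
    """Fit the circuit MLP to a stacked design and report per-condition RMSE.

    ``design`` is a :class:`habcircuit.response.StackedDesign` (or any object
    with ``X``, ``y``, ``condition_index`` and ``conditions`` attributes).
    """
    est = CircuitMLP(max_epochs=epochs, learning_rate=learning_rate,
                     n_restarts=restarts, random_state=seed, **kwargs)
    est.fit(design.X, design.y)
    yhat = est.predict(design.X)
    per_cond = {}
    for ci, cond in enumerate(design.conditions):
        m = design.condition_index == ci
        per_cond[cond] = rmse(yhat[m], design.y[m])
    return FitResult(
        params=est.params_,
        rmse_overall=est.rmse_,
        rmse_per_condition=per_cond,
        training_log=est.loss_curve_,
        seed=seed,
        restarts=restarts,
        epochs_run=est.n_epochs_,
    )


def predict_ablation(params: MLPParams, responses: dict, ablated=()) -> np.ndarray:
    """Counterfactual raphe curve under ablation of the named subtypes.

    ``responses`` maps each of the six subtype names to its characteristic
    response vector (all equal length).  Ablated subtypes are zeroed, the
    forward pass is run timepoint-wise, and the estimated raphe curve is
    returned.
    """
    unknown = set(ablated) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtype(s): {sorted(unknown)}")
    cols = []
    n = None
    for name in SUBTYPES:
        v = np.asarray(responses[name], dtype=float).ravel()
        if n is None:
            n = v.size
        elif v.size != n:
            raise ValueError("responses must share a common length")
        cols.append(np.zeros(n) if name in ablated else v)
    X = np.column_stack(cols)
    return forward(params, X)
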