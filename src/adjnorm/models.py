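"""Cox-partial-likelihood neural survival models.

The network maps a standardized feature vector to a scalar log-risk h(x)
through two hidden layers whose widths default to ceil(sqrt(d)) for input
dimension d (the architecture used by Cox-nnet/DeepSurv-style models), with
ReLU or Tanh activations.  It is trained by minimizing the negative Cox
partial log-likelihood

    L(theta) = - sum_{i: E_i = 1} [ h(x_i) - log sum_{j: t_j >= t_i} exp h(x_j) ]
               + lambda * ||theta||^2

with full-batch gradient descent (Adam available by flag).  Tied event
times are handled Breslow-style: tied events share one risk set.  The
forward pass, loss, analytic gradients and the training loop are all
implemented here in plain numpy so the objective is exactly the one stated
above; with no hidden layers the model is a linear Cox model and its
optimum coincides with the Newton–Raphson fit in :mod:`adjnorm.survival`.

A uniform adapter contract — ``fit(X, time, event)`` / ``predict_risk(X)``
— lets external learners (random survival forests, survival SVMs) plug into
the same cross-validation and evaluation harnesses without this package
reimplementing them.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .survival import concordance_index, fit_cox

logger = logging.getLogger("adjnorm")

__all__ = [
    "CoxNN",
    "TrainConfig",
    "init_cox_nn",
    "nn_forward",
    "cox_nn_loss",
    "partial_nll",
    "train_cox_nn",
    "cv_select_hyperparams",
    "CoxNNModel",
    "CoxPHModel",
    "SksurvAdapter",
]


# ---------------------------------------------------------------------------
# network


@dataclass
class CoxNN:
    """A small multilayer perceptron with a scalar log-risk output."""

    weights: list  # W_l with shape (fan_in, fan_out)
    biases: list
    activation: str = "tanh"

    def __post_init__(self):
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")

    @property
    def layer_widths(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def flatten(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights] + [b.ravel() for b in self.biases])

    def to_json(self) -> str:
        return json.dumps({
            "activation": self.activation,
            "layer_widths": self.layer_widths,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        })

    @classmethod
    def from_json(cls, s: str) -> "CoxNN":
        d = json.loads(s)
        return cls(weights=[np.asarray(w, float) for w in d["weights"]],
                   biases=[np.asarray(b, float) for b in d["biases"]],
                   activation=d["activation"])


def init_cox_nn(n_inputs: int, hidden_widths=None, activation: str = "tanh",
                rng=None) -> CoxNN:
    """Initialize a Cox network; ``hidden_widths=None`` applies the
    ceil(sqrt(d)) two-hidden-layer rule, ``()`` gives a depth-0 linear model.
    Weights and biases are uniform on +/- 1/sqrt(fan_in); nonzero biases
    keep ReLU pre-activations off the exact kink."""
    rng = np.random.default_rng(rng)
    if hidden_widths is None:
        w = math.ceil(math.sqrt(n_inputs))
        hidden_widths = (w, w)
    widths = [n_inputs, *hidden_widths, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return CoxNN(weights=weights, biases=biases, activation=activation)


def _act(z, kind):
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _act_grad(z, kind):
    return (z > 0).astype(float) if kind == "relu" else 1.0 - np.tanh(z) ** 2


def _forward_cached(model: CoxNN, X):
    a = np.asarray(X, dtype=float)
    if a.ndim != 2 or a.shape[1] != model.weights[0].shape[0]:
        raise ValueError(f"X must be 2-D with {model.weights[0].shape[0]} columns")
    pre, acts = [], [a]
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = acts[-1] @ w + b
        pre.append(z)
        acts.append(z if i == len(model.weights) - 1 else _act(z, model.activation))
    return acts[-1][:, 0], pre, acts


def nn_forward(model: CoxNN, X) -> np.ndarray:
    """Deterministic forward pass; one scalar log-risk per sample."""
    return _forward_cached(model, X)[0]


# ---------------------------------------------------------------------------
# loss


def _risk_set_terms(time, event):
    """Sorting machinery shared by the loss and its gradient."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    order = np.argsort(time, kind="stable")
    n = len(time)
    ts = time[order]
    first = np.zeros(n, dtype=int)
    same = ts[1:] == ts[:-1]
    first[1:] = np.where(same, 0, np.arange(1, n))
    first = np.maximum.accumulate(first)
    # last index of each tie group
    last = np.full(n, n - 1, dtype=int)
    last[:-1] = np.where(same, n - 1, np.arange(n - 1))
    last = np.minimum.accumulate(last[::-1])[::-1]
    return order, ts, event[order], first, last


def partial_nll(h, time, event) -> float:
    """Negative Cox partial log-likelihood of risk scores h (Breslow ties)."""
    h = np.asarray(h, dtype=float)
    order, ts, es, first, _ = _risk_set_terms(time, event)
    hs = h[order]
    shift = hs.max()
    w = np.exp(hs - shift)
    rs0 = np.cumsum(w[::-1])[::-1]
    log_s = np.log(rs0[first]) + shift
    ev = es == 1
    return float(-(hs[ev] - log_s[ev]).sum())


def _partial_nll_grad_h(h, time, event):
    """Gradient of the negative partial log-likelihood w.r.t. each h_k."""
    h = np.asarray(h, dtype=float)
    order, ts, es, first, last = _risk_set_terms(time, event)
    hs = h[order]
    shift = hs.max()
    w = np.exp(hs - shift)
    rs0 = np.cumsum(w[::-1])[::-1]
    s = rs0[first]  # risk-set sum (shifted scale) for each sorted sample
    cum = np.cumsum(es / s)
    grad_sorted = -(es - w * cum[last])
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return grad


def cox_nn_loss(h, time, event, lambda_l2: float = 0.0, theta=None) -> float:
    """Training loss: negative partial log-likelihood plus lambda*||theta||^2."""
    loss = partial_nll(h, time, event)
    if lambda_l2:
        if theta is None:
            raise ValueError("theta is required when lambda_l2 > 0")
        theta = np.asarray(theta, dtype=float)
        loss += lambda_l2 * float(theta @ theta)
    return loss


def loss_and_gradients(model: CoxNN, X, time, event, lambda_l2: float = 0.0):
    """Loss plus analytic gradients for every weight and bias (backprop)."""
    h, pre, acts = _forward_cached(model, X)
    loss = partial_nll(h, time, event)
    if lambda_l2:
        theta = model.flatten()
        loss += lambda_l2 * float(theta @ theta)
    delta = _partial_nll_grad_h(h, time, event)[:, None]
    gw = [None] * len(model.weights)
    gb = [None] * len(model.biases)
    for layer in range(len(model.weights) - 1, -1, -1):
        gw[layer] = acts[layer].T @ delta + 2.0 * lambda_l2 * model.weights[layer]
        gb[layer] = delta.sum(axis=0) + 2.0 * lambda_l2 * model.biases[layer]
        if layer:
            delta = (delta @ model.weights[layer].T) * _act_grad(pre[layer - 1], model.activation)
    return loss, gw, gb


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Hyperparameters for full-batch Cox-NN training."""

    lambda_l2: float = 1e-3
    learning_rate: float = 1e-2
    max_epochs: int = 300
    seed: int = 0
    activation: str = "tanh"
    optimizer: str = "gd"  # or "adam"
    hidden_widths: tuple | None = None  # None -> ceil(sqrt(d)) twice; () -> linear
    patience: int | None = None  # early stop on validation loss when val data given
    normalize_loss: bool = True  # scale gradient by 1/n_events for step-size stability

    def __post_init__(self):
        if self.lambda_l2 < 0:
            raise ValueError("lambda_l2 must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def train_cox_nn(X, time, event, config: TrainConfig,
                 X_val=None, time_val=None, event_val=None):
    """Train a Cox network by full-batch gradient descent.

    Deterministic given ``config.seed`` and the data.  Returns
    ``(model, history)`` where history rows are (epoch, loss[, val_loss]).
    Divergence to NaN raises with advice to lower the learning rate.
    """
    X = np.asarray(X, dtype=float)
    model = init_cox_nn(X.shape[1], hidden_widths=config.hidden_widths,
                        activation=config.activation, rng=config.seed)
    scale = 1.0 / max(np.asarray(event).sum(), 1.0) if config.normalize_loss else 1.0
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history = []
    best_val, best_state, stall = np.inf, None, 0
    for epoch in range(1, config.max_epochs + 1):
        loss, gw, gb = loss_and_gradients(model, X, time, event, config.lambda_l2)
        if not np.isfinite(loss):
            raise RuntimeError(
                "Cox-NN training diverged (loss is not finite); try a smaller learning rate"
            )
        row = {"epoch": epoch, "loss": loss}
        for i in range(len(model.weights)):
            g_wi = gw[i] * scale
            g_bi = gb[i] * scale
            if config.optimizer == "adam":
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * g_wi
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * g_wi**2
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * g_bi
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * g_bi**2
                mh_w = m_w[i] / (1 - beta1**epoch)
                vh_w = v_w[i] / (1 - beta2**epoch)
                mh_b = m_b[i] / (1 - beta1**epoch)
                vh_b = v_b[i] / (1 - beta2**epoch)
                model.weights[i] -= config.learning_rate * mh_w / (np.sqrt(vh_w) + eps)
                model.biases[i] -= config.learning_rate * mh_b / (np.sqrt(vh_b) + eps)
            elif config.optimizer == "gd":
                model.weights[i] -= config.learning_rate * g_wi
                model.biases[i] -= config.learning_rate * g_bi
            else:
                raise ValueError(f"unknown optimizer {config.optimizer!r}")
        if X_val is not None:
            h_val = nn_forward(model, X_val)
            val_loss = cox_nn_loss(h_val, time_val, event_val, config.lambda_l2, model.flatten())
            row["val_loss"] = val_loss
            if config.patience is not None:
                if val_loss < best_val - 1e-10:
                    best_val, stall = val_loss, 0
                    best_state = ([w.copy() for w in model.weights], [b.copy() for b in model.biases])
                else:
                    stall += 1
                    if stall >= config.patience:
                        history.append(row)
                        break
        history.append(row)
    if best_state is not None:
        model.weights, model.biases = best_state
    import pandas as pd

    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# model adapters (uniform fit / predict_risk contract)


class CoxNNModel:
    """Adapter: Cox neural network under the fit/predict_risk contract."""

    def __init__(self, config: TrainConfig | None = None, **overrides):
        base = config or TrainConfig()
        if overrides:
            base = TrainConfig(**{**base.__dict__, **overrides})
        self.config = base
        self.model_: CoxNN | None = None

    def fit(self, X, time, event):
        self.model_, self.history_ = train_cox_nn(X, time, event, self.config)
        return self

    def predict_risk(self, X) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("model is not fitted")
        return nn_forward(self.model_, np.asarray(X, dtype=float))


class CoxPHModel:
    """Adapter: linear Cox proportional-hazards model (optionally ridged)."""

    def __init__(self, ridge_lambda: float = 0.0, ties: str = "breslow"):
        self.ridge_lambda = ridge_lambda
        self.ties = ties
        self.fit_ = None

    def fit(self, X, time, event):
        self.fit_ = fit_cox(X, time, event, ridge_lambda=self.ridge_lambda, ties=self.ties)
        return self

    def predict_risk(self, X) -> np.ndarray:
        if self.fit_ is None:
            raise RuntimeError("model is not fitted")
        return np.asarray(X, dtype=float) @ self.fit_.coefficients


class SksurvAdapter:
    """Adapter for scikit-survival style estimators (random survival
    forests, survival SVMs, ...): wraps their structured-array target and
    ``predict`` into the fit/predict_risk contract.  The estimator itself is
    supplied by the caller; this package does not implement those learners."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, time, event):
        y = np.empty(len(time), dtype=[("event", bool), ("time", float)])
        y["event"] = np.asarray(event, dtype=bool)
        y["time"] = np.asarray(time, dtype=float)
        self.estimator.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_risk(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)), dtype=float)


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(event, k, rng):
    """Event-stratified k-fold assignment; every fold keeps events when
    the event count allows it."""
    event = np.asarray(event)
    folds = np.empty(len(event), dtype=int)
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cv_select_hyperparams(model_factory, grid, X, time, event, k: int = 3, seed: int = 0):
    """Select hyperparameters by k-fold cross-validated concordance.

    ``model_factory(params)`` builds a fit/predict_risk model from one grid
    entry (a dict).  Folds are event-stratified; a candidate that fails on
    every fold is excluded with a warning; ties in mean validation C-index
    go to the earlier grid entry.  Returns ``(best_params, table)``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(event, k, rng)
    results = []
    for pi, params in enumerate(grid):
        scores = []
        for fold in range(k):
            tr, va = folds != fold, folds == fold
            if event[tr].sum() < 1 or event[va].sum() < 1:
                continue
            try:
                m = model_factory(params)
                m.fit(X[tr], time[tr], event[tr])
                scores.append(concordance_index(time[va], event[va], m.predict_risk(X[va])))
            except Exception as exc:  # candidate may fail on a fold
                logger.warning("cv candidate %r failed on fold %d: %s", params, fold, exc)
        if scores:
            results.append({"params": params, "order": pi, "mean_c": float(np.mean(scores)),
                            "n_folds": len(scores)})
        else:
            logger.warning("cv candidate %r failed on all folds; excluded", params)
    if not results:
        raise RuntimeError("every hyperparameter candidate failed on every fold")
    best = max(results, key=lambda r: (r["mean_c"], -r["order"]))
    return best["params"], results
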