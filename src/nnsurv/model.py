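"""Discrete-time survival network: heads, likelihood loss, training.

The model maps covariates to a vector ``surv_pred`` of per-interval
conditional survival probabilities ``1 - h_j`` (``h_j`` = hazard: the
probability of failing in interval ``j`` given survival to its start).
Two output heads are provided:

* **flexible** — each interval gets its own dense output neuron with a
  sigmoid activation, so both the baseline hazard and the covariate effect
  may vary freely with follow-up time (no proportional-hazards
  assumption);
* **proportional hazards** — a single linear predictor ``Xβ`` (no bias)
  scales a free per-interval baseline: ``1 - h_j = (1 - h_base,j)^exp(Xβ)``,
  the discrete-time analogue of the Cox model with a complementary
  log-log link.

The loss is the exact negative log likelihood of the discrete-time
survival model, written as a bilinear function of the target encoding
(``surv_s``, ``surv_f``) so that it depends only on the individuals in the
current mini-batch — which is what permits mini-batch gradient descent.
Gradients are computed analytically (the architecture is dense layers with
ReLU plus the sigmoid/power heads, so backpropagation is closed-form) and
verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ExtrapolationError, TrainingDivergedError
from .grid import TimeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "EPS",
    "flexible_head",
    "ph_head",
    "negative_log_likelihood",
    "brown_loss",
    "loss_gradient",
    "survival_curve",
    "survival_at",
    "crossing_time",
    "StepSurvivalCurve",
    "TrainingConfig",
    "TrainingHistory",
    "SurvivalNetwork",
    "life_table_from_encodings",
    "select_l2_cross_validated",
]

#: probabilities are clipped to [EPS, 1 - EPS] before logarithms
EPS = 1e-7


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


def clip_probabilities(p):
    return np.clip(p, EPS, 1.0 - EPS)


# ---------------------------------------------------------------------------
# Output heads
# ---------------------------------------------------------------------------

def flexible_head(hidden, kernel, bias):
    """Per-interval conditional survival from a dense sigmoid layer.

    ``surv_pred(j) = sigmoid(hidden . kernel[:, j] + bias[j])`` — the log
    odds of surviving interval ``j`` are linear in the incoming features.

    Parameters
    ----------
    hidden : (d,) or (batch, d) array
    kernel : (d, n) array
    bias : (n,) array
    """
    hidden = np.asarray(hidden, dtype=float)
    single = hidden.ndim == 1
    hidden = np.atleast_2d(hidden)
    kernel = np.asarray(kernel, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if hidden.shape[1] != kernel.shape[0]:
        raise ValueError(
            f"feature dimension {hidden.shape[1]} does not match kernel rows {kernel.shape[0]}"
        )
    if bias.shape != (kernel.shape[1],):
        raise ValueError("bias length must equal the number of intervals")
    out = _sigmoid(hidden @ kernel + bias)
    return out[0] if single else out


def ph_head(xbeta, base_logits):
    """Proportional-hazards head.

    ``surv_pred(j) = sigmoid(base_logits[j]) ** exp(xbeta)``: the linear
    predictor raises the per-interval baseline conditional survival to the
    power ``exp(Xβ)``, so the covariate effect on the hazard is constant
    over follow-up time.

    ``xbeta`` may be a scalar or a batch vector.
    """
    base = _sigmoid(np.asarray(base_logits, dtype=float))
    xb = np.asarray(xbeta, dtype=float)
    scalar = xb.ndim == 0
    xb = np.atleast_1d(xb)
    # exp(xbeta) is bounded to keep the power finite in float64
    expxb = np.exp(np.clip(xb, -500, 500))
    out = clip_probabilities(base[None, :] ** expxb[:, None])
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _check_shapes(surv_s, surv_f, surv_pred):
    surv_s = np.atleast_2d(np.asarray(surv_s, dtype=float))
    surv_f = np.atleast_2d(np.asarray(surv_f, dtype=float))
    surv_pred = np.atleast_2d(np.asarray(surv_pred, dtype=float))
    if not (surv_s.shape == surv_f.shape == surv_pred.shape):
        raise ValueError(
            f"shape mismatch: surv_s {surv_s.shape}, surv_f {surv_f.shape}, "
            f"surv_pred {surv_pred.shape}"
        )
    return surv_s, surv_f, surv_pred


def negative_log_likelihood(surv_s, surv_f, surv_pred, reduction="sum"):
    """Negative log likelihood of the discrete-time survival model.

    Per individual the log likelihood is::

        sum_j  ln(1 + surv_s(j) * (surv_pred(j) - 1))
             + ln(1 - surv_f(j) * surv_pred(j))

    i.e. ``ln surv_pred(j)`` for every interval survived plus
    ``ln(1 - surv_pred(j)) = ln h_j`` for the failure interval — exactly
    the censored-data likelihood, just written so it vectorizes over a
    mini-batch.  Predictions are clipped to ``[EPS, 1-EPS]`` first.

    ``reduction`` is ``"sum"`` (default) or ``"mean"`` over the batch; the
    choice only rescales gradients (an effective learning-rate change).
    """
    surv_s, surv_f, p = _check_shapes(surv_s, surv_f, surv_pred)
    p = clip_probabilities(p)
    ll = np.log1p(surv_s * (p - 1.0)) + np.log1p(-surv_f * p)
    per_individual = ll.sum(axis=1)
    if reduction == "sum":
        return -per_individual.sum()
    if reduction == "mean":
        return -per_individual.mean()
    raise ValueError(f"unknown reduction {reduction!r}")


def loss_gradient(surv_s, surv_f, surv_pred, reduction="sum"):
    """d(negative_log_likelihood)/d(surv_pred), elementwise.

    Evaluated at the clipped predictions; where clipping is active the
    gradient is zero (the clip is flat), matching finite differences of
    the loss as implemented.
    """
    surv_s, surv_f, p_raw = _check_shapes(surv_s, surv_f, surv_pred)
    p = clip_probabilities(p_raw)
    g = -(surv_s / (1.0 + surv_s * (p - 1.0)) - surv_f / (1.0 - surv_f * p))
    g[(p_raw < EPS) | (p_raw > 1.0 - EPS)] = 0.0
    if reduction == "mean":
        g = g / surv_s.shape[0]
    return g


def brown_loss(surv_s, surv_f, surv_pred, reduction="sum"):
    """Quadratic (heuristic) discrete-time loss, for comparison.

    Per individual: ``1/2 h_j^2`` for every interval survived and
    ``1/2 (1 - h_j)^2`` for the failure interval, with ``h = 1 -
    surv_pred``.  For a saturated (e.g. null) model its minimizer matches
    the life-table hazard ``d_j / r_j``, but for constrained models it is
    *not* the maximum-likelihood estimate and yields different parameters
    than :func:`negative_log_likelihood`.
    """
    surv_s, surv_f, p = _check_shapes(surv_s, surv_f, surv_pred)
    h = 1.0 - p
    per_individual = 0.5 * (surv_s * h**2 + surv_f * (1.0 - h) ** 2).sum(axis=1)
    if reduction == "sum":
        return per_individual.sum()
    if reduction == "mean":
        return per_individual.mean()
    raise ValueError(f"unknown reduction {reduction!r}")


def brown_loss_gradient(surv_s, surv_f, surv_pred, reduction="sum"):
    """d(brown_loss)/d(surv_pred)."""
    surv_s, surv_f, p = _check_shapes(surv_s, surv_f, surv_pred)
    g = -surv_s * (1.0 - p) + surv_f * p
    if reduction == "mean":
        g = g / surv_s.shape[0]
    return g


_LOSSES = {
    "likelihood": (negative_log_likelihood, loss_gradient),
    "brown": (brown_loss, brown_loss_gradient),
}


# ---------------------------------------------------------------------------
# Survival curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepSurvivalCurve:
    """Cumulative survival probabilities at the interval ends.

    ``S[j] = prod_{i<=j} surv_pred(i)`` — the probability of surviving at
    least to the end of interval ``j``.
    """

    grid: TimeGrid
    S: np.ndarray = field()

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        if S.shape != (self.grid.n,):
            raise ValueError("S must have one value per interval")
        object.__setattr__(self, "S", S)

    def at(self, t, mode="linear"):
        return survival_at(t, self, mode=mode)


def survival_curve(surv_pred, grid: TimeGrid) -> StepSurvivalCurve:
    """Cumulative survival from per-interval conditional survival."""
    p = np.asarray(surv_pred, dtype=float)
    return StepSurvivalCurve(grid=grid, S=np.cumprod(p))


def survival_at(t, curve: StepSurvivalCurve, mode="linear"):
    """Survival probability at arbitrary time(s) ``t`` within the grid.

    ``mode="linear"`` (default) interpolates linearly through the knots
    ``(0, 1), (t_1, S_1), ..., (t_n, S_n)``; ``mode="step"`` returns the
    right-continuous step function.  Times past ``t_n`` raise
    :class:`ExtrapolationError` — the model carries no information there.
    """
    t_arr = np.asarray(t, dtype=float)
    boundaries = curve.grid.boundaries
    if np.any(t_arr < 0):
        raise ValueError("negative time")
    if np.any(t_arr > boundaries[-1]):
        raise ExtrapolationError(
            f"t={np.max(t_arr)} is past the last interval boundary "
            f"t_n={boundaries[-1]}; the model does not extrapolate"
        )
    knots_t = np.concatenate(([0.0], boundaries))
    knots_s = np.concatenate(([1.0], curve.S))
    if mode == "linear":
        out = np.interp(t_arr, knots_t, knots_s)
    elif mode == "step":
        idx = np.searchsorted(knots_t, t_arr, side="right") - 1
        out = knots_s[idx]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if t_arr.ndim == 0 else out


def crossing_time(curve: StepSurvivalCurve, level: float = 0.5) -> float:
    """First time at which the (piecewise-linear) curve crosses ``level``.

    With ``level = 0.5`` this is the predicted median survival time.
    Raises :class:`ExtrapolationError` if the curve never reaches the
    level within the grid.
    """
    knots_t = np.concatenate(([0.0], curve.grid.boundaries))
    knots_s = np.concatenate(([1.0], curve.S))
    below = np.flatnonzero(knots_s < level)
    if below.size == 0:
        raise ExtrapolationError(
            f"curve stays above {level} through t_n={knots_t[-1]}"
        )
    i = below[0]
    t0, t1 = knots_t[i - 1], knots_t[i]
    s0, s1 = knots_s[i - 1], knots_s[i]
    return float(t0 + (s0 - level) / (s0 - s1) * (t1 - t0))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyperparameters for mini-batch gradient descent.

    ``seed`` is mandatory: it controls weight initialization and batch
    shuffling, making every fit reproducible.
    """

    seed: int
    optimizer: str = "rmsprop"       # "rmsprop" | "sgd"
    learning_rate: float = 0.01
    batch_size: int = 256
    epochs: int = 1000
    l2: float = 0.0                  # penalty on kernel weights (not biases)
    loss: str = "likelihood"         # "likelihood" | "brown"
    reduction: str = "sum"
    shuffle: bool = True


@dataclass
class TrainingHistory:
    final_loss: float
    losses: list


class _RMSProp:
    def __init__(self, lr, rho=0.9, eps=1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = {}

    def step(self, params, grads):
        for k, g in grads.items():
            c = self.cache.get(k)
            c = (self.rho * c + (1 - self.rho) * g * g) if c is not None else (1 - self.rho) * g * g
            self.cache[k] = c
            params[k] -= self.lr * g / (np.sqrt(c) + self.eps)


class _SGD:
    def __init__(self, lr):
        self.lr = lr

    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * g


class SurvivalNetwork:
    """Dense feed-forward network ending in a survival head.

    Architecture: ``input -> [dense+ReLU] * len(hidden_sizes) -> head``.
    ``hidden_sizes=()`` gives a generalized linear model in the
    covariates; ``input_dim=0`` gives an intercept-only (null) model whose
    maximum-likelihood fit is the life-table hazard.

    The head is ``"flexible"`` (one sigmoid output per interval) or
    ``"ph"`` (scalar linear predictor, no bias, over a free per-interval
    baseline).
    """

    def __init__(self, grid: TimeGrid, input_dim: int, hidden_sizes: Sequence[int] = (),
                 head: str = "flexible"):
        if head not in ("flexible", "ph"):
            raise ValueError(f"unknown head {head!r}")
        if input_dim < 0 or any(h < 1 for h in hidden_sizes):
            raise ValueError("invalid architecture")
        self.grid = grid
        self.input_dim = int(input_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.head = head
        self.params: dict[str, np.ndarray] = {}

    # -- parameters ---------------------------------------------------

    def initialize(self, rng: np.random.Generator):
        dims = (self.input_dim,) + self.hidden_sizes
        p = {}
        for layer, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            limit = np.sqrt(6.0 / (d_in + d_out))
            p[f"W{layer}"] = rng.uniform(-limit, limit, size=(d_in, d_out))
            p[f"b{layer}"] = np.zeros(d_out)
        d_last = dims[-1]
        n = self.grid.n
        if self.head == "flexible":
            limit = np.sqrt(6.0 / (d_last + n))
            p["kernel"] = rng.uniform(-limit, limit, size=(d_last, n))
            p["bias"] = np.zeros(n)
        else:
            limit = np.sqrt(6.0 / (d_last + 1))
            p["beta"] = rng.uniform(-limit, limit, size=(d_last, 1))
            p["base_logits"] = np.zeros(n)
        self.params = p

    @property
    def _kernel_keys(self):
        keys = [k for k in self.params if k.startswith("W")]
        if self.head == "flexible":
            keys.append("kernel")
        else:
            keys.append("beta")
        return keys

    # -- forward / backward -------------------------------------------

    def _forward(self, X):
        """Returns (surv_pred, cache-for-backprop)."""
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[1] != self.input_dim:
            raise ValueError(f"X must be (batch, {self.input_dim}), got {A.shape}")
        cache = {"A": [A], "Z": []}
        for layer in range(len(self.hidden_sizes)):
            Z = A @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            A = np.maximum(Z, 0.0)
            cache["Z"].append(Z)
            cache["A"].append(A)
        if self.head == "flexible":
            P = _sigmoid(A @ self.params["kernel"] + self.params["bias"])
        else:
            xb = (A @ self.params["beta"])[:, 0]
            q = _sigmoid(self.params["base_logits"])
            expxb = np.exp(np.clip(xb, -500, 500))
            P = clip_probabilities(q[None, :] ** expxb[:, None])
            cache.update(xb=xb, q=q, expxb=expxb)
        cache["P"] = P
        return P, cache

    def predict_conditional(self, X):
        """Per-interval conditional survival probabilities, (batch, n)."""
        P, _ = self._forward(np.atleast_2d(X))
        return P

    def predict_survival(self, X):
        """Cumulative survival at every interval end, (batch, n)."""
        return np.cumprod(self.predict_conditional(X), axis=1)

    def predict_curve(self, x) -> StepSurvivalCurve:
        S = self.predict_survival(np.atleast_2d(x))[0]
        return StepSurvivalCurve(grid=self.grid, S=S)

    def _backward(self, cache, dP, l2):
        """Gradients of loss wrt parameters given dLoss/dP."""
        grads = {}
        P = cache["P"]
        if self.head == "flexible":
            dZ = dP * P * (1.0 - P)            # sigmoid'
            A_last = cache["A"][-1]
            grads["kernel"] = A_last.T @ dZ + 2.0 * l2 * self.params["kernel"]
            grads["bias"] = dZ.sum(axis=0)
            dA = dZ @ self.params["kernel"].T
        else:
            q, expxb = cache["q"], cache["expxb"]
            # P = q^e: dP/d base_logits_j = e * P * (1-q_j); dP/d xb = P ln q * e
            dC = dP * (expxb[:, None] * P * (1.0 - q)[None, :])
            grads["base_logits"] = dC.sum(axis=0)
            lnq = np.log(q)
            dxb = (dP * P * lnq[None, :]).sum(axis=1) * expxb
            A_last = cache["A"][-1]
            grads["beta"] = A_last.T @ dxb[:, None] + 2.0 * l2 * self.params["beta"]
            dA = dxb[:, None] @ self.params["beta"].T
        for layer in reversed(range(len(self.hidden_sizes))):
            dZ = dA * (cache["Z"][layer] > 0)
            grads[f"W{layer}"] = cache["A"][layer].T @ dZ + 2.0 * l2 * self.params[f"W{layer}"]
            grads[f"b{layer}"] = dZ.sum(axis=0)
            dA = dZ @ self.params[f"W{layer}"].T
        return grads

    # -- training ------------------------------------------------------

    def loss(self, X, surv_s, surv_f, config: TrainingConfig | None = None,
             loss="likelihood", reduction="sum", l2=0.0):
        if config is not None:
            loss, reduction, l2 = config.loss, config.reduction, config.l2
        loss_fn, _ = _LOSSES[loss]
        P, _ = self._forward(X)
        value = loss_fn(surv_s, surv_f, P, reduction=reduction)
        for k in self._kernel_keys:
            value += l2 * float(np.sum(self.params[k] ** 2))
        return value

    def fit(self, X, surv_s, surv_f, config: TrainingConfig) -> TrainingHistory:
        """Mini-batch gradient descent on the configured loss.

        Raises :class:`TrainingDivergedError` (naming the epoch) if the
        loss becomes non-finite.  Returns the training history; the final
        entry is the full-dataset loss after the last epoch.
        """
        X = np.asarray(X, dtype=float)
        surv_s = np.asarray(surv_s, dtype=float)
        surv_f = np.asarray(surv_f, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("empty dataset")
        if not self.params:
            self.initialize(np.random.default_rng(config.seed))
        rng = np.random.default_rng(config.seed + 1)
        if config.optimizer == "rmsprop":
            opt = _RMSProp(config.learning_rate)
        elif config.optimizer == "sgd":
            opt = _SGD(config.learning_rate)
        else:
            raise ValueError(f"unknown optimizer {config.optimizer!r}")
        _, grad_fn = _LOSSES[config.loss]

        n_samples = X.shape[0]
        losses = []
        for epoch in range(config.epochs):
            order = rng.permutation(n_samples) if config.shuffle else np.arange(n_samples)
            epoch_loss = 0.0
            for start in range(0, n_samples, config.batch_size):
                sel = order[start:start + config.batch_size]
                P, cache = self._forward(X[sel])
                loss_fn, _ = _LOSSES[config.loss]
                batch_loss = loss_fn(surv_s[sel], surv_f[sel], P, reduction=config.reduction)
                dP = grad_fn(surv_s[sel], surv_f[sel], P, reduction=config.reduction)
                grads = self._backward(cache, dP, config.l2)
                opt.step(self.params, grads)
                epoch_loss += float(batch_loss)
            if not np.isfinite(epoch_loss):
                raise TrainingDivergedError(epoch=epoch, loss=epoch_loss)
            losses.append(epoch_loss)
        final = float(self.loss(X, surv_s, surv_f,
                                loss=config.loss, reduction=config.reduction, l2=config.l2))
        if not np.isfinite(final):
            raise TrainingDivergedError(epoch=config.epochs, loss=final)
        return TrainingHistory(final_loss=final, losses=losses)

    # -- persistence ---------------------------------------------------

    def save(self, path, config: TrainingConfig | None = None, covariate_names=None):
        """Write a self-describing JSON checkpoint (grid + architecture +
        parameters + training config)."""
        payload = {
            "format": "nnsurv-checkpoint-v1",
            "grid_boundaries": self.grid.boundaries.tolist(),
            "input_dim": self.input_dim,
            "hidden_sizes": list(self.hidden_sizes),
            "head": self.head,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "training_config": asdict(config) if config is not None else None,
            "covariate_names": list(covariate_names) if covariate_names is not None else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "SurvivalNetwork":
        payload = json.loads(Path(path).read_text())
        model = cls(
            grid=TimeGrid(np.asarray(payload["grid_boundaries"])),
            input_dim=payload["input_dim"],
            hidden_sizes=payload["hidden_sizes"],
            head=payload["head"],
        )
        model.params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return model


# ---------------------------------------------------------------------------
# Life table and cross-validation helpers
# ---------------------------------------------------------------------------

def life_table_from_encodings(surv_s, surv_f):
    """Counts (d_j, r_j) and hazards h_j = d_j / r_j implied by an encoding.

    ``d_j`` = failures in interval j, ``r_j`` = individuals in view during
    interval j under the half-interval censoring-credit convention.  These
    are the maximum-likelihood hazards of the intercept-only model.
    """
    surv_s = np.atleast_2d(np.asarray(surv_s, dtype=float))
    surv_f = np.atleast_2d(np.asarray(surv_f, dtype=float))
    d = surv_f.sum(axis=0)
    r = d + surv_s.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(r > 0, d / np.maximum(r, 1e-300), 0.0)
    return d, r, h


def select_l2_cross_validated(X, surv_s, surv_f, grid, candidates,
                              hidden_sizes=(), head="flexible",
                              k=10, config: TrainingConfig | None = None):
    """Choose the L2 strength maximizing held-out log likelihood.

    k-fold cross-validation on the training set; the score for each
    candidate is the summed held-out log likelihood across folds.  Returns
    ``(best_l2, scores_dict)``.
    """
    from sklearn.model_selection import KFold
    from dataclasses import replace

    if config is None:
        raise ValueError("a TrainingConfig (with seed) is required")
    X = np.asarray(X, dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=config.seed % (2**31))
    scores = {}
    for lam in candidates:
        total = 0.0
        for fold, (tr, te) in enumerate(kf.split(X)):
            model = SurvivalNetwork(grid, X.shape[1], hidden_sizes, head)
            model.fit(X[tr], surv_s[tr], surv_f[tr],
                      replace(config, l2=lam, seed=config.seed + fold))
            P = model.predict_conditional(X[te])
            total -= negative_log_likelihood(surv_s[te], surv_f[te], P)
        scores[lam] = total
        logger.info("cross-validation l2=%g: held-out loglik %.3f", lam, total)
    best = max(scores, key=scores.get)
    return best, scores
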