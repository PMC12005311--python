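"""Toy ordinal classifier with a normalization layer and test-time adaptation.

A two-layer perceptron over tabular features stands in for the imaging
network whose decision layer this package re-implements: the ordinal head
(four nested binary tasks trained with summed binary cross-entropy) and the
adaptation mechanics are what matter here, not the architecture.

The input passes through a feature-normalization layer

    x_norm = gamma * (x - mu) / sqrt(var + eps) + beta

whose statistics (mu, var) are estimated from the training set and whose
affine parameters (gamma, beta) are learned.  Test-time adaptation (TTA)
handles covariate shift without target labels by (i) recomputing mu/var
from the unlabeled target batch and (ii) taking gradient steps on gamma and
beta only, minimizing the Shannon entropy of the model's predictions; every
other weight is left bit-identical.
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import dataclass

import numpy as np

from .ordinal import N_TASKS, decode_matrix

__all__ = [
    "TrainConfig",
    "NormalizingOrdinalClassifier",
    "train_classifier",
    "predict_ordinal",
    "prediction_entropy",
    "test_time_adapt",
    "stage_accuracy",
]

_EPS = 1e-5


@dataclass
class TrainConfig:
    """Full-batch Adam schedule: step decay (halve every ``decay_every``
    epochs), fixed epoch budget, small weight decay."""

    hidden: int = 16
    learning_rate: float = 1e-2
    epochs: int = 300
    decay_every: int = 100
    weight_decay: float = 1e-4
    seed: int = 0


class NormalizingOrdinalClassifier:
    """Normalization layer -> affine -> tanh -> affine -> 4 task logits."""

    def __init__(self, d: int, hidden: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d = d
        self.hidden = hidden
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, N_TASKS))
        self.b2 = np.zeros(N_TASKS)
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.mu = np.zeros(d)
        self.var = np.ones(d)

    # -- forward ---------------------------------------------------------
    def _forward(self, X):
        xh = (X - self.mu) / np.sqrt(self.var + _EPS)
        xn = xh * self.gamma + self.beta
        a1 = xn @ self.W1 + self.b1
        h1 = np.tanh(a1)
        logits = h1 @ self.W2 + self.b2
        p = 1.0 / (1.0 + np.exp(-logits))
        return xh, xn, h1, logits, p

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ValueError(f"expected features of shape (n, {self.d})")
        return self._forward(X)[4]

    # -- (de)serialization ----------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k).tolist() if isinstance(getattr(self, k), np.ndarray)
             else getattr(self, k)
             for k in ("d", "hidden", "W1", "b1", "W2", "b2", "gamma", "beta", "mu", "var")},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizingOrdinalClassifier":
        data = json.loads(text)
        model = cls(data["d"], data["hidden"])
        for k in ("W1", "b1", "W2", "b2", "gamma", "beta", "mu", "var"):
            setattr(model, k, np.asarray(data[k], float))
        return model


def _adam_step(param, grad, state, lr, t):
    m, v = state
    m[:] = 0.9 * m + 0.1 * grad
    v[:] = 0.999 * v + 0.001 * grad * grad
    mhat = m / (1 - 0.9 ** t)
    vhat = v / (1 - 0.999 ** t)
    param -= lr * mhat / (np.sqrt(vhat) + 1e-8)


def train_classifier(X, y, config: TrainConfig | None = None):
    """Fit the classifier on stage-labelled features.

    Minimizes the mean over cases of the summed binary cross-entropy of the
    four nested tasks.  Deterministic given ``config.seed``.  Returns
    ``(model, loss_trace)``.
    """
    config = config or TrainConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels have mismatched shapes")
    n, d = X.shape
    if n < 1:
        raise ValueError("need at least one training case")
    targets = (y[:, None] >= np.arange(1, N_TASKS + 1)[None, :]).astype(float)

    model = NormalizingOrdinalClassifier(d, config.hidden, seed=config.seed)
    # input-layer normalization statistics come from the data alone
    model.mu = X.mean(axis=0)
    model.var = X.var(axis=0)

    params = ["W1", "b1", "W2", "b2", "gamma", "beta"]
    state = {k: (np.zeros_like(getattr(model, k)), np.zeros_like(getattr(model, k)))
             for k in params}
    trace = []
    lr = config.learning_rate
    for epoch in range(config.epochs):
        if epoch > 0 and epoch % config.decay_every == 0:
            lr *= 0.5
        xh, xn, h1, logits, p = model._forward(X)
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        loss = float(-np.mean(np.sum(
            targets * np.log(pc) + (1 - targets) * np.log(1 - pc), axis=1)))
        trace.append(loss)

        dlogits = (p - targets) / n
        gW2 = h1.T @ dlogits + config.weight_decay * model.W2
        gb2 = dlogits.sum(axis=0)
        dh1 = dlogits @ model.W2.T
        da1 = dh1 * (1 - h1 ** 2)
        gW1 = xn.T @ da1 + config.weight_decay * model.W1
        gb1 = da1.sum(axis=0)
        dxn = da1 @ model.W1.T
        ggamma = (dxn * xh).sum(axis=0)
        gbeta = dxn.sum(axis=0)
        grads = dict(W1=gW1, b1=gb1, W2=gW2, b2=gb2, gamma=ggamma, beta=gbeta)
        for k in params:
            _adam_step(getattr(model, k), grads[k], state[k], lr, epoch + 1)
    return model, trace


def predict_ordinal(model: NormalizingOrdinalClassifier, X) -> np.ndarray:
    """Per-row ordinal probability vectors, using stored normalization stats."""
    return model.predict_proba(X)


def prediction_entropy(P) -> float:
    """Shannon entropy of ordinal predictions (natural log).

    Per task ``H = -[p ln p + (1-p) ln(1-p)]`` with ``0 ln 0 = 0``.  A single
    vector returns the sum over its four tasks; a batch returns the mean over
    cases of that sum.
    """
    P = np.atleast_2d(np.asarray(P, float))
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(P > 0, P * np.log(P), 0.0)
              + np.where(P < 1, (1 - P) * np.log(1 - P), 0.0))
    return float(np.mean(h.sum(axis=1)))


def test_time_adapt(model: NormalizingOrdinalClassifier, X_target,
                    steps: int = 10, step_size: float = 1e-2):
    """Adapt the normalization layer to an unlabeled target batch.

    Recomputes (mu, var) from the batch, then runs ``steps`` plain gradient
    steps on (gamma, beta) minimizing the batch prediction entropy.  All
    other weights are untouched (bit-identical).  Returns the adapted copy
    and the entropy trace (length ``steps + 1``: after the statistics
    update, then after each gradient step).
    """
    X = np.asarray(X_target, float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("target batch must be a non-empty (n, d) array")
    if X.shape[1] != model.d:
        raise ValueError(f"expected features of shape (n, {model.d})")
    adapted = deepcopy(model)
    adapted.mu = X.mean(axis=0)
    adapted.var = X.var(axis=0)
    n = X.shape[0]
    trace = [prediction_entropy(adapted.predict_proba(X))]
    for _ in range(steps):
        xh, xn, h1, logits, p = adapted._forward(X)
        # d/dlogit of Bernoulli entropy: -logit * p * (1 - p)
        dlogits = -logits * p * (1 - p) / n
        dh1 = dlogits @ adapted.W2.T
        da1 = dh1 * (1 - h1 ** 2)
        dxn = da1 @ adapted.W1.T
        adapted.gamma -= step_size * (dxn * xh).sum(axis=0)
        adapted.beta -= step_size * dxn.sum(axis=0)
        trace.append(prediction_entropy(adapted.predict_proba(X)))
    return adapted, trace


def stage_accuracy(model: NormalizingOrdinalClassifier, X, y,
                   cutoff: float = 0.5) -> float:
    """Fraction of cases whose decoded stage matches the label."""
    pred = decode_matrix(model.predict_proba(X), cutoff)
    return float(np.mean(pred == np.asarray(y, int)))
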