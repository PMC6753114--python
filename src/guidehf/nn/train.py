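"""Minibatch Adam training with validation-Spearman early stopping."""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
from scipy import stats

from . import engine as eg
from .network import FusionNetwork

__all__ = ["TrainingDivergence", "train_network"]


class TrainingDivergence(RuntimeError):
    """Loss became non-finite; carries the offending configuration."""


class Adam:
    def __init__(self, names, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: None for k in names}
        self.v = {k: None for k in names}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            if g is None:
                continue
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def train_network(
    net: FusionNetwork,
    X: np.ndarray,
    bio: np.ndarray | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    seed: int = 0,
    scope: str = "all",
    max_epochs: int | None = None,
) -> dict:
    """Fit ``net`` in place; returns a history dict.

    Minimizes mean squared error on the training indices; after each epoch
    the validation Spearman is measured and the parameters with the best
    score are restored at the end (early stopping with the configured
    patience). ``scope`` restricts which parameters are updated.
    """
    cfg = net.config
    rng = np.random.default_rng(seed)
    trainable = set(net.param_names(scope))
    opt = Adam(trainable, lr=cfg.learning_rate)
    n_epochs = cfg.max_epochs if max_epochs is None else max_epochs
    history: dict = {"train_loss": [], "val_spearman": []}
    best_score, best_params, since_best = -np.inf, net.copy_params(), 0

    def _val_score() -> float:
        if len(val_idx) == 0:
            return float("nan")
        pred = net.predict(X[val_idx], None if bio is None else bio[val_idx])
        return _spearman(pred, y[val_idx])

    for epoch in range(n_epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            params_t = {
                k: (eg.param(v) if k in trainable else eg.const(v))
                for k, v in net.params.items()
            }
            pred = net.forward(
                X[batch],
                None if bio is None else bio[batch],
                train=True,
                rng=rng,
                params=params_t,
            )
            loss = eg.mean(eg.square(pred - eg.const(y[batch])))
            if not np.isfinite(loss.value):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}; config={asdict(cfg)}"
                )
            loss.backward()
            grads = {k: params_t[k].grad for k in trainable}
            opt.step(net.params, grads)
            epoch_loss += float(loss.value) * len(batch)
        history["train_loss"].append(epoch_loss / len(order))
        score = _val_score()
        history["val_spearman"].append(score)
        if np.isnan(score):
            continue
        if score > best_score:
            best_score, best_params, since_best = score, net.copy_params(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if np.isfinite(best_score):
        net.set_params(best_params)
    history["best_val_spearman"] = best_score
    return history
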