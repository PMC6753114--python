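"""Trainable sequence regressors built on the autodiff engine.

Three architectures share one parameter-dict representation:

* ``rnn`` — embedding + BiLSTM over the 21-token input, dense head.
* ``rnn_biofeature`` — as ``rnn`` with the p hand-crafted biofeatures
  concatenated to the flattened BiLSTM output; the dense head therefore sees
  exactly 21*2n + p inputs (asserted at build time).
* ``cnn`` — 1-D convolution over the one-hot sequence, dense head.

The output unit is a sigmoid so predictions live in the activity range
[0, 1]. Inference goes through the same graph with dropout disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import engine as eg
from .engine import Tensor
from .functional import GATES, LstmParams

SEQ_LEN = 21
VOCAB_SIZE = 5

__all__ = ["NetConfig", "FusionNetwork"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture + optimization hyperparameters for the neural kinds."""

    kind: str = "rnn_biofeature"
    embed_dim: int = 8  # m
    hidden_dim: int = 24  # n
    dense_sizes: tuple[int, ...] = (64,)
    dropout: float = 0.0
    conv_width: int = 5
    conv_filters: int = 32
    learning_rate: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 8
    bio_standardize: bool = True

    def with_kind(self, kind: str) -> "NetConfig":
        return replace(self, kind=kind)


class FusionNetwork:
    """One network instance: parameter dict + forward graph builder."""

    def __init__(self, config: NetConfig, p: int, seed: int = 0):
        if config.kind not in ("rnn", "rnn_biofeature", "cnn"):
            raise ValueError(f"unknown neural kind {config.kind!r}")
        if config.kind != "rnn_biofeature":
            p = 0
        self.config = config
        self.p = p
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        m, n = config.embed_dim, config.hidden_dim
        if config.kind == "cnn":
            K, F = config.conv_width, config.conv_filters
            self.params["conv_W"] = rng.normal(0, np.sqrt(2.0 / (K * VOCAB_SIZE)), (K, VOCAB_SIZE, F))
            self.params["conv_b"] = np.zeros(F)
            head_in = (SEQ_LEN - K + 1) * F
        else:
            self.params["W_m"] = rng.normal(0, 0.3, (VOCAB_SIZE, m))
            for d in ("fwd", "bwd"):
                for g in GATES:
                    self.params[f"{d}_W{g}"] = rng.normal(0, 0.2, (m, n))
                    self.params[f"{d}_U{g}"] = rng.normal(0, 0.2, (n, n))
                    self.params[f"{d}_b{g}"] = np.zeros(n)
            head_in = SEQ_LEN * 2 * n + p
            assert head_in == SEQ_LEN * 2 * n + self.p
        self.head_in = head_in
        prev = head_in
        for i, size in enumerate(config.dense_sizes):
            self.params[f"dense{i}_W"] = rng.normal(0, np.sqrt(2.0 / prev), (prev, size))
            self.params[f"dense{i}_b"] = np.zeros(size)
            prev = size
        self.params["out_W"] = rng.normal(0, np.sqrt(1.0 / prev), (prev, 1))
        self.params["out_b"] = np.zeros(1)

    # -- parameter bookkeeping ------------------------------------------
    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def param_names(self, scope: str = "all") -> list[str]:
        """Names in a training scope; ``last_hidden_layer`` covers the final
        dense hidden layer and the output transform only."""
        if scope == "all":
            return list(self.params)
        if scope == "last_hidden_layer":
            last = len(self.config.dense_sizes) - 1
            names = ["out_W", "out_b"]
            if last >= 0:
                names = [f"dense{last}_W", f"dense{last}_b"] + names
            return names
        raise ValueError(f"unknown scope {scope!r}")

    def lstm_params(self, direction: str) -> LstmParams:
        """Export one direction's weights as a functional LstmParams."""
        return LstmParams(
            W={g: self.params[f"{direction}_W{g}"] for g in GATES},
            U={g: self.params[f"{direction}_U{g}"] for g in GATES},
            b={g: self.params[f"{direction}_b{g}"] for g in GATES},
        )

    # -- graph construction ----------------------------------------------
    def _lstm_direction(
        self, X: np.ndarray, t_order: range, d: str, P: dict[str, Tensor]
    ) -> list[Tensor]:
        B = X.shape[0]
        n = self.config.hidden_dim
        h = eg.const(np.zeros((B, n)))
        c = eg.const(np.zeros((B, n)))
        out: dict[int, Tensor] = {}
        for t in t_order:
            e = eg.const(X[:, t, :]) @ P["W_m"]
            i = eg.sigmoid(e @ P[f"{d}_Wi"] + h @ P[f"{d}_Ui"] + P[f"{d}_bi"])
            f = eg.sigmoid(e @ P[f"{d}_Wf"] + h @ P[f"{d}_Uf"] + P[f"{d}_bf"])
            c = f * c + i * eg.tanh(e @ P[f"{d}_Wc"] + h @ P[f"{d}_Uc"] + P[f"{d}_bc"])
            o = eg.sigmoid(e @ P[f"{d}_Wo"] + h @ P[f"{d}_Uo"] + P[f"{d}_bo"])
            h = o * eg.tanh(c)
            out[t] = h
        return [out[t] for t in range(SEQ_LEN)]

    def forward(
        self,
        X: np.ndarray,
        bio: np.ndarray | None,
        train: bool = False,
        rng: np.random.Generator | None = None,
        params: dict[str, Tensor] | None = None,
    ) -> Tensor:
        """Build the graph for a batch; returns predictions as a (B,) tensor."""
        cfg = self.config
        if params is None:
            params = {k: eg.param(v) for k, v in self.params.items()}
        P = params
        rng = rng or np.random.default_rng(0)
        if cfg.kind == "cnn":
            z = eg.conv1d(eg.const(X), P["conv_W"]) + P["conv_b"]
            z = eg.relu(z)
            h = eg.reshape(z, (X.shape[0], self.head_in))
        else:
            hf = self._lstm_direction(X, range(SEQ_LEN), "fwd", P)
            hb = self._lstm_direction(X, range(SEQ_LEN - 1, -1, -1), "bwd", P)
            steps = []
            for t in range(SEQ_LEN):
                steps += [hf[t], hb[t]]
            if cfg.kind == "rnn_biofeature":
                if bio is None or bio.shape[1] != self.p:
                    raise ValueError(
                        f"rnn_biofeature expects a (B, {self.p}) biofeature matrix"
                    )
                steps = [eg.const(bio)] + steps
            h = eg.concat(steps, axis=1)
            assert h.shape[1] == SEQ_LEN * 2 * cfg.hidden_dim + self.p
        for i in range(len(cfg.dense_sizes)):
            h = eg.relu(h @ P[f"dense{i}_W"] + P[f"dense{i}_b"])
            h = eg.dropout(h, cfg.dropout, rng, train)
        y = eg.sigmoid(h @ P["out_W"] + P["out_b"])
        return eg.reshape(y, (X.shape[0],))

    def predict(self, X: np.ndarray, bio: np.ndarray | None = None) -> np.ndarray:
        consts = {k: eg.const(v) for k, v in self.params.items()}
        return self.forward(X, bio, train=False, params=consts).value
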