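"""Plain-numpy forward passes for the recurrent fusion model.

These are the reference implementations of the model's recurrence:

    i_l = sigmoid(e_l W^i + h_{l-1} U^i + b^i)
    f_l = sigmoid(e_l W^f + h_{l-1} U^f + b^f)
    c_l = f_l * c_{l-1} + i_l * tanh(e_l W^c + h_{l-1} U^c + b^c)
    o_l = sigmoid(e_l W^o + h_{l-1} U^o + b^o)
    h_l = o_l * tanh(c_l)

with zero initial states; the bidirectional pass runs the sequence forwards
and backwards and concatenates per-step hidden states to a 2n vector. The
training path (guidehf.nn.network) uses the same formulas on autodiff
tensors; a test pins the two paths together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LstmParams", "lstm_step", "lstm_sequence", "bilstm_forward", "embed"]

GATES = ("i", "f", "c", "o")


@dataclass
class LstmParams:
    """Per-gate input weights W (m x n), recurrent weights U (n x n) and
    biases b (n) for gates i, f, c, o."""

    W: dict[str, np.ndarray]
    U: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        m, n = self.W["i"].shape
        for g in GATES:
            if self.W[g].shape != (m, n) or self.U[g].shape != (n, n) or self.b[
                g
            ].shape != (n,):
                raise ValueError(f"inconsistent LSTM parameter shapes for gate {g!r}")
            for arr in (self.W[g], self.U[g], self.b[g]):
                if not np.all(np.isfinite(arr)):
                    raise ValueError("LSTM parameters must be finite")

    @property
    def input_dim(self) -> int:
        return self.W["i"].shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W["i"].shape[1]

    @classmethod
    def init(cls, m: int, n: int, rng: np.random.Generator, scale: float = 0.2):
        return cls(
            W={g: rng.normal(0, scale, (m, n)) for g in GATES},
            U={g: rng.normal(0, scale, (n, n)) for g in GATES},
            b={g: np.zeros(n) for g in GATES},
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step(
    e_l: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LstmParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; accepts a single vector or a (B, m) batch."""
    e_l = np.asarray(e_l, dtype=float)
    if e_l.shape[-1] != params.input_dim:
        raise ValueError(
            f"input dim {e_l.shape[-1]} != expected {params.input_dim}"
        )
    W, U, b = params.W, params.U, params.b
    i = _sigmoid(e_l @ W["i"] + h_prev @ U["i"] + b["i"])
    f = _sigmoid(e_l @ W["f"] + h_prev @ U["f"] + b["f"])
    c = f * c_prev + i * np.tanh(e_l @ W["c"] + h_prev @ U["c"] + b["c"])
    o = _sigmoid(e_l @ W["o"] + h_prev @ U["o"] + b["o"])
    h = o * np.tanh(c)
    return h, c


def lstm_sequence(E: np.ndarray, params: LstmParams) -> np.ndarray:
    """Run the cell over time. E: (..., L, m) -> H: (..., L, n)."""
    *lead, L, m = E.shape
    n = params.hidden_dim
    h = np.zeros((*lead, n))
    c = np.zeros((*lead, n))
    H = np.empty((*lead, L, n))
    for t in range(L):
        h, c = lstm_step(E[..., t, :], h, c, params)
        H[..., t, :] = h
    return H


def embed(onehot: np.ndarray, W_m: np.ndarray) -> np.ndarray:
    """Project one-hot tokens to the embedding space: E = x W_m."""
    if onehot.shape[-1] != W_m.shape[0]:
        raise ValueError(
            f"vocabulary size {onehot.shape[-1]} != embedding rows {W_m.shape[0]}"
        )
    return onehot @ W_m


def bilstm_forward(
    E: np.ndarray, fwd: LstmParams, bwd: LstmParams
) -> np.ndarray:
    """Bidirectional pass with per-step concatenation.

    E: (..., L, m) -> H_bi: (..., L, 2n); H_bi[t] = [h_fwd_t ; h_bwd_t] where
    the backward half comes from processing the reversed sequence and
    re-aligning its outputs to the original time axis.
    """
    if fwd.hidden_dim != bwd.hidden_dim:
        raise ValueError("forward/backward hidden sizes differ")
    Hf = lstm_sequence(E, fwd)
    Hb = lstm_sequence(E[..., ::-1, :], bwd)[..., ::-1, :]
    return np.concatenate([Hf, Hb], axis=-1)
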