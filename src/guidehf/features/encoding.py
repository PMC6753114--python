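"""Token and one-hot encoding of 20-nt spacers.

The network input is a length-21 token sequence: a START symbol followed by
the spacer 5'→3'. Vocabulary order is fixed as (START, A, C, G, T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VOCAB = ("<s>", "A", "C", "G", "T")
START_TOKEN = 0
_NT_INDEX = {"A": 1, "C": 2, "G": 3, "T": 4}
SEQ_LEN = 21  # START + 20 spacer positions


@dataclass(frozen=True)
class EncodedGuide:
    """Length-21 token sequence and its 21x5 one-hot matrix."""

    tokens: np.ndarray  # (21,) int
    onehot: np.ndarray  # (21, 5) float

    @property
    def spacer(self) -> str:
        return decode_tokens(self.tokens)


def _check_spacer(spacer: str) -> None:
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    bad = set(spacer) - set("ACGT")
    if bad:
        raise ValueError(f"spacer contains non-ACGT characters: {sorted(bad)}")


def encode_sequence(spacer: str) -> EncodedGuide:
    """Encode one spacer as START-prefixed tokens plus a one-hot matrix."""
    _check_spacer(spacer)
    tokens = np.empty(SEQ_LEN, dtype=np.int64)
    tokens[0] = START_TOKEN
    for i, nt in enumerate(spacer, start=1):
        tokens[i] = _NT_INDEX[nt]
    onehot = np.zeros((SEQ_LEN, len(VOCAB)))
    onehot[np.arange(SEQ_LEN), tokens] = 1.0
    return EncodedGuide(tokens=tokens, onehot=onehot)


def decode_tokens(tokens: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` (drops the START token)."""
    if tokens[0] != START_TOKEN:
        raise ValueError("token sequence must begin with START")
    return "".join(VOCAB[t] for t in tokens[1:])


def encode_batch(spacers: list[str]) -> np.ndarray:
    """One-hot encode many spacers into a (n, 21, 5) array."""
    out = np.zeros((len(spacers), SEQ_LEN, len(VOCAB)))
    for i, s in enumerate(spacers):
        out[i] = encode_sequence(s).onehot
    return out
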