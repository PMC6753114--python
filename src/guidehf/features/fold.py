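"""Guide RNA secondary-structure features.

Two backends:

* ``internal`` — a base-pair-maximization dynamic program (Nussinov-style)
  over Watson-Crick plus G-U wobble pairs with a minimum hairpin loop of
  3 nt. Its folding score is the negated maximal pair count, so lower means
  more folded, matching the sign convention of a free energy. Deterministic
  and dependency-free; the default everywhere.
* ``external`` — ViennaRNA's ``RNAfold`` minimum-free-energy structure in
  kcal/mol, used when thermodynamic energies are wanted. Requesting it
  without the binary on PATH is an explicit error, never a silent fallback.

Sequences may be given as DNA; T is read as U.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap

__all__ = ["FoldReport", "StructureReport", "BackendError", "fold_structure"]

MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
# Watson-Crick + GU wobble, symmetric.
_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in (("A", "U"), ("C", "G"), ("G", "U")):
    _CAN_PAIR[_CODE[_a], _CODE[_b]] = True
    _CAN_PAIR[_CODE[_b], _CODE[_a]] = True


class BackendError(RuntimeError):
    """Requested folding backend is unavailable."""


@_njit(cache=True)
def _fill_dp(codes, can_pair, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair[codes[i], codes[k]]:
                    cand = dp[i + 1][k - 1] + 1 + dp[k + 1][j]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    return dp


def _traceback(dp: np.ndarray, codes: np.ndarray) -> list[tuple[int, int]]:
    """Recover one maximal pairing; ties prefer leaving 5' bases unpaired."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(codes) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if dp[i][j] == dp[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _CAN_PAIR[codes[i], codes[k]] and (
                dp[i][j] == dp[i + 1][k - 1] + 1 + dp[k + 1][j]
            ):
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                if k < j:
                    stack.append((k + 1, j))
                break
    return sorted(pairs)


@dataclass(frozen=True)
class FoldReport:
    """Fold of one RNA: pairing, accessibility, hairpins and a score."""

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    dot_bracket: str
    score: float  # internal: -n_pairs; external: MFE kcal/mol

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def paired(self) -> np.ndarray:
        out = np.zeros(len(self.sequence), dtype=bool)
        for i, j in self.pairs:
            out[i] = out[j] = True
        return out

    @property
    def accessibility(self) -> np.ndarray:
        """1.0 where a position is unpaired."""
        return 1.0 - self.paired.astype(float)

    @property
    def stem_loops(self) -> int:
        """Number of hairpin (innermost) loops."""
        return len(re.findall(r"\(\.*\)", self.dot_bracket))


@dataclass(frozen=True)
class StructureReport:
    """Folds of the spacer alone and, when a scaffold is given, of the full
    spacer+scaffold guide. ``spacer_accessibility`` always covers the 20
    spacer positions, taken from the full-length fold when available."""

    spacer: FoldReport
    full: FoldReport | None

    @property
    def spacer_accessibility(self) -> np.ndarray:
        src = self.full if self.full is not None else self.spacer
        return src.accessibility[:20]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character in sequence: {exc}") from None


@lru_cache(maxsize=100_000)
def _fold_internal(seq: str) -> FoldReport:
    codes = _encode(seq)
    dp = _fill_dp(codes, _CAN_PAIR, MIN_LOOP)
    pairs = _traceback(dp, codes)
    assert len(pairs) == dp[0][len(codes) - 1]
    db = ["."] * len(codes)
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldReport(seq.upper(), tuple(pairs), "".join(db), -float(len(pairs)))


_MFE_RE = re.compile(r"([.()]+)\s+\(\s*(-?\d+\.\d+)\)")


def _fold_external(seq: str) -> FoldReport:
    if shutil.which("RNAfold") is None:
        raise BackendError("external backend requested but RNAfold is not on PATH")
    rna = seq.upper().replace("T", "U")
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", text=True, capture_output=True
    )
    if proc.returncode != 0:
        raise BackendError(f"RNAfold failed: {proc.stderr.strip()}")
    m = _MFE_RE.search(proc.stdout)
    if not m:
        raise BackendError(f"could not parse RNAfold output: {proc.stdout!r}")
    db, mfe = m.group(1), float(m.group(2))
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    return FoldReport(seq.upper(), tuple(sorted(pairs)), db, mfe)


def fold_structure(
    spacer: str, scaffold: str | None = None, backend: str = "internal"
) -> StructureReport:
    """Fold the spacer alone and, optionally, spacer+scaffold."""
    if backend == "internal":
        folder = _fold_internal
    elif backend == "external":
        folder = _fold_external
    else:
        raise ValueError(f"unknown fold backend {backend!r}")
    spacer_rep = folder(spacer)
    full_rep = folder(spacer + scaffold) if scaffold else None
    return StructureReport(spacer=spacer_rep, full=full_rep)
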