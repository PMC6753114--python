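"""Position-dependent and position-independent nucleotide indicator features.

Naming convention: ``G_20`` is a G at position 20 (the base immediately
adjacent to the PAM); ``GG_19`` is a GG dimer starting at position 19.
Positions are 1-based, 5'→3' along the spacer. Dimer counts are overlapping.
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)


def indicator_feature_names() -> list[str]:
    names: list[str] = []
    for pos in range(1, 21):
        for nt in NUCLEOTIDES:
            names.append(f"{nt}_{pos}")
    for pos in range(1, 20):
        for di in DINUCLEOTIDES:
            names.append(f"{di}_{pos}")
    names += [f"n_{nt}" for nt in NUCLEOTIDES]
    names += [f"n_{di}" for di in DINUCLEOTIDES]
    names += ["longest_homopolymer"]
    return names


_NAMES = indicator_feature_names()


def longest_homopolymer_run(spacer: str) -> int:
    best = run = 1
    for a, b in zip(spacer, spacer[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def indicator_features(spacer: str) -> tuple[np.ndarray, list[str]]:
    """Indicator/count features of one spacer.

    Returns 80 position-dependent mononucleotide indicators, 304 overlapping
    dinucleotide indicators, 4 + 16 composition counts (``n_TT`` is the
    overlapping TT-dimer count) and the longest homopolymer run length.
    """
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise ValueError("spacer must be 20 nt over ACGT")
    values = np.zeros(len(_NAMES))
    idx = {name: i for i, name in enumerate(_NAMES)}
    for pos, nt in enumerate(spacer, start=1):
        values[idx[f"{nt}_{pos}"]] = 1.0
        values[idx[f"n_{nt}"]] += 1.0
    for pos in range(1, 20):
        di = spacer[pos - 1 : pos + 1]
        values[idx[f"{di}_{pos}"]] = 1.0
        values[idx[f"n_{di}"]] += 1.0
    values[idx["longest_homopolymer"]] = longest_homopolymer_run(spacer)
    return values, list(_NAMES)
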