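"""Candidate guide enumeration and library-design filters.

Guides are N20 protospacers followed by an NGG PAM, enumerated on both strands.
The library filters keep guides that (1) start with A or G (so either a human
or mouse U6 promoter can transcribe them without a 5' mismatch) and (2) carry
no TTTT run (an RNA-polymerase-III terminator motif) in the spacer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .sequences import reverse_complement

__all__ = ["CandidateGuide", "enumerate_guides", "filter_and_select"]


@dataclass(frozen=True)
class CandidateGuide:
    """A 20-nt spacer + NGG PAM located on one strand of an input sequence.

    ``start`` is the 0-based offset of the spacer's 5'-most base *on the +
    strand of the input* (for − strand guides this is the offset of the base
    pairing with the spacer's 3' end).
    """

    spacer: str
    pam: str
    strand: str
    start: int

    def __post_init__(self) -> None:
        if self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not end in GG")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def enumerate_guides(sequence: str) -> list[CandidateGuide]:
    """All N20-NGG sites on both strands, sorted by start then strand.

    On the − strand a site appears wherever the reverse complement carries
    spacer+NGG; its ``start`` is reported in + strand coordinates.
    """
    if len(sequence) < 23:
        raise ValueError("input sequence shorter than 23 nt")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in input: {sorted(bad)}")
    n = len(sequence)
    out: list[CandidateGuide] = []
    for i in range(n - 22):
        # + strand: spacer at [i, i+20), PAM at [i+20, i+23)
        pam = sequence[i + 20 : i + 23]
        if pam[1:] == "GG":
            out.append(CandidateGuide(sequence[i : i + 20], pam, "+", i))
        # − strand: the site occupies [i, i+23) on the + strand with the PAM
        # at its left edge (CCN on the + strand).
        if sequence[i : i + 2] == "CC":
            rc = reverse_complement(sequence[i : i + 23])
            out.append(CandidateGuide(rc[:20], rc[20:], "-", i + 3))
    out.sort(key=lambda g: (g.start, g.strand))
    return out


def filter_and_select(
    candidates: Sequence[CandidateGuide],
    max_per_feature: int = 4,
    rank_key: Callable[[CandidateGuide], float] | None = None,
) -> list[CandidateGuide]:
    """Apply the A/G-start and no-TTTT library rules, then keep the best few.

    ``rank_key`` scores candidates (higher is better); without one, input
    order is the ranking. The TTTT scan covers the spacer only.
    """
    passing = [
        g
        for g in candidates
        if g.spacer[0] in "AG" and "TTTT" not in g.spacer
    ]
    if rank_key is not None:
        passing.sort(key=rank_key, reverse=True)
    return passing[:max_per_feature]
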