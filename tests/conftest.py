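import numpy as np
import pytest

from guidehf import GuideRecord, LibraryManifest


def make_context(spacer: str, rng: np.random.Generator | None = None) -> str:
    """spacer + AGG PAM with fixed 4-nt flanks."""
    return "TTAC" + spacer + "AGG" + "CATG"


@pytest.fixture
def tiny_manifest() -> LibraryManifest:
    spacers = [
        "ACGTACGTACGTACGTACGT",
        "GGGGCCCCAAAATTTTACGT",
        "ATGCATGCATGCATGCATGC",
    ]
    records = [
        GuideRecord(f"g{i}", f"gene{i}", s, make_context(s), "synthetic")
        for i, s in enumerate(spacers)
    ]
    return LibraryManifest(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_spacer(rng: np.random.Generator, ag_start: bool = False) -> str:
    first = rng.choice(list("AG")) if ag_start else rng.choice(list("ACGT"))
    return str(first) + "".join(rng.choice(list("ACGT"), size=19))
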