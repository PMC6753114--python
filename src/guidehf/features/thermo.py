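"""GC content and nearest-neighbor melting temperatures.

Melting temperatures come from the unified nearest-neighbor thermodynamic
parameter set as implemented by Biopython's ``MeltingTemp.Tm_NN``, evaluated
at fixed, documented conditions: 50 mM Na+, 250 nM strand concentration
(25 nM complement), sodium correction applied to the entropy term. Segment
temperatures cover the PAM-distal (1-5), middle (6-13) and PAM-proximal
(14-20) spacer regions.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

#: Fixed solution conditions for every Tm in the package.
TM_CONDITIONS = {"Na": 50.0, "dnac1": 250.0, "dnac2": 25.0, "saltcorr": 5}

#: Spacer segments (1-based, inclusive) for regional melting temperatures.
TM_SEGMENTS = {"tm_distal": (1, 5), "tm_middle": (6, 13), "tm_proximal": (14, 20)}


@lru_cache(maxsize=200_000)
def melting_temperature(seq: str) -> float:
    """Duplex Tm (deg C) of ``seq`` against its perfect DNA complement."""
    return float(_mt.Tm_NN(seq, **TM_CONDITIONS))


def thermo_features(spacer: str) -> tuple[np.ndarray, list[str]]:
    """GC count/fraction plus global and segment melting temperatures."""
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise ValueError("spacer must be 20 nt over ACGT")
    gc = sum(spacer.count(b) for b in "GC")
    names = ["gc_count", "gc_fraction", "tm_global"]
    values = [float(gc), gc / 20.0, melting_temperature(spacer)]
    for name, (lo, hi) in TM_SEGMENTS.items():
        names.append(name)
        values.append(melting_temperature(spacer[lo - 1 : hi]))
    return np.asarray(values), names
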