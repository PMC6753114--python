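"""Feature registry: named, ordered assembly of hand-crafted guide features.

``assemble_biofeatures`` produces the deterministic p-dimensional vector
h_bio consumed by the fusion model; ``feature_table`` produces the wide
indicator + biophysical table consumed by the conventional regressors. The
registry is a tuple of group names so the composition (and hence p) is fixed
by configuration, recorded alongside any trained model.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ..sequences import SGRNA_SCAFFOLD, GuideRecord
from .fold import fold_structure
from .indicators import indicator_features
from .thermo import thermo_features


class ConfigError(ValueError):
    """Unknown or inconsistent feature-registry configuration."""


@dataclass(frozen=True)
class BiofeatureVector:
    """Named real-valued feature vector of fixed dimension p."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ConfigError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ConfigError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("biofeatures must be finite")

    @property
    def p(self) -> int:
        return len(self.values)


def _group_gc(spacer: str, scaffold: str, backend: str):
    vals, names = thermo_features(spacer)
    return vals[:2], names[:2]


def _group_tm(spacer: str, scaffold: str, backend: str):
    vals, names = thermo_features(spacer)
    return vals[2:], names[2:]


def _group_self_fold(spacer: str, scaffold: str, backend: str):
    rep = fold_structure(spacer, scaffold=None, backend=backend).spacer
    return np.array([rep.score, float(rep.stem_loops)]), [
        "self_fold_score",
        "self_fold_stem_loops",
    ]


def _group_scaffold_fold(spacer: str, scaffold: str, backend: str):
    rep = fold_structure(spacer, scaffold=scaffold, backend=backend)
    assert rep.full is not None
    acc = rep.spacer_accessibility
    values = np.concatenate(
        [[rep.full.score, float(rep.full.stem_loops)], acc]
    )
    names = ["full_fold_score", "full_fold_stem_loops"] + [
        f"accessibility_{i}" for i in range(1, 21)
    ]
    return values, names


_GROUPS = {
    "gc": _group_gc,
    "tm": _group_tm,
    "self_fold": _group_self_fold,
    "scaffold_fold": _group_scaffold_fold,
}

#: Default fusion-model registry: GC content, thermodynamics, self-folding and
#: per-position accessibility within the full-length guide (p = 30).
DEFAULT_REGISTRY = ("gc", "tm", "self_fold", "scaffold_fold")
#: Sequence-local registry without the full-length fold (p = 8); cheaper when
#: features must be recomputed for many hybrid sequences.
MINIMAL_REGISTRY = ("gc", "tm", "self_fold")


def assemble_biofeatures(
    guide: GuideRecord | str,
    registry: Sequence[str] = DEFAULT_REGISTRY,
    scaffold: str = SGRNA_SCAFFOLD,
    backend: str = "internal",
) -> BiofeatureVector:
    """Assemble the ordered h_bio vector for one guide."""
    spacer = guide.spacer if isinstance(guide, GuideRecord) else guide
    values: list[np.ndarray] = []
    names: list[str] = []
    for entry in registry:
        try:
            fn = _GROUPS[entry]
        except KeyError:
            raise ConfigError(
                f"unknown registry entry {entry!r}; known: {sorted(_GROUPS)}"
            ) from None
        v, n = fn(spacer, scaffold, backend)
        values.append(np.asarray(v, dtype=float))
        names.extend(n)
    return BiofeatureVector(np.concatenate(values), tuple(names))


def registry_dimension(registry: Sequence[str] = DEFAULT_REGISTRY) -> int:
    """Dimension p of the vector the registry produces."""
    return assemble_biofeatures("A" * 20, registry=registry).p


def registry_hash(registry: Sequence[str] = DEFAULT_REGISTRY) -> str:
    """Stable fingerprint of the registry composition, stored with models."""
    names = assemble_biofeatures("A" * 20, registry=registry).names
    payload = "|".join(list(registry) + list(names))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def biofeature_matrix(
    spacers: Sequence[str],
    registry: Sequence[str] = DEFAULT_REGISTRY,
    scaffold: str = SGRNA_SCAFFOLD,
    backend: str = "internal",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack h_bio over many spacers into an (n, p) matrix."""
    first = assemble_biofeatures(spacers[0], registry, scaffold, backend)
    out = np.empty((len(spacers), first.p))
    out[0] = first.values
    for i, s in enumerate(spacers[1:], start=1):
        out[i] = assemble_biofeatures(s, registry, scaffold, backend).values
    return out, first.names


def feature_table(
    spacers: Sequence[str],
    include_structure: bool = True,
    scaffold: str = SGRNA_SCAFFOLD,
    backend: str = "internal",
) -> pd.DataFrame:
    """Wide per-guide feature table for the conventional regressors.

    Position indicator features (e.g. ``G_20``, ``GG_19``), composition
    counts, thermodynamics and (optionally) secondary-structure features.
    """
    rows = []
    for s in spacers:
        iv, inames = indicator_features(s)
        tv, tnames = thermo_features(s)
        values = [iv, tv]
        names = inames + tnames
        if include_structure:
            sv, snames = _group_self_fold(s, scaffold, backend)
            fv, fnames = _group_scaffold_fold(s, scaffold, backend)
            values += [sv, fv]
            names += snames + fnames
        rows.append(np.concatenate(values))
    return pd.DataFrame(np.vstack(rows), columns=names, index=list(spacers))


def select_top_features(
    importance: Mapping[str, float], fraction: float = 0.7
) -> list[str]:
    """Keep the ceil(fraction*k) features with largest mean |SHAP|.

    Ties at the cut are broken by lexicographic name so the selection is
    deterministic regardless of input order.
    """
    if not importance:
        raise ValueError("importance mapping is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(importance))
    ranked = sorted(importance.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [name for name, _ in ranked[:k]]
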