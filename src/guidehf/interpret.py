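"""Model interpretation: Shapley attributions and contribution analyses.

Attribution backends
--------------------
``exact_linear``
    Closed form for linear models: phi_i = w_i (x_i - E[x_i]) under a
    feature-independent background.
``tree``
    Exact Tree SHAP through xgboost's native ``pred_contribs``.
``sampling``
    Model-agnostic permutation-sampling Shapley values. Each permutation
    walks from a background row to the explained row one feature at a time;
    marginal changes telescope, so attributions sum exactly to
    prediction - base even at small sample budgets, and converge to the
    Shapley values as the number of permutations grows.

For sequence models the features are the 20 spacer positions: hybrid spacers
are built position by position and the model (including any derived
biofeatures) is re-evaluated, so attributions flow through everything the
sequence touches.

Downstream analyses: per-(position, nucleotide) mean attribution profiles
standardized to Z-scores over all 80 cells (|Z| > 1 called significant),
between-nuclease Z contrasts (|dZ| > 1), repetitive 4-mer contributions, and
top-vs-bottom-quartile log-odds nucleotide composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import IndelTable

NUCLEOTIDES = "ACGT"

__all__ = [
    "AttributionMatrix",
    "PositionProfile",
    "attribute",
    "attribute_positions",
    "position_profile",
    "variant_contrast",
    "homopolymer_contribution",
    "log_odds_composition",
]


@dataclass(frozen=True)
class AttributionMatrix:
    """Per-sample, per-feature attributions plus the background base value."""

    values: np.ndarray  # (n, d)
    base: float
    feature_names: tuple[str, ...]
    predictions: np.ndarray  # (n,)

    def local_accuracy_error(self) -> np.ndarray:
        """|base + sum(attributions) - prediction| per sample."""
        return np.abs(self.base + self.values.sum(axis=1) - self.predictions)

    def mean_abs(self) -> dict[str, float]:
        return dict(zip(self.feature_names, np.abs(self.values).mean(axis=0)))


def _predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model) and not hasattr(model, "predict"):
        return model
    est = getattr(model, "estimator", model)
    if hasattr(est, "predict"):
        return lambda X: np.asarray(est.predict(X), dtype=float)
    raise TypeError(f"cannot derive a predict function from {model!r}")


def _linear_weights(model) -> tuple[np.ndarray, float]:
    from sklearn.pipeline import Pipeline

    est = getattr(model, "estimator", model)
    if isinstance(est, Pipeline):
        scaler = est.named_steps.get("standardscaler")
        lin = est.steps[-1][1]
        w = np.asarray(lin.coef_, dtype=float)
        b = float(lin.intercept_)
        if scaler is not None:
            w = w / scaler.scale_
            b = b - float(np.dot(w, scaler.mean_))
        return w, b
    if hasattr(est, "coef_"):
        return np.asarray(est.coef_, float), float(est.intercept_)
    raise TypeError("exact_linear explainer requires a (pipeline of a) linear model")


def attribute(
    model,
    X: np.ndarray,
    background: np.ndarray,
    explainer: str = "sampling",
    feature_names: Sequence[str] | None = None,
    n_permutations: int = 20,
    seed: int = 0,
) -> AttributionMatrix:
    """Shapley attributions of tabular inputs ``X`` against ``background``."""
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    d = X.shape[1]
    names = tuple(feature_names) if feature_names else tuple(f"f{i}" for i in range(d))
    if explainer == "exact_linear":
        w, b = _linear_weights(model)
        mu = background.mean(axis=0)
        values = (X - mu) * w
        base = float(w @ mu + b)
        preds = X @ w + b
        return AttributionMatrix(values, base, names, preds)
    if explainer == "tree":
        import xgboost as xgb

        est = getattr(model, "estimator", model)
        booster = est.get_booster() if hasattr(est, "get_booster") else est
        if not isinstance(booster, xgb.Booster):
            raise TypeError("tree explainer requires an xgboost model")
        contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        values, base_col = contribs[:, :-1], contribs[:, -1]
        preds = booster.predict(xgb.DMatrix(X))
        return AttributionMatrix(values, float(base_col[0]), names, preds)
    if explainer == "sampling":
        f = _predict_fn(model)
        return _sampling_attribute(f, X, background, names, n_permutations, seed)
    raise ValueError(f"unknown explainer {explainer!r}")


def _antithetic_plan(
    rng: np.random.Generator, d: int, n: int, nb: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Permutations in antithetic (forward, reversed) pairs, each pair bound
    to one background row.

    Averaging a permutation with its reverse against the same background
    cancels the sampling error that pairwise feature interactions induce,
    which sharply reduces the budget needed for a given accuracy.
    """
    perms: list[np.ndarray] = []
    bg_idx: list[int] = []
    pair = 0
    while len(perms) < n:
        p = rng.permutation(d)
        perms.append(p)
        bg_idx.append(pair % nb)
        if len(perms) < n:
            perms.append(p[::-1].copy())
            bg_idx.append(pair % nb)
        pair += 1
    return perms, np.asarray(bg_idx)


def _sampling_attribute(
    f: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    names: tuple[str, ...],
    n_permutations: int,
    seed: int,
) -> AttributionMatrix:
    rng = np.random.default_rng(seed)
    n, d = X.shape
    nb = len(background)
    perms, bg_idx = _antithetic_plan(rng, d, n_permutations, nb)
    bg_rows = background[bg_idx]
    base = float(f(bg_rows).mean())
    values = np.zeros((n, d))
    for i in range(n):
        # all intermediate hybrids for all permutations, evaluated in one call
        hybrids = np.empty((n_permutations, d + 1, d))
        for p, perm in enumerate(perms):
            row = bg_rows[p].copy()
            hybrids[p, 0] = row
            for k, j in enumerate(perm, start=1):
                row[j] = X[i, j]
                hybrids[p, k] = row
        fx = f(hybrids.reshape(-1, d)).reshape(n_permutations, d + 1)
        deltas = np.diff(fx, axis=1)  # (n_permutations, d)
        for p, perm in enumerate(perms):
            values[i, perm] += deltas[p]
    values /= n_permutations
    preds = f(X)
    return AttributionMatrix(values, base, names, preds)


def attribute_positions(
    model,
    spacers: Sequence[str],
    background_spacers: Sequence[str],
    n_permutations: int = 16,
    seed: int = 0,
) -> AttributionMatrix:
    """Sampling-Shapley attribution of the 20 spacer positions.

    ``model`` must predict from spacer strings (an ActivityResults or any
    callable mapping a list of spacers to scores). Hybrid sequences are fully
    re-featurized at each step, so derived biofeatures are attributed back to
    the positions that change them.
    """
    if callable(model) and not hasattr(model, "predict"):
        f = model
    else:
        f = model.predict
    rng = np.random.default_rng(seed)
    d = 20
    spacers = list(spacers)
    bgs = list(background_spacers)
    perms, bg_idx = _antithetic_plan(rng, d, n_permutations, len(bgs))
    bg_rows = [bgs[i] for i in bg_idx]
    base = float(np.mean(f(bg_rows)))
    values = np.zeros((len(spacers), d))
    for i, x in enumerate(spacers):
        hybrids: list[str] = []
        for p, perm in enumerate(perms):
            row = list(bg_rows[p])
            hybrids.append("".join(row))
            for j in perm:
                row[j] = x[j]
                hybrids.append("".join(row))
        fx = np.asarray(f(hybrids), dtype=float).reshape(n_permutations, d + 1)
        deltas = np.diff(fx, axis=1)
        for p, perm in enumerate(perms):
            values[i, perm] += deltas[p]
    values /= n_permutations
    preds = np.asarray(f(spacers), dtype=float)
    names = tuple(f"pos_{i}" for i in range(1, 21))
    return AttributionMatrix(values, base, names, preds)


@dataclass(frozen=True)
class PositionProfile:
    """Mean attribution, Z-score and significance per (position, nucleotide).

    All matrices are 20 x 4 over positions 1..20 (rows) and A/C/G/T
    (columns). Cells with no carrier guide are flagged missing and excluded
    from standardization. ``degenerate`` marks an all-equal profile whose
    Z-scores are undefined.
    """

    mean: np.ndarray
    z: np.ndarray
    significant: np.ndarray
    missing: np.ndarray
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(20):
            for k, nt in enumerate(NUCLEOTIDES):
                rows.append(
                    (
                        pos + 1,
                        nt,
                        self.mean[pos, k],
                        self.z[pos, k],
                        bool(self.significant[pos, k]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["position", "nucleotide", "mean_shap", "z", "significant"]
        )

    def cell(self, nt: str, position: int) -> tuple[float, float, bool]:
        k = NUCLEOTIDES.index(nt)
        return (
            float(self.mean[position - 1, k]),
            float(self.z[position - 1, k]),
            bool(self.significant[position - 1, k]),
        )


def position_profile(
    attributions: AttributionMatrix, spacers: Sequence[str]
) -> PositionProfile:
    """Average positional attributions over carriers of each nucleotide, then
    Z-standardize jointly over all 80 cells."""
    values = attributions.values
    if values.shape[1] != 20:
        raise ValueError("position_profile expects attributions over 20 positions")
    spacers = list(spacers)
    if len(spacers) != values.shape[0]:
        raise ValueError("spacers and attributions differ in length")
    total = np.zeros((20, 4))
    count = np.zeros((20, 4))
    for s, row in zip(spacers, values):
        for pos, nt in enumerate(s):
            k = NUCLEOTIDES.index(nt)
            total[pos, k] += row[pos]
            count[pos, k] += 1
    missing = count == 0
    mean = np.where(missing, np.nan, total / np.where(missing, 1, count))
    cells = mean[~missing]
    sd = cells.std()
    if sd == 0:
        z = np.full_like(mean, np.nan)
        return PositionProfile(mean, z, np.zeros_like(missing), missing, degenerate=True)
    z = (mean - cells.mean()) / sd
    significant = np.abs(z) > 1.0
    significant &= ~missing
    return PositionProfile(mean, z, significant, missing)


def variant_contrast(
    profile_variant: PositionProfile, profile_wt: PositionProfile
) -> tuple[np.ndarray, np.ndarray]:
    """dZ = z_variant - z_wt with |dZ| > 1 called a significant change."""
    if profile_variant.z.shape != profile_wt.z.shape:
        raise ValueError("profiles have mismatched shapes")
    dz = profile_variant.z - profile_wt.z
    significant = np.abs(dz) > 1.0
    significant &= ~np.isnan(dz)
    return dz, significant


def homopolymer_contribution(
    attributions: AttributionMatrix,
    spacers: Sequence[str],
    motif: str,
    positions: str = "spacer",
) -> dict[int, float]:
    """Mean summed attribution of a repetitive 4-mer per start position.

    Start positions run 1..17 on the 20-nt spacer (``positions='spacer'``) or
    are labelled 2..18 in the coordinates of the START-prefixed length-21
    encoded input (``positions='encoded'``). Starts with no carrier guide map
    to NaN.
    """
    if motif not in {"AAAA", "CCCC", "GGGG", "TTTT"}:
        raise ValueError("motif must be a homopolymer 4-mer")
    spacers = list(spacers)
    values = attributions.values
    offset = 1 if positions == "encoded" else 0
    out: dict[int, float] = {}
    for start in range(17):  # 0-based start on the spacer
        sums = [
            row[start : start + 4].sum()
            for s, row in zip(spacers, values)
            if s[start : start + 4] == motif
        ]
        out[start + 1 + offset] = float(np.mean(sums)) if sums else float("nan")
    return out


def log_odds_composition(
    activities: "IndelTable | Sequence[float]",
    spacers: Sequence[str],
    quantile: float = 0.25,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Log-odds of nucleotide frequency, top vs bottom activity quantile.

    For each (position, nucleotide), with carrier counts c and group sizes N:

        LO = ln((c_top + q) / (N_top + 4q)) - ln((c_bot + q) / (N_bot + 4q))

    with Laplace pseudocount q = 0.5 by default. Invariant to any strictly
    monotone transform of the activities; swapping the groups negates it.
    """
    if isinstance(activities, IndelTable):
        series = activities.frequencies(valid_only=False)
        acts = series.to_numpy()
    else:
        acts = np.asarray(activities, dtype=float)
    spacers = list(spacers)
    if len(acts) != len(spacers):
        raise ValueError("activities and spacers differ in length")
    if len(spacers) < 8:
        raise ValueError("need at least 8 guides")
    if not 0.0 < quantile <= 0.5:
        raise ValueError("quantile must be in (0, 0.5]")
    order = np.argsort(acts, kind="stable")
    n_q = max(1, int(np.floor(quantile * len(spacers))))
    bottom = [spacers[i] for i in order[:n_q]]
    top = [spacers[i] for i in order[-n_q:]]

    def _counts(group: list[str]) -> np.ndarray:
        c = np.zeros((20, 4))
        for s in group:
            for pos, nt in enumerate(s):
                c[pos, NUCLEOTIDES.index(nt)] += 1
        return c

    q = pseudocount
    lt = np.log((_counts(top) + q) / (n_q + 4 * q))
    lb = np.log((_counts(bottom) + q) / (n_q + 4 * q))
    lo = lt - lb
    return pd.DataFrame(lo, index=range(1, 21), columns=list(NUCLEOTIDES))
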