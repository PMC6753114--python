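"""Guide-activity regression models.

The central objects follow the Model/Results convention of statistical
modelling packages: :class:`GuideActivityModel` is built from spacers and
measured activities, its :meth:`~GuideActivityModel.fit` returns an
:class:`ActivityResults` carrying the fitted estimator, the data split, the
train/validation/test evaluation reports and a ``summary()`` table. The
module-level functions (``train_model``, ``evaluate_model``, ``fine_tune``,
``hyperparameter_search``, ``kfold_validation``) are thin wrappers over those
objects.

Model kinds
-----------
``linear``/``ridge``/``gbt``/``mlp`` regress on the wide indicator +
biophysical feature table (fitted on training+validation, 85% of the data);
``cnn``/``rnn``/``rnn_biofeature`` are the neural kinds trained on the
encoded sequence (plus the p-dimensional biofeature vector for the fusion
kind) with early stopping on validation Spearman.

The data split is 76.5% / 8.5% / 15% via seeded shuffle with
floor/floor/remainder sizes, which reproduces the screen's printed
42,537/4,726/8,341 partition of 55,604 guides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .features.encoding import encode_batch
from .features.registry import (
    DEFAULT_REGISTRY,
    biofeature_matrix,
    feature_table,
    registry_hash,
)
from .nn import FusionNetwork, NetConfig, train_network

__all__ = [
    "DataSplit",
    "EvalReport",
    "GuideActivityModel",
    "ActivityResults",
    "split_dataset",
    "train_model",
    "evaluate_model",
    "fine_tune",
    "hyperparameter_search",
    "kfold_validation",
]

TRAIN_FRAC, VAL_FRAC = 0.765, 0.085
MODEL_KINDS = ("linear", "ridge", "gbt", "mlp", "cnn", "rnn", "rnn_biofeature")
NEURAL_KINDS = ("cnn", "rnn", "rnn_biofeature")


@dataclass(frozen=True)
class DataSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.train) + len(self.validation) + len(self.test)
        union = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(union)) != n:
            raise ValueError("split indices must be disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


def split_dataset(n_items: int, seed: int = 0) -> DataSplit:
    """Seeded shuffle, then 76.5/8.5/15 partition (floor/floor/remainder)."""
    if n_items < 3:
        raise ValueError("need at least 3 items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    n_train = math.floor(TRAIN_FRAC * n_items)
    n_val = math.floor(VAL_FRAC * n_items)
    return DataSplit(
        train=order[:n_train],
        validation=order[n_train : n_train + n_val],
        test=order[n_train + n_val :],
    )


@dataclass(frozen=True)
class EvalReport:
    """Spearman + MSE on one index set. ``spearman`` is NaN with
    ``spearman_undefined`` set when predictions are constant."""

    spearman: float
    mse: float
    n: int
    spearman_undefined: bool = False

    def __str__(self) -> str:
        rho = "undefined" if self.spearman_undefined else f"{self.spearman:.4f}"
        return f"spearman={rho} mse={self.mse:.5f} n={self.n}"


def _evaluate(pred: np.ndarray, truth: np.ndarray) -> EvalReport:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    mse = float(np.mean((pred - truth) ** 2))
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        return EvalReport(float("nan"), mse, len(pred), spearman_undefined=True)
    rho = float(stats.spearmanr(pred, truth).statistic)
    return EvalReport(rho, mse, len(pred))


class GuideActivityModel:
    """Activity regression model over (spacer, activity in [0,1]) pairs."""

    def __init__(
        self,
        spacers: Sequence[str],
        activities: Sequence[float],
        kind: str = "rnn_biofeature",
        config: NetConfig | None = None,
        registry: Sequence[str] = DEFAULT_REGISTRY,
        feature_columns: Sequence[str] | None = None,
        sk_params: Mapping | None = None,
    ):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}; known: {MODEL_KINDS}")
        self.spacers = list(spacers)
        self.activities = np.asarray(activities, dtype=float)
        if len(self.spacers) != len(self.activities):
            raise ValueError("spacers and activities differ in length")
        if np.any((self.activities < 0) | (self.activities > 1)):
            raise ValueError("activities must lie in [0, 1]")
        self.kind = kind
        self.config = (config or NetConfig()).with_kind(kind) if kind in NEURAL_KINDS else config
        self.registry = tuple(registry)
        self.feature_columns = list(feature_columns) if feature_columns else None
        self.sk_params = dict(sk_params or {})
        self._cache: dict[str, object] = {}

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        kind: str = "rnn_biofeature",
        spacer_col: str = "spacer",
        activity_col: str = "indel_frequency",
        **kwargs,
    ) -> "GuideActivityModel":
        return cls(frame[spacer_col].tolist(), frame[activity_col].to_numpy(), kind, **kwargs)

    # -- featurization ---------------------------------------------------
    def _onehot(self) -> np.ndarray:
        if "onehot" not in self._cache:
            self._cache["onehot"] = encode_batch(self.spacers)
        return self._cache["onehot"]  # type: ignore[return-value]

    def _bio(self) -> np.ndarray:
        if "bio" not in self._cache:
            self._cache["bio"], self._cache["bio_names"] = biofeature_matrix(
                self.spacers, registry=self.registry
            )
        return self._cache["bio"]  # type: ignore[return-value]

    def _table(self) -> pd.DataFrame:
        if "table" not in self._cache:
            tab = feature_table(self.spacers)
            if self.feature_columns is not None:
                tab = tab[list(self.feature_columns)]
            self._cache["table"] = tab
        return self._cache["table"]  # type: ignore[return-value]

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int = 0, split: DataSplit | None = None, **train_kwargs) -> "ActivityResults":
        split = split or split_dataset(len(self.spacers), seed=seed)
        if self.kind in NEURAL_KINDS:
            return self._fit_neural(seed, split, **train_kwargs)
        return self._fit_conventional(seed, split)

    def _fit_conventional(self, seed: int, split: DataSplit) -> "ActivityResults":
        from sklearn.linear_model import LinearRegression, Ridge
        from sklearn.neural_network import MLPRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from xgboost import XGBRegressor

        X = self._table().to_numpy()
        y = self.activities
        fit_idx = np.concatenate([split.train, split.validation])
        if self.kind == "linear":
            est = make_pipeline(StandardScaler(), LinearRegression())
        elif self.kind == "ridge":
            est = make_pipeline(
                StandardScaler(), Ridge(alpha=self.sk_params.get("alpha", 1.0))
            )
        elif self.kind == "mlp":
            est = make_pipeline(
                StandardScaler(),
                MLPRegressor(
                    hidden_layer_sizes=self.sk_params.get("hidden_layer_sizes", (64,)),
                    max_iter=self.sk_params.get("max_iter", 400),
                    random_state=seed,
                ),
            )
        else:  # gbt
            est = XGBRegressor(
                n_estimators=self.sk_params.get("n_estimators", 200),
                max_depth=self.sk_params.get("max_depth", 5),
                learning_rate=self.sk_params.get("learning_rate", 0.1),
                random_state=seed,
                n_jobs=1,
            )
        est.fit(X[fit_idx], y[fit_idx])
        reports = {
            name: _evaluate(est.predict(X[idx]), y[idx])
            for name, idx in (
                ("train", fit_idx),
                ("validation", split.validation),
                ("test", split.test),
            )
        }
        return ActivityResults(self, split, estimator=est, reports=reports, seed=seed)

    def _fit_neural(self, seed: int, split: DataSplit, **train_kwargs) -> "ActivityResults":
        X = self._onehot()
        y = self.activities
        bio = None
        bio_stats = None
        if self.kind == "rnn_biofeature":
            bio_raw = self._bio()
            if self.config.bio_standardize:
                mu = bio_raw[split.train].mean(axis=0)
                sd = bio_raw[split.train].std(axis=0)
                sd[sd == 0] = 1.0
                bio_stats = (mu, sd)
                bio = (bio_raw - mu) / sd
            else:
                bio = bio_raw
        net = FusionNetwork(self.config, p=0 if bio is None else bio.shape[1], seed=seed)
        history = train_network(
            net, X, bio, y, split.train, split.validation, seed=seed, **train_kwargs
        )
        reports = {}
        for name, idx in (
            ("train", split.train),
            ("validation", split.validation),
            ("test", split.test),
        ):
            if len(idx) == 0:
                continue
            pred = net.predict(X[idx], None if bio is None else bio[idx])
            reports[name] = _evaluate(pred, y[idx])
        return ActivityResults(
            self, split, estimator=net, reports=reports, seed=seed,
            history=history, bio_stats=bio_stats,
        )


@dataclass
class ActivityResults:
    """Fit artifacts: estimator, split, evaluation reports, provenance."""

    model: GuideActivityModel
    split: DataSplit
    estimator: object
    reports: dict[str, EvalReport]
    seed: int
    history: dict | None = None
    bio_stats: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def kind(self) -> str:
        return self.model.kind

    @property
    def registry_fingerprint(self) -> str:
        return registry_hash(self.model.registry)

    # -- prediction -------------------------------------------------------
    def predict(self, spacers: Sequence[str]) -> np.ndarray:
        spacers = list(spacers)
        if self.kind in NEURAL_KINDS:
            X = encode_batch(spacers)
            bio = None
            if self.kind == "rnn_biofeature":
                bio, _ = biofeature_matrix(spacers, registry=self.model.registry)
                if self.bio_stats is not None:
                    mu, sd = self.bio_stats
                    bio = (bio - mu) / sd
            return self.estimator.predict(X, bio)
        tab = feature_table(spacers)
        if self.model.feature_columns is not None:
            tab = tab[list(self.model.feature_columns)]
        return np.asarray(self.estimator.predict(tab.to_numpy()), dtype=float)

    def evaluate(self, spacers: Sequence[str], activities: Sequence[float]) -> EvalReport:
        return _evaluate(self.predict(spacers), np.asarray(activities, float))

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Guide activity regression results",
            "=" * 44,
            f"kind:            {self.kind}",
            f"n observations:  {len(self.model.spacers)}",
            f"split sizes:     {self.split.sizes} (train/val/test)",
            f"seed:            {self.seed}",
            f"registry:        {','.join(self.model.registry)} "
            f"[{self.registry_fingerprint}]",
        ]
        for name in ("train", "validation", "test"):
            if name in self.reports:
                lines.append(f"{name:<12s}     {self.reports[name]}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "version": __version__,
            "kind": self.kind,
            "registry": self.model.registry,
            "registry_hash": self.registry_fingerprint,
            "seed": self.seed,
            "bio_stats": self.bio_stats,
            "reports": self.reports,
        }
        if self.kind in NEURAL_KINDS:
            payload["net_config"] = self.estimator.config
            payload["net_p"] = self.estimator.p
            payload["params"] = self.estimator.copy_params()
        else:
            payload["estimator"] = self.estimator
        joblib.dump(payload, path)

    @staticmethod
    def load(path: str | Path) -> "LoadedModel":
        payload = joblib.load(path)
        current = registry_hash(payload["registry"])
        if current != payload["registry_hash"]:
            raise ValueError(
                "feature-registry fingerprint mismatch: model was trained with "
                f"{payload['registry_hash']}, this installation computes {current}; "
                "refusing to predict"
            )
        return LoadedModel(payload)


class LoadedModel:
    """A deserialized model restricted to prediction."""

    def __init__(self, payload: dict):
        self.payload = payload
        self.kind = payload["kind"]
        if self.kind in NEURAL_KINDS:
            net = FusionNetwork(payload["net_config"], p=payload["net_p"], seed=0)
            net.set_params(payload["params"])
            self.estimator = net
        else:
            self.estimator = payload["estimator"]

    def predict(self, spacers: Sequence[str]) -> np.ndarray:
        spacers = list(spacers)
        if self.kind in NEURAL_KINDS:
            X = encode_batch(spacers)
            bio = None
            if self.kind == "rnn_biofeature":
                bio, _ = biofeature_matrix(spacers, registry=self.payload["registry"])
                if self.payload["bio_stats"] is not None:
                    mu, sd = self.payload["bio_stats"]
                    bio = (bio - mu) / sd
            return self.estimator.predict(X, bio)
        return np.asarray(self.estimator.predict(feature_table(spacers).to_numpy()), float)


# -------------------------------------------------------------------------
# Functional wrappers


def train_model(
    kind: str,
    spacers: Sequence[str],
    activities: Sequence[float],
    split: DataSplit | None = None,
    config: NetConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> ActivityResults:
    model = GuideActivityModel(spacers, activities, kind=kind, config=config, **kwargs)
    return model.fit(seed=seed, split=split)


def evaluate_model(
    results: ActivityResults | LoadedModel,
    spacers: Sequence[str],
    activities: Sequence[float],
    indices: np.ndarray | None = None,
) -> EvalReport:
    spacers = list(spacers)
    activities = np.asarray(activities, float)
    if indices is not None:
        if len(indices) == 0:
            raise ValueError("indices must be nonempty")
        spacers = [spacers[i] for i in indices]
        activities = activities[indices]
    return _evaluate(results.predict(spacers), activities)


def fine_tune(
    results: ActivityResults,
    spacers: Sequence[str],
    activities: Sequence[float],
    scope: str = "last_hidden_layer",
    epochs: int = 20,
    seed: int = 0,
) -> ActivityResults:
    """Transfer learning: retrain only the parameters in ``scope`` on new
    data; everything outside the scope stays bit-identical."""
    if results.kind not in NEURAL_KINDS:
        raise TypeError(f"fine_tune is unsupported for kind {results.kind!r}")
    net: FusionNetwork = results.estimator  # type: ignore[assignment]
    new_net = FusionNetwork(net.config, p=net.p, seed=seed)
    new_net.set_params(net.copy_params())
    spacers = list(spacers)
    X = encode_batch(spacers)
    bio = None
    if results.kind == "rnn_biofeature":
        bio, _ = biofeature_matrix(spacers, registry=results.model.registry)
        if results.bio_stats is not None:
            mu, sd = results.bio_stats
            bio = (bio - mu) / sd
    y = np.asarray(activities, float)
    split = split_dataset(len(spacers), seed=seed) if len(spacers) >= 3 else None
    train_idx = split.train if split else np.arange(len(spacers))
    val_idx = split.validation if split else np.array([], dtype=int)
    history = None
    if epochs > 0:
        history = train_network(
            new_net, X, bio, y, train_idx, val_idx, seed=seed, scope=scope,
            max_epochs=epochs,
        )
    reports = {"train": _evaluate(new_net.predict(X, bio), y)}
    return ActivityResults(
        results.model, results.split, estimator=new_net, reports=reports,
        seed=seed, history=history, bio_stats=results.bio_stats,
    )


def _sample_config(space: Mapping[str, Sequence], rng: np.random.Generator) -> dict:
    return {k: v[rng.integers(0, len(v))] for k, v in space.items()}


def hyperparameter_search(
    kind: str,
    spacers: Sequence[str],
    activities: Sequence[float],
    space: Mapping[str, Sequence],
    budget: tuple[int, int] = (30, 300),
    strategy: str = "random",
    seed: int = 0,
    config_base: NetConfig | None = None,
    train_kwargs: Mapping | None = None,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Search ``space`` (name -> candidate values) for the config with the
    best validation Spearman; returns (best config, full trace).

    ``random`` draws independently; ``bayesian`` seeds with ``n_init`` random
    points then picks acquisitions by expected improvement under a Gaussian
    process over the numeric encoding of the space.
    """
    n_init, n_iter = budget
    if n_init + n_iter <= 0:
        raise ValueError("search budget must be positive")
    if not space:
        raise ValueError("search space is empty")
    rng = np.random.default_rng(seed)
    split = split_dataset(len(spacers), seed=seed)
    base = config_base or NetConfig()
    train_kwargs = dict(train_kwargs or {})

    def _score(cfg_update: dict) -> float:
        if kind in NEURAL_KINDS:
            cfg = replace(base, **cfg_update).with_kind(kind)
            res = train_model(kind, spacers, activities, split=split, config=cfg,
                              seed=seed, **train_kwargs)
        else:
            res = train_model(kind, spacers, activities, split=split, seed=seed,
                              sk_params=cfg_update)
        rep = res.reports.get("validation") or res.reports["train"]
        return -np.inf if rep.spearman_undefined else rep.spearman

    keys = sorted(space)
    trace: list[tuple[dict, float]] = []
    for _ in range(n_init):
        cand = _sample_config(space, rng)
        trace.append((cand, _score(cand)))
    if strategy == "random":
        for _ in range(n_iter):
            cand = _sample_config(space, rng)
            trace.append((cand, _score(cand)))
    elif strategy == "bayesian":
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        def _encode(cfg: dict) -> list[float]:
            return [float(list(space[k]).index(cfg[k])) for k in keys]

        for _ in range(n_iter):
            Xobs = np.array([_encode(c) for c, _ in trace])
            yobs = np.array([s for _, s in trace])
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), normalize_y=True, random_state=seed
            ).fit(Xobs, yobs)
            cands = [_sample_config(space, rng) for _ in range(64)]
            mu, sd = gp.predict(np.array([_encode(c) for c in cands]), return_std=True)
            best = yobs.max()
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best) / sd
                ei = (mu - best) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
                ei[sd == 0] = 0.0
            cand = cands[int(np.argmax(ei))]
            trace.append((cand, _score(cand)))
    else:
        raise ValueError(f"unknown search strategy {strategy!r}")
    best_cfg = max(trace, key=lambda t: t[1])[0]
    return best_cfg, trace


def kfold_validation(
    kind: str,
    spacers: Sequence[str],
    activities: Sequence[float],
    k: int = 10,
    seed: int = 0,
    config: NetConfig | None = None,
    **kwargs,
) -> tuple[float, float, list[float]]:
    """k seeded reshuffles of the 76.5/8.5/15 split (shuffled validation, not
    partitioned CV); retrains per fold and reports mean and sd of the test
    Spearman together with the per-fold scores."""
    if k < 2:
        raise ValueError("k must be >= 2")
    scores = []
    for fold in range(k):
        fold_seed = seed * 1000 + fold
        split = split_dataset(len(spacers), seed=fold_seed)
        res = train_model(kind, spacers, activities, split=split, config=config,
                          seed=fold_seed, **kwargs)
        scores.append(res.reports["test"].spearman)
    arr = np.asarray(scores)
    return float(arr.mean()), float(arr.std()), scores
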