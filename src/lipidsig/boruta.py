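"""Boruta all-relevant feature selection.

Each iteration appends a permuted "shadow" copy of every active feature,
fits a forest on the augmented matrix, and scores a *hit* for every real
feature whose importance strictly exceeds the maximum shadow importance.
Accumulated hits are tested against Binomial(k, 1/2) with Bonferroni
correction (factor = initial feature count): features whose hit excess is
significant are *confirmed*, features whose hit deficit is significant are
*rejected* and dropped from subsequent iterations; everything else remains
*tentative*.  Only confirmed features are selected downstream.

Three importance backends are provided:

- ``permutation_z`` (default): out-of-sample permutation-importance z-scores
  from a random forest, in the spirit of the original accuracy-decrease
  formulation;
- ``impurity``: random-forest Gini importance;
- ``impurity_fast``: a numba extremely-randomized-forest Gini importance,
  cheap enough for in-fold use inside resampling loops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from ._fast_forest import fast_forest_importance
from .errors import ConfigurationError, DataError

DECISION_CONFIRMED = "confirmed"
DECISION_TENTATIVE = "tentative"
DECISION_REJECTED = "rejected"


@dataclass(frozen=True)
class BorutaConfig:
    """Boruta settings; defaults follow the emulated protocol
    (100 iterations, 500 trees, Bonferroni-adjusted p < 0.01)."""

    n_iter: int = 100
    n_trees: int = 500
    alpha: float = 0.01
    adjust: str = "bonferroni"
    importance_kind: str = "permutation_z"
    max_features: int | str = "sqrt"
    max_depth: int | None = None
    min_samples_leaf: int = 1
    holdout_fraction: float = 0.3
    n_permutation_repeats: int = 5
    burn_in: int = 5
    early_stop: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_trees < 1:
            raise ConfigurationError("n_iter and n_trees must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.adjust != "bonferroni":
            raise ConfigurationError(f"unsupported adjustment {self.adjust!r}")
        if self.importance_kind not in ("permutation_z", "impurity", "impurity_fast"):
            raise ConfigurationError(
                f"unknown importance_kind {self.importance_kind!r}"
            )


@dataclass
class BorutaResult:
    """Per-feature decisions, hit counts and binomial tail p-values."""

    decisions: pd.Series  # confirmed / tentative / rejected
    hits: pd.Series
    n_participated: pd.Series
    p_confirm: pd.Series
    p_reject: pd.Series
    importance_history: pd.DataFrame  # iterations x features, NaN once inactive
    config: BorutaConfig

    @property
    def confirmed(self) -> list:
        return list(self.decisions.index[self.decisions == DECISION_CONFIRMED])

    @property
    def mean_importance(self) -> pd.Series:
        return self.importance_history.mean(axis=0, skipna=True)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "decisions": self.decisions.to_dict(),
                    "hits": self.hits.astype(int).to_dict(),
                    "n_participated": self.n_participated.astype(int).to_dict(),
                    "p_confirm": {k: float(v) for k, v in self.p_confirm.items()},
                    "p_reject": {k: float(v) for k, v in self.p_reject.items()},
                },
                indent=1,
                sort_keys=True,
            )
        )


def shadow_augment(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Append one independently row-permuted shadow column per feature."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 1:
        raise DataError("X must be a 2-D matrix with >= 1 feature")
    # one argsort of iid uniforms = an independent permutation per column
    order = np.argsort(rng.random(X.shape), axis=0)
    shadows = np.take_along_axis(X, order, axis=0)
    return np.hstack([X, shadows])


def _importances(M: np.ndarray, y: np.ndarray, config: BorutaConfig, seed: int) -> np.ndarray:
    """Importance of every column of the shadow-augmented matrix ``M``."""
    if config.importance_kind == "impurity_fast":
        return fast_forest_importance(
            M,
            y,
            n_trees=config.n_trees,
            max_features=config.max_features,
            max_depth=8 if config.max_depth is None else config.max_depth,
            min_samples_leaf=max(config.min_samples_leaf, 5),
            seed=seed,
        )
    rf_kwargs = dict(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        n_jobs=1,
        random_state=seed % 2**31,
    )
    if config.importance_kind == "impurity":
        rf = RandomForestClassifier(**rf_kwargs)
        rf.fit(M, y)
        return rf.feature_importances_
    # permutation z-scores on a held-out bag
    M_fit, M_hold, y_fit, y_hold = train_test_split(
        M,
        y,
        test_size=config.holdout_fraction,
        stratify=y,
        random_state=seed % 2**31,
    )
    rf = RandomForestClassifier(**rf_kwargs)
    rf.fit(M_fit, y_fit)
    perm = permutation_importance(
        rf,
        M_hold,
        y_hold,
        n_repeats=config.n_permutation_repeats,
        random_state=seed % 2**31,
        n_jobs=1,
    )
    return perm.importances_mean / (perm.importances_std + 1e-12)


def boruta_run(
    X: np.ndarray,
    y: np.ndarray,
    config: BorutaConfig = BorutaConfig(),
    feature_names=None,
) -> BorutaResult:
    """Run Boruta on a feature matrix with binary labels.

    Rejected features leave the model immediately; confirmed features stay
    in the model (keeping the forest realistic) but their hit counts are
    frozen at the deciding iteration.  Iteration stops early once no feature
    is undecided.
    """
    # the fast backend consumes float32; converting once avoids a copy per iteration
    dtype = np.float32 if config.importance_kind == "impurity_fast" else np.float64
    X = np.asarray(X, dtype=dtype)
    y = np.asarray(y)
    if X.ndim != 2:
        raise DataError("X must be 2-D")
    if np.isnan(X).any():
        raise DataError("X contains missing values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError("y must contain exactly two classes")
    y = (y == classes[1]).astype(np.int64)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    feature_names = list(feature_names)
    if len(feature_names) != p:
        raise ConfigurationError("feature_names length must equal n_features")

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 97]))
    m_bonf = p  # Bonferroni factor: initial feature count (conservative)

    active = np.ones(p, bool)      # still fed to the forest
    undecided = np.ones(p, bool)   # neither confirmed nor rejected yet
    decision = np.full(p, DECISION_TENTATIVE, dtype=object)
    hits = np.zeros(p, int)
    part = np.zeros(p, int)
    history = np.full((config.n_iter, p), np.nan)

    n_done = 0
    for it in range(config.n_iter):
        n_done = it + 1
        idx = np.flatnonzero(active)
        M = shadow_augment(X[:, idx], rng)
        imp = _importances(M, y, config, seed=int(rng.integers(2**31)))
        real_imp = imp[: len(idx)]
        shadow_max = imp[len(idx):].max()
        history[it, idx] = real_imp

        und = undecided[idx]
        hit_now = real_imp > shadow_max
        hits[idx[und]] += hit_now[und]
        part[idx[und]] += 1

        if it + 1 >= config.burn_in:
            test = idx[und]
            if len(test):
                pc = binom.sf(hits[test] - 1, part[test], 0.5)
                pr = binom.cdf(hits[test], part[test], 0.5)
                conf = test[pc * m_bonf < config.alpha]
                rej = test[pr * m_bonf < config.alpha]
                decision[conf] = DECISION_CONFIRMED
                undecided[conf] = False
                decision[rej] = DECISION_REJECTED
                undecided[rej] = False
                active[rej] = False
        if config.early_stop and not undecided.any():
            break

    index = pd.Index(feature_names, name="feature")
    p_confirm = binom.sf(hits - 1, np.maximum(part, 1), 0.5)
    p_reject = binom.cdf(hits, np.maximum(part, 1), 0.5)
    return BorutaResult(
        decisions=pd.Series(decision, index=index),
        hits=pd.Series(hits, index=index),
        n_participated=pd.Series(part, index=index),
        p_confirm=pd.Series(p_confirm, index=index),
        p_reject=pd.Series(p_reject, index=index),
        importance_history=pd.DataFrame(
            history[:n_done], columns=index,
            index=pd.RangeIndex(n_done, name="iteration"),
        ),
        config=config,
    )
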