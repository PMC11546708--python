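"""Pluggable classifier registry for the ensemble engine.

Each :class:`ClassifierSpec` bundles a name, an estimator factory and a
hyperparameter search space sampled during nested random-search tuning.
The default suite spans eight diverse families (regularized logistic
regression, shrinkage LDA, radial and polynomial SVMs, random forest,
gradient boosting, k-nearest neighbours, Gaussian naive Bayes); a
seed-averaged multilayer perceptron is registered as an opt-in ninth
member.  Every model exposes a cancer score in [0, 1]; scores >= 0.5 vote
cancer.

Profiles ("full", "ci", "smoke") scale the tree-ensemble sizes so the same
suite runs both at study scale and inside fast resampling loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError

PROFILES = ("full", "ci", "smoke")


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier family with a random-search hyperparameter space.

    ``space`` maps parameter name to a dimension:
    ``("choice", [..])``, ``("uniform", lo, hi)``, ``("loguniform", lo, hi)``
    or ``("randint", lo, hi)`` (hi inclusive).
    """

    name: str
    factory: Callable[[dict, int], object]
    space: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> dict:
        params = {}
        for pname, dim in self.space.items():
            kind = dim[0]
            if kind == "choice":
                params[pname] = dim[1][int(rng.integers(len(dim[1])))]
            elif kind == "uniform":
                params[pname] = float(rng.uniform(dim[1], dim[2]))
            elif kind == "loguniform":
                params[pname] = float(np.exp(rng.uniform(np.log(dim[1]), np.log(dim[2]))))
            elif kind == "randint":
                params[pname] = int(rng.integers(dim[1], dim[2] + 1))
            else:
                raise ConfigurationError(f"unknown dimension kind {kind!r}")
        return params


def predict_score(model, X: np.ndarray) -> np.ndarray:
    """Cancer score in [0, 1]: predict_proba when available, else a
    logistic squash of the decision function (0 margin -> 0.5)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return expit(model.decision_function(X))


class SeedAveragedMLP:
    """Average of small MLPs fitted from different initializations
    (an avNNet-style analogue)."""

    def __init__(self, hidden: int, alpha: float, n_seeds: int, seed: int):
        self.models = [
            MLPClassifier(
                hidden_layer_sizes=(hidden,),
                alpha=alpha,
                max_iter=300,
                random_state=seed + 13 * k,
            )
            for k in range(n_seeds)
        ]

    def fit(self, X, y):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for m in self.models:
                m.fit(X, y)
        return self

    def predict_proba(self, X):
        return np.mean([m.predict_proba(X) for m in self.models], axis=0)


def _tree_sizes(profile: str) -> list[int]:
    return {"full": [200, 350, 500], "ci": [60, 100], "smoke": [25, 40]}[profile]


def _boost_sizes(profile: str) -> list[int]:
    return {"full": [100, 200, 300], "ci": [40, 80], "smoke": [20, 40]}[profile]


def registry(profile: str = "ci") -> dict[str, ClassifierSpec]:
    """All known classifier specs, keyed by name."""
    if profile not in PROFILES:
        raise ConfigurationError(f"unknown profile {profile!r}")
    specs = [
        ClassifierSpec(
            "logistic",
            lambda p, s: LogisticRegression(C=p["C"], max_iter=2000),
            {"C": ("loguniform", 1e-3, 1e3)},
        ),
        ClassifierSpec(
            "lda",
            lambda p, s: LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=p["shrinkage"]
            ),
            {"shrinkage": ("uniform", 0.0, 1.0)},
        ),
        ClassifierSpec(
            "svm_rbf",
            lambda p, s: SVC(kernel="rbf", C=p["C"], gamma=p["gamma"]),
            {"C": ("loguniform", 0.01, 100.0), "gamma": ("loguniform", 1e-3, 1.0)},
        ),
        ClassifierSpec(
            "svm_poly",
            lambda p, s: SVC(kernel="poly", C=p["C"], degree=p["degree"], coef0=1.0),
            {"C": ("loguniform", 0.01, 100.0), "degree": ("choice", [2, 3])},
        ),
        ClassifierSpec(
            "random_forest",
            lambda p, s: RandomForestClassifier(
                n_estimators=p["n_estimators"],
                max_features=p["max_features"],
                min_samples_leaf=p["min_samples_leaf"],
                random_state=s,
                n_jobs=1,
            ),
            {
                "n_estimators": ("choice", _tree_sizes(profile)),
                "max_features": ("choice", ["sqrt", 0.3, 0.6]),
                "min_samples_leaf": ("randint", 1, 5),
            },
        ),
        ClassifierSpec(
            "grad_boost",
            lambda p, s: GradientBoostingClassifier(
                n_estimators=p["n_estimators"],
                learning_rate=p["learning_rate"],
                max_depth=p["max_depth"],
                subsample=0.8,
                random_state=s,
            ),
            {
                "n_estimators": ("choice", _boost_sizes(profile)),
                "learning_rate": ("loguniform", 0.03, 0.3),
                "max_depth": ("choice", [1, 2, 3]),
            },
        ),
        ClassifierSpec(
            "knn",
            lambda p, s: KNeighborsClassifier(
                n_neighbors=p["n_neighbors"], weights=p["weights"]
            ),
            {"n_neighbors": ("randint", 3, 15), "weights": ("choice", ["uniform", "distance"])},
        ),
        ClassifierSpec(
            "naive_bayes",
            lambda p, s: GaussianNB(var_smoothing=p["var_smoothing"]),
            {"var_smoothing": ("loguniform", 1e-11, 1e-6)},
        ),
        ClassifierSpec(
            "mlp_avg",
            lambda p, s: SeedAveragedMLP(
                hidden=p["hidden"], alpha=p["alpha"], n_seeds=3, seed=s
            ),
            {"hidden": ("choice", [3, 5, 8]), "alpha": ("loguniform", 1e-4, 1.0)},
        ),
    ]
    return {s.name: s for s in specs}


DEFAULT_SUITE = [
    "logistic",
    "lda",
    "svm_rbf",
    "svm_poly",
    "random_forest",
    "grad_boost",
    "knn",
    "naive_bayes",
]


def default_suite(profile: str = "ci", names=None) -> list[ClassifierSpec]:
    """The default eight-member suite (or any named subset) for a profile."""
    reg = registry(profile)
    names = DEFAULT_SUITE if names is None else list(names)
    unknown = set(names) - set(reg)
    if unknown:
        raise ConfigurationError(f"unknown classifier {sorted(unknown)[0]!r}")
    return [reg[n] for n in names]
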