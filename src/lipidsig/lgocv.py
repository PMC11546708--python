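"""Repeated leave-group-out CV with in-fold Boruta and a majority-vote ensemble.

The discovery engine repeats a stratified 80/20 train/test split many times.
Within every iteration, feature selection (Boruta) runs on the training
split only; each classifier is tuned by random search over a nested 80/20
resampling of the training split, refit on the full training split and
evaluated on the held-out samples; the ensemble predicts by majority vote
with ties going to cancer.  Selection frequency across iterations ranks
lipids into a robust signature; a final evaluation re-runs the resampling
with the signature and hyperparameters frozen; a sensitivity analysis
sweeps the signature size.

All randomness flows from the split plan / function seeds through named
substreams, so a full run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .boruta import BorutaConfig, boruta_run
from .classifiers import ClassifierSpec, predict_score
from .errors import ConfigurationError, DataError, InsufficientDataError

FPR_GRID = np.linspace(0.0, 1.0, 101)

CERTAINTY_HIGH = "high"
CERTAINTY_MEDIUM = "medium"
CERTAINTY_LOW = "low"


# ------------------------------------------------------------------- splits
@dataclass
class SplitPlan:
    """A reproducible list of train/test index splits."""

    n_iter: int
    test_fraction: float
    stratified: bool
    seed: int
    splits: list  # [(train_idx, test_idx), ...]


def make_splits(
    labels: np.ndarray,
    n_iter: int = 2000,
    test_fraction: float = 0.2,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Independent random 80/20-style splits; |test| = round(fraction * n).

    Stratification allocates per-class test counts by largest remainder, so
    test class proportions stay within one sample of the overall ones.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 10:
        raise InsufficientDataError("need >= 10 samples to split")
    classes, counts = np.unique(y, return_counts=True)
    if stratified and (counts < 2).any():
        raise InsufficientDataError("each class needs >= 2 samples")
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ConfigurationError(
            f"test_fraction={test_fraction} yields test size {n_test} of {n}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 5]))

    if stratified:
        exact = counts * n_test / n
        base = np.floor(exact).astype(int)
        rem = n_test - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:rem]] += 1
        per_class = base
    splits = []
    for _ in range(n_iter):
        if stratified:
            test = np.concatenate(
                [
                    rng.choice(np.flatnonzero(y == c), k, replace=False)
                    for c, k in zip(classes, per_class)
                ]
            )
        else:
            test = rng.choice(n, n_test, replace=False)
        test = np.sort(test)
        train = np.setdiff1d(np.arange(n), test)
        splits.append((train, test))
    return SplitPlan(n_iter, test_fraction, stratified, seed, splits)


# ----------------------------------------------------------------- ensemble
def ensemble_vote(votes: np.ndarray) -> int:
    """Majority vote over binary model votes; ties predict cancer (1)."""
    votes = np.asarray(votes)
    if votes.size == 0:
        raise DataError("need at least one model vote")
    cancer = int(votes.sum())
    return int(cancer >= votes.size - cancer)


def ensemble_score(votes: np.ndarray) -> float:
    """Fraction of models voting cancer."""
    votes = np.asarray(votes)
    if votes.size == 0:
        raise DataError("need at least one model vote")
    return float(votes.mean())


def certainty(votes: np.ndarray) -> str:
    """Agreement level: high = unanimous, medium = >= 80%, low otherwise."""
    votes = np.asarray(votes)
    if votes.size == 0:
        raise DataError("need at least one model vote")
    cancer = int(votes.sum())
    agree = max(cancer, votes.size - cancer)
    if agree == votes.size:
        return CERTAINTY_HIGH
    if agree / votes.size >= 0.8:
        return CERTAINTY_MEDIUM
    return CERTAINTY_LOW


def _metrics(pred: np.ndarray, y: np.ndarray) -> dict:
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
    }


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


# ------------------------------------------------------------------- tuning
def nested_tune(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    n_nested: int = 50,
    tune_len: int = 10,
    rng: np.random.Generator | None = None,
) -> dict:
    """Random-search tuning over nested 80/20 resampling of the training set.

    Draws ``tune_len`` candidate configurations, scores each by mean accuracy
    over ``n_nested`` nested splits and returns the best (ties: first drawn).
    The caller refits on the full training set.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("training set must contain both classes")
    candidates = [spec.sample(rng) for _ in range(max(tune_len, 1))]
    if not spec.space:
        return candidates[0]
    # deduplicate while preserving draw order (first-drawn wins ties anyway)
    seen, unique_cands = set(), []
    for c in candidates:
        key = tuple(sorted((k, repr(v)) for k, v in c.items()))
        if key not in seen:
            seen.add(key)
            unique_cands.append(c)
    if len(unique_cands) == 1:
        return unique_cands[0]

    plan = make_splits(
        y, n_iter=n_nested, test_fraction=0.2, stratified=True,
        seed=int(rng.integers(2**31)),
    )
    best_params, best_acc = None, -1.0
    for params in unique_cands:
        accs = []
        for tr, te in plan.splits:
            model = spec.factory(params, 0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            pred = (predict_score(model, X[te]) >= 0.5).astype(int)
            accs.append(float(np.mean(pred == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_params, best_acc = params, acc
    return best_params


# ---------------------------------------------------------------- discovery
@dataclass
class IterationRecord:
    """Everything one LGOCV iteration produced."""

    index: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    selected_features: list
    fallback_all: bool
    boruta_mean_importance: pd.Series
    classifier_params: dict
    classifier_votes: dict
    classifier_metrics: dict
    ensemble_fraction: np.ndarray
    ensemble_pred: np.ndarray
    ensemble_metrics: dict
    audit: dict  # stage -> row-index array actually consumed

    def to_json_line(self) -> str:
        return json.dumps(
            {
                "iteration": self.index,
                "train_idx": self.train_idx.tolist(),
                "test_idx": self.test_idx.tolist(),
                "selected_features": list(self.selected_features),
                "fallback_all": self.fallback_all,
                "classifier_params": self.classifier_params,
                "classifier_metrics": self.classifier_metrics,
                "ensemble_metrics": self.ensemble_metrics,
                "ensemble_fraction": [round(float(v), 8) for v in self.ensemble_fraction],
            },
            sort_keys=True,
        )


def discovery_run(
    X: np.ndarray,
    y: np.ndarray,
    feature_names,
    classifiers: list[ClassifierSpec],
    boruta_cfg: BorutaConfig,
    plan: SplitPlan,
    n_nested: int = 50,
    tune_len: int = 10,
) -> list[IterationRecord]:
    """Per iteration: in-fold Boruta, per-classifier nested tuning + refit,
    held-out evaluation, majority-vote ensemble.

    An iteration whose Boruta confirms nothing falls back to all features
    and is flagged; its selections do not count toward selection frequency.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    feature_names = list(feature_names)
    records = []
    root = np.random.SeedSequence([int(plan.seed) % 2**31, 17])
    iter_seeds = root.spawn(plan.n_iter)
    for i, (train, test) in enumerate(plan.splits):
        rng = np.random.default_rng(iter_seeds[i])
        cfg = replace(boruta_cfg, seed=int(rng.integers(2**31)))
        bres = boruta_run(X[train], y[train], cfg, feature_names=feature_names)
        confirmed = bres.confirmed
        fallback = len(confirmed) == 0
        if fallback:
            if not any(r.fallback_all for r in records):
                warnings.warn(
                    "empty Boruta set in at least one iteration; "
                    "falling back to all features (flagged per record)"
                )
            confirmed = feature_names
        sel = [feature_names.index(f) for f in confirmed]

        votes = np.zeros((len(classifiers), len(test)), dtype=int)
        cl_params, cl_votes, cl_metrics = {}, {}, {}
        for k, spec in enumerate(classifiers):
            params = nested_tune(
                X[np.ix_(train, sel)], y[train], spec,
                n_nested=n_nested, tune_len=tune_len, rng=rng,
            )
            model = spec.factory(params, int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[np.ix_(train, sel)], y[train])
            score = predict_score(model, X[np.ix_(test, sel)])
            votes[k] = (score >= 0.5).astype(int)
            cl_params[spec.name] = params
            cl_votes[spec.name] = votes[k].copy()
            cl_metrics[spec.name] = _metrics(votes[k], y[test])

        fraction = votes.mean(axis=0) if len(classifiers) else np.zeros(len(test))
        pred = (fraction >= 0.5).astype(int)
        records.append(
            IterationRecord(
                index=i,
                train_idx=train.copy(),
                test_idx=test.copy(),
                selected_features=list(confirmed) if not fallback else list(feature_names),
                fallback_all=fallback,
                boruta_mean_importance=bres.mean_importance,
                classifier_params=cl_params,
                classifier_votes=cl_votes,
                classifier_metrics=cl_metrics,
                ensemble_fraction=fraction,
                ensemble_pred=pred,
                ensemble_metrics=_metrics(pred, y[test]) if len(classifiers) else {},
                audit={"selection_rows": train.copy(), "tuning_rows": train.copy()},
            )
        )
    return records


def average_prediction_matrix(records: list[IterationRecord], n_samples: int) -> pd.DataFrame:
    """Per-sample average held-out prediction of each model across iterations.

    Rows are sample positions, columns the classifiers plus the ensemble;
    entries are the mean cancer vote over the iterations in which the sample
    was held out (NaN if never held out).
    """
    if not records:
        raise InsufficientDataError("no iteration records")
    names = list(records[0].classifier_votes) + ["ensemble"]
    sums = pd.DataFrame(0.0, index=range(n_samples), columns=names)
    counts = pd.Series(0, index=range(n_samples), dtype=int)
    for r in records:
        for name, v in r.classifier_votes.items():
            sums.loc[r.test_idx, name] += v
        sums.loc[r.test_idx, "ensemble"] += r.ensemble_pred
        counts.loc[r.test_idx] += 1
    out = sums.div(counts.replace(0, np.nan), axis=0)
    out.index.name = "sample_position"
    return out


# ------------------------------------------------------- selection frequency
def selection_frequency(records: list[IterationRecord], feature_names) -> pd.DataFrame:
    """Per-lipid Boruta confirmation frequency across iterations.

    ``proportion`` = confirmed count / number of iterations (fallback
    iterations count in the denominator but select nothing).  Ranking is by
    proportion, then mean Boruta importance, then lipid_id.
    """
    if not records:
        raise InsufficientDataError("no iteration records")
    feature_names = list(feature_names)
    counts = pd.Series(0, index=pd.Index(feature_names, name="lipid_id"), dtype=int)
    imp = pd.DataFrame(
        [r.boruta_mean_importance.reindex(feature_names) for r in records]
    )
    for r in records:
        if not r.fallback_all:
            counts.loc[r.selected_features] += 1
    out = pd.DataFrame(
        {
            "selections": counts,
            "proportion": counts / len(records),
            "mean_importance": imp.mean(axis=0, skipna=True).fillna(0.0),
        }
    )
    out["_id"] = out.index
    out = out.sort_values(
        ["proportion", "mean_importance", "_id"],
        ascending=[False, False, True],
        kind="stable",
    ).drop(columns="_id")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_k(freq: pd.DataFrame, k: int = 20, strict: bool = True) -> list:
    """The first k lipids of the selection-frequency ranking.

    With ``strict`` (default) it is an error to ask for more lipids than
    were ever confirmed; ``strict=False`` fills the remaining ranks from
    the mean-importance tie-break of the ranking.
    """
    ever = int((freq["proportion"] > 0).sum())
    if strict and k > ever:
        raise ConfigurationError(
            f"k={k} exceeds the {ever} lipids ever selected"
        )
    if k > len(freq):
        raise ConfigurationError(f"k={k} exceeds the {len(freq)} ranked lipids")
    return list(freq.index[:k])


# ------------------------------------------------- final hyperparameter rule
def pick_final_hyperparams(records: list[IterationRecord], classifier_name: str) -> dict:
    """Freeze a classifier's hyperparameters from its best-rank iterations.

    Within each iteration classifiers are ranked by test accuracy (1 = best,
    ties share the minimum rank).  Among the iterations where the classifier
    attains its best-ever rank, the one with the median accuracy is chosen
    (lower median for even counts; first such iteration on ties) and its
    tuned hyperparameters are returned.
    """
    if not records:
        raise InsufficientDataError("no iteration records")
    ranks, accs = [], []
    for r in records:
        if classifier_name not in r.classifier_metrics:
            raise ConfigurationError(
                f"classifier {classifier_name!r} missing from iteration {r.index}"
            )
        acc_all = {n: m["accuracy"] for n, m in r.classifier_metrics.items()}
        mine = acc_all[classifier_name]
        rank = 1 + sum(a > mine for a in acc_all.values())
        ranks.append(rank)
        accs.append(mine)
    best_rank = min(ranks)
    pool = [(a, i) for i, (rk, a) in enumerate(zip(ranks, accs)) if rk == best_rank]
    pool_accs = sorted(a for a, _ in pool)
    target = pool_accs[(len(pool_accs) - 1) // 2]  # lower median
    chosen = min(i for a, i in pool if a == target)
    return records[chosen].classifier_params[classifier_name]


# ------------------------------------------------------------ final ensemble
@dataclass
class PerformanceSummary:
    """Mean +/- SD metrics, averaged ROC/AUC and certainty breakdown."""

    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    auc_mean: float
    roc: pd.DataFrame  # fpr, tpr_mean
    certainty: pd.DataFrame  # index (outcome, level) -> percent
    per_iteration: pd.DataFrame
    classifier_means: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_mean": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
            "auc_mean": self.auc_mean,
            "certainty_percent": {
                f"{outcome}:{level}": float(v)
                for (outcome, level), v in self.certainty["percent"].items()
            },
        }


def final_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    feature_names,
    signature: list,
    classifiers: list[ClassifierSpec],
    fixed_params: dict,
    plan: SplitPlan,
) -> PerformanceSummary:
    """Repeat the LGOCV with feature set and hyperparameters frozen.

    Per iteration all classifiers are fit on the training split restricted
    to the signature and vote on the test split; the ensemble vote fraction
    is the continuous score for the per-iteration AUC.  The averaged ROC is
    the vertical mean of per-iteration curves on a fixed FPR grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    feature_names = list(feature_names)
    missing = set(signature) - set(feature_names)
    if missing:
        raise ConfigurationError(f"signature lipid {sorted(missing)[0]!r} not in table")
    sel = [feature_names.index(f) for f in signature]
    root = np.random.SeedSequence([int(plan.seed) % 2**31, 29])
    iter_seeds = root.spawn(plan.n_iter)

    rows, aucs, tprs = [], [], []
    cls_rows = []
    cert_counts: dict[tuple, int] = {}
    for i, (train, test) in enumerate(plan.splits):
        rng = np.random.default_rng(iter_seeds[i])
        votes = np.zeros((len(classifiers), len(test)), dtype=int)
        for k, spec in enumerate(classifiers):
            model = spec.factory(fixed_params[spec.name], int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[np.ix_(train, sel)], y[train])
            score = predict_score(model, X[np.ix_(test, sel)])
            votes[k] = (score >= 0.5).astype(int)
            cls_rows.append({"classifier": spec.name, **_metrics(votes[k], y[test])})
        fraction = votes.mean(axis=0)
        pred = (fraction >= 0.5).astype(int)
        rows.append(_metrics(pred, y[test]))
        aucs.append(_rank_auc(fraction, y[test]))
        fpr, tpr, _ = roc_curve(y[test], fraction)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        for j in range(len(test)):
            level = certainty(votes[:, j])
            outcome = "correct" if pred[j] == y[test][j] else "incorrect"
            cert_counts[(outcome, level)] = cert_counts.get((outcome, level), 0) + 1

    per_iter = pd.DataFrame(rows)
    per_iter["auc"] = aucs
    cert_rows = []
    for outcome in ("correct", "incorrect"):
        total = sum(v for (o, _), v in cert_counts.items() if o == outcome)
        for level in (CERTAINTY_HIGH, CERTAINTY_MEDIUM, CERTAINTY_LOW):
            n = cert_counts.get((outcome, level), 0)
            cert_rows.append(
                {
                    "outcome": outcome,
                    "level": level,
                    "count": n,
                    "percent": 100.0 * n / total if total else 0.0,
                }
            )
    cert = pd.DataFrame(cert_rows).set_index(["outcome", "level"])
    cls_means = (
        pd.DataFrame(cls_rows).groupby("classifier").mean().sort_index()
        if cls_rows
        else pd.DataFrame()
    )
    return PerformanceSummary(
        accuracy_mean=float(per_iter["accuracy"].mean()),
        accuracy_sd=float(per_iter["accuracy"].std(ddof=1)) if len(per_iter) > 1 else 0.0,
        sensitivity_mean=float(per_iter["sensitivity"].mean()),
        sensitivity_sd=float(per_iter["sensitivity"].std(ddof=1)) if len(per_iter) > 1 else 0.0,
        specificity_mean=float(per_iter["specificity"].mean()),
        specificity_sd=float(per_iter["specificity"].std(ddof=1)) if len(per_iter) > 1 else 0.0,
        auc_mean=float(np.nanmean(aucs)),
        roc=pd.DataFrame({"fpr": FPR_GRID, "tpr_mean": np.mean(tprs, axis=0)}),
        certainty=cert,
        per_iteration=per_iter,
        classifier_means=cls_means,
    )


# --------------------------------------------------------------- sensitivity
@dataclass
class SensitivityResult:
    """Ensemble accuracy distribution as a function of signature size."""

    table: pd.DataFrame  # index k; q05, median, q95, mean
    chosen_k: int
    tolerance: float


def sensitivity_analysis(
    X: np.ndarray,
    y: np.ndarray,
    feature_names,
    ranked_lipids: list,
    classifiers: list[ClassifierSpec],
    fixed_params: dict,
    plan: SplitPlan,
    sizes=range(14, 31),
    tolerance: float = 0.005,
) -> SensitivityResult:
    """Re-evaluate the frozen ensemble for each top-k signature size.

    ``chosen_k`` is the smallest size whose median accuracy comes within
    ``tolerance`` of the best median (parsimony rule).
    """
    sizes = sorted(sizes)
    if not sizes:
        raise ConfigurationError("sizes must be non-empty")
    if len(ranked_lipids) < sizes[-1]:
        raise ConfigurationError("ranked_lipids shorter than the largest size")
    rows = {}
    for k in sizes:
        summary = final_evaluation(
            X, y, feature_names, list(ranked_lipids[:k]), classifiers, fixed_params, plan
        )
        acc = summary.per_iteration["accuracy"]
        rows[k] = {
            "q05": float(acc.quantile(0.05)),
            "median": float(acc.quantile(0.5)),
            "q95": float(acc.quantile(0.95)),
            "mean": float(acc.mean()),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "signature_size"
    best = table["median"].max()
    chosen = next(k for k in sizes if table.loc[k, "median"] >= best - tolerance)
    return SensitivityResult(table=table, chosen_k=int(chosen), tolerance=tolerance)


# -------------------------------------------------------------- panel overlap
def compare_panels(panels: dict) -> pd.DataFrame:
    """Exclusive membership of every intersection region of >= 2 named panels.

    Returns one row per non-empty subset of panel names with the lipids that
    belong to exactly those panels.
    """
    if len(panels) < 2:
        raise ConfigurationError("need at least two panels to compare")
    sets = {name: set(p) for name, p in panels.items()}
    names = list(sets)
    rows = []
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in names if c not in combo))
            exclusive = sorted(inside - outside)
            rows.append(
                {
                    "region": "&".join(combo),
                    "n_panels": r,
                    "n_lipids": len(exclusive),
                    "lipids": ";".join(exclusive),
                }
            )
    return pd.DataFrame(rows)
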