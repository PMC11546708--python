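"""Differential-abundance panel workflow with LOOCV logistic evaluation.

Implements the classical single-lipid discovery route: per-lipid linear
models on log2 concentrations (group effect with optional cohort/batch
blocking), Benjamini-Hochberg FDR control, fold-change + FDR panel selection
with isomer inclusion, greedy AIC-stepwise restriction over m/z groups,
leave-one-out cross-validated logistic regression scored with an
accuracy-optimized threshold, and the per-subject EV/plasma correlation
check.

Note the threshold is optimized on the same LOOCV scores it is reported on;
that mirrors the emulated protocol and is a known source of optimism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable
from .errors import ConfigurationError, DataError, InsufficientDataError

__all__ = [
    "da_test",
    "bh_adjust",
    "select_panel",
    "stepwise_restrict",
    "loocv_logistic",
    "optimize_threshold",
    "subject_correlation",
    "PanelSpec",
    "LOOCVResult",
    "SubjectCorrelation",
]


# ------------------------------------------------------------------- DA test
def da_test(
    table: FeatureTable,
    blocking: Iterable[str] = ("cohort",),
    method: str = "fixed",
) -> pd.DataFrame:
    """Per-lipid differential abundance between cancer and control.

    Fits, per lipid, the additive model ``log2conc ~ group [+ cohort] [+ batch]``
    on the non-QC samples and reports the group effect:

    - ``log2fc`` / ``fc``: group coefficient (cancer minus control) and the
      corresponding linear-scale ratio of geometric means,
    - ``p``: group-effect F-test p-value (equal to the squared-t test for the
      single-df contrast), ``q``: BH-adjusted p.

    ``method="mixed"`` instead fits a mixed model with a random batch
    intercept (REML) per lipid; it is slower and intended for small tables.
    Blocking terms with a single level are dropped automatically.
    """
    if not table.log_flag:
        raise DataError("da_test expects log2-scale values")
    bio = table.biological()
    y01 = bio.labels().to_numpy()
    if (y01 == 1).sum() < 2 or (y01 == 0).sum() < 2:
        raise InsufficientDataError("need >= 2 samples per group")
    Y = bio.values.to_numpy(dtype=float)
    n, p = Y.shape

    cols = [np.ones(n), y01.astype(float)]
    for term in blocking:
        if method == "mixed" and term == "batch":
            continue
        levels = bio.sample_meta[term].astype(str)
        uniq = sorted(levels.unique())
        for lv in uniq[1:]:
            cols.append((levels == lv).to_numpy(dtype=float))
    X = np.column_stack(cols)

    if method == "mixed":
        return _da_mixed(bio, X, Y)
    if method != "fixed":
        raise ConfigurationError(f"unknown da_test method {method!r}")

    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # k x p
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    if dof <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(XtX_inv[1, 1] * sigma2)
    coef = beta[1]

    constant = Y.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    degenerate = constant | (se == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} lipid(s) with zero residual variance; "
            "reported as fc=1, p=1"
        )
        pvals = np.where(degenerate, 1.0, pvals)
        coef = np.where(degenerate, 0.0, coef)

    out = pd.DataFrame(
        {
            "log2fc": coef,
            "fc": np.power(2.0, coef),
            "p": pvals,
        },
        index=bio.values.columns.rename("lipid_id"),
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def _da_mixed(bio: FeatureTable, X: np.ndarray, Y: np.ndarray) -> pd.DataFrame:
    """Random-batch-intercept variant, fitted lipid by lipid via REML."""
    import statsmodels.formula.api as smf

    frame = pd.DataFrame(
        {
            "group": bio.labels().to_numpy(),
            "cohort": bio.sample_meta["cohort"].astype(str).to_numpy(),
            "batch": bio.sample_meta["batch"].astype(str).to_numpy(),
        }
    )
    multi_cohort = frame["cohort"].nunique() > 1
    rows = []
    for j, lid in enumerate(bio.values.columns):
        frame["y"] = Y[:, j]
        if frame["y"].std() == 0:
            rows.append((0.0, 1.0))
            continue
        formula = "y ~ group + C(cohort)" if multi_cohort else "y ~ group"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, frame, groups=frame["batch"]).fit(reml=True)
        rows.append((float(fit.params["group"]), float(fit.pvalues["group"])))
    coef = np.array([r[0] for r in rows])
    pvals = np.array([r[1] for r in rows])
    out = pd.DataFrame(
        {"log2fc": coef, "fc": np.power(2.0, coef), "p": pvals},
        index=bio.values.columns.rename("lipid_id"),
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------- BH adjust
def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------- panel selection
@dataclass
class PanelSpec:
    """An ordered lipid panel with per-lipid selection provenance."""

    lipid_ids: list
    provenance: pd.DataFrame  # columns: da_selected, isomer_included, stepwise_retained

    def __post_init__(self) -> None:
        if list(self.provenance.index) != list(self.lipid_ids):
            raise ConfigurationError("provenance index must match lipid_ids order")


def select_panel(
    da: pd.DataFrame,
    schema: pd.DataFrame,
    fc_min: float = 1.2,
    q_max: float = 0.05,
) -> PanelSpec:
    """FDR + fold-change filter with isomer inclusion.

    A lipid is selected when ``q < q_max`` and ``max(fc, 1/fc) > fc_min``
    (the fold-change criterion is direction-agnostic: depleted lipids count).
    Isomer-group mates of any selected lipid are then added and flagged
    ``isomer_included``.  Output is ordered by significance (q ascending,
    then |log2fc| descending, then lipid_id).
    """
    if fc_min < 1 or not 0 < q_max <= 1:
        raise ConfigurationError("need fc_min >= 1 and q_max in (0, 1]")
    fc = da["fc"].to_numpy(dtype=float)
    if (fc <= 0).any():
        raise DataError("fold changes must be positive")
    magnitude = np.maximum(fc, 1.0 / fc)
    hit = (da["q"].to_numpy() < q_max) & (magnitude > fc_min)
    selected = set(da.index[hit])

    groups = schema["isomer_group"]
    hit_groups = set(groups.loc[groups.index.intersection(selected)])
    mates = set(groups.index[groups.isin(hit_groups)]) - selected

    order = da.assign(_mag=np.abs(da["log2fc"])).sort_values(
        ["q", "_mag"], ascending=[True, False], kind="stable"
    )
    ordered = [l for l in order.index if l in selected]
    ordered += sorted(mates)
    prov = pd.DataFrame(
        {
            "da_selected": [l in selected for l in ordered],
            "isomer_included": [l in mates for l in ordered],
            "stepwise_retained": False,
        },
        index=pd.Index(ordered, name="lipid_id"),
    )
    return PanelSpec(lipid_ids=ordered, provenance=prov)


# ------------------------------------------------------------------- stepwise
def _logit_loglik_aic(X: np.ndarray, y: np.ndarray) -> float:
    """AIC of a maximum-likelihood logistic fit (duplicate columns dropped)."""
    import statsmodels.api as sm

    X = np.unique(X, axis=1) if X.shape[1] else X
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if np.isnan(fit.llf):
                raise ValueError("nan log-likelihood")
            return float(2 * design.shape[1] - 2 * fit.llf)
        except Exception:
            # perfect separation or singular Hessian: penalized fallback
            warnings.warn("separation in stepwise fit; using penalized likelihood")
            clf = LogisticRegression(C=1e4, max_iter=2000).fit(X, y) if X.shape[1] else None
            if clf is None:
                p1 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
                ll = y.sum() * np.log(p1) + (len(y) - y.sum()) * np.log(1 - p1)
                return float(2 - 2 * ll)
            prob = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
            ll = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
            return float(2 * design.shape[1] - 2 * ll)


def stepwise_restrict(
    table: FeatureTable,
    panel: PanelSpec,
    labels: pd.Series | np.ndarray | None = None,
) -> PanelSpec:
    """Greedy forward selection of m/z groups by AIC.

    Panel lipids are grouped by identical m/z; a group enters the logistic
    model as the set of its member lipids.  Groups are added while the AIC
    decreases; the returned panel is the union of retained groups.
    """
    if not panel.lipid_ids:
        raise ConfigurationError("panel is empty")
    bio = table.biological()
    y = bio.labels().to_numpy() if labels is None else np.asarray(labels, dtype=int)
    mz = table.lipid_meta.loc[panel.lipid_ids, "mz"]
    groups: dict[float, list] = {}
    for lid, m in mz.items():
        groups.setdefault(float(m), []).append(lid)
    order = sorted(groups)

    V = bio.values
    current: list[float] = []
    current_aic = _logit_loglik_aic(np.empty((len(y), 0)), y)
    remaining = list(order)
    while remaining:
        trial = [
            (_logit_loglik_aic(
                V[[l for g in current + [m] for l in groups[g]]].to_numpy(), y
            ), m)
            for m in remaining
        ]
        best_aic, best_m = min(trial)
        if best_aic < current_aic:
            current.append(best_m)
            remaining.remove(best_m)
            current_aic = best_aic
        else:
            break

    kept = [l for l in panel.lipid_ids if float(mz[l]) in current]
    prov = panel.provenance.loc[kept].copy()
    prov["stepwise_retained"] = True
    return PanelSpec(lipid_ids=kept, provenance=prov)


# -------------------------------------------------------------------- LOOCV
def optimize_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy-maximizing decision threshold (scores > t predicted cancer).

    Candidates are midpoints between consecutive sorted unique scores plus
    -inf/+inf sentinels; ties in accuracy break toward the smallest
    threshold (favoring sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise InsufficientDataError("both classes must be present")
    u = np.unique(scores)
    candidates = np.concatenate([[-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]])
    best_t, best_acc = -np.inf, -1.0
    for t in candidates:
        acc = float(np.mean((scores > t).astype(int) == labels))
        if acc > best_acc:
            best_t, best_acc = t, acc
    return float(best_t)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC; tied score pairs count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class LOOCVResult:
    """Leave-one-out logistic regression evaluation."""

    scores: pd.Series
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc: pd.DataFrame  # columns fpr, tpr
    auc: float

    def confusion_frame(self) -> pd.DataFrame:
        """Index-test rows x reference-test columns confusion matrix."""
        return pd.DataFrame(
            [[self.tp, self.fp], [self.fn, self.tn]],
            index=pd.Index(["pred_cancer", "pred_control"], name="index_test"),
            columns=pd.Index(["cancer", "control"], name="reference_test"),
        )

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "auc": self.auc,
            "scores": {k: round(float(v), 10) for k, v in self.scores.items()},
        }


def loocv_logistic(
    table: FeatureTable,
    panel: PanelSpec,
    labels: pd.Series | np.ndarray | None = None,
) -> LOOCVResult:
    """LOOCV logistic regression over panel lipids.

    For each sample the model is trained on all other samples and scores the
    held-out sample with its cancer probability.  The decision threshold is
    then chosen to maximize accuracy over the pooled LOOCV scores; AUC comes
    from the Mann-Whitney rank statistic.
    """
    bio = table.biological()
    y = bio.labels().to_numpy() if labels is None else np.asarray(labels, dtype=int)
    n = len(y)
    if n < 10:
        raise InsufficientDataError("LOOCV needs at least 10 samples")
    if len(panel.lipid_ids) >= n - 1:
        raise InsufficientDataError("panel size must be < n - 1")
    X = bio.values[panel.lipid_ids].to_numpy(dtype=float)

    scores = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        clf = LogisticRegression(C=1e6, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[mask], y[mask])
        scores[i] = clf.predict_proba(X[i : i + 1])[0, 1]

    threshold = optimize_threshold(scores, y)
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fpr, tpr, _ = roc_curve(y, scores)
    return LOOCVResult(
        scores=pd.Series(scores, index=bio.values.index),
        threshold=threshold,
        accuracy=(tp + tn) / n,
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        auc=_rank_auc(scores, y),
    )


# --------------------------------------------------- EV/plasma correlation
class SubjectCorrelation(NamedTuple):
    table: pd.DataFrame  # subject_id, r; sorted descending
    n_above_cutoff: int
    cutoff: float


def subject_correlation(
    ev: FeatureTable,
    plasma: FeatureTable,
    panel: PanelSpec,
    r_cutoff: float = 0.9,
) -> SubjectCorrelation:
    """Per-subject Pearson correlation of EV vs plasma panel-lipid profiles.

    Computed on log2 concentrations of panel lipids, per matched subject;
    returned sorted descending together with the count of subjects whose
    correlation exceeds ``r_cutoff``.
    """
    if len(panel.lipid_ids) < 3:
        raise InsufficientDataError("need >= 3 panel lipids for a correlation")

    def _log_values(t: FeatureTable) -> pd.DataFrame:
        sub = t.biological().subset_lipids(panel.lipid_ids)
        vals = sub.values if t.log_flag else np.log2(sub.values + 2.0**-20)
        return vals.set_index(sub.sample_meta["subject_id"])

    a = _log_values(ev)
    b = _log_values(plasma)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise DataError("no shared subject_ids between the tables")
    av = a.loc[shared].to_numpy()
    bv = b.loc[shared].to_numpy()
    ac = av - av.mean(axis=1, keepdims=True)
    bc = bv - bv.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    r = np.where(denom > 0, (ac * bc).sum(axis=1) / np.where(denom > 0, denom, 1.0), np.nan)
    out = (
        pd.DataFrame({"subject_id": shared, "r": r})
        .sort_values("r", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return SubjectCorrelation(
        table=out,
        n_above_cutoff=int((out["r"] > r_cutoff).sum()),
        cutoff=r_cutoff,
    )
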