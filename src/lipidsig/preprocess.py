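"""Preprocessing: internal-standard ratios, log transform, QC CVs, batch normalization.

Raw peak areas become relative concentrations by division with the per-class
internal standard (ISTD), are optionally batch-normalized on the linear scale
(sample-median scaling plus internal reference scaling against the pooled QC
samples present in every batch), and are finally log2-transformed for the
statistical stages.  QC replicate CVs quantify technical reproducibility per
sample type; lipids with CV >= 30% are flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .errors import (
    ConfigurationError,
    DataError,
    InsufficientDataError,
    SchemaError,
    StateError,
)

CV_FLAG_PERCENT = 30.0


# ------------------------------------------------------------------ ISTD ratio
def istd_ratio(raw_areas: FeatureTable, istd_areas: pd.DataFrame) -> FeatureTable:
    """Divide each lipid's peak area by its class ISTD area, per sample.

    ``istd_areas`` is a samples x lipid-class table of positive ISTD peak
    areas; every lipid class present in the table must have a column.
    """
    if raw_areas.log_flag:
        raise StateError("istd_ratio expects a linear-scale table")
    classes = raw_areas.lipid_meta["lipid_class"]
    missing = set(classes) - set(istd_areas.columns)
    if missing:
        raise SchemaError(f"no ISTD column for lipid class {sorted(missing)[0]!r}")
    missing_rows = raw_areas.values.index.difference(istd_areas.index)
    if len(missing_rows):
        raise SchemaError(f"no ISTD areas for sample {missing_rows[0]!r}")
    istd = istd_areas.loc[raw_areas.values.index, classes.to_numpy()]
    arr = istd.to_numpy(dtype=float)
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise DataError(
            f"non-positive ISTD area for sample {istd.index[i]!r}, "
            f"class {classes.iloc[j]!r}"
        )
    ratios = raw_areas.values.to_numpy(dtype=float) / arr
    return raw_areas.with_values(
        pd.DataFrame(ratios, index=raw_areas.values.index, columns=raw_areas.values.columns),
        log_flag=False,
    )


# --------------------------------------------------------------- log transform
def log_transform(table: FeatureTable, pseudo: float = 2.0**-20) -> FeatureTable:
    """log2(value + pseudo); errors if the table is already log-scale."""
    if table.log_flag:
        raise StateError("table is already log-transformed")
    if pseudo < 0:
        raise ConfigurationError("pseudo-count must be >= 0")
    vals = table.values.to_numpy(dtype=float) + pseudo
    if (vals <= 0).any():
        raise DataError("zero values require a positive pseudo-count")
    return table.with_values(
        pd.DataFrame(np.log2(vals), index=table.values.index, columns=table.values.columns),
        log_flag=True,
    )


# ------------------------------------------------------------------------ QC CV
def qc_cv(table: FeatureTable, min_replicates: int = 2) -> pd.DataFrame:
    """Per-lipid percent CV over QC replicates, per sample type.

    Returns a QC report with one row per (lipid, sample_type):
    ``lipid_id, sample_type, cv_percent, flag_30``.  CVs are computed on the
    linear scale (sample SD / mean * 100).  A zero mean leaves the CV
    undefined (NaN) and flags the lipid.
    """
    if table.log_flag:
        raise StateError("qc_cv expects linear-scale concentrations")
    qc = table.qc_replicates()
    if qc.n_samples == 0:
        raise InsufficientDataError("table contains no QC replicates")
    rows = []
    for stype, sub in qc.values.groupby(qc.sample_meta["sample_type"]):
        if len(sub) < min_replicates:
            raise InsufficientDataError(
                f"sample_type {stype!r} has {len(sub)} QC replicates; "
                f"need >= {min_replicates}"
            )
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = 100.0 * sd / mean
        cv = cv.where(mean != 0, np.nan)
        flag = (cv >= CV_FLAG_PERCENT) | cv.isna()
        rows.append(
            pd.DataFrame(
                {
                    "lipid_id": sub.columns,
                    "sample_type": stype,
                    "cv_percent": cv.to_numpy(),
                    "flag_30": flag.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# -------------------------------------------------------------- normalization
@dataclass
class NormalizationModel:
    """Multiplicative normalization factors.

    ``sample_scale`` holds one factor per sample (median scaling);
    ``lipid_batch_scale`` holds one factor per (lipid, batch) pair (internal
    reference scaling against the pooled QC samples).  All factors are
    positive, and per lipid the batch factors have geometric mean 1.
    """

    sample_scale: pd.Series
    lipid_batch_scale: pd.DataFrame  # index lipid_id, columns batch

    def __post_init__(self) -> None:
        if (self.sample_scale <= 0).any() or (self.lipid_batch_scale.to_numpy() <= 0).any():
            raise DataError("normalization factors must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sample_scale": self.sample_scale.round(12).to_dict(),
                    "lipid_batch_scale": {
                        b: self.lipid_batch_scale[b].round(12).to_dict()
                        for b in self.lipid_batch_scale.columns
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            sample_scale=pd.Series(d["sample_scale"]),
            lipid_batch_scale=pd.DataFrame(d["lipid_batch_scale"]),
        )


def fit_normalization(table: FeatureTable) -> NormalizationModel:
    """Fit median + internal-reference-scaling batch normalization.

    The internal reference scaling factor for (lipid, batch) aligns the
    batch mean of the pooled reference (QC) samples with its cross-batch
    geometric mean; the median-scaling factor then equalizes each
    biological sample's median (of the batch-corrected values) to the
    global median of sample medians.  QC samples keep sample factor 1 -
    they are the reference material the batch factors are anchored to.

    After applying the model, per-batch reference means are exactly equal
    for every lipid and biological sample medians are exactly equal, so a
    refit on the normalized table returns unit factors: fit+apply is
    idempotent to floating-point precision.
    """
    if table.log_flag:
        raise StateError("normalization operates on linear-scale concentrations")
    qc = table.qc_mask
    batches = table.sample_meta["batch"]
    for b, sub in table.sample_meta.groupby("batch"):
        if not sub["qc"].any():
            raise ConfigurationError(f"batch {b!r} has no QC/reference sample")

    V = table.values.to_numpy(dtype=float).copy()
    qc_arr = qc.to_numpy()
    batch_labels = sorted(batches.unique())
    batch_rows = {b: np.flatnonzero((batches == b).to_numpy()) for b in batch_labels}
    qc_rows = {b: rows[qc_arr[rows]] for b, rows in batch_rows.items()}

    ref_means = np.stack(
        [V[qc_rows[b]].mean(axis=0) for b in batch_labels], axis=1
    )  # p x B
    if (ref_means <= 0).any():
        raise DataError("a reference-sample batch mean is non-positive")
    geo = np.exp(np.mean(np.log(ref_means), axis=1))
    g = geo[:, None] / ref_means  # p x B

    for k, b in enumerate(batch_labels):
        V[batch_rows[b]] *= g[:, k]

    s = np.ones(V.shape[0])
    bio_rows = np.flatnonzero(~qc_arr)
    if len(bio_rows):
        med = np.median(V[bio_rows], axis=1)
        if (med <= 0).any():
            raise DataError("a sample median is non-positive; cannot median-scale")
        s[bio_rows] = np.median(med) / med

    return NormalizationModel(
        sample_scale=pd.Series(s, index=table.values.index),
        lipid_batch_scale=pd.DataFrame(g, index=table.values.columns, columns=batch_labels),
    )


def apply_normalization(table: FeatureTable, model: NormalizationModel) -> FeatureTable:
    """Apply fitted per-sample and per-(lipid, batch) factors."""
    if table.log_flag:
        raise StateError("normalization operates on linear-scale concentrations")
    missing = table.values.index.difference(model.sample_scale.index)
    if len(missing):
        raise SchemaError(f"no sample factor for {missing[0]!r}")
    V = table.values.to_numpy(dtype=float).copy()
    V *= model.sample_scale.loc[table.values.index].to_numpy()[:, None]
    batches = table.sample_meta["batch"]
    G = model.lipid_batch_scale.loc[table.values.columns]
    for b in batches.unique():
        if b not in G.columns:
            raise SchemaError(f"no batch factors for batch {b!r}")
        rows = np.flatnonzero((batches == b).to_numpy())
        V[rows] *= G[b].to_numpy()
    return table.with_values(
        pd.DataFrame(V, index=table.values.index, columns=table.values.columns),
        log_flag=False,
    )
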