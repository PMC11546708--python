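"""Core in-memory container for lipidomics feature tables.

A :class:`FeatureTable` bundles the samples x lipids concentration matrix with
per-sample metadata (group, cohort, batch, QC flag, subject, sample type) and
per-lipid metadata (class, annotation, m/z, isomer group).  It is the lingua
franca passed between every pipeline stage, and round-trips losslessly through
a trio of CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

SAMPLE_META_COLUMNS = ["group", "cohort", "batch", "qc", "subject_id", "sample_type"]
LIPID_META_COLUMNS = ["lipid_class", "annotation", "mz", "isomer_group"]

#: group labels; the positive (cancer) class is encoded 1 throughout
GROUP_CONTROL = "control"
GROUP_CANCER = "cancer"


@dataclass
class FeatureTable:
    """Samples x lipids concentration matrix plus metadata.

    Parameters
    ----------
    values
        Non-negative concentrations on the linear scale, or log2 values when
        ``log_flag`` is set.  Index = sample_id, columns = lipid_id.
    sample_meta
        One row per sample (index sample_id) with columns
        ``group, cohort, batch, qc, subject_id, sample_type``.  QC samples
        carry ``qc=True`` and no group label.
    lipid_meta
        One row per lipid (index lipid_id) with columns
        ``lipid_class, annotation, mz, isomer_group``.
    log_flag
        Whether ``values`` are log2-transformed.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    lipid_meta: pd.DataFrame
    log_flag: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise SchemaError(f"duplicate sample_id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise SchemaError(f"duplicate lipid_id {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = v.columns[[not np.issubdtype(d, np.number) for d in v.dtypes]][0]
            raise DataError(f"non-numeric values in column {bad!r}")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                f"non-finite value at sample {v.index[i]!r}, lipid {v.columns[j]!r}"
            )
        if not self.log_flag and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative linear-scale value at sample {v.index[i]!r}, "
                f"lipid {v.columns[j]!r}"
            )
        missing = v.index.difference(self.sample_meta.index)
        if len(missing):
            raise SchemaError(f"sample {missing[0]!r} missing from sample metadata")
        missing = v.columns.difference(self.lipid_meta.index)
        if len(missing):
            raise SchemaError(f"lipid {missing[0]!r} missing from lipid metadata")
        for col in SAMPLE_META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise SchemaError(f"sample metadata lacks column {col!r}")
        for col in LIPID_META_COLUMNS:
            if col not in self.lipid_meta.columns:
                raise SchemaError(f"lipid metadata lacks column {col!r}")
        # align metadata to the value matrix ordering
        self.sample_meta = self.sample_meta.loc[v.index]
        self.lipid_meta = self.lipid_meta.loc[v.columns]

    # -------------------------------------------------------------- accessors
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.values.shape[1]

    @property
    def qc_mask(self) -> pd.Series:
        return self.sample_meta["qc"].astype(bool)

    def biological(self) -> "FeatureTable":
        """Subset to non-QC samples."""
        keep = ~self.qc_mask
        return FeatureTable(
            self.values.loc[keep],
            self.sample_meta.loc[keep],
            self.lipid_meta,
            self.log_flag,
        )

    def qc_replicates(self) -> "FeatureTable":
        keep = self.qc_mask
        return FeatureTable(
            self.values.loc[keep],
            self.sample_meta.loc[keep],
            self.lipid_meta,
            self.log_flag,
        )

    def subset_lipids(self, lipid_ids) -> "FeatureTable":
        lipid_ids = list(lipid_ids)
        missing = set(lipid_ids) - set(self.values.columns)
        if missing:
            raise SchemaError(f"unknown lipid {sorted(missing)[0]!r}")
        return FeatureTable(
            self.values[lipid_ids],
            self.sample_meta,
            self.lipid_meta.loc[lipid_ids],
            self.log_flag,
        )

    def labels(self) -> pd.Series:
        """Binary group labels for non-QC samples (cancer=1, control=0)."""
        bio = self.sample_meta.loc[~self.qc_mask, "group"]
        bad = bio[~bio.isin([GROUP_CONTROL, GROUP_CANCER])]
        if len(bad):
            raise DataError(f"sample {bad.index[0]!r} has group {bad.iloc[0]!r}")
        return (bio == GROUP_CANCER).astype(int)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            self.sample_meta.copy(),
            self.lipid_meta.copy(),
            self.log_flag,
        )

    def with_values(self, values: pd.DataFrame, log_flag: bool | None = None) -> "FeatureTable":
        return FeatureTable(
            values,
            self.sample_meta.copy(),
            self.lipid_meta.copy(),
            self.log_flag if log_flag is None else log_flag,
        )


# ---------------------------------------------------------------------- I/O
def write_feature_table(table: FeatureTable, directory: str | Path, prefix: str = "") -> dict:
    """Write a feature table to ``<prefix>values.csv / samples.csv / lipids.csv``.

    Returns the mapping of role -> written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": directory / f"{prefix}values.csv",
        "samples": directory / f"{prefix}samples.csv",
        "lipids": directory / f"{prefix}lipids.csv",
    }
    values = table.values.copy()
    values.insert(0, "log_flag", int(table.log_flag))
    values.to_csv(paths["values"], index_label="sample_id", float_format="%.17g")
    table.sample_meta.to_csv(paths["samples"], index_label="sample_id")
    table.lipid_meta.to_csv(paths["lipids"], index_label="lipid_id")
    return {k: str(p) for k, p in paths.items()}


def read_feature_table(directory: str | Path, prefix: str = "") -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    directory = Path(directory)
    values = pd.read_csv(directory / f"{prefix}values.csv", index_col="sample_id")
    log_flag = bool(values.pop("log_flag").iloc[0]) if "log_flag" in values else False
    values = values.astype(float)
    values.columns.name = "lipid_id"
    sample_meta = pd.read_csv(
        directory / f"{prefix}samples.csv",
        index_col="sample_id",
        dtype={"batch": str, "cohort": str},
        keep_default_na=True,
    )
    sample_meta["qc"] = sample_meta["qc"].astype(bool)
    lipid_meta = pd.read_csv(directory / f"{prefix}lipids.csv", index_col="lipid_id")
    return FeatureTable(values, sample_meta, lipid_meta, log_flag)
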