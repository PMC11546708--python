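"""Synthetic lipidomics cohorts with planted ground truth.

The generator emulates the statistical structure a plasma/EV lipid
biomarker-discovery analysis assumes: ~450 lipid species in ~15 classes,
log-normal concentrations with within-class correlation, a planted
discriminative lipid subset separating two groups (control vs cancer),
per-batch multiplicative effects, technical noise that is larger for
EV-derived than for plasma-derived measurements, pooled-reference QC
replicates in every batch, and matched EV/plasma tables sharing the same
biological latents.  Every downstream stage of the pipeline is testable
against the planted truth, and a closed-form Bayes AUC provides an oracle
for achievable classifier performance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import (
    FeatureTable,
    GROUP_CANCER,
    GROUP_CONTROL,
    LIPID_META_COLUMNS,
    SAMPLE_META_COLUMNS,
)
from .errors import ConfigurationError, DataError

#: canonical lipid class labels, most frequently annotated classes first
LIPID_CLASSES = [
    "TG", "PC", "LPC", "PE", "SM", "DG", "CE", "Cer", "PI", "PS",
    "PG", "LPE", "PA", "Hex1Cer", "FA", "LPI", "LPS", "PEt", "SPH", "ChE",
]

_STREAM = {"schema": 11, "bio": 23, "ev": 37, "plasma": 41, "qc": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[stream]]))


# --------------------------------------------------------------------- schema
def build_lipid_schema(
    n_lipids: int,
    n_classes: int,
    isomer_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a lipid metadata table (the schema of a feature table).

    Lipids are spread over ``n_classes`` classes with a skewed size
    distribution (a few large classes such as TG/PC dominate, as in real
    annotation runs).  A fraction ``isomer_rate`` of lipids is placed into
    multi-member isomer groups whose members share annotation and m/z.
    """
    if n_classes < 1 or n_lipids < 1:
        raise ConfigurationError("n_lipids and n_classes must be >= 1")
    if n_classes > n_lipids:
        raise ConfigurationError("n_classes may not exceed n_lipids")
    if not 0.0 <= isomer_rate < 1.0:
        raise ConfigurationError("isomer_rate must lie in [0, 1)")
    rng = _rng(seed, "schema")

    classes = [LIPID_CLASSES[i % len(LIPID_CLASSES)] + ("" if i < len(LIPID_CLASSES) else f"_{i}")
               for i in range(n_classes)]
    # geometric class weights -> skewed sizes; each class gets at least one lipid
    w = 0.75 ** np.arange(n_classes)
    w /= w.sum()
    sizes = np.ones(n_classes, dtype=int)
    extra = n_lipids - n_classes
    if extra > 0:
        alloc = np.floor(w * extra).astype(int)
        rem = extra - alloc.sum()
        order = np.argsort(-(w * extra - alloc), kind="stable")
        alloc[order[:rem]] += 1
        sizes += alloc

    lipid_class = np.repeat(classes, sizes)
    lipid_ids = [f"LID{i:04d}" for i in range(n_lipids)]
    carbons = rng.integers(12, 29, n_lipids) * 2  # even total carbon counts
    dbonds = rng.integers(0, 9, n_lipids)
    annotation = np.array(
        [f"{c} {cc}:{db}" for c, cc, db in zip(lipid_class, carbons, dbonds)]
    )
    mz = np.round(rng.uniform(400.0, 1000.0, n_lipids), 4)

    isomer_group = np.array(lipid_ids, dtype=object)
    n_isomeric = int(round(isomer_rate * n_lipids))
    if n_isomeric >= 2:
        placed = 0
        gid = 0
        # pair up lipids within a class so group members share class/annotation/mz
        class_pools = {c: list(np.flatnonzero(lipid_class == c)) for c in classes}
        pool_order = sorted(class_pools, key=lambda c: -len(class_pools[c]))
        for c in pool_order:
            pool = class_pools[c]
            while len(pool) >= 2 and placed + 2 <= n_isomeric:
                pick = rng.choice(len(pool), size=2, replace=False)
                a, b = sorted(pool[i] for i in pick)
                for i in sorted(pick, reverse=True):
                    pool.pop(i)
                isomer_group[a] = isomer_group[b] = f"IG{gid:04d}"
                annotation[b] = annotation[a]
                mz[b] = mz[a]
                gid += 1
                placed += 2
            if placed + 2 > n_isomeric:
                break

    schema = pd.DataFrame(
        {
            "lipid_class": lipid_class,
            "annotation": annotation,
            "mz": mz,
            "isomer_group": isomer_group,
        },
        index=pd.Index(lipid_ids, name="lipid_id"),
    )
    return schema[LIPID_META_COLUMNS]


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort generator.

    Defaults mirror the emulated study: 256 samples balanced over two groups,
    454 lipids in 15 classes, a planted 10-lipid discriminative subset with a
    one-unit log2 fold change, plasma concentrations a few-fold above EV with
    lower technical noise, and five pooled-reference QC replicates per batch.
    All effect sizes and SDs are on the log2 scale; tables are emitted on the
    linear scale.
    """

    n_control: int = 128
    n_cancer: int = 128
    n_lipids: int = 454
    n_classes: int = 15
    n_informative: int = 10
    effect_log2fc: float | tuple = 1.0
    within_class_corr: float = 0.3
    sigma_bio: float = 1.0
    sigma_tech_plasma: float = 0.15
    sigma_tech_ev: float = 0.45
    plasma_scale: float = 5.0
    n_batches: int = 4
    batch_sd: float = 0.15
    n_qc_replicates_per_batch: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_control": self.n_control,
            "n_cancer": self.n_cancer,
            "n_lipids": self.n_lipids,
            "n_classes": self.n_classes,
            "n_batches": self.n_batches,
            "n_qc_replicates_per_batch": self.n_qc_replicates_per_batch,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if self.n_informative < 0 or self.n_informative > self.n_lipids:
            raise ConfigurationError("n_informative must lie in [0, n_lipids]")
        if self.n_classes > self.n_lipids:
            raise ConfigurationError("n_classes may not exceed n_lipids")
        sds = {
            "within_class_corr": self.within_class_corr,
            "sigma_bio": self.sigma_bio,
            "sigma_tech_plasma": self.sigma_tech_plasma,
            "sigma_tech_ev": self.sigma_tech_ev,
            "batch_sd": self.batch_sd,
        }
        for name, v in sds.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.within_class_corr < 1.0:
            raise ConfigurationError("within_class_corr must lie in [0, 1)")
        if self.plasma_scale <= 0:
            raise ConfigurationError("plasma_scale must be > 0")

    def effects(self) -> np.ndarray:
        """Per-informative-lipid log2 fold changes as an array."""
        if np.isscalar(self.effect_log2fc):
            return np.full(self.n_informative, float(self.effect_log2fc))
        eff = np.asarray(self.effect_log2fc, dtype=float)
        if eff.shape != (self.n_informative,):
            raise ConfigurationError(
                "effect_log2fc sequence length must equal n_informative"
            )
        return eff

    def sigma_tech(self, sample_type: str) -> float:
        if sample_type == "plasma":
            return self.sigma_tech_plasma
        if sample_type == "ev":
            return self.sigma_tech_ev
        raise ConfigurationError(f"unknown sample_type {sample_type!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth: informative lipids, effects and batch factors."""

    informative_lipids: list
    effect_map: dict
    batch_factors: dict  # sample_type -> batch -> lipid_id -> linear factor

    def __post_init__(self) -> None:
        if set(self.effect_map) != set(self.informative_lipids):
            raise ConfigurationError("effect_map keys must equal informative_lipids")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ----------------------------------------------------------------- simulation
def _informative_indices(config: GeneratorConfig, schema: pd.DataFrame) -> np.ndarray:
    """Pick informative lipids spread over distinct classes when possible.

    Spreading keeps planted effects mutually independent under the one-factor
    per-class correlation model, which is what the closed-form Bayes AUC
    oracle assumes.
    """
    rng = _rng(config.seed, "schema")
    classes = schema["lipid_class"].to_numpy()
    uniq = list(dict.fromkeys(classes))
    idx = []
    if config.n_informative <= len(uniq):
        for c in uniq[: config.n_informative]:
            pool = np.flatnonzero(classes == c)
            idx.append(int(rng.choice(pool)))
    else:
        idx = list(rng.choice(len(classes), config.n_informative, replace=False))
    return np.array(sorted(idx), dtype=int)


def _biological_latents(config: GeneratorConfig, schema: pd.DataFrame):
    """Draw group labels and per-sample biological log2 abundances.

    Returns (Z, groups, baseline, informative_idx, effects) with Z of shape
    (n_samples, n_lipids) on the log2 scale, before batch/technical effects.
    """
    rng = _rng(config.seed, "bio")
    n = config.n_control + config.n_cancer
    p = config.n_lipids
    classes = schema["lipid_class"].to_numpy()
    uniq = list(dict.fromkeys(classes))
    class_idx = np.array([uniq.index(c) for c in classes])

    class_mean = rng.uniform(6.0, 14.0, len(uniq))
    lipid_offset = rng.normal(0.0, 1.5, p)
    baseline = class_mean[class_idx] + lipid_offset

    groups = np.array([0] * config.n_control + [1] * config.n_cancer)

    rho = config.within_class_corr
    factor = rng.normal(size=(n, len(uniq)))
    eps = rng.normal(size=(n, p))
    z = config.sigma_bio * (
        np.sqrt(rho) * factor[:, class_idx] + np.sqrt(1.0 - rho) * eps
    )
    z += baseline

    informative = _informative_indices(config, schema)
    effects = config.effects()
    if len(informative):
        z[np.ix_(groups == 1, informative)] += effects
    return z, groups, baseline, informative, effects


def _batch_assignment(config: GeneratorConfig, groups: np.ndarray) -> np.ndarray:
    """Round-robin batches within each group, so groups balance per batch."""
    batch = np.empty(len(groups), dtype=int)
    for g in (0, 1):
        pos = np.flatnonzero(groups == g)
        batch[pos] = np.arange(len(pos)) % config.n_batches
    return batch


def _measure(
    config: GeneratorConfig,
    schema: pd.DataFrame,
    z_bio: np.ndarray,
    groups: np.ndarray,
    baseline: np.ndarray,
    sample_type: str,
    subject_ids: list,
):
    """Apply batch + technical effects and assemble a FeatureTable."""
    rng = _rng(config.seed, sample_type)
    n, p = z_bio.shape
    batch = _batch_assignment(config, groups)
    batch_delta = rng.normal(0.0, config.batch_sd, size=(config.n_batches, p))
    if config.batch_sd == 0:
        batch_delta[:] = 0.0
    sigma_t = config.sigma_tech(sample_type)
    tech = rng.normal(0.0, sigma_t, size=(n, p)) if sigma_t > 0 else np.zeros((n, p))
    log2_scale = np.log2(config.plasma_scale) if sample_type == "plasma" else 0.0

    z = z_bio + batch_delta[batch] + tech + log2_scale
    sample_ids = [f"{sample_type.upper()}{i:04d}" for i in range(n)]

    # pooled-reference QC replicates, one fixed profile re-measured per batch
    n_qc = config.n_batches * config.n_qc_replicates_per_batch
    qc_tech = rng.normal(0.0, sigma_t, size=(n_qc, p)) if sigma_t > 0 else np.zeros((n_qc, p))
    qc_batch = np.repeat(np.arange(config.n_batches), config.n_qc_replicates_per_batch)
    z_qc = baseline + batch_delta[qc_batch] + qc_tech + log2_scale
    qc_ids = [
        f"QC_{sample_type.upper()}_B{b}_{r}"
        for b in range(config.n_batches)
        for r in range(config.n_qc_replicates_per_batch)
    ]

    values = pd.DataFrame(
        np.power(2.0, np.vstack([z, z_qc])),
        index=pd.Index(sample_ids + qc_ids, name="sample_id"),
        columns=schema.index,
    )
    sample_meta = pd.DataFrame(
        {
            "group": [GROUP_CANCER if g else GROUP_CONTROL for g in groups]
            + [None] * n_qc,
            "cohort": "C1",
            "batch": [f"B{b}" for b in np.concatenate([batch, qc_batch])],
            "qc": [False] * n + [True] * n_qc,
            "subject_id": subject_ids + [None] * n_qc,
            "sample_type": sample_type,
        },
        index=values.index,
    )[SAMPLE_META_COLUMNS]
    table = FeatureTable(values, sample_meta, schema.copy(), log_flag=False)
    factors = {
        f"B{b}": {
            lid: float(2.0 ** batch_delta[b, j])
            for j, lid in enumerate(schema.index)
        }
        for b in range(config.n_batches)
    }
    return table, factors


def simulate_cohort(
    config: GeneratorConfig,
    schema: pd.DataFrame,
    sample_type: str = "plasma",
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate one cohort of the given sample type with planted truth."""
    if len(schema) != config.n_lipids:
        raise ConfigurationError(
            f"schema has {len(schema)} lipids but config.n_lipids={config.n_lipids}"
        )
    config.sigma_tech(sample_type)  # validates the type
    z, groups, baseline, informative, effects = _biological_latents(config, schema)
    subjects = [f"SUBJ{i:04d}" for i in range(len(groups))]
    table, factors = _measure(config, schema, z, groups, baseline, sample_type, subjects)
    lipid_ids = schema.index.to_numpy()
    truth = SyntheticTruth(
        informative_lipids=[str(lipid_ids[i]) for i in informative],
        effect_map={str(lipid_ids[i]): float(e) for i, e in zip(informative, effects)},
        batch_factors={sample_type: factors},
    )
    return table, truth


def simulate_matched_pair(
    config: GeneratorConfig,
    schema: pd.DataFrame,
) -> tuple[FeatureTable, FeatureTable, SyntheticTruth]:
    """Simulate matched EV and plasma tables sharing biological latents.

    Both tables observe the same per-subject biological abundances; they
    differ by the plasma concentration scale, independent batch factors and
    independent technical noise, so per-subject cross-table correlation is
    high when biological variation dominates technical noise.
    """
    if len(schema) != config.n_lipids:
        raise ConfigurationError(
            f"schema has {len(schema)} lipids but config.n_lipids={config.n_lipids}"
        )
    z, groups, baseline, informative, effects = _biological_latents(config, schema)
    subjects = [f"SUBJ{i:04d}" for i in range(len(groups))]
    ev, f_ev = _measure(config, schema, z, groups, baseline, "ev", subjects)
    plasma, f_pl = _measure(config, schema, z, groups, baseline, "plasma", subjects)
    lipid_ids = schema.index.to_numpy()
    truth = SyntheticTruth(
        informative_lipids=[str(lipid_ids[i]) for i in informative],
        effect_map={str(lipid_ids[i]): float(e) for i, e in zip(informative, effects)},
        batch_factors={"ev": f_ev, "plasma": f_pl},
    )
    return ev, plasma, truth


# --------------------------------------------------------------------- oracle
def analytic_bayes_auc(
    config: GeneratorConfig,
    sample_type: str = "plasma",
    cov: np.ndarray | None = None,
) -> float:
    """Closed-form AUC of the Bayes-optimal rule under the generator model.

    With Gaussian log2 abundances the optimal score is linear and
    AUC = Phi(Delta / sqrt(2)) where Delta is the Mahalanobis distance
    between the group means.  Without an explicit covariance the informative
    lipids are treated as independent with total log2 variance
    sigma_bio^2 + sigma_tech^2 + batch_sd^2; this requires either
    within_class_corr = 0 or informative lipids in distinct classes (which
    the generator guarantees whenever n_informative <= n_classes).
    """
    delta = config.effects()
    if len(delta) == 0:
        return 0.5
    if cov is None:
        if config.within_class_corr > 0 and config.n_informative > config.n_classes:
            raise ConfigurationError(
                "independent-feature closed form needs within_class_corr=0 or "
                "informative lipids in distinct classes; supply cov explicitly"
            )
        var = (
            config.sigma_bio**2
            + config.sigma_tech(sample_type) ** 2
            + config.batch_sd**2
        )
        maha_sq = float(np.sum(delta**2) / var)
    else:
        cov = np.asarray(cov, dtype=float)
        try:
            sol = np.linalg.solve(cov, delta)
        except np.linalg.LinAlgError as exc:
            raise DataError(f"covariance is singular: {exc}") from exc
        maha_sq = float(delta @ sol)
        if maha_sq < 0 or not np.all(np.linalg.eigvalsh(cov) > 0):
            raise DataError("covariance must be positive definite")
    return float(norm.cdf(np.sqrt(maha_sq) / np.sqrt(2.0)))
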