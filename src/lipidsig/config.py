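"""Declarative pipeline configuration (YAML or JSON) with schema validation.

A single config file drives every CLI stage.  All randomness flows from the
mandatory root ``seed`` through named per-stage substreams; compute scale is
set by a ``profile`` (``full`` mirrors the emulated study protocol —
2000 LGOCV iterations, 50 nested tuning splits, 500-tree forests; ``ci``
and ``smoke`` scale engines down for fast runs) and any field can be
overridden explicitly.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

PROFILE_DEFAULTS = {
    "full": {
        "splits": {"n_iter": 2000},
        "tuning": {"n_nested": 50, "tune_len": 10},
        "boruta": {"n_iter": 100, "n_trees": 500, "importance_kind": "permutation_z"},
    },
    "ci": {
        "splits": {"n_iter": 100},
        "tuning": {"n_nested": 10, "tune_len": 10},
        "boruta": {"n_iter": 100, "n_trees": 100, "importance_kind": "impurity_fast"},
    },
    "smoke": {
        "splits": {"n_iter": 10},
        "tuning": {"n_nested": 3, "tune_len": 2},
        "boruta": {"n_iter": 25, "n_trees": 50, "importance_kind": "impurity_fast"},
    },
}

#: published schema: key -> (type, min, max) or (type, allowed values)
SCHEMA = {
    "seed": (int, 0, 2**31 - 1),
    "out_dir": (str,),
    "profile": (str, tuple(PROFILE_DEFAULTS)),
    "generator.n_control": (int, 1, 10**6),
    "generator.n_cancer": (int, 1, 10**6),
    "generator.n_lipids": (int, 1, 10**5),
    "generator.n_classes": (int, 1, 10**4),
    "generator.n_informative": (int, 0, 10**5),
    "generator.effect_log2fc": (float, -10.0, 10.0),
    "generator.within_class_corr": (float, 0.0, 0.999),
    "generator.sigma_bio": (float, 0.0, 100.0),
    "generator.sigma_tech_plasma": (float, 0.0, 100.0),
    "generator.sigma_tech_ev": (float, 0.0, 100.0),
    "generator.plasma_scale": (float, 1e-6, 1e6),
    "generator.n_batches": (int, 1, 1000),
    "generator.batch_sd": (float, 0.0, 100.0),
    "generator.n_qc_replicates_per_batch": (int, 1, 1000),
    "generator.isomer_rate": (float, 0.0, 0.999),
    "generator.sample_type": (str, ("ev", "plasma", "both")),
    "preprocess.pseudo": (float, 0.0, 1.0),
    "preprocess.normalize": (bool,),
    "da_panel.fc_min": (float, 1.0, 100.0),
    "da_panel.q_max": (float, 1e-9, 1.0),
    "da_panel.stepwise": (bool,),
    "splits.n_iter": (int, 1, 10**6),
    "splits.test_fraction": (float, 1e-9, 0.999999),
    "splits.stratified": (bool,),
    "tuning.n_nested": (int, 1, 10**4),
    "tuning.tune_len": (int, 1, 10**4),
    "boruta.n_iter": (int, 1, 10**5),
    "boruta.n_trees": (int, 1, 10**5),
    "boruta.alpha": (float, 1e-12, 0.999999),
    "boruta.importance_kind": (str, ("permutation_z", "impurity", "impurity_fast")),
    "signature_size": (int, 1, 10**4),
}

DEFAULTS = {
    "out_dir": "results",
    "profile": "ci",
    "generator": {
        "n_control": 128,
        "n_cancer": 128,
        "n_lipids": 454,
        "n_classes": 15,
        "n_informative": 10,
        "effect_log2fc": 1.0,
        "within_class_corr": 0.3,
        "sigma_bio": 1.0,
        "sigma_tech_plasma": 0.15,
        "sigma_tech_ev": 0.45,
        "plasma_scale": 5.0,
        "n_batches": 4,
        "batch_sd": 0.15,
        "n_qc_replicates_per_batch": 5,
        "isomer_rate": 0.05,
        "sample_type": "both",
    },
    "preprocess": {"pseudo": 2.0**-20, "normalize": True},
    "da_panel": {"fc_min": 1.2, "q_max": 0.05, "blocking": ["cohort"], "stepwise": True},
    "splits": {"test_fraction": 0.2, "stratified": True},
    "boruta": {"alpha": 0.01},
    "tuning": {},
    "classifiers": None,  # None -> default eight-member suite
    "signature_size": 20,
    "sensitivity_sizes": list(range(14, 31)),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :data:`SCHEMA`)."""

    seed: int
    out_dir: str
    profile: str
    generator: dict
    preprocess: dict
    da_panel: dict
    splits: dict
    boruta: dict
    tuning: dict
    classifiers: list | None
    signature_size: int
    sensitivity_sizes: list

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """sha256 of the canonical (key-sorted) JSON form."""
        canonical = json.dumps(self.as_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed derived from the root seed."""
        return (self.seed * 2654435761 + zlib.crc32(stage.encode())) % 2**31


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _check(key: str, value):
    rule = SCHEMA.get(key)
    if rule is None:
        return value
    typ = rule[0]
    if typ is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if typ is int and isinstance(value, bool):
        raise ConfigurationError(f"config key {key!r}: expected int, got bool")
    if not isinstance(value, typ):
        raise ConfigurationError(
            f"config key {key!r}: expected {typ.__name__}, got {type(value).__name__}"
        )
    if len(rule) == 2 and isinstance(rule[1], tuple):
        if value not in rule[1]:
            raise ConfigurationError(
                f"config key {key!r}: {value!r} not in {sorted(rule[1])}"
            )
    elif len(rule) == 3:
        lo, hi = rule[1], rule[2]
        if not lo <= value <= hi:
            raise ConfigurationError(
                f"config key {key!r}: {value!r} outside [{lo}, {hi}]"
            )
    return value


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Load and validate a pipeline config from YAML/JSON file or dict."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    if "seed" not in raw:
        raise ConfigurationError("config key 'seed' is mandatory")

    merged = _merge(DEFAULTS, raw)
    profile = _check("profile", merged.get("profile", "ci"))
    # profile defaults fill engine-scale fields the user did not set
    for section, values in PROFILE_DEFAULTS[profile].items():
        for k, v in values.items():
            merged.setdefault(section, {})
            user = raw.get(section, {}) if isinstance(raw.get(section), dict) else {}
            if k not in user:
                merged[section][k] = v

    seed = _check("seed", merged["seed"])
    for section in ("generator", "preprocess", "da_panel", "splits", "boruta", "tuning"):
        sect = merged.get(section)
        if not isinstance(sect, dict):
            raise ConfigurationError(f"config section {section!r} must be a mapping")
        for k, v in sect.items():
            full = f"{section}.{k}"
            if isinstance(v, (int, float, str, bool)):
                sect[k] = _check(full, v)
    sig = _check("signature_size", merged["signature_size"])

    return PipelineConfig(
        seed=seed,
        out_dir=str(merged["out_dir"]),
        profile=profile,
        generator=merged["generator"],
        preprocess=merged["preprocess"],
        da_panel=merged["da_panel"],
        splits=merged["splits"],
        boruta=merged["boruta"],
        tuning=merged["tuning"],
        classifiers=merged.get("classifiers"),
        signature_size=sig,
        sensitivity_sizes=list(merged["sensitivity_sizes"]),
    )
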