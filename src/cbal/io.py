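"""Trace/report I/O, experiment configuration and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ValidationError
from .strategies import RunConfig
from .synthetic import PoolSpec

TRACE_COLUMNS = [
    "t", "n_minority", "n_majority", "added_minority", "added_majority",
    "N_t", "L", "accuracy", "auc",
]

#: experiment presets mirroring the three study harnesses
EXPERIMENT_PRESETS = {
    # strategy comparison: T=40, tau=0.25, K=2 (quotas 1/1), 10 trials
    "experiment1": {
        "pool": {"n_total": 12588, "minority_fraction": 0.04, "class_separation": 2.0, "dim": 14},
        "run": {"T": 40, "tau": 0.25, "k1_hat": 1, "k2_hat": 1, "m": 10},
        "strategies": ["cbal", "ubal", "cbrl", "ubrl", "full"],
        "n_trials": 10,
        "test_fraction": 1346 / 12588,
    },
    # class-ratio sweep: K=10, minority share 20%..80%
    "experiment2": {
        "pool": {"n_total": 12588, "minority_fraction": 0.04, "class_separation": 2.0, "dim": 14},
        "run": {"T": 40, "tau": 0.25, "m": 10},
        "ratios": [(2, 8), (4, 6), (5, 5), (6, 4), (8, 2)],
        "n_trials": 3,
        "test_fraction": 1346 / 12588,
    },
    # cost-model validation: p0 = 0.04, predicted vs observed N_t
    "experiment3": {
        "pool": {"n_total": 11242, "minority_fraction": 0.04, "class_separation": 2.0, "dim": 14},
        "run": {"T": 40, "k1_hat": 1, "k2_hat": 1},
        "p0": 0.04,
        "n_replicates": 50,
    },
}


def write_trace(trace_df: pd.DataFrame, path) -> None:
    """Write a run trace as CSV with the documented header."""
    missing = [c for c in TRACE_COLUMNS if c not in trace_df.columns]
    if missing:
        raise ValidationError(f"trace missing columns: {missing}")
    trace_df[TRACE_COLUMNS].to_csv(path, index=False)


def read_trace(path) -> pd.DataFrame:
    """Read a trace CSV back; lossless round trip of write_trace."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trace file {path} missing columns: {missing}")
    return df[TRACE_COLUMNS]


def load_config(path) -> dict:
    """Load and schema-check a YAML experiment configuration.

    Recognized top-level keys: ``preset`` (one of the experiment presets)
    or explicit ``pool`` / ``run`` / ``strategies`` sections, plus
    ``seed``, ``n_trials``, ``test_fraction``, ``outdir``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    if "preset" in raw:
        name = raw["preset"]
        if name not in EXPERIMENT_PRESETS:
            raise ValidationError(f"preset: unknown preset {name!r}")
        merged = {**EXPERIMENT_PRESETS[name], **{k: v for k, v in raw.items() if k != "preset"}}
        merged["preset"] = name
        raw = merged
    for section, cls in (("pool", PoolSpec), ("run", RunConfig)):
        if section in raw:
            valid = set(cls.__dataclass_fields__)
            bad = set(raw[section]) - valid
            if bad:
                raise ValidationError(f"{section}: unknown fields {sorted(bad)}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        raise ValidationError("seed: must be an integer")
    return raw


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(outdir, config: dict, seeds: dict, extra: dict | None = None) -> Path:
    """Machine-readable run manifest: config hash, seeds, package version."""
    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def pool_spec_from_config(config: dict, seed: int) -> PoolSpec:
    return PoolSpec(**{**config.get("pool", {}), "seed": seed})


def run_config_from_config(config: dict, strategy: str, seed: int) -> RunConfig:
    return RunConfig(**{**config.get("run", {}), "strategy": strategy, "seed": seed})


def asdict_config(cfg) -> dict:
    return asdict(cfg)
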