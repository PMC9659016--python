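"""Delimited-text I/O, run configuration and provenance headers.

All tabular artifacts are comma-delimited text with a fixed header; every
file written by the package starts with ``#``-prefixed provenance lines
(package version, seed, config hash) which readers skip.  Weights and run
configuration travel as JSON (YAML also accepted for configs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import InvalidInputError, SchemaError
from .synthdata import EXPERIMENT_COLUMNS

__all__ = [
    "read_experiment_csv",
    "write_experiment_csv",
    "write_table_csv",
    "read_table_csv",
    "config_hash",
    "RunConfig",
]


def config_hash(config: dict | None) -> str:
    """Short deterministic hash of a JSON-serialisable configuration."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance_lines(seed, config) -> str:
    return (
        f"# berryopt {__version__}\n"
        f"# seed={seed if seed is not None else 'none'} "
        f"config_sha={config_hash(config)}\n"
    )


def write_table_csv(table: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write any DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(seed, config))
        table.to_csv(fh, index=False, float_format="%.12g")


def read_table_csv(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table_csv` (or any plain CSV)."""
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None


def write_experiment_csv(table: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write an experiment table, enforcing the canonical column schema."""
    missing = set(EXPERIMENT_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"experiment table missing columns: {sorted(missing)}")
    write_table_csv(table[list(EXPERIMENT_COLUMNS)], path, seed=seed, config=config)


def read_experiment_csv(path) -> pd.DataFrame:
    """Read an experiment table, validating the exact column schema.

    Raises :class:`SchemaError` naming any missing or unknown column; an
    empty file is an error.  Values round-trip losslessly at 12
    significant digits.
    """
    table = read_table_csv(path)
    missing = [c for c in EXPERIMENT_COLUMNS if c not in table.columns]
    extra = [c for c in table.columns if c not in EXPERIMENT_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"{path}: schema mismatch — missing columns {missing}, "
            f"unknown columns {extra}"
        )
    if len(table) == 0:
        raise SchemaError(f"{path}: table has a header but no rows")
    table = table[list(EXPERIMENT_COLUMNS)]
    return table.astype({c: (int if c == "rep" else float) for c in table.columns})


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration.

    Sections mirror the pipeline stages; unknown keys are rejected so a
    typo cannot silently fall back to a default.
    """

    seed: int = 0
    out_dir: str = "berryopt_out"
    synthdata: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    nsga2: dict = field(default_factory=dict)
    report_policy: str = "min_DT"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InvalidInputError(f"config file not found: {path}")
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        data = data or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "synthdata": self.synthdata,
            "training": self.training,
            "nsga2": self.nsga2,
            "report_policy": self.report_policy,
        }
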