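"""Reading and writing the tabular formats used by the pipeline.

Input is a TSV/CSV long table with a header row and columns
protein_id, experiment, group, sample, replicate, value.  Outputs are
plain TSVs (statistics, classification, cost curve), JSON (models, test
results) and a JSON manifest recording the exact configuration and seed of
a run so two runs with equal manifests are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .anova_vc import REQUIRED_COLUMNS, AbundanceTable, ConsistencyStats

__all__ = [
    "RunConfig",
    "load_config",
    "read_abundance",
    "read_statistics",
    "write_statistics",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    input: str
    outdir: str
    criterion: str = "bic"
    boot: int = 500
    alpha: float = 0.05
    gamma: float = 0.5
    truncate: bool = True
    seed: int = 0
    verbose: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.criterion.lower() not in ("aic", "bic", "hq"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.boot < 1:
            raise ValueError("boot must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "outdir": self.outdir,
            "criterion": self.criterion,
            "boot": self.boot,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "truncate": self.truncate,
            "seed": self.seed,
        }


def load_config(path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = {k for k in RunConfig.__dataclass_fields__ if k != "extra"}
    extra = {k: v for k, v in raw.items() if k not in known}
    kwargs = {k: v for k, v in raw.items() if k in known}
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs, extra=extra)


def _read_delim(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_abundance(path) -> AbundanceTable:
    """Read and validate a long-format abundance table (TSV or CSV)."""
    df = _read_delim(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad = df[pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()]
    if len(bad):
        lines = (bad.index + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric value(s) at line(s) {lines}")
    df["value"] = pd.to_numeric(df["value"])
    tbl = AbundanceTable(df)
    tbl.validate()
    return tbl


def read_statistics(path) -> pd.DataFrame:
    """Read a per-protein statistics table; needs protein_id and z columns."""
    df = _read_delim(path)
    for c in ("protein_id", "z"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    return df


def write_statistics(stats: ConsistencyStats, path) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(path, cfg: RunConfig, status: str = "OK", **extras) -> None:
    from . import __version__

    payload = {"config": cfg.to_dict(), "status": status, "version": __version__, **extras}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
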