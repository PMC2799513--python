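"""File formats and configuration shared by all pipeline stages.

Formats are plain text with pinned dialects (UTF-8, "." decimal, no thousands
separators): expression matrices and metadata as TSV, gene sets as GMT, QPCR
amplification tables as CSV, statistics and planted truth as JSON.  Gene
identifiers are opaque strings.  All readers reject malformed input with an
error naming the offending line or identifier; write-then-read round trips are
identities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .epig import EpigParams
from .qpcr_damage import AmpliconSpec, ConfigurationError, DataError, DEFAULT_AMPLICONS


class ParseError(DataError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Expression matrices and metadata
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (gene-id first column, sample-id header)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pandas raises various parser errors
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        line = df.index.get_loc(bad.index[0]) + 2  # +1 header, +1 1-based
        raise ParseError(f"{path}: non-numeric value {bad.iloc[0]!r} at line {line}")
    if df.isna().any().any():
        n = int(df.isna().sum().sum())
        import logging
        logging.getLogger(__name__).info("%s: %d missing values", path, n)
    df.index.name = "gene_id"
    return df


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id column required)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated name, description, genes.

    Duplicate genes within a set are de-duplicated with a warning; empty sets
    and short lines are rejected with the line number.
    """
    import logging
    log = logging.getLogger(__name__)
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            log.warning("%s:%d: set %r has duplicate genes; de-duplicated", path, lineno, name)
        sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# QPCR amplification tables
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "group", "target", "signal"]


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a QPCR CSV with columns sample_id, group, target, signal."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "target": str})
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["signal"]):
        bad = df["signal"][pd.to_numeric(df["signal"], errors="coerce").isna()]
        raise ParseError(f"{path}: non-numeric signal at line {bad.index[0] + 2}")
    return df[QPCR_COLUMNS]


def write_qpcr_table(table: pd.DataFrame, path: str | Path) -> None:
    table[QPCR_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def write_json(obj: Any, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds, amplicon panel, and stochastic-stage settings for a run."""

    seed: int
    fdr_threshold_percent: float = 1.0
    gsa_p_threshold: float = 0.01
    consensus_fraction: float = 0.25
    damage_threshold_per_10kb: float = 0.85
    stratify_threshold_ddct: float = -2.5
    n_perm: int = 200
    epig: EpigParams = field(default_factory=EpigParams)
    amplicons: tuple[AmpliconSpec, ...] = DEFAULT_AMPLICONS

    def __post_init__(self) -> None:
        if self.fdr_threshold_percent < 0:
            raise ConfigurationError("fdr_threshold_percent must be >= 0")
        if not 0 < self.gsa_p_threshold <= 1:
            raise ConfigurationError("gsa_p_threshold must be in (0, 1]")
        if not 0 < self.consensus_fraction <= 1:
            raise ConfigurationError("consensus_fraction must be in (0, 1]")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for stochastic stages")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "epig" in raw:
            raw["epig"] = EpigParams(**raw["epig"])
        if "amplicons" in raw:
            raw["amplicons"] = tuple(AmpliconSpec(**a) for a in raw["amplicons"])
        return cls(**raw)
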