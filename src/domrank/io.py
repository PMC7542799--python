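"""CSV/JSON readers and writers and run configuration.

All tables are UTF-8 CSV with a header row and ISO dates; run configuration
is a single JSON document. There is no standard interchange format for
agonistic-interaction data, so plain CSV keeps the package's inputs
readable, diffable and writable from any field database export.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compare import DEFAULT_AIC_THRESHOLD, MetricComparison, ModelSpec, TallyResult
from .hierarchy import BOUT_COLUMNS
from .rank_metrics import RANK_COLUMNS

__all__ = [
    "read_bouts",
    "write_bouts",
    "read_ranks",
    "write_ranks",
    "read_traits",
    "write_results",
    "RunConfig",
    "TraitBlock",
    "config_hash",
]

logger = logging.getLogger("domrank")

RESULT_COLUMNS = [
    "trait",
    "sex",
    "aic_ordinal",
    "aic_proportional",
    "aic_null",
    "delta",
    "classification",
]


def read_bouts(path) -> pd.DataFrame:
    """Read and validate a bout table (``date,group,sex,winner,loser``).

    Malformed rows — unparseable dates or a bout whose winner and loser are
    the same individual — are reported with their file line numbers
    (header = line 1).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    errors = []
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    for i in np.flatnonzero(parsed.isna().to_numpy()):
        errors.append(f"line {i + 2}: unparseable date {df['date'].iloc[i]!r}")
    same = df["winner"] == df["loser"]
    for i in np.flatnonzero(same.to_numpy()):
        errors.append(
            f"line {i + 2}: winner equals loser ({df['winner'].iloc[i]!r})"
        )
    null_rows = df[BOUT_COLUMNS].isna().any(axis=1)
    for i in np.flatnonzero(null_rows.to_numpy()):
        errors.append(f"line {i + 2}: missing field")
    if errors:
        raise ValueError(f"{path}: invalid bout rows:\n" + "\n".join(errors))
    return df[BOUT_COLUMNS].copy()


def write_bouts(bouts: pd.DataFrame, path) -> None:
    bouts[BOUT_COLUMNS].to_csv(path, index=False)


def read_ranks(path) -> pd.DataFrame:
    """Read a rank table (``individual,period,group,sex,ordinal,n,proportional``)."""
    df = pd.read_csv(
        path,
        dtype={
            "individual": str,
            "period": str,
            "group": str,
            "sex": str,
        },
    )
    missing = [c for c in RANK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[RANK_COLUMNS].copy()


def write_ranks(ranks: pd.DataFrame, path) -> None:
    out = ranks[RANK_COLUMNS].sort_values(
        ["group", "sex", "period", "ordinal"], kind="mergesort"
    )
    out.to_csv(path, index=False, float_format="%.6f")


def read_traits(path) -> pd.DataFrame:
    """Read a trait table (``individual,period,...`` plus trait/covariates)."""
    df = pd.read_csv(path, dtype={"individual": str, "period": str})
    for col in ("individual", "period"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_results(
    comparisons: Sequence[MetricComparison],
    tally: Optional[TallyResult],
    path,
) -> None:
    """Write the per-trait comparison table and the tally summary.

    The comparison table goes to ``path`` (deterministic column order, rows
    sorted by trait then sex, AICs at fixed 6-decimal precision); the tally
    goes to a JSON sidecar named ``<path stem>_tally.json``.
    """
    path = Path(path)
    rows = sorted(comparisons, key=lambda c: (c.trait, c.sex))
    table = pd.DataFrame(
        [
            {
                "trait": c.trait,
                "sex": c.sex,
                "aic_ordinal": c.aic_ordinal,
                "aic_proportional": c.aic_proportional,
                "aic_null": c.aic_null,
                "delta": c.delta_metrics,
                "classification": c.classification,
            }
            for c in rows
        ],
        columns=RESULT_COLUMNS,
    )
    table.to_csv(path, index=False, float_format="%.6f")
    if tally is not None:
        sidecar = path.with_name(path.stem + "_tally.json")
        sidecar.write_text(
            json.dumps(
                {
                    "counts": tally.counts,
                    "binomial_p": tally.binomial_p,
                    "fisher_p": tally.fisher_p,
                    "table": tally.table,
                },
                indent=2,
            )
            + "\n"
        )


@dataclass
class TraitBlock:
    """Per-trait model description from the run configuration."""

    name: str
    sex: str = ""
    response: str = "trait"
    family: str = "gaussian"
    covariates: tuple[str, ...] = ()
    random_effect: Optional[str] = None
    event_col: Optional[str] = None

    def to_model_spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response,
            family=self.family,
            covariates=tuple(self.covariates),
            random_effect=self.random_effect,
            event_col=self.event_col,
        )


@dataclass
class RunConfig:
    """Whole-run settings: windows, thresholds, conventions, seed, models."""

    threshold: float = DEFAULT_AIC_THRESHOLD
    window: int = 1
    maternal_convention: str = "measurement"
    seed: Optional[int] = None
    traits: list[TraitBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.window < 1:
            raise ValueError("window must be at least 1 month")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {"threshold", "window", "maternal_convention", "seed", "traits"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        blocks = [TraitBlock(**b) for b in raw.pop("traits", [])]
        return cls(traits=blocks, **raw)


def config_hash(path) -> str:
    """Short content hash for provenance logging of a config file."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
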