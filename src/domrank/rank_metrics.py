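"""Ordinal and proportional dominance rank metrics.

Simple ordinal rank is an individual's integer position in the hierarchy
(1 = most dominant). Proportional (also called relative or standardized)
rank rescales that position by hierarchy size::

    proportional = 1 - (ordinal - 1) / (n - 1)

so it equals the fraction of other hierarchy members the individual
outranks: 1 at the top, 0 at the bottom, for every hierarchy size. The two
metrics are perfectly correlated while hierarchy size is constant and
diverge as soon as it varies — across groups or over time — which is what
makes comparing them informative about the underlying competitive regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import HierarchyOrdering

__all__ = [
    "proportional_rank",
    "rank_table",
    "assign_maternal_rank",
    "metric_divergence",
    "DivergenceSeries",
    "RANK_COLUMNS",
]

RANK_COLUMNS = ["individual", "period", "group", "sex", "ordinal", "n", "proportional"]


def proportional_rank(ordinal: int, hierarchy_size: int) -> float:
    """Proportion of other hierarchy members that this individual outranks.

    Returns a value in [0, 1]: 1 for the top-ranked individual, 0 for the
    bottom. For a single-member hierarchy the quantity is undefined (there
    is nobody to outrank) and NaN is returned with a warning.
    """
    if hierarchy_size < 1:
        raise ValueError("hierarchy size must be at least 1")
    if not 1 <= ordinal <= hierarchy_size:
        raise ValueError(
            f"ordinal rank {ordinal} outside 1..{hierarchy_size}"
        )
    if hierarchy_size == 1:
        warnings.warn(
            "proportional rank undefined for a single-member hierarchy",
            stacklevel=2,
        )
        return math.nan
    return 1.0 - (ordinal - 1) / (hierarchy_size - 1)


def rank_table(orderings: Iterable[HierarchyOrdering]) -> pd.DataFrame:
    """One rank record per individual-period from a set of orderings.

    Ordinal rank is the position in ``ranked_ids`` (1 = top); proportional
    rank follows from the standardization formula. Single-member hierarchies
    yield NaN proportional ranks.
    """
    rows = []
    seen_keys = set()
    for o in orderings:
        key = (o.period, o.group, o.sex)
        if key in seen_keys:
            raise ValueError(f"duplicate ordering for {key}")
        seen_keys.add(key)
        if len(set(o.ranked_ids)) != len(o.ranked_ids):
            raise ValueError(f"duplicate individual in ordering for {key}")
        n = len(o.ranked_ids)
        for k, ind in enumerate(o.ranked_ids, start=1):
            prop = math.nan if n == 1 else 1.0 - (k - 1) / (n - 1)
            rows.append((ind, o.period, o.group, o.sex, k, n, prop))
    return pd.DataFrame(rows, columns=RANK_COLUMNS)


def assign_maternal_rank(
    immature_id: str,
    mother_id: str,
    trait_period: str,
    ranks: pd.DataFrame,
    convention: str = "measurement",
    birth_period: Optional[str] = None,
) -> Optional[pd.Series]:
    """Look up the mother's rank record to use as an immature's predictor.

    ``convention`` selects the reference month: ``"measurement"`` (default)
    uses the trait-measurement month; ``"birth"`` uses the immature's birth
    month, which must then be supplied. Returns the mother's rank record
    (a row of ``ranks``) or None, with a warning, if she has no record in
    the reference month.
    """
    if convention == "measurement":
        period = trait_period
    elif convention == "birth":
        if birth_period is None:
            raise ValueError("birth convention requires birth_period")
        period = birth_period
    else:
        raise ValueError(f"unknown maternal-rank convention {convention!r}")

    hit = ranks[(ranks["individual"] == mother_id) & (ranks["period"] == period)]
    if hit.empty:
        warnings.warn(
            f"no rank record for mother {mother_id} of {immature_id} in "
            f"{period} ({convention} convention)",
            stacklevel=2,
        )
        return None
    return hit.iloc[0]


@dataclass
class DivergenceSeries:
    """Paired rank trajectories for one individual and their agreement.

    ``correlation`` is the Spearman rank correlation between the negated
    ordinal trajectory and the proportional trajectory: exactly 1 whenever
    hierarchy size is constant (the metrics are then affinely related), and
    lower when size changes pull the two metrics apart.
    """

    individual: str
    periods: list[str]
    ordinal: np.ndarray
    proportional: np.ndarray
    hierarchy_size: np.ndarray
    correlation: float


def metric_divergence(records: pd.DataFrame, individual: str) -> DivergenceSeries:
    """Trajectory-level disagreement between the two rank metrics.

    Sorts the individual's records by period and correlates (-ordinal) with
    proportional rank. Degenerate trajectories use a fixed convention: both
    series constant -> 1.0 (the metrics tell the same, trivial story);
    exactly one constant -> 0.0 (one metric reports change that the other
    cannot see, the situation of an individual holding a fixed position in a
    growing hierarchy).
    """
    sub = records[records["individual"] == individual].sort_values("period")
    if len(sub) < 2:
        raise ValueError(
            f"need at least 2 periods for {individual}, got {len(sub)}"
        )
    ordinal = sub["ordinal"].to_numpy(dtype=float)
    prop = sub["proportional"].to_numpy(dtype=float)
    sizes = sub["n"].to_numpy(dtype=int)

    ord_const = np.all(ordinal == ordinal[0])
    prop_const = np.all(prop == prop[0])
    if ord_const and prop_const:
        corr = 1.0
    elif ord_const or prop_const:
        corr = 0.0
    else:
        corr = float(stats.spearmanr(-ordinal, prop).statistic)
    return DivergenceSeries(
        individual=individual,
        periods=sub["period"].tolist(),
        ordinal=ordinal,
        proportional=prop,
        hierarchy_size=sizes,
        correlation=corr,
    )
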