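"""Dominance hierarchy inference from dyadic agonistic interactions.

Wins and losses between same-sex group members are tabulated into monthly
win-loss matrices, and a linear hierarchy is inferred by finding the ordering
of individuals that minimizes the number of bout outcomes falling below the
matrix diagonal (i.e. bouts won by the lower-ranked member of the dyad).
The objective is combinatorial; the search is exact (exhaustive) for small
hierarchies and a deterministic local search for larger ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgonisticBout",
    "WinLossMatrix",
    "HierarchyOrdering",
    "build_winloss_matrix",
    "count_inconsistencies",
    "order_hierarchy",
    "assign_periods",
    "monthly_orderings",
]

# exhaustive search is exact up to this hierarchy size (8! = 40320 orderings)
EXHAUSTIVE_LIMIT = 8

BOUT_COLUMNS = ["date", "group", "sex", "winner", "loser"]


@dataclass(frozen=True)
class AgonisticBout:
    """A decided dyadic conflict: ``winner`` displaced or dominated ``loser``.

    Both participants belong to the same sex class; intersexual interactions
    are outside the scope of sex-specific hierarchies.
    """

    date: str
    group: str
    winner: str
    loser: str
    sex: str

    def __post_init__(self) -> None:
        if self.winner == self.loser:
            raise ValueError(
                f"bout on {self.date} in group {self.group}: winner and loser "
                f"are both {self.winner!r}"
            )


@dataclass
class WinLossMatrix:
    """Square bout-count matrix for one (period, group, sex) cell.

    ``counts[i, j]`` is the number of bouts in which ``ids[i]`` beat
    ``ids[j]``; the diagonal is structurally zero.
    """

    period: str
    group: str
    sex: str
    ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.ids)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} ids"
            )
        if n < 1:
            raise ValueError("a win-loss matrix needs at least one individual")
        if (self.counts < 0).any():
            raise ValueError("bout counts must be nonnegative")
        if np.diagonal(self.counts).any():
            raise ValueError("diagonal of a win-loss matrix must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def total_bouts(self) -> int:
        return int(self.counts.sum())

    def win_proportions(self) -> dict[str, float]:
        """Fraction of an individual's bouts that it won (0 if unobserved)."""
        wins = self.counts.sum(axis=1)
        losses = self.counts.sum(axis=0)
        total = wins + losses
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(total > 0, wins / np.maximum(total, 1), 0.0)
        return dict(zip(self.ids, prop.astype(float)))

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a labelled DataFrame (winners on rows)."""
        return pd.DataFrame(self.counts, index=self.ids, columns=self.ids)


@dataclass
class HierarchyOrdering:
    """A linear ordering of a matrix's individuals, rank 1 first.

    ``inconsistencies`` is the number of bouts won by the lower-ranked member
    of a dyad under this ordering — the quantity the ordering minimizes.
    """

    period: str
    group: str
    sex: str
    ranked_ids: list[str]
    inconsistencies: int


def _coerce_bouts(bouts) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of AgonisticBout records."""
    if isinstance(bouts, pd.DataFrame):
        missing = [c for c in BOUT_COLUMNS if c not in bouts.columns]
        if missing:
            raise ValueError(f"bout table missing columns: {missing}")
        return bouts
    rows = [
        (b.date, b.group, b.sex, b.winner, b.loser) for b in bouts
    ]
    return pd.DataFrame(rows, columns=BOUT_COLUMNS)


def build_winloss_matrix(
    bouts,
    period: str,
    group: str,
    sex: str,
    roster: Optional[Sequence[str]] = None,
) -> WinLossMatrix:
    """Tabulate bouts into a win-loss matrix for one (period, group, sex).

    Parameters
    ----------
    bouts
        Bouts already restricted to the stated period/group/sex, either a
        DataFrame with columns ``date,group,sex,winner,loser`` or an iterable
        of :class:`AgonisticBout`.
    roster
        Optional list of eligible individuals. Roster members with no bouts
        appear as all-zero rows/columns; a bout participant outside the
        roster is an error. Without a roster the ids are the bout
        participants, and an empty bout set is an error (there is no way to
        know who should be ranked).
    """
    df = _coerce_bouts(bouts)
    participants = sorted(set(df["winner"]) | set(df["loser"]))
    if roster is not None:
        roster = list(dict.fromkeys(roster))  # preserve order, drop dups
        extra = [p for p in participants if p not in set(roster)]
        if extra:
            raise ValueError(
                f"bout participants {extra} are not on the roster for "
                f"{group}/{sex}/{period}"
            )
        ids = roster
    else:
        if not participants:
            raise ValueError(
                f"no bouts and no roster for {group}/{sex}/{period}: "
                "cannot build an empty matrix"
            )
        ids = participants

    index = {ind: i for i, ind in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    if len(df):
        w = df["winner"].map(index).to_numpy()
        l = df["loser"].map(index).to_numpy()
        np.add.at(counts, (w, l), 1)
    return WinLossMatrix(period=period, group=group, sex=sex, ids=ids, counts=counts)


def count_inconsistencies(matrix: WinLossMatrix, ordering: Sequence[str]) -> int:
    """Bouts won by the lower-ranked member of a dyad under ``ordering``.

    Equivalently: the sum of matrix entries below the diagonal once rows and
    columns are permuted into rank order.
    """
    if sorted(ordering) != sorted(matrix.ids):
        raise ValueError("ordering is not a permutation of the matrix ids")
    index = {ind: i for i, ind in enumerate(matrix.ids)}
    order = np.array([index[ind] for ind in ordering])
    reordered = matrix.counts[np.ix_(order, order)]
    return int(np.tril(reordered, k=-1).sum())


@lru_cache(maxsize=None)
def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _costs_for_perms(counts: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Below-diagonal totals for many candidate orderings at once."""
    n = counts.shape[0]
    costs = np.zeros(len(perms), dtype=np.int64)
    for hi in range(n):
        for lo in range(hi + 1, n):
            costs += counts[perms[:, lo], perms[:, hi]]
    return costs


def _preference_index(
    matrix: WinLossMatrix, prior: Optional[HierarchyOrdering]
) -> dict[str, int]:
    """Total deterministic preference over individuals for tie-breaking.

    Cascade: prior month's relative order first, then descending win
    proportion, then lexicographic id. Individuals absent from the prior
    sort after those present in it.
    """
    prior_pos: Mapping[str, int] = {}
    if prior is not None:
        prior_pos = {ind: i for i, ind in enumerate(prior.ranked_ids)}
    props = matrix.win_proportions()
    big = len(prior_pos) + len(matrix.ids)
    ordered = sorted(
        matrix.ids,
        key=lambda ind: (prior_pos.get(ind, big), -props[ind], ind),
    )
    return {ind: i for i, ind in enumerate(ordered)}


def _order_exhaustive(
    matrix: WinLossMatrix, pref: dict[str, int]
) -> tuple[list[str], int]:
    n = matrix.n
    perms = _all_permutations(n)
    costs = _costs_for_perms(matrix.counts, perms)
    best = costs.min()
    candidates = perms[costs == best]
    # break ties: pick the ordering lexicographically smallest under the
    # preference index
    pref_vec = np.array([pref[ind] for ind in matrix.ids])
    mapped = pref_vec[candidates]
    winner = candidates[np.lexsort(mapped.T[::-1])][0]
    return [matrix.ids[i] for i in winner], int(best)


def _order_local(
    matrix: WinLossMatrix, pref: dict[str, int]
) -> tuple[list[str], int]:
    """Single-individual relocation descent from the preference ordering.

    Accepts only strict improvements, scanning individuals and insertion
    points in a fixed order, so the result is deterministic.
    """
    counts = matrix.counts
    index = {ind: i for i, ind in enumerate(matrix.ids)}
    order = [index[ind] for ind in sorted(matrix.ids, key=pref.__getitem__)]
    n = len(order)

    def cost(o: list[int]) -> int:
        arr = counts[np.ix_(o, o)]
        return int(np.tril(arr, k=-1).sum())

    current = cost(order)
    improved = True
    while improved:
        improved = False
        for pos in range(n):
            ind = order[pos]
            rest = order[:pos] + order[pos + 1 :]
            for target in range(n):
                if target == pos:
                    continue
                candidate = rest[:target] + [ind] + rest[target:]
                c = cost(candidate)
                if c < current:
                    order, current = candidate, c
                    improved = True
                    break
            if improved:
                break
    return [matrix.ids[i] for i in order], current


def order_hierarchy(
    matrix: WinLossMatrix, prior: Optional[HierarchyOrdering] = None
) -> HierarchyOrdering:
    """Infer the linear ordering minimizing below-diagonal bout counts.

    For hierarchies of up to eight individuals the minimum is exact (global
    over all orderings); beyond that a deterministic relocation descent finds
    a local minimum. Ties among equally minimal orderings are broken by the
    previous month's relative order (temporal continuity), then by higher win
    proportion, then by id, so repeated runs on identical inputs give
    identical rankings.
    """
    pref = _preference_index(matrix, prior)
    if matrix.n <= EXHAUSTIVE_LIMIT:
        ranked, cost = _order_exhaustive(matrix, pref)
    else:
        ranked, cost = _order_local(matrix, pref)
    return HierarchyOrdering(
        period=matrix.period,
        group=matrix.group,
        sex=matrix.sex,
        ranked_ids=ranked,
        inconsistencies=cost,
    )


def assign_periods(bouts: pd.DataFrame, window: int = 1) -> pd.DataFrame:
    """Attach a ``period`` column by pooling calendar months.

    ``window`` is the number of consecutive calendar months pooled into one
    ranking period (1 = monthly matrices, the default convention). Each
    period is labelled by its first calendar month, ``YYYY-MM``.
    """
    if window < 1:
        raise ValueError("window must be at least 1 month")
    df = bouts.copy()
    months = pd.PeriodIndex(pd.to_datetime(df["date"], format="ISO8601"), freq="M")
    if window == 1:
        df["period"] = months.astype(str)
    else:
        idx = months.year * 12 + (months.month - 1)
        start = idx.min()
        bucket_start = start + ((idx - start) // window) * window
        df["period"] = [
            f"{b // 12:04d}-{b % 12 + 1:02d}" for b in bucket_start
        ]
    return df


def monthly_orderings(
    bouts: pd.DataFrame,
    rosters: Optional[Mapping[tuple[str, str, str], Sequence[str]]] = None,
    carry_prior: bool = True,
    window: int = 1,
) -> list[HierarchyOrdering]:
    """Order every (group, sex, period) cell of a bout table.

    Periods are processed in sorted order within each (group, sex) series and,
    when ``carry_prior`` is true, each month's ordering seeds the next month's
    tie-breaking — the temporal-continuity convention of a longitudinal study.
    ``rosters`` optionally maps (group, sex, period) to the eligible
    individuals for that cell (so members with no bouts are still ranked).
    """
    df = _coerce_bouts(bouts)
    if "period" not in df.columns:
        df = assign_periods(df, window=window)
    results: list[HierarchyOrdering] = []
    for (group, sex), chunk in df.groupby(["group", "sex"], sort=True):
        prior: Optional[HierarchyOrdering] = None
        for period, cell in sorted(chunk.groupby("period")):
            roster = rosters.get((group, sex, period)) if rosters else None
            matrix = build_winloss_matrix(
                cell, period=period, group=group, sex=sex, roster=roster
            )
            ordering = order_hierarchy(matrix, prior=prior if carry_prior else None)
            results.append(ordering)
            prior = ordering
    return results
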