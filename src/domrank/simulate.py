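"""Synthetic longitudinal study generator under explicit competitive regimes.

The generator emulates a multi-group, multi-year observational study of a
species with sex-specific linear dominance hierarchies: each group carries a
latent linear hierarchy whose size changes over time as immigrants join at
the bottom; dyads interact in agonistic bouts that the higher-ranked member
wins with probability 1 - epsilon; and individual traits are produced each
month under one of two competitive regimes.

Under DENSITY_DEPENDENT competition the total resource base is fixed at r1
regardless of hierarchy size (per-capita access r1/n shrinks as the
hierarchy grows), so an individual's outcome is governed by how many others
rank above it — its simple ordinal rank. Under DENSITY_INDEPENDENT
competition the resource base grows as r1 * n (per-capita access constant),
so outcomes track the proportion of others outranked — proportional rank.
The regime-recovery experiment closes the loop: it feeds the simulated bouts
through hierarchy inference, rank computation and the three-model AIC
comparison, and checks that the comparison identifies the generating regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compare import ModelSpec, compare_rank_metrics
from .hierarchy import monthly_orderings
from .rank_metrics import rank_table

__all__ = [
    "DENSITY_DEPENDENT",
    "DENSITY_INDEPENDENT",
    "RegimeSimConfig",
    "ResourceCurve",
    "SimulatedStudy",
    "RecoveryResult",
    "resource_availability",
    "resource_curve",
    "simulate_bouts",
    "generate_trait",
    "simulate_study",
    "regime_recovery_experiment",
]

DENSITY_DEPENDENT = "density_dependent"
DENSITY_INDEPENDENT = "density_independent"
_REGIMES = (DENSITY_DEPENDENT, DENSITY_INDEPENDENT)


@dataclass(frozen=True)
class RegimeSimConfig:
    """All simulator knobs.

    Defaults describe a study of 4 groups followed for 24 months with
    hierarchy sizes between 5 and 15 (initial sizes spread across that range,
    bottom-joining immigration thereafter), a 10% chance that the
    lower-ranked member wins any bout, and 2 bouts per dyad per month.
    The linear trait generator uses a signal-to-noise ratio of about one
    noise standard deviation per rank step: ``beta_ordinal`` is the trait
    change per ordinal step and ``beta_proportional`` the slope on the [0,1]
    proportional scale (9.0 ~ one sigma per step at the mid-range hierarchy
    size of 10). ``r1`` is the resource quantity available at hierarchy
    size 1 (0.2 resource units, e.g. oestrous females, per day).
    """

    n_groups: int = 4
    n_months: int = 24
    size_min: int = 5
    size_max: int = 15
    initial_sizes: Optional[tuple[int, ...]] = None
    join_prob: float = 0.15
    join_at_bottom: bool = True
    epsilon: float = 0.1
    bouts_per_dyad: int = 2
    regime: str = DENSITY_DEPENDENT
    r1: float = 0.2
    alpha: float = 10.0
    beta_ordinal: float = 1.0
    beta_proportional: float = 9.0
    sigma: float = 1.0
    trait_generator: str = "linear"
    queue_fixed_m: Optional[int] = None
    days_per_month: int = 30
    sex: str = "M"
    start_period: str = "2000-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("upset probability must satisfy 0 <= epsilon < 0.5")
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")
        if self.regime not in _REGIMES:
            raise ValueError(f"regime must be one of {_REGIMES}")
        if self.trait_generator not in ("linear", "queue"):
            raise ValueError("trait_generator must be 'linear' or 'queue'")
        if self.size_min < 2:
            raise ValueError("hierarchies must have at least 2 members")

    def resolved_initial_sizes(self) -> tuple[int, ...]:
        if self.initial_sizes is not None:
            if len(self.initial_sizes) != self.n_groups:
                raise ValueError("initial_sizes length must equal n_groups")
            return self.initial_sizes
        return tuple(
            int(round(s))
            for s in np.linspace(self.size_min, self.size_max, self.n_groups)
        )


def resource_availability(n: int, r1: float, regime: str) -> float:
    """Expected total resource base for a hierarchy of size ``n``.

    Density-dependent: the base stays at r1 however large the hierarchy.
    Density-independent: the base grows by r1 for every member, r1 * n.
    """
    if n < 1:
        raise ValueError("hierarchy size must be at least 1")
    if regime == DENSITY_DEPENDENT:
        return r1
    if regime == DENSITY_INDEPENDENT:
        return r1 * n
    raise ValueError(f"regime must be one of {_REGIMES}")


@dataclass
class ResourceCurve:
    """Total and per-capita resource base across hierarchy sizes."""

    sizes: np.ndarray
    total: np.ndarray
    per_capita: np.ndarray
    regime: str
    r1: float


def resource_curve(sizes: Sequence[int], r1: float, regime: str) -> ResourceCurve:
    sizes = np.asarray(sizes, dtype=int)
    total = np.array([resource_availability(int(n), r1, regime) for n in sizes])
    return ResourceCurve(
        sizes=sizes, total=total, per_capita=total / sizes, regime=regime, r1=r1
    )


def simulate_bouts(
    config: RegimeSimConfig,
    group: str,
    period: str,
    latent_order: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One month of dyadic bouts for one group.

    Every dyad fights ``bouts_per_dyad`` times; the higher-ranked member of
    the dyad (earlier in ``latent_order``) wins each bout independently with
    probability 1 - epsilon.
    """
    ids = np.asarray(latent_order, dtype=object)
    n = len(ids)
    hi, lo = np.triu_indices(n, k=1)
    hi = np.repeat(hi, config.bouts_per_dyad)
    lo = np.repeat(lo, config.bouts_per_dyad)
    upset = rng.random(len(hi)) < config.epsilon
    winners = np.where(upset, ids[lo], ids[hi])
    losers = np.where(upset, ids[hi], ids[lo])
    days = rng.integers(1, 29, size=len(hi))
    return pd.DataFrame(
        {
            "date": [f"{period}-{d:02d}" for d in days],
            "group": group,
            "sex": config.sex,
            "winner": winners,
            "loser": losers,
        }
    )


def generate_trait(
    config: RegimeSimConfig,
    rank_records: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trait values for one month's hierarchy members.

    Linear generator: under density dependence the trait declines by
    ``beta_ordinal`` per ordinal step (alpha - beta * k + noise); under
    density independence it rises with proportional rank
    (alpha + beta * proportional + noise). Queue generator: each day the
    number of available resource units m is drawn with mean equal to the
    regime's resource base R(n) (or held at ``queue_fixed_m``), the m
    top-ranked members obtain access, and the trait is the fraction of days
    with access — so under density dependence expected access depends only
    on ordinal rank, and under density independence only on proportional
    rank.
    """
    ordinal = rank_records["ordinal"].to_numpy(dtype=int)
    if config.trait_generator == "linear":
        if config.regime == DENSITY_DEPENDENT:
            mean = config.alpha - config.beta_ordinal * ordinal
        else:
            prop = rank_records["proportional"].to_numpy(dtype=float)
            mean = config.alpha + config.beta_proportional * prop
        values = mean + rng.normal(0.0, config.sigma, size=len(ordinal))
    else:
        n = int(rank_records["n"].iloc[0])
        base = resource_availability(n, config.r1, config.regime)
        if config.queue_fixed_m is not None:
            m = np.full(config.days_per_month, config.queue_fixed_m)
        else:
            m = rng.poisson(base, size=config.days_per_month)
        # access[i, d] = 1 when individual of ordinal rank i is within the
        # top m_d on day d
        access = ordinal[:, None] <= m[None, :]
        values = access.mean(axis=1)
    out = rank_records[["individual", "period", "group", "sex"]].copy()
    out["trait"] = values
    return out


@dataclass
class SimulatedStudy:
    """Everything the generator produced for one simulated study.

    ``bouts`` is the observational record (what a field team would have);
    ``true_ranks`` the latent monthly hierarchies the bouts were drawn from;
    ``traits`` the monthly trait values generated from the latent ranks;
    ``rosters`` maps (group, sex, period) to that month's members, so
    downstream ranking retains individuals with no observed bouts.
    """

    config: RegimeSimConfig
    bouts: pd.DataFrame
    true_ranks: pd.DataFrame
    traits: pd.DataFrame
    rosters: dict[tuple[str, str, str], list[str]]


def _period_sequence(start: str, n_months: int) -> list[str]:
    return [str(p) for p in pd.period_range(start=start, periods=n_months, freq="M")]


def simulate_study(config: RegimeSimConfig) -> SimulatedStudy:
    """Generate a full multi-group longitudinal study from one seed.

    Each group starts from its initial latent hierarchy; every subsequent
    month one immigrant may join (probability ``join_prob``, until
    ``size_max``), entering at the bottom of the hierarchy (or at a random
    position when ``join_at_bottom`` is off). The latent order is otherwise
    stable; observed upsets come from the bout-level epsilon.
    """
    rng = np.random.default_rng(config.seed)
    periods = _period_sequence(config.start_period, config.n_months)
    sizes = config.resolved_initial_sizes()

    bout_frames: list[pd.DataFrame] = []
    rank_rows: list[pd.DataFrame] = []
    trait_frames: list[pd.DataFrame] = []
    rosters: dict[tuple[str, str, str], list[str]] = {}

    for gi in range(config.n_groups):
        group = f"G{gi + 1}"
        order = [f"{group}I{j:03d}" for j in range(sizes[gi])]
        next_id = sizes[gi]
        for period in periods:
            if period != periods[0] and len(order) < config.size_max:
                if rng.random() < config.join_prob:
                    newcomer = f"{group}I{next_id:03d}"
                    next_id += 1
                    if config.join_at_bottom:
                        order.append(newcomer)
                    else:
                        pos = int(rng.integers(0, len(order) + 1))
                        order.insert(pos, newcomer)
            rosters[(group, config.sex, period)] = list(order)
            bout_frames.append(
                simulate_bouts(config, group, period, order, rng)
            )
            n = len(order)
            records = pd.DataFrame(
                {
                    "individual": order,
                    "period": period,
                    "group": group,
                    "sex": config.sex,
                    "ordinal": np.arange(1, n + 1),
                    "n": n,
                    "proportional": 1.0 - np.arange(n) / (n - 1),
                }
            )
            rank_rows.append(records)
            trait_frames.append(generate_trait(config, records, rng))

    return SimulatedStudy(
        config=config,
        bouts=pd.concat(bout_frames, ignore_index=True),
        true_ranks=pd.concat(rank_rows, ignore_index=True),
        traits=pd.concat(trait_frames, ignore_index=True),
        rosters=rosters,
    )


@dataclass
class RecoveryResult:
    """Confusion summary of a regime-recovery experiment.

    ``counts`` tallies per-replicate classifications (ORDINAL /
    PROPORTIONAL / INDISTINGUISHABLE / INVALID); ``fraction_correct`` is the
    share classified as the metric the generating regime predicts (ordinal
    for density-dependent, proportional for density-independent);
    ``fraction_preferred_and_beats_null`` is the share where some metric was
    preferred AND that metric beat the null by the AIC threshold — the
    false-positive rate of interest when the trait carries no rank signal.
    """

    regime: str
    replicates: int
    counts: dict[str, int]
    fraction_correct: float
    fraction_preferred_and_beats_null: float


def _derive_seed(base: int, i: int) -> int:
    return int((base * 1_000_003 + 7919 * i + 1) % (2**31 - 1))


def analyze_study(
    sim: SimulatedStudy, threshold: float = 2.0
) -> "MetricComparison":
    """Run the full inference pipeline on one simulated study.

    Bouts -> monthly win-loss matrices (with rosters, prior carried month to
    month) -> inconsistency-minimizing orderings -> rank table -> join with
    traits -> three-model AIC comparison of the rank metrics.
    """
    from .hierarchy import assign_periods

    bouts = assign_periods(sim.bouts)
    orderings = monthly_orderings(bouts, rosters=sim.rosters)
    ranks = rank_table(orderings)
    dataset = sim.traits.merge(
        ranks, on=["individual", "period", "group", "sex"], validate="one_to_one"
    )
    spec = ModelSpec(response="trait", family="gaussian")
    return compare_rank_metrics(
        dataset, spec, trait="simulated", sex=sim.config.sex, threshold=threshold
    )


def regime_recovery_experiment(
    config: RegimeSimConfig,
    replicates: int,
    base_seed: Optional[int] = None,
    threshold: float = 2.0,
) -> RecoveryResult:
    """Simulate, re-infer and classify ``replicates`` independent studies.

    Each replicate uses a seed derived deterministically from ``base_seed``
    (default: the config's seed), so the whole experiment is reproducible
    from a single integer.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    base = config.seed if base_seed is None else base_seed
    counts = {"ORDINAL": 0, "PROPORTIONAL": 0, "INDISTINGUISHABLE": 0, "INVALID": 0}
    n_signal = 0
    for i in range(replicates):
        cfg = replace(config, seed=_derive_seed(base, i))
        comparison = analyze_study(simulate_study(cfg), threshold=threshold)
        counts[comparison.classification] += 1
        if comparison.classification in ("ORDINAL", "PROPORTIONAL"):
            preferred = comparison.classification.lower()
            if comparison.beats_null.get(preferred, False):
                n_signal += 1
    expected = (
        "ORDINAL" if config.regime == DENSITY_DEPENDENT else "PROPORTIONAL"
    )
    return RecoveryResult(
        regime=config.regime,
        replicates=replicates,
        counts=counts,
        fraction_correct=counts[expected] / replicates,
        fraction_preferred_and_beats_null=n_signal / replicates,
    )
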