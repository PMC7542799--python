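"""Three-model AIC comparison of rank metrics, and tally statistics.

For each trait, three models are fitted on the identical row set: one with
simple ordinal rank as the rank term, one with proportional rank, and a null
model with no rank term. The model with the lowest AIC wins, with an AIC
difference of at least 2 required before one model is called preferred over
another (differences under 2 are treated as indistinguishable). A metric
"beats the null" when its AIC is at least 2 units below the null model's.

Classifications are then tallied per sex and tested: a two-tailed exact
binomial test of each sex's ordinal/proportional split against chance, and
Fisher's exact test of the sex-by-metric contingency table.

All fits maximize the full likelihood (never a restricted likelihood), so
AICs are comparable across models that differ in fixed effects. The Cox
family contributes its partial likelihood to the AIC.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "MetricComparison",
    "TallyResult",
    "fit_model",
    "classify_aic",
    "compare_rank_metrics",
    "binomial_two_tailed",
    "fisher_two_sided",
    "tally_and_test",
    "DEFAULT_AIC_THRESHOLD",
]

DEFAULT_AIC_THRESHOLD = 2.0

FAMILIES = ("gaussian", "binomial", "poisson", "negative-binomial", "cox")
RANK_TERMS = ("ordinal", "proportional", "none")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model for a trait.

    ``rank_term`` selects which rank metric (if any) enters as a predictor;
    everything else — response, family, covariates, optional random-effect
    grouping column — is shared across the three candidates of a comparison.
    For the cox family, ``response`` is the duration column and ``event_col``
    the 0/1 event indicator.
    """

    response: str
    family: str = "gaussian"
    covariates: tuple[str, ...] = ()
    random_effect: Optional[str] = None
    rank_term: str = "none"
    event_col: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.rank_term not in RANK_TERMS:
            raise ValueError(f"rank_term must be one of {RANK_TERMS}")
        if self.family == "cox" and self.event_col is None:
            raise ValueError("cox family requires event_col")

    @property
    def predictors(self) -> tuple[str, ...]:
        rank = () if self.rank_term == "none" else (self.rank_term,)
        return rank + self.covariates


@dataclass
class FitResult:
    """Maximum-likelihood fit summary: the ingredients of an AIC.

    ``n_params`` counts every estimated parameter, including dispersion and
    variance components, so ``aic == 2 * n_params - 2 * loglik`` always.
    """

    loglik: float
    n_params: int
    aic: float
    converged: bool
    params: dict[str, float] = field(default_factory=dict)
    message: str = ""


def _required_columns(spec: ModelSpec) -> list[str]:
    cols = [spec.response, *spec.predictors]
    if spec.random_effect:
        cols.append(spec.random_effect)
    if spec.event_col:
        cols.append(spec.event_col)
    return cols


def _cox_null_loglik(durations: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood of the empty Cox model.

    With no covariates every subject has hazard ratio 1, so each event at
    time t contributes -log(size of the risk set at t).
    """
    order = np.argsort(durations)
    d = durations[order]
    e = events[order].astype(bool)
    n = len(d)
    # risk set at an event time = subjects with duration >= that time
    risk = n - np.searchsorted(d, d, side="left")
    return float(-np.sum(np.log(risk[e])))


def _fit_cox(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    from lifelines import CoxPHFitter

    durations = df[spec.response].to_numpy(dtype=float)
    events = df[spec.event_col].to_numpy(dtype=float)
    if not spec.predictors:
        ll = _cox_null_loglik(durations, events)
        return FitResult(loglik=ll, n_params=0, aic=-2.0 * ll, converged=True)
    sub = df[[spec.response, spec.event_col, *spec.predictors]]
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(sub, duration_col=spec.response, event_col=spec.event_col)
    except Exception as exc:  # noqa: BLE001 - any failure means no comparison
        return FitResult(np.nan, 0, np.nan, False, message=str(exc))
    ll = float(fitter.log_likelihood_)
    k = len(fitter.params_)
    return FitResult(ll, k, 2.0 * k - 2.0 * ll, True, dict(fitter.params_))


def fit_model(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one candidate model by full maximum likelihood.

    Gaussian models without a random effect are ordinary least squares (the
    error variance counts as an estimated parameter); with a random effect
    they are linear mixed models fitted by ML, not REML, so that AICs remain
    comparable when fixed effects differ across the three candidates.
    Binomial and Poisson responses use GLMs, negative-binomial responses
    estimate the dispersion jointly, and survival responses use the Cox
    partial likelihood. Non-convergence (including separation in binomial
    fits) is flagged rather than raised, so the caller can abort the
    comparison for that trait.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    missing = [c for c in _required_columns(spec) if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    df = dataset.dropna(subset=_required_columns(spec))

    if spec.family == "cox":
        return _fit_cox(df, spec)

    rhs = " + ".join(spec.predictors) if spec.predictors else "1"
    formula = f"{spec.response} ~ {rhs}"

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if spec.random_effect is not None:
                if spec.family != "gaussian":
                    raise ValueError(
                        "random effects are supported for the gaussian "
                        "family only (linear mixed model, ML)"
                    )
                res = smf.mixedlm(
                    formula, df, groups=df[spec.random_effect]
                ).fit(reml=False)
                k = len(res.fe_params) + 2  # + RE variance + residual variance
                converged = bool(res.converged)
            elif spec.family == "gaussian":
                res = smf.ols(formula, df).fit()
                k = len(res.params) + 1  # + error variance (ML estimate)
                converged = True
            elif spec.family == "negative-binomial":
                res = smf.negativebinomial(formula, df).fit(disp=0)
                k = len(res.params)  # includes the dispersion alpha
                converged = bool(res.mle_retvals.get("converged", True))
            else:
                family = (
                    sm.families.Binomial()
                    if spec.family == "binomial"
                    else sm.families.Poisson()
                )
                res = smf.glm(formula, df, family=family).fit(tol=1e-10)
                k = len(res.params)
                converged = bool(getattr(res, "converged", True))
            separation = any(
                "separation" in str(w.message).lower() for w in caught
            )
    except Exception as exc:  # noqa: BLE001
        return FitResult(np.nan, 0, np.nan, False, message=str(exc))

    ll = float(res.llf)
    if separation or not np.isfinite(ll):
        return FitResult(
            ll, k, 2.0 * k - 2.0 * ll, False,
            message="separation or non-finite likelihood",
        )
    params = {} if spec.random_effect else dict(res.params)
    return FitResult(ll, k, 2.0 * k - 2.0 * ll, converged, params)


@dataclass
class MetricComparison:
    """AIC triplet for one trait and its classification.

    ``delta_metrics`` is AIC(ordinal) - AIC(proportional); the trait is
    classified INDISTINGUISHABLE when |delta_metrics| is under the threshold,
    otherwise by whichever metric has the lower AIC. ``beats_null`` records,
    independently for each metric, whether its AIC undercuts the null
    model's by at least the threshold. ``valid`` is False when any of the
    three fits failed, in which case the classification is not meaningful.
    """

    trait: str
    sex: str
    aic_ordinal: float
    aic_proportional: float
    aic_null: float
    delta_metrics: float
    delta_preferred_null: float
    classification: str
    beats_null: dict[str, bool]
    valid: bool = True
    reason: str = ""


def classify_aic(
    aic_ordinal: float,
    aic_proportional: float,
    aic_null: float,
    threshold: float = DEFAULT_AIC_THRESHOLD,
) -> tuple[str, dict[str, bool]]:
    """Apply the AIC-difference rule to a triplet of AIC scores.

    Returns the classification (ORDINAL / PROPORTIONAL / INDISTINGUISHABLE)
    and, for each metric, whether it beats the null model by the threshold.
    """
    delta = aic_ordinal - aic_proportional
    if abs(delta) < threshold:
        classification = "INDISTINGUISHABLE"
    elif aic_ordinal < aic_proportional:
        classification = "ORDINAL"
    else:
        classification = "PROPORTIONAL"
    beats_null = {
        "ordinal": aic_ordinal <= aic_null - threshold,
        "proportional": aic_proportional <= aic_null - threshold,
    }
    return classification, beats_null


def compare_rank_metrics(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    trait: str = "",
    sex: str = "",
    threshold: float = DEFAULT_AIC_THRESHOLD,
) -> MetricComparison:
    """Fit the ordinal, proportional and null models and classify the trait.

    All three fits use the identical row set: rows missing the response, any
    covariate, or either rank column are dropped up front (single-member
    hierarchies have no proportional rank, so they are excluded everywhere).
    """
    if threshold <= 0:
        raise ValueError("AIC threshold must be positive")
    for col in ("ordinal", "proportional"):
        if col not in dataset.columns:
            raise ValueError(f"dataset missing rank column {col!r}")
    needed = set(_required_columns(spec)) | {"ordinal", "proportional"}
    rows = dataset.dropna(subset=[c for c in needed if c in dataset.columns])

    fits = {
        term: fit_model(rows, replace(spec, rank_term=term))
        for term in ("ordinal", "proportional", "none")
    }
    trait = trait or spec.response

    if not all(f.converged for f in fits.values()):
        bad = [t for t, f in fits.items() if not f.converged]
        return MetricComparison(
            trait=trait, sex=sex,
            aic_ordinal=fits["ordinal"].aic,
            aic_proportional=fits["proportional"].aic,
            aic_null=fits["none"].aic,
            delta_metrics=np.nan, delta_preferred_null=np.nan,
            classification="INVALID", beats_null={},
            valid=False,
            reason=f"non-convergent fits: {bad}",
        )

    aic_o = fits["ordinal"].aic
    aic_p = fits["proportional"].aic
    aic_n = fits["none"].aic
    delta = aic_o - aic_p
    classification, beats_null = classify_aic(aic_o, aic_p, aic_n, threshold)
    return MetricComparison(
        trait=trait,
        sex=sex,
        aic_ordinal=aic_o,
        aic_proportional=aic_p,
        aic_null=aic_n,
        delta_metrics=delta,
        delta_preferred_null=min(aic_o, aic_p) - aic_n,
        classification=classification,
        beats_null=beats_null,
    )


def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Two-tailed exact binomial p-value by the small-p-values method.

    Sums the probabilities of all outcomes no more likely than the observed
    one under Binomial(n, p0).
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums the hypergeometric probabilities, over all tables with the observed
    margins, of tables no more probable than the observed one.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("Fisher test requires a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("at least one positive margin required")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


@dataclass
class TallyResult:
    """Per-sex classification counts and the exact tests over them.

    The binomial tests compare each sex's ordinal count against chance
    (p0 = 0.5) among traits where one metric was preferred; traits classified
    INDISTINGUISHABLE or INVALID do not enter the tests. The Fisher test
    contrasts the two sexes' ordinal/proportional splits. Tests whose inputs
    are empty are reported as None.
    """

    counts: dict[str, dict[str, int]]
    binomial_p: dict[str, Optional[float]]
    fisher_p: Optional[float]
    table: Optional[list[list[int]]]


def tally_and_test(
    comparisons: Sequence[MetricComparison], p0: float = 0.5
) -> TallyResult:
    """Tally classifications by sex and run the exact tests."""
    counts: dict[str, dict[str, int]] = {}
    for c in comparisons:
        sex_counts = counts.setdefault(
            c.sex, {"ORDINAL": 0, "PROPORTIONAL": 0, "INDISTINGUISHABLE": 0, "INVALID": 0}
        )
        sex_counts[c.classification] += 1

    binomial_p: dict[str, Optional[float]] = {}
    for sex, sc in counts.items():
        n_classified = sc["ORDINAL"] + sc["PROPORTIONAL"]
        binomial_p[sex] = (
            binomial_two_tailed(sc["ORDINAL"], n_classified, p0)
            if n_classified > 0
            else None
        )

    fisher_p = None
    table = None
    sexes = sorted(counts)
    if len(sexes) == 2:
        table = [
            [counts[s]["ORDINAL"], counts[s]["PROPORTIONAL"]] for s in sexes
        ]
        if sum(sum(row) for row in table) > 0:
            fisher_p = fisher_two_sided(table)
    return TallyResult(counts=counts, binomial_p=binomial_p, fisher_p=fisher_p, table=table)
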