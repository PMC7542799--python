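"""Model fitting, AIC classification, and the exact tally tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from domrank import (
    MetricComparison,
    ModelSpec,
    binomial_two_tailed,
    classify_aic,
    compare_rank_metrics,
    fisher_two_sided,
    fit_model,
    tally_and_test,
)


# ---------------------------------------------------------------- oracles

def binomial_oracle(k, n, p0):
    """Sum of P(X=i) over outcomes no more probable than the observed one."""
    probs = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    observed = probs[k]
    return sum(p for p in probs if p <= observed * (1 + 1e-12))


def fisher_oracle(table):
    """Hypergeometric enumeration over all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    total = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(total, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    observed = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= observed * (1 + 1e-12))


def dataset_with_signal(rng, n_rows=400, slope=-0.5, sigma=0.01, sizes=(5, 9, 13)):
    """Trait rows spanning several hierarchy sizes with an ordinal signal."""
    n = rng.choice(sizes, size=n_rows)
    ordinal = np.array([rng.integers(1, s + 1) for s in n])
    prop = 1 - (ordinal - 1) / (n - 1)
    y = 3.0 + slope * ordinal + rng.normal(0, sigma, n_rows)
    return pd.DataFrame(
        {"trait": y, "ordinal": ordinal, "proportional": prop, "n": n}
    )


# ---------------------------------------------------------------- fitting

class TestFitModel:
    def test_aic_recomputable_from_loglik_and_params(self, rng):
        df = dataset_with_signal(rng)
        res = fit_model(df, ModelSpec(response="trait", rank_term="ordinal"))
        assert res.converged
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.loglik, abs=1e-9)

    def test_planted_ordinal_signal_detected(self, rng):
        df = dataset_with_signal(rng, slope=-0.5, sigma=0.01)
        with_rank = fit_model(df, ModelSpec(response="trait", rank_term="ordinal"))
        null = fit_model(df, ModelSpec(response="trait", rank_term="none"))
        assert with_rank.params["ordinal"] < 0
        assert null.aic - with_rank.aic > 100  # far beyond the 2-unit rule

    def test_null_preferred_for_majority_of_pure_noise_replicates(self):
        # under no signal, the extra rank parameter costs 2 AIC on average
        rng = np.random.default_rng(77)
        wins = 0
        reps = 200
        for _ in range(reps):
            df = dataset_with_signal(rng, n_rows=60, slope=0.0, sigma=1.0)
            with_rank = fit_model(df, ModelSpec(response="trait", rank_term="ordinal"))
            null = fit_model(df, ModelSpec(response="trait", rank_term="none"))
            wins += null.aic < with_rank.aic
        assert wins > reps / 2

    def test_binomial_separation_flagged_not_raised(self, rng):
        df = dataset_with_signal(rng, n_rows=40)
        df["trait"] = 1.0  # all successes: no MLE exists
        res = fit_model(df, ModelSpec(response="trait", family="binomial", rank_term="ordinal"))
        assert not res.converged

    def test_gaussian_random_intercept_uses_full_ml(self, rng):
        df = dataset_with_signal(rng, n_rows=300, slope=-0.4, sigma=0.5)
        df["grp"] = rng.integers(0, 4, len(df)).astype(str)
        df["trait"] = df["trait"] + df["grp"].astype(int) * 0.5
        spec = ModelSpec(
            response="trait", rank_term="ordinal", random_effect="grp"
        )
        res = fit_model(df, spec)
        assert res.converged
        # fixed slope + intercept + RE variance + residual variance
        assert res.n_params == 4
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.loglik, abs=1e-9)

    def test_cox_family_uses_partial_likelihood(self, rng):
        n = 150
        ordinal = rng.integers(1, 10, n)
        hazard = np.exp(0.3 * ordinal)
        durations = rng.exponential(1 / hazard)
        df = pd.DataFrame(
            {
                "time": durations,
                "event": 1,
                "ordinal": ordinal,
                "proportional": 1 - (ordinal - 1) / 9,
            }
        )
        spec = ModelSpec(
            response="time", family="cox", event_col="event", rank_term="ordinal"
        )
        with_rank = fit_model(df, spec)
        null = fit_model(df, ModelSpec(response="time", family="cox", event_col="event"))
        assert with_rank.converged and null.converged
        assert null.n_params == 0
        # rank carries real signal: partial likelihood improves by >> 1
        assert with_rank.loglik - null.loglik > 10


# ----------------------------------------------------- classification rule

class TestClassification:
    def test_threshold_rule_on_plain_numbers(self):
        cls, beats = classify_aic(100.0, 104.0, 110.0)
        assert cls == "ORDINAL"
        assert beats == {"ordinal": True, "proportional": True}
        cls, _ = classify_aic(104.0, 100.0, 110.0)
        assert cls == "PROPORTIONAL"
        cls, beats = classify_aic(100.0, 101.0, 101.5)
        assert cls == "INDISTINGUISHABLE"
        assert beats == {"ordinal": False, "proportional": False}

    def test_raising_threshold_never_creates_a_metric_preference(self, rng):
        for _ in range(100):
            aics = rng.normal(100, 5, 3)
            lo, hi = sorted(rng.uniform(0.5, 8, 2))
            at_lo, _ = classify_aic(*aics, threshold=lo)
            at_hi, _ = classify_aic(*aics, threshold=hi)
            if at_lo == "INDISTINGUISHABLE":
                assert at_hi == "INDISTINGUISHABLE"

    def test_fixed_hierarchy_size_makes_metrics_indistinguishable(self, rng):
        # at constant n, proportional rank is an affine function of ordinal
        df = dataset_with_signal(rng, n_rows=200, slope=-0.3, sigma=0.3, sizes=(8,))
        comparison = compare_rank_metrics(df, ModelSpec(response="trait"))
        assert abs(comparison.delta_metrics) < 1e-6
        assert comparison.classification == "INDISTINGUISHABLE"

    def test_identical_row_set_despite_missing_proportional(self, rng):
        df = dataset_with_signal(rng, n_rows=120, slope=-0.5, sigma=0.1)
        df.loc[df.index[:10], "proportional"] = np.nan  # singleton hierarchies
        comparison = compare_rank_metrics(df, ModelSpec(response="trait"))
        assert comparison.valid
        # all three AICs computed on the same 110 rows: deltas stay coherent
        assert comparison.classification == "ORDINAL"

    def test_nonconvergent_fit_invalidates_comparison(self, rng):
        df = dataset_with_signal(rng, n_rows=50)
        df["trait"] = 1.0
        comparison = compare_rank_metrics(
            df, ModelSpec(response="trait", family="binomial")
        )
        assert not comparison.valid
        assert comparison.classification == "INVALID"
        assert "non-convergent" in comparison.reason


# ------------------------------------------------------------- exact tests

class TestExactTests:
    def test_binomial_matches_enumeration_everywhere(self):
        for n in range(1, 13):
            for k in range(n + 1):
                for p0 in (0.5, 0.3):
                    assert binomial_two_tailed(k, n, p0) == pytest.approx(
                        binomial_oracle(k, n, p0), abs=1e-12
                    )

    def test_binomial_symmetry_at_half(self):
        for n in range(1, 13):
            assert binomial_two_tailed(0, n, 0.5) == pytest.approx(
                binomial_two_tailed(n, n, 0.5), abs=1e-12
            )

    def test_fisher_matches_enumeration_for_small_margins(self):
        cells = range(0, 7)
        for a, b, c, d in itertools.product(cells, repeat=4):
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            assert fisher_two_sided(table) == pytest.approx(
                fisher_oracle(table), abs=1e-12
            )

    def test_fisher_symmetric_under_row_and_column_swap(self):
        table = [[7, 0], [3, 4]]
        swapped = [[4, 3], [0, 7]]
        assert fisher_two_sided(table) == pytest.approx(
            fisher_two_sided(swapped), abs=1e-12
        )

    def test_balanced_table_is_uninformative(self):
        assert fisher_two_sided([[1, 1], [1, 1]]) == pytest.approx(1.0)


# ------------------------------------------------------------------ tally

def comparison(sex, classification):
    return MetricComparison(
        trait="t", sex=sex, aic_ordinal=0, aic_proportional=0, aic_null=0,
        delta_metrics=0, delta_preferred_null=0,
        classification=classification, beats_null={},
    )


class TestTally:
    def test_sex_specific_counts_and_exact_tests(self):
        comparisons = (
            [comparison("male", "ORDINAL")] * 7
            + [comparison("female", "ORDINAL")] * 3
            + [comparison("female", "PROPORTIONAL")] * 4
        )
        tally = tally_and_test(comparisons)
        assert tally.counts["male"]["ORDINAL"] == 7
        assert tally.binomial_p["male"] == pytest.approx(0.015625, abs=1e-12)
        assert tally.binomial_p["female"] == pytest.approx(1.0, abs=1e-12)
        assert tally.fisher_p == pytest.approx(
            fisher_oracle([[3, 4], [7, 0]]), abs=1e-12
        )
        assert tally.fisher_p == pytest.approx(0.0699, abs=5e-5)

    def test_all_indistinguishable_yields_missing_tests(self):
        comparisons = [comparison("male", "INDISTINGUISHABLE")] * 5
        tally = tally_and_test(comparisons)
        assert tally.binomial_p["male"] is None
        assert tally.fisher_p is None

    def test_label_shuffle_keeps_fisher_calibrated(self):
        # with sex labels random, p <= 0.05 should occur at most ~5% of shuffles
        rng = np.random.default_rng(99)
        classes = ["ORDINAL"] * 7 + ["PROPORTIONAL"] * 7
        hits = 0
        n_shuffles = 500
        for _ in range(n_shuffles):
            sexes = rng.permutation(["male"] * 7 + ["female"] * 7)
            tally = tally_and_test(
                [comparison(s, c) for s, c in zip(sexes, classes)]
            )
            hits += tally.fisher_p <= 0.05
        # discrete exact test is conservative; allow binomial sampling error
        assert hits / n_shuffles <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_shuffles)
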