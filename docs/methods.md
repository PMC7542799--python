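# Methods

## Hierarchy inference

Dominance ranks are computed per (group, sex, period) cell. Bouts are
pooled by calendar month by default (`window` months may be pooled; each
period is labelled by its first month). The inferred ordering minimizes the
number of bout outcomes falling below the matrix diagonal — the number of
bouts won by the lower-ranked member of a dyad. This objective defines a
minimum-violation linear ordering problem; the package solves it:

- **n ≤ 8**: exhaustively, over all n! orderings, vectorized over the
  permutation array. The reported inconsistency count is the global minimum.
- **n > 8**: by deterministic single-individual relocation descent: start
  from the tie-break preference order (below), repeatedly move one
  individual to another position whenever that strictly reduces the
  objective, scanning positions in a fixed order, until no relocation
  improves. The result is a local minimum under all pairwise relocations
  and is deterministic given the inputs.

The objective typically has many co-minimal orderings (sparse matrices,
unobserved dyads). Ties are broken by a total preference over individuals:
(1) relative order in the previous period's ordering, if one is supplied —
hierarchies are near-stable month to month, so temporal continuity is the
scientifically sensible default; (2) higher observed win proportion;
(3) lexicographic id. Among co-minimal orderings the one lexicographically
smallest under this preference is returned, which makes an all-zero matrix
reproduce its prior ordering exactly. Roster members with no bouts in the
period are retained and placed by the same preference; individuals not on
the roster (or, without a roster, not observed) are absent from that
period's hierarchy.

These conventions are this package's own; long-term field projects each
have their own unstated carry-over rules, and no attempt is made to
reconstruct any particular one.

## Rank metrics

Ordinal rank k is the position in the ordering (1 = most dominant).
Proportional rank is 1 − (k − 1)/(n − 1) ∈ [0, 1], the fraction of other
members outranked. For n = 1 the quantity is undefined (division by zero;
a lone individual has no within-group competitors): it is emitted as NaN
with a warning, and such rows are dropped from all model fits. Maternal
rank for immatures defaults to the mother's record in the trait-measurement
month; a birth-month convention is selectable, since field studies differ
and neither convention is canonical.

The divergence diagnostic summarizes, per individual, the agreement between
the ordinal and proportional trajectories as the Spearman correlation of
(−ordinal) with proportional across periods: exactly 1 while hierarchy size
is constant (the metrics are then affinely related), lower when size
changes decouple them. Degenerate trajectories use a fixed convention:
both series constant → 1.0; exactly one constant → 0.0 (one metric reports
change the other cannot see — the signature case of a fixed ordinal
position in a growing hierarchy). This summary is a deliberately simple
stand-in for richer change-point diagnostics; it is a screening statistic,
not a test.

## Model comparison

For each trait, three models are fitted **on the identical row set**: with
an ordinal-rank term, with a proportional-rank term, and with no rank term.
All fits are full maximum likelihood — never restricted likelihood, whose
AICs are not comparable across models with different fixed effects. AIC is
2k − 2ℓ with k counting every estimated parameter, including the error
variance of gaussian models, the dispersion of negative-binomial models,
and the variance components of mixed models. Families:

| family | backend | parameter count |
|---|---|---|
| gaussian | OLS (statsmodels) | coefficients + 1 (σ²) |
| gaussian + random intercept | MixedLM, `reml=False` | fixed + 2 (RE var, residual var) |
| binomial / poisson | GLM (IRLS, tol 1e-10) | coefficients |
| negative-binomial | full MLE with dispersion | coefficients + 1 (α) |
| cox | partial likelihood (lifelines) | covariates (no intercept) |

The empty Cox null model has no fitting surface in lifelines, so its null
partial log-likelihood (each event contributing −log risk-set size,
Breslow) is computed by a small in-package routine. Random effects are
supported for the gaussian family only; a non-gaussian spec with a random
effect raises, rather than silently fitting a different model, because no
installed backend offers full-ML non-gaussian GLMMs. Non-convergence —
including separation in binomial fits — flags the fit and invalidates the
whole comparison for that trait rather than raising.

Classification uses the standard ΔAIC ≥ 2 rule (threshold configurable):
below 2 the metrics are INDISTINGUISHABLE; otherwise the lower-AIC metric
is preferred. Plain AIC is used, not AICc. Whether a metric "beats the
null" (AIC ≤ AIC_null − 2) is tracked independently of which metric is
preferred; the two flags answer different questions and are not merged
into a combined rule. Raising the threshold can only move traits toward
INDISTINGUISHABLE, never away from it.

Tallies across traits test each sex's ordinal/proportional split against
chance with the two-tailed exact binomial test (small-p-values method: sum
of outcome probabilities no larger than the observed outcome's) and
contrast the sexes with the two-sided Fisher exact test. Both are exact
enumerations (scipy), cross-checked in the test suite against independent
brute-force enumeration. INDISTINGUISHABLE and invalid traits do not enter
the tests.

## Simulator

The generator emulates a multi-group longitudinal study: each group holds a
latent linear hierarchy; every dyad fights a fixed number of bouts per
month, the higher-ranked member winning each independently with probability
1 − ε; immigrants join at the bottom of the hierarchy (random insertion is
available as a flag); traits are generated monthly from the latent ranks.

Regimes fix the resource geometry: density-dependent keeps the total
resource base at r₁ for any hierarchy size (per-capita r₁/n, declining);
density-independent grows it as r₁·n (per-capita constant). The two
per-capita curves intersect at n = 1 with value r₁ (default 0.2 resource
units — e.g. oestrous females — per day).

Trait generators:

- **linear** — density-dependent: y = α − β_ord·k + N(0, σ²);
  density-independent: y = α + β_prop·p + N(0, σ²).
- **queue** (priority of access) — each of 30 days, the number of available
  resource units m is drawn Poisson with mean equal to the regime's
  resource base R(n) (or held at a fixed m for deterministic checks); the m
  top-ranked members obtain access; the trait is the fraction of days with
  access. Under density dependence an individual's expected access depends
  only on its ordinal rank, whatever n; under density independence, only on
  its proportional rank — the two scenarios in their purest form. The
  Poisson choice is a modelling decision: only the mean resource curve is
  specified by the framework, and a count distribution with that mean is the
  minimal completion.

Default study conditions: 4 groups, 24 months, hierarchy sizes 5–15
(initial sizes spread evenly across the range; bottom-joining immigration
with monthly probability 0.15, capped at 15), ε = 0.1, 2 bouts per dyad per
month. Effect sizes default to a signal-to-noise ratio of about one noise
SD per rank step: σ = 1, β_ord = 1, and β_prop = 9 (a unit step in
proportional rank is 1/(n−1) of an ordinal step; 9 ≈ n−1 at the mid-range
size 10). Two slope parameters are needed precisely because the two scales
differ by that factor.

The regime-recovery experiment draws per-replicate seeds deterministically
from one base seed, runs simulate → matrix building (with rosters, so
bout-less members stay ranked) → ordering (prior carried month to month) →
rank table → gaussian three-model comparison, and reports the confusion
summary plus the rate of "metric preferred and beats null" calls — the
false-positive rate of interest when β = 0.

### What the simulator does and does not emulate

It captures the features that make the two metrics separable: multiple
groups of different sizes, hierarchy growth over time, imperfect bout data,
and regime-specific trait generation. It does not model births, deaths,
rank reversals in the latent order (upsets are bout-level only), fission/
fusion, sex-structured interaction, or observation effort varying across
individuals. Passing recovery tests therefore show the statistical
machinery is sound under clean longitudinal variation in hierarchy size;
they do not show that any particular field dataset carries enough such
variation to separate the metrics — with constant n the comparison is
provably uninformative (the designs are affinely equivalent and the
classification is INDISTINGUISHABLE by construction).

## Numerical and scale choices

- Recovery experiments in the test suite use 100 replicates per regime at
  the default study conditions above (~1 s per replicate on one core);
  single-replicate versions of the same checks run at reduced scale in the
  unit tests.
- GLM IRLS tolerance is tightened to 1e-10 so that the affine-equivalence
  identity at fixed n holds to 1e-6 in AIC.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical config + seed gives byte-identical outputs.

## Known limitations

- The ordering heuristic above n = 8 is a local optimum; inconsistency-
  minimizing orderings are NP-hard in general and exhaustive search is the
  only exactness guarantee offered.
- Cardinal metrics (Elo, David's score) and inconsistency-strength-weighted
  I&SI variants are out of scope, as are intersex matrices.
- The comparison assumes the three candidate models differ only in the rank
  term; it does not search model space or correct for multiple testing
  across traits.
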