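# Methods

## The decision model

`oppmcda` implements a weighted-additive MCDA value model for comparing
off-patent medicines. For a product with partial scores `sᵢ ∈ [0, 1]` on
criteria with normalized weights `wᵢ` (Σwᵢ = 1), the total is
`V = 100 · Σᵢ wᵢ sᵢ` on a 0–100 scale. Additivity assumes preferential
independence between criteria — the standard assumption of this model family;
the tool does not attempt to detect or model interactions between criteria.

### Weight elicitation

Weights are not entered directly. They come from a four-stage anonymous
group-voting protocol:

1. **Inclusion (plurality).** A categorical vote on how many of the proposed
   criteria to keep. The winner is the option with the largest share. Exact
   ties are never broken silently: the result marks the tie, and a tie-break
   policy must be chosen explicitly (`rerun` forces a re-vote error, `fewest`
   / `most` pick deterministically among the tied "keep_N" options). If the
   winning option keeps fewer criteria than proposed, the pipeline stops with
   a structured error: the follow-up vote on *which* criteria to drop is a
   separate workshop step this tool does not model, since the pilot protocol
   it implements never exercised that branch.
2. **Threshold (mean).** The price-differential threshold *T* is the
   arithmetic mean of numeric votes, in percent of the reference price.
   Means, not medians, are used throughout for numeric questions — the
   protocol enters group averages into the tool after each voting round.
3. **SMART batch ranking.** Criteria are ranked in ordered batches (for nine
   criteria: top three, middle three, bottom three). Within a batch each
   voter submits an ordered list drawn from the ids not yet placed; the group
   order is ascending mean of within-batch positions (equivalent to a Borda
   count for fixed-size batches). Ties on mean position are broken by
   lexicographic criterion id — a deterministic, documented choice; the
   protocol itself is silent on within-batch ties. A ballot naming an
   already-placed id is a validation error naming the voter and the id.
4. **Swing increments (mean).** For each adjacent rank pair, voters state the
   percentage by which rank *i* outweighs rank *i+1*; per-question means give
   Δ₁…Δₙ₋₁.

### The weight chain

"Incremental weight over the previous criterion" is composed multiplicatively
from the bottom: the last rank is the anchor with raw weight 1 and
`raw[i] = raw[i+1] · (1 + Δᵢ)`; normalized weights are `raw / Σ raw`. This
bottom-anchored multiplicative reading is the one under which the pilot's
eight elicited increments reproduce all nine of its published final weights
to one decimal. Its consequences, enforced as invariants:

- Σwᵢ = 1 to 1e−12 (normalization is exact up to float rounding);
- weights are non-increasing in rank, with `wᵢ = wᵢ₊₁` exactly when Δᵢ = 0
  (the pilot's rank-7/rank-8 pair);
- multiplying all raw weights by any positive constant leaves normalized
  weights unchanged;
- negative increments are rejected (they would break rank monotonicity).

A numerical caveat: "equality iff Δ = 0" holds in floating point only for
increments above machine epsilon (Δ ≳ 1e−16, where `1 + Δ > 1`); the property
tests therefore draw increments from {0} ∪ [1e−6, 5].

### Partial value functions

**Price.** `s = clamp(1 − (p − p_ref)/(T·p_ref), 0, 1)`, with `p_ref` the
cheapest comparator's price by default (the reference is endogenous to the
comparison set; an external reference may be supplied, and cheaper products
then clamp to 1). The function is linear on `[p_ref, p_ref(1+T)]`, weakly
decreasing, bounded in [0, 1], and 1-Lipschitz in the normalized price
`(p − p_ref)/(T·p_ref)`. At the cutoff `p = p_ref(1+T)` the linear form is
exactly 0, so "not eligible above the cutoff" needs no discontinuity.

**Ordinal criteria.** The pilot did not publish the scoring scales used for
its non-price criteria, so scales are configuration. The default is a
four-level ladder (none/low/moderate/high → 0, 1/3, 2/3, 1): equally spaced,
anchored at 0 and 1, deliberately neutral. Any strictly increasing scale with
max 1 and min ≥ 0 can be set per criterion in the criteria config.

### Rounding and display

All arithmetic is at full double precision; rounding to one decimal (percent
for weights, points for totals) happens only at display, using decimal
half-up. None of the pilot's published weights sits on a .x5 boundary, so
half-up versus banker's rounding is immaterial for reproducing them. Ranking
uses unrounded totals, so display rounding can never create artificial ties;
exact ties are reported as groups, never broken silently.

## Sensitivity scan

Rank stability is probed by perturbing the *increments*, not the final
weights: each Δᵢ is multiplied by an independent factor uniform on
[1−ε, 1+ε], the chain is re-derived (so every perturbed scheme is still a
valid elicitation outcome), products are re-scored, and the per-pair reversal
frequency against the baseline order is reported. Baseline ties are resolved
by the reported baseline order; a perturbed exact tie counts as half a
reversal. Two products with equal baseline totals whose tie the perturbation
breaks symmetrically therefore show a reversal frequency near 0.5, which is
the expected signature rather than an artifact. Note that a zero increment
stays zero under multiplicative jitter — criteria tied by Δ = 0 remain tied
by design.

## Synthetic workshops (fixtures)

`generate_ballots` emulates the elicitation structure around a planted
consensus: defaults are 21 voters (the pilot's panel size), the pilot's
elicited increments, and a threshold distribution centred on 204%. Noise
models:

- **Ranking noise**: each voter perturbs the planted ranking by k ~
  Binomial(n−1, noise) random adjacent transpositions — the simplest
  neighborhood noise with one intensity knob. Ballots are generated
  *sequentially*: after each batch the group aggregate fixes the placed
  criteria and every voter ranks their top remaining ids by their own noisy
  preference, so generated ballots always respect the eligible-pool rule even
  when voters disagree across batch boundaries.
- **Numeric spread**: threshold and increment votes are normal around the
  planted mean, truncated at 0 (votes are non-negative percentages).

With zero noise every voter reproduces the planted profile and the pipeline's
output is known in closed form — this is the recovery oracle used in the
tests. What the generator does **not** emulate: anchoring after seeing
interim results, strategic voting, correlated preferences across criteria,
or panel attrition. Passing recovery tests therefore demonstrates the
pipeline's correctness as an aggregation machine, not robustness of the
elicited weights to panel composition or behavioural effects in real
workshops.

`generate_dossiers` samples levels uniformly per scale and prices uniformly
over a range; for n ≥ 2 the last two dossiers form a constructed dominance
pair (one weakly better on every criterion and cheaper), giving the dominance
consistency property (`sᵢ(A) ≥ sᵢ(B) ∀i ⇒ V(A) ≥ V(B)`) a guaranteed
non-vacuous test on every draw.

## Reproducing the pilot's numbers

The pilot published group-level aggregates only — vote shares, the threshold,
the increments and the final weights — not per-voter ballots, the product
test case, or the non-price scales. `scripts/acceptance.py` therefore
reconstructs a ballot set whose aggregates equal the published values (21
voters split 12/4/5 on inclusion, the closest integer realisation of the
reported 57/19/24 percent shares; unanimous batch rankings in the elicited
order; numeric votes as symmetric two-point splits around each published
mean), runs `run_workshop`, and evaluates the price function at the published
202 AED / 100 AED / 204% example. Every aggregation stage is
permutation-invariant, so the seed (which shuffles ballot order) does not
affect the output. Quantities the pilot did not publish are covered by the
property suites in `tests/` (normalization, monotonicity, scale invariance,
price-function anchors and Lipschitz bound, dominance consistency, unanimity
recovery, brute-force agreement of the batch ranking on small panels) rather
than by point comparisons.

## Problem sizes

The test suite's stochastic sweeps use 1,000 random increment vectors, 1,000
random dossier pairs, a 10,000-trial sensitivity run on a two-criterion tie,
a 20,000-draw noise-model cross-check, and exhaustive enumeration of all
3-criterion voter-profile combinations up to 3 voters — sizes at which every
estimate used in an assertion has negligible Monte-Carlo error while the
whole suite runs in a few seconds.

## Known limitations

- The exclusion branch of the inclusion vote (keep fewer than all criteria)
  is reported but not resolved; see above.
- Weight elicitation assumes a complete ballot set per stage; partially
  attending voters are rejected, not imputed.
- Currency is AED throughout; the price function is scale-free in the ratio
  p/p_ref, so this matters only for display.
- The additive model ignores criterion interactions, and the sensitivity scan
  perturbs increments only — it does not propagate uncertainty in the ordinal
  performance assessments.
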