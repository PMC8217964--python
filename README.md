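# oppmcda

A multi-criteria decision analysis (MCDA) toolkit for value-based purchasing
of off-patent (generic) medicines, built around the pilot tool developed with
the Dubai Health Authority. It is written for procurement analysts and
health-policy researchers who need to (a) turn anonymous workshop votes into
a defensible set of criterion weights and (b) score competing products under
those weights.

## The model

Products are compared on the nine criteria of the international evidence
framework for off-patent pharmaceutical review (EFOR) — real-world outcomes,
manufacturing quality, equivalence with the originator, stability and
formulation, acquisition cost, supply reliability, macroeconomic benefit,
pharmacovigilance, and added-value services. The workshop protocol elicits,
by anonymous vote:

1. **Criteria inclusion** — a plurality vote on how many proposed criteria to
   keep.
2. **Price-differential threshold** *T* — the mean voted percentage above the
   cheapest alternative's price beyond which a product earns no price score.
3. **SMART ranking** — criteria ranked in batches (most important three
   first); within a batch the group rank is the ascending mean of voters'
   positions.
4. **Swing increments** Δ₁…Δ₈ — for each adjacent pair of ranks, the mean
   voted percentage by which rank *i* outweighs rank *i+1*.

Weights follow a bottom-anchored multiplicative chain: the last rank has raw
weight 1, `raw[i] = raw[i+1] · (1 + Δᵢ)`, and final weights are the raw
weights normalized to sum to 100%. A product's score is the weighted-additive
total on a 0–100 scale, `V = 100 · Σᵢ wᵢ sᵢ`, where ordinal criteria map
performance levels through a scoring scale and the price criterion uses the
linear threshold partial-value function

```
s_price(p) = clamp(1 − (p − p_ref) / (T · p_ref), 0, 1)
```

with `p_ref` the cheapest comparator's price: the cheapest product earns the
full price score, and any product costing more than `p_ref · (1 + T)` earns
none of it.

## Worked example

The built-in `demo` replays the pilot workshop from its published aggregates
(21 voters; 204% voted threshold; elicited swing increments):

```
$ oppmcda demo
Criteria                                            Rank  Incremental weight  Final weight (%)
--------------------------------------------------  ----  ------------------  ----------------
Real-world clinical or economic outcomes            1     14.5%               19.8
Quality assurance of manufacturing                  2     16.8%               17.3
Equivalence with the references (original) product  3     20.5%               14.8
Stability and drug formulation                      4     30.3%               12.3
Pharmaceutical acquisition cost (price)             5     23.2%               9.4
Drug supply reliability                             6     16.1%               7.7
Macroeconomic benefit (local investment)            7     0.0%                6.6
Pharmacovigilance                                   8     19.5%               6.6
Added value service related to the product          9     —                   5.5
price threshold: 204%
```

The final-weight column is the normalized chain: real-world outcomes carry
19.8% of the total score, acquisition cost 9.4%, and the zero increment at
rank 7 gives macroeconomic benefit and pharmacovigilance identical 6.6%
weights.

Scoring synthetic dossiers end to end:

```
$ oppmcda fixtures --out-dir demo --seed 3 --n-products 3
$ oppmcda rank --ballots demo/ballots.csv --dossiers demo/dossiers.csv
1. p002  total 87.8
2. p003  total 48.2
3. p001  total 46.1
$ oppmcda sensitivity --ballots demo/ballots.csv --dossiers demo/dossiers.csv -n 1000 --perturbation 0.5 --seed 1
baseline order: p002 > p003 > p001
reversal p001 vs p002: 0.000
reversal p001 vs p003: 0.046
reversal p002 vs p003: 0.000
```

p002 wins on strong quality criteria despite not being cheapest; the
sensitivity scan jitters every swing increment by up to ±50% and reports how
often each pairwise order flips — here the close p001/p003 pair reverses in
4.6% of 1000 perturbed re-scorings, while the clear winner never does.

The same pipeline runs from the library: `default_efor_registry()`,
`read_ballots()`, `run_workshop()`, `score_products()`, `rank_products()`,
`sensitivity_scan()`.

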