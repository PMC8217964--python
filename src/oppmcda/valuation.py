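"""Product scoring: price partial-value function and weighted-additive totals.

Each product is scored per criterion on [0, 1]. Ordinal criteria map their
performance level through the criterion's scoring scale; the acquisition-cost
criterion uses a linear threshold partial-value function anchored at the
cheapest comparator: the cheapest product earns the full price score, the
score falls linearly with the price differential, and a product whose price
exceeds the reference by more than the voted threshold earns nothing.
The total is the weight-additive sum on a 0-100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .criteria import Criterion, CriterionSet

if TYPE_CHECKING:  # pragma: no cover
    from .elicitation import WeightScheme

__all__ = [
    "PriceRule",
    "ProductDossier",
    "ScoreCard",
    "ValuationError",
    "price_score",
    "criterion_score",
    "total_score",
    "score_products",
    "rank_products",
    "sensitivity_scan",
    "SensitivityReport",
]


class ValuationError(ValueError):
    pass


@dataclass(frozen=True)
class PriceRule:
    """Linear threshold partial-value function for the price criterion.

    ``threshold`` is the voted price-differential ceiling as a fraction of the
    reference price (2.04 for the voted 204%); ``reference_price`` is the
    cheapest comparator's price in AED, or None until a comparison set fixes
    it (the default is endogenous: the minimum price among compared dossiers).
    """

    threshold: float
    reference_price: float | None = None

    def __post_init__(self):
        if not (self.threshold > 0) or not math.isfinite(self.threshold):
            raise ValuationError(f"threshold must be positive, got {self.threshold}")
        if self.reference_price is not None and not (self.reference_price > 0):
            raise ValuationError(f"reference price must be positive, got {self.reference_price}")

    def with_reference(self, p_ref: float) -> "PriceRule":
        return PriceRule(threshold=self.threshold, reference_price=float(p_ref))

    @property
    def cutoff_price(self) -> float:
        """Price at and beyond which the score is exactly 0: p_ref·(1 + T)."""
        if self.reference_price is None:
            raise ValuationError("price rule has no reference price yet")
        return self.reference_price * (1.0 + self.threshold)


@dataclass(frozen=True)
class ProductDossier:
    """One product's submission: price in AED and per-criterion levels."""

    product_id: str
    price: float
    performance: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "performance", dict(self.performance))
        if not (self.price > 0) or not math.isfinite(self.price):
            raise ValuationError(f"product {self.product_id!r}: price must be positive")


@dataclass(frozen=True)
class ScoreCard:
    """Scored product: partial scores, weighted contributions, 0-100 total."""

    product_id: str
    partials: Mapping[str, float]
    contributions: Mapping[str, float]
    total: float
    scheme_fingerprint: str

    def __post_init__(self):
        object.__setattr__(self, "partials", dict(self.partials))
        object.__setattr__(self, "contributions", dict(self.contributions))

    def display_total(self, ndigits: int = 1) -> float:
        from .elicitation import round_half_up

        return round_half_up(self.total, ndigits)


def price_score(p: float, rule: PriceRule) -> float:
    """Linear threshold partial value of price ``p``.

    ``s = clamp(1 − (p − p_ref)/(T·p_ref), 0, 1)``: 1 at or below the
    reference price, falling linearly to 0 at ``p_ref·(1+T)`` and beyond.
    """
    if not (p > 0) or not math.isfinite(p):
        raise ValuationError(f"price must be positive, got {p}")
    if rule.reference_price is None:
        raise ValuationError("price rule has no reference price; score within a comparison set")
    p_ref = rule.reference_price
    s = 1.0 - (p - p_ref) / (rule.threshold * p_ref)
    return min(1.0, max(0.0, s))


def criterion_score(level: str, criterion: Criterion) -> float:
    """Scale value of an ordinal performance level (monotone in level order)."""
    if criterion.is_price:
        raise ValuationError(f"criterion {criterion.id!r} is scored by the price rule")
    try:
        return criterion.scale.value(level)
    except KeyError:
        raise ValuationError(
            f"criterion {criterion.id!r}: unknown level {level!r} "
            f"(expected one of {list(criterion.scale.labels)})"
        ) from None


def total_score(
    d: ProductDossier, ws: "WeightScheme", rule: PriceRule, cs: CriterionSet
) -> ScoreCard:
    """Weighted-additive total of one dossier on the 0-100 scale.

    The price criterion's partial comes from :func:`price_score` (the rule
    must carry a reference price); every other criterion maps its level
    through its scale. Missing performance entries are reported together.
    """
    missing = [c.id for c in cs.non_price if c.id not in d.performance]
    if missing:
        raise ValuationError(
            f"product {d.product_id!r}: missing performance for criteria {missing}"
        )
    weights = ws.as_mapping()
    extra = [cid for cid in cs.ids if cid not in weights]
    if extra:
        raise ValuationError(f"weight scheme does not cover criteria {extra}")
    partials: dict[str, float] = {}
    contributions: dict[str, float] = {}
    for c in cs.criteria:
        s = price_score(d.price, rule) if c.is_price else criterion_score(d.performance[c.id], c)
        partials[c.id] = s
        contributions[c.id] = 100.0 * weights[c.id] * s
    total = math.fsum(contributions.values())
    return ScoreCard(
        product_id=d.product_id,
        partials=partials,
        contributions=contributions,
        total=total,
        scheme_fingerprint=ws.fingerprint,
    )


def score_products(
    dossiers: Sequence[ProductDossier],
    ws: "WeightScheme",
    rule: PriceRule,
    cs: CriterionSet,
) -> list[ScoreCard]:
    """Score a comparison set of dossiers under one scheme.

    If the rule has no reference price it is anchored at the minimum price in
    the set (the cheapest alternative), per the elicited protocol.
    """
    if not dossiers:
        raise ValuationError("empty comparison set")
    if rule.reference_price is None:
        rule = rule.with_reference(min(d.price for d in dossiers))
    return [total_score(d, ws, rule, cs) for d in dossiers]


def rank_products(cards: Sequence[ScoreCard]) -> list[list[ScoreCard]]:
    """Order score cards by descending total; exact ties stay grouped.

    Returns a list of tie groups (singletons when totals are distinct); the
    flattened output is a permutation of the input and stable under input
    reordering up to tie-group membership.
    """
    if not cards:
        raise ValuationError("no score cards to rank")
    fps = {c.scheme_fingerprint for c in cards}
    if len(fps) > 1:
        raise ValuationError(f"cards scored under different weight schemes: {sorted(fps)}")
    groups: dict[float, list[ScoreCard]] = {}
    for c in cards:
        groups.setdefault(c.total, []).append(c)
    out = []
    for total in sorted(groups, reverse=True):
        out.append(sorted(groups[total], key=lambda c: c.product_id))
    return out


@dataclass(frozen=True)
class SensitivityReport:
    """Rank-reversal frequencies under random perturbation of the increments.

    ``reversal_freq`` maps each unordered product pair to the fraction of
    perturbed re-scorings whose relative order differs from the baseline
    (ties in either run count as half a reversal).
    """

    perturbation: float
    n: int
    seed: int
    baseline_order: tuple[str, ...]
    reversal_freq: Mapping[tuple[str, str], float]

    def __post_init__(self):
        object.__setattr__(self, "reversal_freq", dict(self.reversal_freq))


def sensitivity_scan(
    dossiers: Sequence[ProductDossier],
    ws: "WeightScheme",
    rule: PriceRule,
    cs: CriterionSet,
    perturbation: float,
    n: int,
    seed: int,
) -> SensitivityReport:
    """Probe rank stability by jittering the elicited swing increments.

    Each trial multiplies every increment Δᵢ by an independent factor drawn
    uniformly from [1−perturbation, 1+perturbation], re-derives the weight
    chain (so perturbed schemes stay valid), re-scores all dossiers, and
    records, per product pair, whether their order reversed relative to the
    unperturbed baseline. Deterministic given ``seed``.
    """
    from .elicitation import derive_weights

    if perturbation < 0:
        raise ValuationError("perturbation must be >= 0")
    if n < 1:
        raise ValuationError("need at least one trial")
    base_cards = score_products(dossiers, ws, rule, cs)
    base_totals = {c.product_id: c.total for c in base_cards}
    order = tuple(
        c.product_id for grp in rank_products(base_cards) for c in grp
    )
    pids = sorted(base_totals)
    pairs = [(a, b) for i, a in enumerate(pids) for b in pids[i + 1 :]]
    if not pairs:
        return SensitivityReport(perturbation, n, seed, order, {})

    rng = np.random.default_rng(seed)
    incr = np.asarray(ws.incrementals, dtype=float)
    rev_count = {pair: 0.0 for pair in pairs}

    def sign(a: float, b: float) -> int:
        return (a > b) - (a < b)

    # baseline exact ties are resolved by the reported baseline order, so a
    # tie-breaking perturbation registers as a reversal about half the time
    pos = {pid: i for i, pid in enumerate(order)}
    base_sign = {
        (a, b): sign(base_totals[a], base_totals[b]) or sign(pos[b], pos[a])
        for a, b in pairs
    }
    for _ in range(n):
        factors = rng.uniform(1.0 - perturbation, 1.0 + perturbation, size=incr.shape)
        pert = derive_weights(ws.ranked_ids, incr * factors)
        cards = score_products(dossiers, pert, rule, cs)
        totals = {c.product_id: c.total for c in cards}
        for a, b in pairs:
            s = sign(totals[a], totals[b])
            if s == 0:
                rev_count[(a, b)] += 0.5  # perturbed tie: ambiguous order
            elif s != base_sign[(a, b)]:
                rev_count[(a, b)] += 1.0
    freq = {pair: c / n for pair, c in rev_count.items()}
    return SensitivityReport(perturbation, n, seed, order, freq)
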