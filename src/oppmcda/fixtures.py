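"""Deterministic synthetic workshops and dossiers for end-to-end testing.

The generator emulates the structure of the elicitation workshop — a panel of
voters answering the inclusion question, the threshold question, the batched
SMART ranking and the eight swing-increment questions — around a *planted*
consensus profile. With zero ranking noise every voter reproduces the planted
profile exactly, so the pipeline's output is known in closed form; with noise,
each voter holds a privately perturbed ranking (random adjacent transpositions)
and votes consistently with it at every batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .criteria import CriterionSet, default_efor_registry
from .elicitation import (
    Ballot,
    Q_INCLUSION,
    Q_INCREMENTS,
    Q_RANK_BATCHES,
    Q_THRESHOLD,
    QuestionType,
    VoteSet,
    standard_question_registry,
)
from .valuation import ProductDossier

__all__ = [
    "WorkshopScenario",
    "generate_ballots",
    "generate_dossiers",
    "pilot_workshop_votes",
    "PILOT_INCLUSION_COUNTS",
    "PILOT_THRESHOLD_PCT",
    "PILOT_INCREMENTS_PCT",
]

#: Published aggregates of the 21-participant pilot workshop. The inclusion
#: split is the closest integer realisation of the reported 57/19/24 percent
#: shares; the threshold and swing increments are the elicited group values.
PILOT_INCLUSION_COUNTS = {"keep_9": 12, "keep_8": 4, "keep_7": 5}
PILOT_THRESHOLD_PCT = 204.0
PILOT_INCREMENTS_PCT = (14.5, 16.8, 20.5, 30.3, 23.2, 16.1, 0.0, 19.5)


def pilot_workshop_votes(seed: int = 0, cs: CriterionSet | None = None) -> VoteSet:
    """Reconstruct the pilot workshop's ballots from its published aggregates.

    Inclusion ballots realise the reported vote shares over 21 voters; the
    ranking batches are unanimous on the elicited order; each threshold and
    increment question is answered with a symmetric two-point split around
    the published group mean, so every aggregate reproduces the published
    value exactly. ``seed`` shuffles ballot order (aggregation is
    permutation-invariant, so results are seed-independent).
    """
    if cs is None:
        cs = default_efor_registry()
    ranked = tuple(c.id for c in cs.by_rank())
    n_voters = sum(PILOT_INCLUSION_COUNTS.values())
    voters = [f"v{i + 1:03d}" for i in range(n_voters)]
    ballots: list[Ballot] = []

    pool = list(voters)
    for option, count in PILOT_INCLUSION_COUNTS.items():
        for v in pool[:count]:
            ballots.append(Ballot(v, Q_INCLUSION, option))
        pool = pool[count:]

    # two-point symmetric splits keep per-question means at the published value
    def numeric_votes(qid: str, mean: float, half_width: float) -> None:
        for i, v in enumerate(voters):
            offset = half_width if i % 2 == 0 else -half_width
            if n_voters % 2 == 1 and i == n_voters - 1:
                offset = 0.0
            ballots.append(Ballot(v, qid, mean + offset))

    numeric_votes(Q_THRESHOLD, PILOT_THRESHOLD_PCT, 4.0)
    batch = len(ranked) // len(Q_RANK_BATCHES)
    for k, q in enumerate(Q_RANK_BATCHES):
        triple = ranked[k * batch : (k + 1) * batch]
        ballots += [Ballot(v, q, triple) for v in voters]
    for qid, pct in zip(Q_INCREMENTS, PILOT_INCREMENTS_PCT):
        numeric_votes(qid, pct, min(0.2, pct / 2))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ballots))
    return VoteSet(
        ballots=tuple(ballots[i] for i in order), registry=standard_question_registry()
    )


@dataclass(frozen=True)
class WorkshopScenario:
    """Parameters of a synthetic workshop.

    Defaults mirror the pilot workshop's shape: 21 voters over nine criteria,
    threshold votes centred on 204% (the voted value), planted increments set
    to the elicited swing percentages. ``ranking_noise`` is the per-voter
    probability scale of adjacent swaps: each voter applies k ~ Binomial(n−1,
    noise) random adjacent transpositions to the planted ranking.
    """

    seed: int
    n_voters: int = 21
    planted_ranking: tuple[str, ...] = ()
    planted_increments: tuple[float, ...] = (
        0.145, 0.168, 0.205, 0.303, 0.232, 0.161, 0.0, 0.195,
    )
    threshold_mean: float = 204.0
    threshold_spread: float = 0.0
    ranking_noise: float = 0.0
    increment_spread: float = 0.0

    def __post_init__(self):
        if self.n_voters < 1:
            raise ValueError("need at least one voter")
        if not (0.0 <= self.ranking_noise <= 1.0):
            raise ValueError("ranking noise must be in [0, 1]")
        if self.threshold_spread < 0 or self.increment_spread < 0:
            raise ValueError("spreads must be non-negative")


def _noisy_ranking(
    planted: Sequence[str], noise: float, rng: np.random.Generator
) -> list[str]:
    """Apply k ~ Binomial(n-1, noise) random adjacent transpositions."""
    order = list(planted)
    n = len(order)
    if noise == 0.0 or n < 2:
        return order
    k = rng.binomial(n - 1, noise)
    for _ in range(k):
        j = int(rng.integers(0, n - 1))
        order[j], order[j + 1] = order[j + 1], order[j]
    return order


def _truncated_normal(mean: float, spread: float, rng: np.random.Generator) -> float:
    """Normal draw truncated at zero (votes are non-negative percentages)."""
    if spread == 0.0:
        return max(mean, 0.0)
    while True:
        v = rng.normal(mean, spread)
        if v >= 0.0:
            return float(v)


def generate_ballots(sc: WorkshopScenario, cs: CriterionSet | None = None) -> VoteSet:
    """Draw one complete synthetic VoteSet per the scenario.

    Voters answer every question of the standard workshop. The ranking stage
    is simulated sequentially, as in the live protocol: after each batch the
    group aggregate fixes the placed criteria, and every voter then ranks
    their top remaining ids according to their own (noisy) preference — so
    generated ballots always respect the eligible-pool rule. Fully
    reproducible given the scenario seed.
    """
    if cs is None:
        cs = default_efor_registry()
    planted = sc.planted_ranking or cs.ids
    if sorted(planted) != sorted(cs.ids):
        raise ValueError("planted ranking must be a permutation of the criterion ids")
    n = len(planted)
    if len(sc.planted_increments) != n - 1:
        raise ValueError(f"need {n - 1} planted increments for {n} criteria")

    rng = np.random.default_rng(sc.seed)
    registry = standard_question_registry()
    voters = [f"v{i + 1:03d}" for i in range(sc.n_voters)]
    ballots: list[Ballot] = []

    # inclusion: unanimous keep-all (the scenario plants a full consensus set)
    keep_all = f"keep_{n}"
    ballots += [Ballot(v, Q_INCLUSION, keep_all) for v in voters]

    # threshold votes around the planted mean, truncated at zero
    for v in voters:
        ballots.append(
            Ballot(v, Q_THRESHOLD, _truncated_normal(sc.threshold_mean, sc.threshold_spread, rng))
        )

    # each voter's private noisy preference order
    prefs = {v: _noisy_ranking(planted, sc.ranking_noise, rng) for v in voters}

    # sequential batches: pool shrinks by the aggregate's picks, voters rank
    # their top-m among the remaining pool per their own preference
    pool = list(planted)
    batch_size = n // len(Q_RANK_BATCHES)
    for q in Q_RANK_BATCHES:
        m = batch_size
        votes_this_batch: dict[str, tuple[str, ...]] = {}
        for v in voters:
            mine = [cid for cid in prefs[v] if cid in pool][:m]
            votes_this_batch[v] = tuple(mine)
            ballots.append(Ballot(v, q, tuple(mine)))
        # aggregate exactly as smart_rank does to fix the next pool
        positions: dict[str, list[int]] = {}
        for triple in votes_this_batch.values():
            for pos, cid in enumerate(triple, start=1):
                positions.setdefault(cid, []).append(pos)
        order = sorted(
            positions, key=lambda cid: (math.fsum(positions[cid]) / len(positions[cid]), cid)
        )
        for cid in order[:m]:
            pool.remove(cid)

    # increment votes: truncated-normal spread around each planted value (%)
    for qi, d in zip(Q_INCREMENTS, sc.planted_increments):
        for v in voters:
            ballots.append(
                Ballot(v, qi, _truncated_normal(100.0 * d, sc.increment_spread, rng))
            )

    return VoteSet(ballots=tuple(ballots), registry=registry)


def generate_dossiers(
    n_products: int,
    cs: CriterionSet,
    price_range: tuple[float, float],
    seed: int,
) -> list[ProductDossier]:
    """Draw complete random dossiers; reproducible given the seed.

    Levels are sampled uniformly over each criterion's scale and prices
    uniformly over ``price_range``. When ``n_products >= 2`` the last two
    dossiers form a constructed dominance pair (the penultimate weakly
    dominates the last on every criterion and on price) for property tests.
    """
    if n_products < 1:
        raise ValueError("need at least one product")
    lo, hi = price_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid price range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    dossiers = []
    for i in range(n_products):
        perf = {
            c.id: c.scale.labels[int(rng.integers(0, len(c.scale.labels)))]
            for c in cs.non_price
        }
        price = float(rng.uniform(lo, hi))
        dossiers.append(ProductDossier(product_id=f"p{i + 1:03d}", price=price, performance=perf))
    if n_products >= 2:
        # rebuild the last two as a dominance pair: dominator takes, per
        # criterion, a level at least as high as the dominated one
        weak = dossiers[-1]
        better_perf = {}
        for c in cs.non_price:
            labels = c.scale.labels
            base_idx = labels.index(weak.performance[c.id])
            better_perf[c.id] = labels[int(rng.integers(base_idx, len(labels)))]
        better_price = float(rng.uniform(lo, weak.price))
        dossiers[-2] = ProductDossier(
            product_id=dossiers[-2].product_id, price=better_price, performance=better_perf
        )
    return dossiers
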