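"""Group elicitation: ballot aggregation, SMART batch ranking, swing weights.

The workshop protocol runs four stages on anonymous ballots:

1. a categorical vote on how many of the proposed criteria to keep,
2. a numeric vote on the price-differential threshold (percent),
3. SMART ranking in batches — voters rank the most important criteria first,
   then the next batch among those still unplaced, and so on,
4. per-adjacent-rank swing increments Δᵢ (percent), averaged across voters.

Weights follow from the increments by a bottom-anchored multiplicative chain:
the last-ranked criterion gets raw weight 1, and each criterion's raw weight
exceeds the next rank's by its increment, raw[i] = raw[i+1]·(1 + Δᵢ). Raw
weights are then normalized to sum to 1 (displayed as percentages summing to
100). A zero increment therefore yields exactly equal adjacent weights.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .criteria import CriterionSet
from .valuation import PriceRule

__all__ = [
    "QuestionType",
    "Ballot",
    "VoteSet",
    "WeightScheme",
    "ElicitationError",
    "TieError",
    "BallotValidationError",
    "CategoricalResult",
    "aggregate_categorical",
    "aggregate_numeric",
    "smart_rank",
    "derive_weights",
    "run_workshop",
    "WorkshopResult",
    "Q_INCLUSION",
    "Q_THRESHOLD",
    "Q_RANK_BATCHES",
    "Q_INCREMENTS",
    "standard_question_registry",
    "round_half_up",
]


class ElicitationError(ValueError):
    """Aggregation failed; ``stage`` names the pipeline stage when known."""

    def __init__(self, message: str, *, stage: str | None = None):
        super().__init__(message if stage is None else f"[{stage}] {message}")
        self.stage = stage


class TieError(ElicitationError):
    """Exact tie between top categorical options; carries the tied labels."""

    def __init__(self, options: Sequence[str], *, stage: str | None = None):
        self.options = tuple(sorted(options))
        super().__init__(
            f"exact tie between options {self.options}; re-vote or pass an explicit tie-break",
            stage=stage,
        )


class BallotValidationError(ElicitationError):
    """A ballot violates the question contract; names voter and offending value."""


class QuestionType(enum.Enum):
    CATEGORICAL = "categorical"
    NUMERIC = "numeric"
    RANKING_BATCH = "ranking_batch"


@dataclass(frozen=True)
class Ballot:
    """One voter's response to one elicitation question.

    ``response`` is a categorical label (str), a numeric value (float), or an
    ordered tuple of criterion ids for a ranking batch.
    """

    voter_id: str
    question_id: str
    response: str | float | tuple[str, ...]


@dataclass(frozen=True)
class VoteSet:
    """All ballots of a workshop plus the registry typing each question."""

    ballots: tuple[Ballot, ...]
    registry: Mapping[str, QuestionType]

    def __post_init__(self):
        object.__setattr__(self, "ballots", tuple(self.ballots))
        object.__setattr__(self, "registry", dict(self.registry))
        seen: set[tuple[str, str]] = set()
        for b in self.ballots:
            if b.question_id not in self.registry:
                raise BallotValidationError(
                    f"voter {b.voter_id!r}: unregistered question {b.question_id!r}"
                )
            key = (b.voter_id, b.question_id)
            if key in seen:
                raise BallotValidationError(
                    f"voter {b.voter_id!r}: duplicate response to {b.question_id!r}"
                )
            seen.add(key)
            qt = self.registry[b.question_id]
            if qt is QuestionType.CATEGORICAL and not isinstance(b.response, str):
                raise BallotValidationError(
                    f"voter {b.voter_id!r}, question {b.question_id!r}: expected a label"
                )
            if qt is QuestionType.NUMERIC and not isinstance(b.response, (int, float)):
                raise BallotValidationError(
                    f"voter {b.voter_id!r}, question {b.question_id!r}: expected a number"
                )
            if qt is QuestionType.RANKING_BATCH and not isinstance(b.response, tuple):
                raise BallotValidationError(
                    f"voter {b.voter_id!r}, question {b.question_id!r}: expected an ordered id list"
                )

    def for_question(self, question_id: str) -> tuple[Ballot, ...]:
        return tuple(b for b in self.ballots if b.question_id == question_id)


# Conventional question ids of the standard nine-criterion workshop.
Q_INCLUSION = "criteria_inclusion"
Q_THRESHOLD = "price_threshold"
Q_RANK_BATCHES = ("ranking_batch_1", "ranking_batch_2", "ranking_batch_3")
Q_INCREMENTS = tuple(f"increment_{i}" for i in range(1, 9))


def standard_question_registry() -> dict[str, QuestionType]:
    """Question registry for the standard workshop (9 criteria, 3 batches)."""
    reg: dict[str, QuestionType] = {
        Q_INCLUSION: QuestionType.CATEGORICAL,
        Q_THRESHOLD: QuestionType.NUMERIC,
    }
    for q in Q_RANK_BATCHES:
        reg[q] = QuestionType.RANKING_BATCH
    for q in Q_INCREMENTS:
        reg[q] = QuestionType.NUMERIC
    return reg


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used for all displayed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Stage aggregators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoricalResult:
    """Plurality outcome: winner (None on an unresolved tie) and vote shares."""

    winner: str | None
    shares: Mapping[str, float]
    tied: tuple[str, ...] = ()

    @property
    def is_tie(self) -> bool:
        return bool(self.tied)


def aggregate_categorical(
    votes: VoteSet, question_id: str, tie_break: str | None = None
) -> CategoricalResult:
    """Plurality aggregation of a categorical question.

    The winner is the option with the largest ballot share; shares sum to 1
    and the result is invariant under ballot reordering. An exact tie between
    the top options is surfaced explicitly (``winner=None``) unless an explicit
    ``tie_break`` policy is passed: ``"fewest"``/``"most"`` pick the
    lexicographically smallest/largest tied label, mirroring "keep fewest /
    keep most criteria" on keep_N-style options; ``"rerun"`` raises
    :class:`TieError` to force a re-vote.
    """
    ballots = votes.for_question(question_id)
    if not ballots:
        raise ElicitationError(f"no ballots for question {question_id!r}")
    if votes.registry[question_id] is not QuestionType.CATEGORICAL:
        raise ElicitationError(f"question {question_id!r} is not categorical")
    counts: dict[str, int] = {}
    for b in ballots:
        counts[b.response] = counts.get(b.response, 0) + 1
    total = len(ballots)
    shares = {opt: c / total for opt, c in sorted(counts.items())}
    top = max(counts.values())
    leaders = sorted(opt for opt, c in counts.items() if c == top)
    if len(leaders) == 1:
        return CategoricalResult(winner=leaders[0], shares=shares)
    if tie_break == "fewest":
        return CategoricalResult(winner=leaders[0], shares=shares, tied=tuple(leaders))
    if tie_break == "most":
        return CategoricalResult(winner=leaders[-1], shares=shares, tied=tuple(leaders))
    if tie_break == "rerun":
        raise TieError(leaders)
    return CategoricalResult(winner=None, shares=shares, tied=tuple(leaders))


def aggregate_numeric(votes: VoteSet, question_id: str) -> float:
    """Arithmetic mean of the numeric responses (order-invariant)."""
    ballots = votes.for_question(question_id)
    if not ballots:
        raise ElicitationError(f"no ballots for question {question_id!r}")
    if votes.registry[question_id] is not QuestionType.NUMERIC:
        raise ElicitationError(f"question {question_id!r} is not numeric")
    vals = []
    for b in ballots:
        if not isinstance(b.response, (int, float)) or isinstance(b.response, bool):
            raise BallotValidationError(
                f"voter {b.voter_id!r}, question {question_id!r}: non-numeric response"
            )
        vals.append(float(b.response))
    return math.fsum(vals) / len(vals)


def smart_rank(
    votes: VoteSet,
    batch_questions: Sequence[str],
    cs: CriterionSet,
) -> tuple[str, ...]:
    """Aggregate batched SMART rankings into one full criterion ordering.

    Batches are processed in order. Within batch *k* each voter submits an
    ordered list drawn from the ids not yet placed by earlier batches;
    criteria are placed in ascending order of mean within-batch position
    (Borda-equivalent for fixed-size batches). The number of positions a
    batch fills equals its ballots' list length. Ties on mean position are
    broken deterministically by lexicographic criterion id.

    Raises :class:`BallotValidationError`, naming voter and id, if a ballot
    ranks an id outside the eligible pool.
    """
    pool = set(cs.ids)
    ranked: list[str] = []
    for q in batch_questions:
        ballots = votes.for_question(q)
        if not ballots:
            raise ElicitationError(f"no ballots for ranking batch {q!r}")
        if votes.registry[q] is not QuestionType.RANKING_BATCH:
            raise ElicitationError(f"question {q!r} is not a ranking batch")
        sizes = {len(b.response) for b in ballots}
        if len(sizes) != 1:
            raise BallotValidationError(f"batch {q!r}: ballots disagree on list length {sizes}")
        (m,) = sizes
        if m == 0 or m > len(pool):
            raise BallotValidationError(f"batch {q!r}: list length {m} invalid for pool of {len(pool)}")
        positions: dict[str, list[int]] = {}
        for b in ballots:
            if len(set(b.response)) != len(b.response):
                raise BallotValidationError(f"voter {b.voter_id!r}, batch {q!r}: repeated id")
            for pos, cid in enumerate(b.response, start=1):
                if cid not in pool:
                    raise BallotValidationError(
                        f"voter {b.voter_id!r}, batch {q!r}: id {cid!r} not in the eligible pool"
                    )
                positions.setdefault(cid, []).append(pos)
        # ascending mean position, then lexicographic id; take the m winners
        order = sorted(
            positions, key=lambda cid: (math.fsum(positions[cid]) / len(positions[cid]), cid)
        )
        placed = order[:m]
        ranked.extend(placed)
        pool.difference_update(placed)
    if pool:
        raise ElicitationError(
            f"ranking batches left {sorted(pool)} unplaced; add a final batch covering them"
        )
    return tuple(ranked)


# ---------------------------------------------------------------------------
# Weight derivation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightScheme:
    """Normalized swing weights over ranked criteria.

    ``incrementals[i]`` is Δᵢ₊₁, the fractional excess of rank i+1's weight
    over rank i+2's. ``raw`` is the bottom-anchored multiplicative chain and
    ``weights`` its normalization to unit sum (kept at full precision;
    rounding happens only at display).
    """

    ranked_ids: tuple[str, ...]
    incrementals: tuple[float, ...]
    raw: tuple[float, ...]
    weights: tuple[float, ...]

    def weight_of(self, cid: str) -> float:
        return self.weights[self.ranked_ids.index(cid)]

    def display_percents(self, ndigits: int = 1) -> tuple[float, ...]:
        """Weights as percentages, half-up rounded for presentation."""
        return tuple(round_half_up(100.0 * w, ndigits) for w in self.weights)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.ranked_ids, self.weights))

    @property
    def fingerprint(self) -> str:
        import hashlib

        payload = ",".join(self.ranked_ids) + "|" + ",".join(repr(w) for w in self.weights)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def derive_weights(
    ranked_ids: Sequence[str], incrementals: Sequence[float]
) -> WeightScheme:
    """Turn adjacent-rank swing increments into normalized criterion weights.

    The bottom rank is the anchor with raw weight 1; walking up the ranking,
    ``raw[i] = raw[i+1] * (1 + Δᵢ)``. Normalized weights sum to 1 and are
    non-increasing in rank, with equality exactly where Δᵢ = 0.
    """
    ranked_ids = tuple(ranked_ids)
    incrementals = tuple(float(d) for d in incrementals)
    if len(ranked_ids) < 1:
        raise ElicitationError("need at least one ranked criterion")
    if len(incrementals) != len(ranked_ids) - 1:
        raise ElicitationError(
            f"expected {len(ranked_ids) - 1} increments for {len(ranked_ids)} ranks, "
            f"got {len(incrementals)}"
        )
    for i, d in enumerate(incrementals):
        if d < 0 or not math.isfinite(d):
            raise ElicitationError(
                f"increment {i + 1} is {d}; negative or non-finite increments would break "
                "rank monotonicity"
            )
    raw = [1.0]
    for d in reversed(incrementals):
        raw.append(raw[-1] * (1.0 + d))
    raw.reverse()
    total = math.fsum(raw)
    weights = tuple(r / total for r in raw)
    return WeightScheme(
        ranked_ids=ranked_ids,
        incrementals=incrementals,
        raw=tuple(raw),
        weights=weights,
    )


# ---------------------------------------------------------------------------
# End-to-end workshop pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkshopResult:
    """Everything the workshop produced, plus a log of each aggregated value."""

    kept: CriterionSet
    price_rule: PriceRule
    scheme: WeightScheme
    report: tuple[str, ...]


def _kept_count(option: str) -> int | None:
    # inclusion options follow the "keep_N" convention
    if option.startswith("keep_"):
        try:
            return int(option.split("_", 1)[1])
        except ValueError:
            return None
    return None


def run_workshop(
    votes: VoteSet,
    cs: CriterionSet,
    *,
    inclusion_question: str = Q_INCLUSION,
    threshold_question: str = Q_THRESHOLD,
    batch_questions: Sequence[str] = Q_RANK_BATCHES,
    increment_questions: Sequence[str] = Q_INCREMENTS,
    tie_break: str | None = None,
) -> WorkshopResult:
    """Run the four elicitation stages in workshop order.

    Stages: criteria-inclusion plurality vote → price-threshold mean (percent)
    → batched SMART ranking → per-rank increment means → weight chain. Every
    aggregated value entered into the scheme is logged in ``report``. Any
    stage failure is re-raised with the stage name attached.
    """
    log: list[str] = []

    def run_stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ElicitationError as exc:
            if exc.stage is None:
                raise ElicitationError(str(exc), stage=name) from exc
            raise

    # 1. criteria inclusion
    incl = run_stage(
        "inclusion", aggregate_categorical, votes, inclusion_question, tie_break=tie_break
    )
    if incl.winner is None:
        raise ElicitationError(
            f"inclusion vote tied between {incl.tied}; re-vote or pass a tie-break",
            stage="inclusion",
        )
    share_txt = ", ".join(f"{o}={100 * s:.0f}%" for o, s in incl.shares.items())
    log.append(f"inclusion: winner {incl.winner} (shares {share_txt})")
    n_keep = _kept_count(incl.winner)
    if n_keep is not None and n_keep != len(cs):
        raise ElicitationError(
            f"winner {incl.winner!r} keeps {n_keep} of {len(cs)} criteria; the follow-up "
            "exclusion vote is not part of this tool's protocol",
            stage="inclusion",
        )
    kept = cs

    # 2. price-differential threshold (voted in percent)
    threshold_pct = run_stage("threshold", aggregate_numeric, votes, threshold_question)
    log.append(f"threshold: mean {threshold_pct:g}% of the cheapest alternative's price")
    price_rule = PriceRule(threshold=threshold_pct / 100.0)

    # 3. SMART batch ranking
    ranked_ids = run_stage("ranking", smart_rank, votes, batch_questions, kept)
    log.append("ranking: " + " > ".join(ranked_ids))

    # 4. swing increments and weight chain
    increments = []
    for i, q in enumerate(increment_questions, start=1):
        mean_pct = run_stage(f"increment_{i}", aggregate_numeric, votes, q)
        log.append(f"increment {i} (rank {i} over rank {i + 1}): mean {mean_pct:g}%")
        increments.append(mean_pct / 100.0)
    scheme = run_stage("weights", derive_weights, ranked_ids, increments)
    pct = scheme.display_percents()
    log.append("final weights (%): " + ", ".join(f"{cid}={p}" for cid, p in zip(ranked_ids, pct)))

    return WorkshopResult(kept=kept, price_rule=price_rule, scheme=scheme, report=tuple(log))
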