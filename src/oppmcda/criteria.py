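"""Decision criteria, scoring scales and the default nine-criterion registry.

The tool evaluates off-patent (generic) medicines against a fixed set of
decision criteria. Eight of the nine default criteria are scored on ordinal
scales mapped to fractions in [0, 1]; the acquisition-cost criterion is
scored by a linear threshold partial-value function (see
:mod:`oppmcda.valuation`) and is marked here with a distinguished
``PRICE_RULE`` scale sentinel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "ScoringScale",
    "PRICE_RULE",
    "Criterion",
    "CriterionSet",
    "ValidationIssue",
    "ConfigError",
    "DEFAULT_SCALE",
    "default_efor_registry",
    "validate_criterion_set",
    "criterion_set_from_config",
    "criterion_set_to_config",
]


class ConfigError(ValueError):
    """Malformed criteria configuration; ``field`` names the offending entry."""

    def __init__(self, message: str, *, field: str | None = None):
        super().__init__(message)
        self.field = field


@dataclass(frozen=True)
class ScoringScale:
    """Ordered performance levels mapped to fractions of the criterion score.

    ``levels`` is an ordered tuple of ``(label, value)`` pairs; values must be
    strictly increasing, non-negative, and top out at exactly 1 so that the
    best level always earns the criterion's full weight.
    """

    levels: tuple[tuple[str, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple((str(l), float(v)) for l, v in self.levels))

    def value(self, label: str) -> float:
        for lab, val in self.levels:
            if lab == label:
                return val
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.levels)

    def issues(self, owner: str = "scale") -> list["ValidationIssue"]:
        out: list[ValidationIssue] = []
        labels = [l for l, _ in self.levels]
        values = [v for _, v in self.levels]
        if len(set(labels)) != len(labels):
            out.append(ValidationIssue(owner, "duplicate level labels"))
        if not values:
            out.append(ValidationIssue(owner, "scale has no levels"))
            return out
        for (la, va), (lb, vb) in zip(self.levels, self.levels[1:]):
            if vb <= va:
                out.append(
                    ValidationIssue(
                        owner, f"values not strictly increasing at ({la}={va}, {lb}={vb})"
                    )
                )
        if values[0] < 0:
            out.append(ValidationIssue(owner, f"minimum value {values[0]} below 0"))
        if values[-1] != 1:
            out.append(ValidationIssue(owner, f"maximum value {values[-1]} is not 1"))
        return out


class _PriceRuleMarker:
    """Sentinel scale for the criterion scored by the price partial-value function."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PRICE_RULE"


PRICE_RULE = _PriceRuleMarker()

#: Default 4-level ordinal scale for non-price criteria. The workshop did not
#: publish per-criterion scales, so this neutral equally-spaced ladder is the
#: package default and is overridable per criterion in configuration.
DEFAULT_SCALE = ScoringScale(
    levels=(
        ("none", 0.0),
        ("low", 1.0 / 3.0),
        ("moderate", 2.0 / 3.0),
        ("high", 1.0),
    )
)


@dataclass(frozen=True)
class Criterion:
    """One decision criterion: identity, display name, rank and scoring scale."""

    id: str
    name: str
    rank: int | None = None
    scale: Union[ScoringScale, _PriceRuleMarker] = DEFAULT_SCALE
    description: str = ""

    @property
    def is_price(self) -> bool:
        return self.scale is PRICE_RULE or isinstance(self.scale, _PriceRuleMarker)


@dataclass(frozen=True)
class CriterionSet:
    """Ordered collection of criteria with a provenance note."""

    criteria: tuple[Criterion, ...]
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "criteria", tuple(self.criteria))

    def __len__(self) -> int:
        return len(self.criteria)

    def __iter__(self):
        return iter(self.criteria)

    def get(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def by_rank(self) -> tuple[Criterion, ...]:
        return tuple(sorted(self.criteria, key=lambda c: (c.rank is None, c.rank)))

    @property
    def price_criterion(self) -> Criterion | None:
        for c in self.criteria:
            if c.is_price:
                return c
        return None

    @property
    def non_price(self) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if not c.is_price)


@dataclass(frozen=True)
class ValidationIssue:
    """One invariant violation found while validating a criterion set."""

    where: str
    message: str

    def __str__(self) -> str:
        return f"{self.where}: {self.message}"


# ---------------------------------------------------------------------------
# Default registry: the nine-criterion international evidence framework for
# off-patent pharmaceutical review (EFOR), ranked as elicited in the Dubai
# Health Authority workshop. Acquisition cost (rank 5) carries the price rule.
# ---------------------------------------------------------------------------

_EFOR_ROWS: tuple[tuple[str, str, int, bool], ...] = (
    ("real_world_outcomes", "Real-world clinical or economic outcomes", 1, False),
    ("manufacturing_quality", "Quality assurance of manufacturing", 2, False),
    ("reference_equivalence", "Equivalence with the references (original) product", 3, False),
    ("stability_formulation", "Stability and drug formulation", 4, False),
    ("price", "Pharmaceutical acquisition cost (price)", 5, True),
    ("supply_reliability", "Drug supply reliability", 6, False),
    ("macroeconomic_benefit", "Macroeconomic benefit (local investment)", 7, False),
    ("pharmacovigilance", "Pharmacovigilance", 8, False),
    ("added_value_service", "Added value service related to the product", 9, False),
)


def default_efor_registry() -> CriterionSet:
    """Return the default nine-criterion EFOR registry in elicited rank order.

    Idempotent and side-effect free; two calls return equal values. Exactly
    one criterion (acquisition cost, rank 5) is flagged as the price criterion.
    """
    crits = tuple(
        Criterion(
            id=cid,
            name=name,
            rank=rank,
            scale=PRICE_RULE if is_price else DEFAULT_SCALE,
        )
        for cid, name, rank, is_price in _EFOR_ROWS
    )
    return CriterionSet(criteria=crits, source="EFOR default registry")


def validate_criterion_set(cs: CriterionSet) -> list[ValidationIssue]:
    """Check all CriterionSet invariants; empty list iff the set is valid.

    Reports duplicate ids, out-of-range or duplicated ranks, rank gaps, and
    scoring-scale violations. Does not raise on violations — callers decide.
    """
    issues: list[ValidationIssue] = []
    n = len(cs.criteria)

    seen_ids: set[str] = set()
    for c in cs.criteria:
        if c.id in seen_ids:
            issues.append(ValidationIssue(f"criterion {c.id!r}", "duplicate id"))
        seen_ids.add(c.id)

    ranks = [c.rank for c in cs.criteria if c.rank is not None]
    for c in cs.criteria:
        if c.rank is not None and not (1 <= c.rank <= n):
            issues.append(
                ValidationIssue(f"criterion {c.id!r}", f"rank {c.rank} outside [1, {n}]")
            )
    if ranks and len(ranks) == n:
        if sorted(ranks) != list(range(1, n + 1)):
            issues.append(
                ValidationIssue("ranks", f"ranks {sorted(ranks)} are not the permutation 1..{n}")
            )

    n_price = sum(1 for c in cs.criteria if c.is_price)
    if n_price > 1:
        issues.append(ValidationIssue("criteria", f"{n_price} criteria carry the price rule"))

    for c in cs.criteria:
        if not c.is_price:
            issues.extend(c.scale.issues(owner=f"criterion {c.id!r} scale"))
    return issues


# ---------------------------------------------------------------------------
# Config round-trip (JSON / YAML document with a top-level "criteria" list).
# The shipped criteria.schema.json documents the same contract.
# ---------------------------------------------------------------------------


def _scale_from_config(entry, where: str) -> Union[ScoringScale, _PriceRuleMarker]:
    if entry == "price_rule":
        return PRICE_RULE
    if entry is None:
        return DEFAULT_SCALE
    if not isinstance(entry, list):
        raise ConfigError(f"{where}: scale must be 'price_rule' or a list of levels", field=where)
    levels = []
    for i, lev in enumerate(entry):
        if not isinstance(lev, dict) or "label" not in lev or "value" not in lev:
            raise ConfigError(
                f"{where}: scale level {i} must be an object with 'label' and 'value'",
                field=f"{where}.scale[{i}]",
            )
        try:
            levels.append((str(lev["label"]), float(lev["value"])))
        except (TypeError, ValueError) as exc:
            raise ConfigError(
                f"{where}: scale level {i} has non-numeric value", field=f"{where}.scale[{i}].value"
            ) from exc
    return ScoringScale(levels=tuple(levels))


def criterion_set_from_config(doc: dict, source: str = "config") -> CriterionSet:
    """Build a CriterionSet from a parsed JSON/YAML document.

    Raises :class:`ConfigError` naming the offending field on malformed input;
    invariant violations (duplicate ids etc.) are left to
    :func:`validate_criterion_set` so they can all be reported at once.
    """
    if not isinstance(doc, dict) or "criteria" not in doc:
        raise ConfigError("document must contain a top-level 'criteria' list", field="criteria")
    raw = doc["criteria"]
    if not isinstance(raw, list) or not raw:
        raise ConfigError("'criteria' must be a non-empty list", field="criteria")
    crits = []
    for i, entry in enumerate(raw):
        where = f"criteria[{i}]"
        if not isinstance(entry, dict):
            raise ConfigError(f"{where}: entry must be an object", field=where)
        for key in ("id", "name"):
            if key not in entry or not isinstance(entry[key], str) or not entry[key]:
                raise ConfigError(f"{where}: missing or empty '{key}'", field=f"{where}.{key}")
        rank = entry.get("rank")
        if rank is not None and (isinstance(rank, bool) or not isinstance(rank, int)):
            raise ConfigError(f"{where}: rank must be an integer", field=f"{where}.rank")
        crits.append(
            Criterion(
                id=entry["id"],
                name=entry["name"],
                rank=rank,
                scale=_scale_from_config(entry.get("scale"), where),
                description=str(entry.get("description", "")),
            )
        )
    return CriterionSet(criteria=tuple(crits), source=source)


def criterion_set_to_config(cs: CriterionSet) -> dict:
    """Inverse of :func:`criterion_set_from_config` (round-trips exactly)."""
    out = []
    for c in cs.criteria:
        entry: dict = {"id": c.id, "name": c.name}
        if c.rank is not None:
            entry["rank"] = c.rank
        if c.is_price:
            entry["scale"] = "price_rule"
        else:
            entry["scale"] = [{"label": l, "value": v} for l, v in c.scale.levels]
        if c.description:
            entry["description"] = c.description
        out.append(entry)
    return {"criteria": out}


def schema_path() -> Path:
    """Path of the shipped JSON-Schema document for criteria configs."""
    return Path(__file__).with_name("criteria.schema.json")
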