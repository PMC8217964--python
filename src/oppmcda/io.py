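"""File formats: criteria config (JSON/YAML), ballots and dossiers (CSV),
weight/score reports (JSON, CSV, plain table).

All CSV is comma-separated UTF-8 with "." decimals; ranking responses are
semicolon-separated ordered id lists. JSON reports embed the package version,
the input checksums and the seed so identical inputs give byte-identical
output.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .criteria import (
    ConfigError,
    CriterionSet,
    criterion_set_from_config,
    criterion_set_to_config,
    validate_criterion_set,
)
from .elicitation import (
    Ballot,
    QuestionType,
    VoteSet,
    WeightScheme,
    round_half_up,
    standard_question_registry,
)
from .valuation import ProductDossier, ScoreCard

__all__ = [
    "IOError_",
    "RunConfig",
    "read_criteria_config",
    "read_ballots",
    "write_ballots",
    "read_dossiers",
    "write_dossiers",
    "weights_table",
    "write_report",
    "read_report",
    "file_checksum",
]

BALLOT_HEADER = ["voter_id", "question_id", "response"]


class IOError_(ValueError):
    """Structured read/parse failure; ``line`` is 1-based when applicable."""

    def __init__(self, message: str, *, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class RunConfig:
    """Paths and policies of one tool run; recorded in every report."""

    criteria_path: Path | None = None
    ballots_path: Path | None = None
    dossiers_path: Path | None = None
    tie_break: str | None = None
    display_digits: int = 1
    seed: int = 0
    out_dir: Path | None = None

    def validate(self) -> list[str]:
        problems = []
        for label, p in (
            ("criteria", self.criteria_path),
            ("ballots", self.ballots_path),
            ("dossiers", self.dossiers_path),
        ):
            if p is not None and not Path(p).exists():
                problems.append(f"{label} path does not exist: {p}")
        if self.tie_break not in (None, "rerun", "fewest", "most"):
            problems.append(f"unknown tie-break policy {self.tie_break!r}")
        return problems


def file_checksum(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Criteria config
# ---------------------------------------------------------------------------


def read_criteria_config(path: Path | str) -> CriterionSet:
    """Load and validate a criteria config (JSON or YAML by extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise IOError_(f"cannot parse {path.name}: {exc}") from exc
    cs = criterion_set_from_config(doc, source=str(path))
    issues = validate_criterion_set(cs)
    if issues:
        raise ConfigError(
            f"{path.name}: invalid criteria config: " + "; ".join(map(str, issues))
        )
    return cs


# ---------------------------------------------------------------------------
# Ballots CSV
# ---------------------------------------------------------------------------


def _parse_response(raw: str, qtype: QuestionType):
    if qtype is QuestionType.CATEGORICAL:
        return raw
    if qtype is QuestionType.NUMERIC:
        return float(raw)
    return tuple(tok.strip() for tok in raw.split(";") if tok.strip())


def read_ballots(
    path: Path | str, registry: Mapping[str, QuestionType] | None = None
) -> VoteSet:
    """Read a ballots CSV (header ``voter_id,question_id,response``).

    Ranking responses are semicolon-separated id lists. Malformed rows raise
    :class:`IOError_` with the 1-based line number; unknown question ids and
    duplicate (voter, question) pairs are rejected.
    """
    if registry is None:
        registry = standard_question_registry()
    path = Path(path)
    ballots: list[Ballot] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise IOError_("missing header row") from None
        if [h.strip() for h in header] != BALLOT_HEADER:
            raise IOError_(f"expected header {','.join(BALLOT_HEADER)}, got {','.join(header)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise IOError_(f"expected 3 fields, got {len(row)}", line=lineno)
            voter, qid, raw = (f.strip() for f in row)
            if qid not in registry:
                raise IOError_(f"unknown question id {qid!r}", line=lineno)
            try:
                resp = _parse_response(raw, registry[qid])
            except ValueError:
                raise IOError_(
                    f"question {qid!r} expects a number, got {raw!r}", line=lineno
                ) from None
            ballots.append(Ballot(voter_id=voter, question_id=qid, response=resp))
    return VoteSet(ballots=tuple(ballots), registry=dict(registry))


def write_ballots(votes: VoteSet, path: Path | str) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BALLOT_HEADER)
        for b in votes.ballots:
            if isinstance(b.response, tuple):
                raw = ";".join(b.response)
            elif isinstance(b.response, float):
                raw = repr(b.response)
            else:
                raw = b.response
            w.writerow([b.voter_id, b.question_id, raw])


# ---------------------------------------------------------------------------
# Dossiers CSV
# ---------------------------------------------------------------------------


def read_dossiers(path: Path | str, cs: CriterionSet) -> list[ProductDossier]:
    """Read dossiers CSV: ``product_id,price_aed,<criterion_id>...`` columns.

    One column per non-price criterion, cells holding scale level labels.
    """
    path = Path(path)
    expected = [c.id for c in cs.non_price]
    dossiers = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise IOError_("missing header row")
        missing_cols = [c for c in ["product_id", "price_aed", *expected] if c not in reader.fieldnames]
        if missing_cols:
            raise IOError_(f"missing columns: {missing_cols}", line=1)
        for lineno, row in enumerate(reader, start=2):
            try:
                price = float(row["price_aed"])
            except (TypeError, ValueError):
                raise IOError_(f"non-numeric price {row.get('price_aed')!r}", line=lineno) from None
            perf = {cid: (row[cid] or "").strip() for cid in expected}
            empty = [cid for cid, lev in perf.items() if not lev]
            if empty:
                raise IOError_(f"empty performance cells for {empty}", line=lineno)
            dossiers.append(
                ProductDossier(product_id=row["product_id"].strip(), price=price, performance=perf)
            )
    return dossiers


def write_dossiers(dossiers: Sequence[ProductDossier], cs: CriterionSet, path: Path | str) -> None:
    cols = ["product_id", "price_aed", *[c.id for c in cs.non_price]]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for d in dossiers:
            w.writerow([d.product_id, repr(d.price), *[d.performance[c] for c in cols[2:]]])


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def weights_table(scheme: WeightScheme, cs: CriterionSet | None = None, ndigits: int = 1) -> str:
    """Fixed-width table: criterion, rank, incremental %, final weight %."""
    rows = []
    pct = scheme.display_percents(ndigits)
    for i, cid in enumerate(scheme.ranked_ids):
        name = cs.get(cid).name if cs is not None else cid
        inc = (
            f"{round_half_up(100.0 * scheme.incrementals[i], ndigits)}%"
            if i < len(scheme.incrementals)
            else "—"
        )
        rows.append((name, str(i + 1), inc, f"{pct[i]}"))
    header = ("Criteria", "Rank", "Incremental weight", "Final weight (%)")
    widths = [max(len(r[j]) for r in [header, *rows]) for j in range(4)]
    lines = []
    for r in [header, *rows]:
        lines.append("  ".join(r[j].ljust(widths[j]) for j in range(4)).rstrip())
        if r is header:
            lines.append("  ".join("-" * widths[j] for j in range(4)))
    return "\n".join(lines)


def _scheme_payload(scheme: WeightScheme, ndigits: int) -> dict:
    return {
        "ranked_ids": list(scheme.ranked_ids),
        "incrementals": list(scheme.incrementals),
        "raw": list(scheme.raw),
        "weights": list(scheme.weights),
        "display_percents": list(scheme.display_percents(ndigits)),
        "fingerprint": scheme.fingerprint,
    }


def _card_payload(card: ScoreCard, ndigits: int) -> dict:
    return {
        "product_id": card.product_id,
        "partials": dict(card.partials),
        "contributions": dict(card.contributions),
        "total": card.total,
        "display_total": card.display_total(ndigits),
        "scheme_fingerprint": card.scheme_fingerprint,
    }


def write_report(
    scheme: WeightScheme,
    cards: Sequence[ScoreCard],
    path: Path | str,
    *,
    cs: CriterionSet | None = None,
    fmt: str = "json",
    seed: int | None = None,
    checksums: Mapping[str, str] | None = None,
    ndigits: int = 1,
) -> None:
    """Write the weight scheme and score cards to ``path``.

    ``json`` round-trips bit-exactly through :func:`read_report`; ``csv``
    emits the weights table then one row per card; ``table`` is the
    human-readable fixed-width rendering.
    """
    from . import __version__

    path = Path(path)
    if fmt == "json":
        doc = {
            "version": __version__,
            "seed": seed,
            "checksums": dict(checksums or {}),
            "scheme": _scheme_payload(scheme, ndigits),
            "cards": [_card_payload(c, ndigits) for c in cards],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    elif fmt == "csv":
        buf = _io.StringIO()
        w = csv.writer(buf)
        w.writerow(["criterion", "rank", "incremental", "final_weight_pct"])
        pct = scheme.display_percents(ndigits)
        for i, cid in enumerate(scheme.ranked_ids):
            inc = scheme.incrementals[i] if i < len(scheme.incrementals) else ""
            w.writerow([cid, i + 1, inc, pct[i]])
        if cards:
            w.writerow([])
            w.writerow(["product_id", "total", "display_total"])
            for c in cards:
                w.writerow([c.product_id, repr(c.total), c.display_total(ndigits)])
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif fmt == "table":
        parts = [weights_table(scheme, cs, ndigits)]
        if cards:
            parts.append("")
            for c in cards:
                parts.append(f"{c.product_id}: total {c.display_total(ndigits)}")
        path.write_text("\n".join(parts) + "\n", encoding="utf-8")
    else:
        raise IOError_(f"unknown report format {fmt!r}")


def read_report(path: Path | str) -> dict:
    """Read back a JSON report (inverse of the ``json`` format)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
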