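"""Readers, writers and summaries for study-level input tables.

Formats
-------
Studies CSV: UTF-8, comma-separated, mandatory header, one row per study,
missing = empty cell. ``outcomes`` is a ``|``-separated list (``OS|DFS`` or
``none``); ``effect_sources`` is an optional JSON-encoded column so that a
write/load round-trip preserves every field exactly. The JSON mirror holds
one object per study with the same field names.

Contingency CSV: columns ``study_id, feature, a, b, c, d``; lines starting
with ``#`` are header comments declaring the outcome convention per feature.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

from .errors import EmptyInputError, ParseError, ValidationError
from .records import (
    Adjustment,
    ContingencyTable,
    EffectSource,
    KMCurve,
    Method,
    Outcome,
    StudyRecord,
)

STUDY_COLUMNS = [
    "study_id",
    "first_author",
    "year",
    "n_total",
    "n_male",
    "n_female",
    "n_high",
    "n_low",
    "method",
    "follow_up_months",
    "outcomes",
    "nos_score",
    "effect_sources",
]


def _opt_int(cell: str, line: int, col: str) -> Optional[int]:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise ParseError(f"line {line}: column {col!r}: not an integer: {cell!r}") from exc


def _opt_float(cell: str, line: int, col: str) -> Optional[float]:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(f"line {line}: column {col!r}: not a number: {cell!r}") from exc


def _req_int(cell: str, line: int, col: str) -> int:
    v = _opt_int(cell, line, col)
    if v is None:
        raise ParseError(f"line {line}: column {col!r}: required value missing")
    return v


def _km_to_jsonable(curve: KMCurve) -> dict:
    d = {
        "arm_label": curve.arm_label,
        "points": [list(p) for p in curve.points],
        "n_at_risk_initial": curve.n_at_risk_initial,
    }
    if curve.at_risk_times is not None:
        d["at_risk_times"] = [list(p) for p in curve.at_risk_times]
    return d


def _km_from_jsonable(d: dict) -> KMCurve:
    return KMCurve(
        arm_label=d["arm_label"],
        points=tuple(tuple(p) for p in d["points"]),
        n_at_risk_initial=int(d["n_at_risk_initial"]),
        at_risk_times=tuple(tuple(p) for p in d["at_risk_times"]) if d.get("at_risk_times") else None,
    )


def _source_to_jsonable(src: EffectSource) -> dict:
    d = {"outcome": src.outcome.value, "adjustment": src.adjustment.value}
    if src.hr is not None:
        d.update(hr=src.hr, ci_low=src.ci_low, ci_high=src.ci_high)
    if src.km_curves is not None:
        d["km_curves"] = [_km_to_jsonable(c) for c in src.km_curves]
    return d


def _source_from_jsonable(d: dict) -> EffectSource:
    km = d.get("km_curves")
    return EffectSource(
        outcome=Outcome(d["outcome"]),
        adjustment=Adjustment(d["adjustment"]),
        hr=d.get("hr"),
        ci_low=d.get("ci_low"),
        ci_high=d.get("ci_high"),
        km_curves=tuple(_km_from_jsonable(c) for c in km) if km else None,
    )


def _study_to_jsonable(s: StudyRecord) -> dict:
    return {
        "study_id": s.study_id,
        "first_author": s.first_author,
        "year": s.year,
        "n_total": s.n_total,
        "n_male": s.n_male,
        "n_female": s.n_female,
        "n_high": s.n_high,
        "n_low": s.n_low,
        "method": s.method.value,
        "follow_up_months": s.follow_up_months,
        "outcomes": sorted(o.value for o in s.outcomes),
        "nos_score": s.nos_score,
        "effect_sources": [_source_to_jsonable(e) for e in s.effect_sources],
    }


def _study_from_jsonable(d: dict, where: str) -> StudyRecord:
    try:
        return StudyRecord(
            study_id=d["study_id"],
            first_author=d.get("first_author", ""),
            year=int(d["year"]),
            n_total=int(d["n_total"]),
            n_male=None if d.get("n_male") is None else int(d["n_male"]),
            n_female=None if d.get("n_female") is None else int(d["n_female"]),
            n_high=int(d["n_high"]),
            n_low=int(d["n_low"]),
            method=Method(d["method"]),
            follow_up_months=d.get("follow_up_months"),
            outcomes=frozenset(Outcome(o) for o in d["outcomes"]),
            nos_score=None if d.get("nos_score") is None else int(d["nos_score"]),
            effect_sources=tuple(_source_from_jsonable(e) for e in d.get("effect_sources", [])),
        )
    except KeyError as exc:
        raise ParseError(f"{where}: missing field {exc.args[0]!r}") from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ParseError(f"{where}: {exc}") from exc


def load_studies(path, format: Optional[str] = None) -> List[StudyRecord]:
    """Load validated study records from a CSV or JSON table, in file order.

    ``format`` is ``"csv"`` or ``"json"``; when omitted it is inferred from
    the file suffix. Missing cells become ``None``, never zero. Malformed
    content raises :class:`ParseError` naming the line; invariant violations
    raise :class:`ValidationError` naming the study and field.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {exc.lineno}: invalid JSON: {exc.msg}") from exc
        if not isinstance(payload, list):
            raise ParseError(f"{path}: top-level JSON must be a list of study objects")
        return [_study_from_jsonable(d, f"{path}: study #{i + 1}") for i, d in enumerate(payload)]
    if fmt != "csv":
        raise ParseError(f"unknown study table format {fmt!r}")

    records: List[StudyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file (header row required)")
        missing = [c for c in STUDY_COLUMNS if c not in reader.fieldnames and c != "effect_sources"]
        if missing:
            raise ParseError(f"{path}: line 1: missing required columns: {', '.join(missing)}")
        for row in reader:
            line = reader.line_num
            try:
                srcs_cell = (row.get("effect_sources") or "").strip()
                sources = ()
                if srcs_cell:
                    try:
                        sources = tuple(
                            _source_from_jsonable(d) for d in json.loads(srcs_cell)
                        )
                    except json.JSONDecodeError as exc:
                        raise ParseError(
                            f"line {line}: column 'effect_sources': invalid JSON: {exc.msg}"
                        ) from exc
                outcomes_cell = row["outcomes"].strip()
                if not outcomes_cell:
                    raise ParseError(f"line {line}: column 'outcomes': required value missing")
                try:
                    outcomes = frozenset(Outcome(o) for o in outcomes_cell.split("|"))
                    method = Method(row["method"])
                except ValueError as exc:
                    raise ParseError(f"line {line}: {exc}") from exc
                rec = StudyRecord(
                    study_id=row["study_id"],
                    first_author=row["first_author"],
                    year=_req_int(row["year"], line, "year"),
                    n_total=_req_int(row["n_total"], line, "n_total"),
                    n_male=_opt_int(row["n_male"], line, "n_male"),
                    n_female=_opt_int(row["n_female"], line, "n_female"),
                    n_high=_req_int(row["n_high"], line, "n_high"),
                    n_low=_req_int(row["n_low"], line, "n_low"),
                    method=method,
                    follow_up_months=_opt_float(row["follow_up_months"], line, "follow_up_months"),
                    outcomes=outcomes,
                    nos_score=_opt_int(row["nos_score"], line, "nos_score"),
                    effect_sources=sources,
                )
            except KeyError as exc:
                raise ParseError(f"{path}: line {line}: missing column {exc.args[0]!r}") from exc
            records.append(rec)
    return records


def write_studies(studies: Sequence[StudyRecord], path, format: Optional[str] = None) -> None:
    """Write studies to CSV or JSON such that :func:`load_studies` round-trips."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([_study_to_jsonable(s) for s in studies], fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=STUDY_COLUMNS)
        writer.writeheader()
        for s in studies:
            d = _study_to_jsonable(s)
            row = {k: ("" if d[k] is None else d[k]) for k in STUDY_COLUMNS if k not in ("outcomes", "effect_sources")}
            row["outcomes"] = "|".join(d["outcomes"])
            row["effect_sources"] = json.dumps(d["effect_sources"]) if s.effect_sources else ""
            writer.writerow(row)


def load_contingency_tables(path) -> List[ContingencyTable]:
    """Load 2x2 tables from a contingency CSV (``#`` lines are comments)."""
    tables: List[ContingencyTable] = []
    with open(path, encoding="utf-8") as fh:
        rows = [(i + 1, line) for i, line in enumerate(fh) if line.strip() and not line.startswith("#")]
    if not rows:
        raise ParseError(f"{path}: no content rows")
    header_line, header = rows[0]
    cols = [c.strip() for c in header.strip().split(",")]
    expected = ["study_id", "feature", "a", "b", "c", "d"]
    if cols != expected:
        raise ParseError(f"{path}: line {header_line}: header must be {','.join(expected)}")
    for line_no, line in rows[1:]:
        parts = [p.strip() for p in line.strip().split(",")]
        if len(parts) != 6:
            raise ParseError(f"{path}: line {line_no}: expected 6 fields, got {len(parts)}")
        cells = [_req_int(p, line_no, c) for p, c in zip(parts[2:], "abcd")]
        tables.append(ContingencyTable(parts[0], parts[1], *cells))
    return tables


def write_contingency_tables(tables: Sequence[ContingencyTable], path, comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for ln in comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("study_id,feature,a,b,c,d\n")
        for t in tables:
            fh.write(f"{t.study_id},{t.feature},{t.a},{t.b},{t.c},{t.d}\n")


def round_half_up_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (display convention)."""
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountsSummary:
    """Patient tallies over a study set."""

    n_studies: int
    total_patients: int
    total_high: int
    total_low: int
    high_percent: float  # rounded half-up to 0.1%
    per_method: dict
    per_outcome: dict
    total_male: int  # over studies reporting sex
    total_female: int


def summarize_counts(studies: Sequence[StudyRecord]) -> CountsSummary:
    """Tally patients, marker-high proportion, and per-method/outcome counts.

    Studies with unreported sex are excluded from the sex denominators.
    """
    if not studies:
        raise EmptyInputError("summarize_counts: no studies supplied")
    total = sum(s.n_total for s in studies)
    high = sum(s.n_high for s in studies)
    low = sum(s.n_low for s in studies)
    per_method: dict = {}
    per_outcome: dict = {}
    for s in studies:
        per_method[s.method.value] = per_method.get(s.method.value, 0) + 1
        for o in sorted(o.value for o in s.outcomes):
            per_outcome[o] = per_outcome.get(o, 0) + 1
    return CountsSummary(
        n_studies=len(studies),
        total_patients=total,
        total_high=high,
        total_low=low,
        high_percent=round_half_up_percent(high, total),
        per_method=per_method,
        per_outcome=per_outcome,
        total_male=sum(s.n_male for s in studies if s.n_male is not None),
        total_female=sum(s.n_female for s in studies if s.n_female is not None),
    )


def format_sig4(x: float) -> str:
    """Report-table float formatting: 4 significant digits."""
    return format(float(x), ".4g")
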