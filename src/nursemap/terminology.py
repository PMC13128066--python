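"""Terminology tables, nursing records, annotated corpora and gold annotations.

The coded vocabulary being mapped onto is a set of nursing terms — diagnoses
and interventions — drawn from a standardized nursing classification (CCC,
with NANDA-I / NIC entries as supplementary codes). This module holds the
in-memory model for that vocabulary, the record/annotation containers that
the retrieval and generation stages consume, the file formats (CSV/TSV/JSON
for terminologies, JSONL for records and annotations), and the terminology
coverage report.

Codes are opaque strings. Matching trims surrounding whitespace and is
otherwise exact and case-preserving: validation is an integrity gate, not a
fuzzy matcher. All files are UTF-8; writers emit byte-stable output (fixed
column order, sorted JSON keys) so artifacts diff cleanly.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "SourceVocab",
    "TermEntry",
    "TerminologySet",
    "NursingRecord",
    "GoldAnnotation",
    "AnnotatedExample",
    "CoverageReport",
    "TerminologyFormatError",
    "TerminologyIntegrityError",
    "UnknownCodeError",
    "load_terminology",
    "write_terminology",
    "load_records",
    "write_records",
    "load_gold",
    "write_gold",
    "load_examples",
    "write_examples",
    "coverage_report",
]


class Category(str, Enum):
    """Kind of nursing term: a diagnosis or an intervention."""

    DIAGNOSIS = "diagnosis"
    INTERVENTION = "intervention"


class SourceVocab(str, Enum):
    """Vocabulary a term originates from.

    CCC is the primary coded terminology; NANDA-I and NIC entries serve as
    supplementary standards when no primary match exists.
    """

    CCC = "CCC"
    NANDA_I = "NANDA_I"
    NIC = "NIC"


class TerminologyFormatError(ValueError):
    """A terminology source does not parse in the declared format."""


class TerminologyIntegrityError(ValueError):
    """A terminology violates an integrity constraint (e.g. duplicate code)."""


class UnknownCodeError(KeyError):
    """A code does not resolve in the governing terminology."""


def normalize_code(code: str) -> str:
    """Canonical form of a code: surrounding whitespace trimmed, case kept."""
    return code.strip()


@dataclass(frozen=True)
class TermEntry:
    """One coded term of the terminology."""

    code: str
    label: str
    category: Category
    care_component: str = ""
    source_vocab: SourceVocab = SourceVocab.CCC
    description: str = ""

    def __post_init__(self) -> None:
        if not normalize_code(self.code):
            raise TerminologyIntegrityError("term code must be non-empty")
        object.__setattr__(self, "code", normalize_code(self.code))
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "source_vocab", SourceVocab(self.source_vocab))

    @property
    def embedding_text(self) -> str:
        """Serialized form used when the entry is embedded for retrieval."""
        if self.description:
            return f"{self.label} — {self.description}"
        return self.label


class TerminologySet:
    """A terminology: the validation authority for every predicted code.

    Provides total code → entry lookup over its contents and consistent
    per-category counts. Duplicate codes are rejected at construction.
    """

    def __init__(self, entries: Iterable[TermEntry] = ()):
        self._entries: list[TermEntry] = []
        self._index: dict[str, TermEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: TermEntry) -> None:
        if entry.code in self._index:
            raise TerminologyIntegrityError(f"duplicate terminology code: {entry.code!r}")
        self._entries.append(entry)
        self._index[entry.code] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[TermEntry]:
        return iter(self._entries)

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TerminologySet):
            return NotImplemented
        return self._entries == other._entries

    def validate_code(self, code: str) -> TermEntry:
        """Resolve ``code`` to its entry, or raise :class:`UnknownCodeError`.

        Matching trims surrounding whitespace; no fuzzy matching is applied.
        """
        key = normalize_code(code)
        try:
            return self._index[key]
        except KeyError:
            raise UnknownCodeError(code) from None

    def get(self, code: str) -> TermEntry | None:
        return self._index.get(normalize_code(code))

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self._entries]

    def entries_of(self, category: Category) -> list[TermEntry]:
        category = Category(category)
        return [e for e in self._entries if e.category is category]

    def count(self, category: Category) -> int:
        return len(self.entries_of(category))

    def category_of(self, code: str) -> Category:
        """Category is a property of the terminology, never of a prediction."""
        return self.validate_code(code).category


@dataclass(frozen=True)
class NursingRecord:
    """A free-text nursing record (text may mix Chinese and English)."""

    record_id: str
    text: str


@dataclass(frozen=True)
class GoldAnnotation:
    """Consensus gold code sets for one record, split by category."""

    record_id: str
    diagnosis_codes: frozenset[str] = frozenset()
    intervention_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagnosis_codes", frozenset(self.diagnosis_codes))
        object.__setattr__(self, "intervention_codes", frozenset(self.intervention_codes))

    def codes(self, category: Category | None = None) -> frozenset[str]:
        if category is None:
            return self.diagnosis_codes | self.intervention_codes
        category = Category(category)
        if category is Category.DIAGNOSIS:
            return self.diagnosis_codes
        return self.intervention_codes


@dataclass(frozen=True)
class AnnotatedExample:
    """One annotated corpus sample: text plus its assigned code set."""

    example_id: str
    text: str
    codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))


@dataclass(frozen=True)
class CoverageReport:
    """How much of one category's code inventory the gold annotations use."""

    category: Category
    unique_codes_used: int
    total_codes: int

    def __post_init__(self) -> None:
        if not 0 <= self.unique_codes_used <= self.total_codes:
            raise ValueError(
                f"unique_codes_used={self.unique_codes_used} outside "
                f"[0, {self.total_codes}]"
            )

    @property
    def percentage(self) -> float:
        """100 × used / total, rounded to one decimal."""
        return round(100.0 * self.unique_codes_used / self.total_codes, 1)


# ---------------------------------------------------------------------------
# Terminology I/O

_TERM_COLUMNS = ["code", "label", "category", "care_component", "source_vocab", "description"]
_REQUIRED_COLUMNS = {"code", "label", "category"}


def _entry_from_mapping(row: dict) -> TermEntry:
    missing = _REQUIRED_COLUMNS - {k for k, v in row.items() if v is not None}
    if missing:
        raise TerminologyFormatError(f"missing required column(s): {sorted(missing)}")
    try:
        return TermEntry(
            code=row["code"],
            label=row["label"],
            category=Category(row["category"]),
            care_component=row.get("care_component") or "",
            source_vocab=SourceVocab(row.get("source_vocab") or "CCC"),
            description=row.get("description") or "",
        )
    except ValueError as exc:
        raise TerminologyFormatError(str(exc)) from exc


def load_terminology(source: str | Path | TextIO, format: str = "csv") -> TerminologySet:
    """Load a terminology from CSV, TSV or a JSON array of entry objects.

    Every row becomes a :class:`TermEntry`; a repeated code raises
    :class:`TerminologyIntegrityError` naming the code. An empty table is
    legal (a warning is logged) so that incremental vocabularies round-trip.
    """
    if format not in {"csv", "tsv", "json"}:
        raise TerminologyFormatError(f"unsupported terminology format: {format!r}")
    own = isinstance(source, (str, Path))
    stream: TextIO = open(source, encoding="utf-8") if own else source  # type: ignore[arg-type]
    try:
        if format == "json":
            try:
                rows = json.load(stream)
            except json.JSONDecodeError as exc:
                raise TerminologyFormatError(f"invalid JSON terminology: {exc}") from exc
            if not isinstance(rows, list):
                raise TerminologyFormatError("JSON terminology must be an array of objects")
        else:
            delim = "\t" if format == "tsv" else ","
            reader = csv.DictReader(stream, delimiter=delim)
            if reader.fieldnames is None:
                raise TerminologyFormatError("terminology table has no header row")
            header_missing = _REQUIRED_COLUMNS - set(reader.fieldnames)
            if header_missing:
                raise TerminologyFormatError(
                    f"missing required column(s): {sorted(header_missing)}"
                )
            rows = list(reader)
    finally:
        if own:
            stream.close()

    terms = TerminologySet(_entry_from_mapping(row) for row in rows)
    if len(terms) == 0:
        logger.warning("loaded an empty terminology")
    return terms


def write_terminology(terms: TerminologySet, dest: str | Path | TextIO, format: str = "csv") -> None:
    """Write a terminology with a fixed field order (byte-stable output)."""
    if format not in {"csv", "tsv", "json"}:
        raise TerminologyFormatError(f"unsupported terminology format: {format!r}")
    buf = io.StringIO()
    if format == "json":
        payload = [
            {
                "care_component": e.care_component,
                "category": e.category.value,
                "code": e.code,
                "description": e.description,
                "label": e.label,
                "source_vocab": e.source_vocab.value,
            }
            for e in terms
        ]
        json.dump(payload, buf, ensure_ascii=False, sort_keys=True, indent=2)
        buf.write("\n")
    else:
        delim = "\t" if format == "tsv" else ","
        writer = csv.writer(buf, delimiter=delim, lineterminator="\n")
        writer.writerow(_TERM_COLUMNS)
        for e in terms:
            writer.writerow(
                [e.code, e.label, e.category.value, e.care_component, e.source_vocab.value, e.description]
            )
    _write_text(dest, buf.getvalue())


# ---------------------------------------------------------------------------
# JSONL I/O for records / gold / corpus


def _write_text(dest: str | Path | TextIO, text: str) -> None:
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


def _iter_jsonl(source: str | Path | TextIO) -> Iterator[dict]:
    own = isinstance(source, (str, Path))
    stream: TextIO = open(source, encoding="utf-8") if own else source  # type: ignore[arg-type]
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TerminologyFormatError(f"invalid JSONL at line {lineno}: {exc}") from exc
            yield obj
    finally:
        if own:
            stream.close()


def _dump_jsonl(objs: Iterable[dict], dest: str | Path | TextIO) -> None:
    text = "".join(json.dumps(o, ensure_ascii=False, sort_keys=True) + "\n" for o in objs)
    _write_text(dest, text)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TerminologyIntegrityError(f"duplicate {what}: {i!r}")
        seen.add(i)


def load_records(source: str | Path | TextIO) -> list[NursingRecord]:
    records = [NursingRecord(record_id=o["id"], text=o["text"]) for o in _iter_jsonl(source)]
    _check_unique([r.record_id for r in records], "record id")
    return records


def write_records(records: Iterable[NursingRecord], dest: str | Path | TextIO) -> None:
    _dump_jsonl(({"id": r.record_id, "text": r.text} for r in records), dest)


def load_gold(source: str | Path | TextIO) -> list[GoldAnnotation]:
    gold = [
        GoldAnnotation(
            record_id=o["id"],
            diagnosis_codes=frozenset(o.get("diagnosis_codes", ())),
            intervention_codes=frozenset(o.get("intervention_codes", ())),
        )
        for o in _iter_jsonl(source)
    ]
    _check_unique([g.record_id for g in gold], "gold record id")
    return gold


def write_gold(gold: Iterable[GoldAnnotation], dest: str | Path | TextIO) -> None:
    _dump_jsonl(
        (
            {
                "diagnosis_codes": sorted(g.diagnosis_codes),
                "id": g.record_id,
                "intervention_codes": sorted(g.intervention_codes),
            }
            for g in gold
        ),
        dest,
    )


def load_examples(source: str | Path | TextIO) -> list[AnnotatedExample]:
    examples = [
        AnnotatedExample(example_id=o["id"], text=o["text"], codes=frozenset(o.get("codes", ())))
        for o in _iter_jsonl(source)
    ]
    _check_unique([e.example_id for e in examples], "example id")
    return examples


def write_examples(examples: Iterable[AnnotatedExample], dest: str | Path | TextIO) -> None:
    _dump_jsonl(
        ({"codes": sorted(e.codes), "id": e.example_id, "text": e.text} for e in examples),
        dest,
    )


# ---------------------------------------------------------------------------
# Coverage


def coverage_report(
    gold: Iterable[GoldAnnotation],
    terms: TerminologySet,
    category: Category,
) -> CoverageReport:
    """Fraction of one category's code inventory observed across gold sets.

    ``unique_codes_used`` is the cardinality of the union of the category's
    code sets over all records, so the report is invariant to record order
    and to repeated mentions of a code.
    """
    category = Category(category)
    total = terms.count(category)
    if total == 0:
        raise ZeroDivisionError(f"terminology has no {category.value} codes")
    used: set[str] = set()
    for g in gold:
        for code in g.codes(category):
            entry = terms.validate_code(code)
            if entry.category is not category:
                raise TerminologyIntegrityError(
                    f"code {code!r} annotated as {category.value} but the "
                    f"terminology lists it as {entry.category.value}"
                )
            used.add(entry.code)
    return CoverageReport(category=category, unique_codes_used=len(used), total_codes=total)
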