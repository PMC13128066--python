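"""Stage 2: constrained prompting, generation, parsing and validation.

Every subquery is rendered into a prompt under one of four strategies:

* ``no_rag`` — instruction + record text only, no retrieved context;
* ``rag_zero_shot`` — retrieved terminology entries, no examples;
* ``rag_few_shot_retrieved`` — retrieved terminology entries plus the
  most semantically similar annotated examples per subquery;
* ``few_shot_static`` — retrieved terminology entries plus a fixed example
  set drawn once per run with a recorded seed.

The prompt instructs the backend to return nursing diagnosis and
intervention codes as a single JSON array of code strings — no prose, no
duplicates, an empty array when no valid code applies. Backends are
pluggable text→text adapters; the raw responses are parsed by regular
expression (fenced JSON block preferred, else the first bracketed span),
cross-referenced against the terminology for validation (unknown codes are
dropped and counted), and aggregated per record by set union, with each
surviving code routed to the diagnosis or intervention set according to
its terminology entry.
"""

from __future__ import annotations

import json
import logging
import re
from collections.abc import Sequence
from dataclasses import dataclass, field
from enum import Enum
from typing import Protocol, runtime_checkable

from .embedders import Embedder
from .retrieval import (
    DEFAULT_PUNCTUATION,
    ContextWindow,
    DenseIndex,
    HitSource,
    RetrievalHit,
    Subquery,
    SubqueryOrigin,
    build_context_window,
    embed,
    l2_normalize,
    segment_record,
)
from .terminology import (
    AnnotatedExample,
    NursingRecord,
    TerminologySet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PromptMode",
    "Prompt",
    "OutputFlags",
    "ModelOutput",
    "GenerationBackend",
    "BackendError",
    "ConstantBackend",
    "DEFAULT_RULES_TEXT",
    "select_fewshot_examples",
    "render_prompt",
    "generate",
    "parse_output",
    "validate_and_aggregate",
    "map_record",
    "map_records",
]


class PromptMode(str, Enum):
    NO_RAG = "no_rag"
    RAG_ZERO_SHOT = "rag_zero_shot"
    RAG_FEW_SHOT_RETRIEVED = "rag_few_shot_retrieved"
    FEW_SHOT_STATIC = "few_shot_static"


#: Default coding guidance included in every RAG prompt. Configurable: real
#: deployments substitute the full coding-guideline text of their
#: terminology release.
DEFAULT_RULES_TEXT = (
    "Assign standardized nursing terminology codes. Prefer primary-vocabulary "
    "codes; use supplementary-vocabulary codes only when no primary term "
    "matches. Assign a code only when the text explicitly supports it."
)

_SCHEMA_NOTE = (
    "Return the applicable nursing diagnosis and intervention codes as a "
    'JSON array of code strings, e.g. ["D001", "I002"]. Do not add '
    "explanatory text. Do not repeat codes. If no valid code applies, "
    "return an empty array []."
)


@dataclass(frozen=True)
class Prompt:
    """A rendered prompt plus the structured pieces it was built from."""

    subquery: Subquery
    mode: PromptMode
    rendered_text: str
    rules_context: tuple[str, ...] = ()
    example_context: tuple[str, ...] = ()
    record_id: str = ""


class BackendError(RuntimeError):
    """The generation backend failed; distinct from a parse failure and retriable."""


@runtime_checkable
class GenerationBackend(Protocol):
    """Text→text generation contract.

    ``complete`` receives the rendered prompt. The full :class:`Prompt` is
    passed so that adapters can log structured metadata; pure-text backends
    use only ``prompt.rendered_text``. Deterministic backends must be
    reproducible given (prompt, seed).
    """

    def complete(self, prompt: Prompt) -> str: ...

    @property
    def fingerprint(self) -> str: ...


class ConstantBackend:
    """Backend returning a fixed response for every prompt (testing stub)."""

    def __init__(self, response: str = "[]"):
        self.response = response

    def complete(self, prompt: Prompt) -> str:
        return self.response

    @property
    def fingerprint(self) -> str:
        return f"constant({self.response!r})"


@dataclass
class OutputFlags:
    """Counters for the degradation paths of parsing and validation."""

    parse_errors: int = 0
    unknown_code_drops: int = 0
    duplicate_drops: int = 0


@dataclass
class ModelOutput:
    """Per-record mapping result: raw responses through validated code sets."""

    record_id: str
    raw_responses: list[str] = field(default_factory=list)
    parsed_codes: list[list[str]] = field(default_factory=list)
    diagnosis_codes: frozenset[str] = frozenset()
    intervention_codes: frozenset[str] = frozenset()
    flags: OutputFlags = field(default_factory=OutputFlags)

    def codes(self) -> frozenset[str]:
        return self.diagnosis_codes | self.intervention_codes


# ---------------------------------------------------------------------------
# Few-shot example selection


def select_fewshot_examples(
    subquery: Subquery,
    examples: Sequence[AnnotatedExample],
    corpus_index: DenseIndex,
    embedder: Embedder,
    k: int = 5,
) -> list[AnnotatedExample]:
    """Top-k annotated examples most similar to the subquery.

    Ranked by cosine score against the corpus index, deduplicated by
    example id with a stable tie-break. An empty corpus yields an empty
    list and a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(corpus_index) == 0:
        logger.warning("few-shot selection requested but the example corpus is empty")
        return []
    by_id = {e.example_id: e for e in examples}
    queries = l2_normalize(embed([subquery.text], embedder))
    hits = corpus_index.search(queries, k)[0]
    selected: list[AnnotatedExample] = []
    seen: set[str] = set()
    for hit in hits:
        if hit.item_id in seen:
            continue
        seen.add(hit.item_id)
        selected.append(by_id[hit.item_id])
    return selected


# ---------------------------------------------------------------------------
# Prompt rendering


def _format_rule_entry(hit: RetrievalHit, terms: TerminologySet) -> str:
    entry = terms.validate_code(hit.item_id)
    return f"{entry.code} [{entry.category.value}] {entry.label}"


def _format_example(example: AnnotatedExample) -> str:
    return f"Text: {example.text}\nCodes: {json.dumps(sorted(example.codes), ensure_ascii=False)}"


def render_prompt(
    subquery: Subquery,
    mode: PromptMode,
    terms: TerminologySet,
    window: ContextWindow | None = None,
    examples: Sequence[AnnotatedExample] | None = None,
    rules_text: str = DEFAULT_RULES_TEXT,
    record_id: str = "",
) -> Prompt:
    """Render the fixed template: instruction, coding rules, retrieved
    terminology entries, worked examples, the subquery, output schema.

    The template is deterministic — identical inputs render byte-identical
    text. Mode constraints are enforced: ``no_rag`` forbids retrieved
    context and examples, ``rag_zero_shot`` forbids examples.
    """
    mode = PromptMode(mode)
    has_window = window is not None and bool(window.hits)
    has_examples = bool(examples)
    if mode is PromptMode.NO_RAG and (has_window or has_examples):
        raise ValueError("no_rag prompts take neither retrieved context nor examples")
    if mode is PromptMode.RAG_ZERO_SHOT and has_examples:
        raise ValueError("rag_zero_shot prompts take no examples")
    if mode in (PromptMode.RAG_FEW_SHOT_RETRIEVED, PromptMode.FEW_SHOT_STATIC) and not has_examples:
        logger.warning("few-shot prompt rendered without examples")

    rules_context: tuple[str, ...] = ()
    if mode is not PromptMode.NO_RAG and window is not None:
        rules_context = tuple(
            _format_rule_entry(h, terms) for h in window.hits if h.source is HitSource.REFERENCE
        )
    example_context: tuple[str, ...] = tuple(_format_example(e) for e in (examples or ()))

    sections = [
        "You are a nursing-terminology coding assistant. Map the nursing "
        "text below to standardized nursing diagnosis and intervention codes.",
        "Coding rules:\n" + rules_text,
    ]
    if rules_context:
        sections.append("Candidate terminology entries:\n" + "\n".join(rules_context))
    if example_context:
        sections.append("Worked examples:\n" + "\n\n".join(example_context))
    sections.append("Nursing text:\n" + subquery.text)
    sections.append(_SCHEMA_NOTE)
    rendered = "\n\n".join(sections)
    return Prompt(
        subquery=subquery,
        mode=mode,
        rendered_text=rendered,
        rules_context=rules_context,
        example_context=example_context,
        record_id=record_id,
    )


def generate(prompt: Prompt, backend: GenerationBackend) -> str:
    """Invoke the backend; return its raw text unmodified."""
    try:
        raw = backend.complete(prompt)
    except BackendError:
        raise
    except Exception as exc:  # adapter bugs surface as backend errors
        raise BackendError(f"generation backend failed: {exc}") from exc
    logger.debug("backend %s returned %d chars", getattr(backend, "fingerprint", "?"), len(raw))
    return raw


# ---------------------------------------------------------------------------
# Parsing

_FENCED_RE = re.compile(r"```(?:json)?\s*(\[.*?\])\s*```", re.DOTALL)
_BRACKET_RE = re.compile(r"\[[^\[\]]*\]", re.DOTALL)


def parse_output(raw: str) -> tuple[list[str], bool]:
    """Extract the first well-formed JSON array of strings from raw text.

    Precedence: a fenced code block, then the first bracketed span. Order
    is preserved and duplicates kept (deduplication belongs to validation).
    When nothing parses, returns an empty list with the parse-error flag —
    the same shape as a legitimate empty-array response, but flagged.
    """
    candidates = _FENCED_RE.findall(raw) + _BRACKET_RE.findall(raw)
    for candidate in candidates:
        try:
            value = json.loads(candidate)
        except json.JSONDecodeError:
            continue
        if isinstance(value, list) and all(isinstance(v, str) for v in value):
            return list(value), False
    return [], True


# ---------------------------------------------------------------------------
# Validation and aggregation


def validate_and_aggregate(
    record_id: str,
    per_subquery_codes: Sequence[Sequence[str]],
    terms: TerminologySet,
    raw_responses: Sequence[str] = (),
    parse_errors: int = 0,
) -> ModelOutput:
    """Validate parsed codes against the terminology and union per record.

    Unknown codes are dropped with a counted warning; duplicates (within
    or across subqueries) collapse, counted once per extra occurrence.
    Surviving codes are routed to the diagnosis or intervention set by
    their terminology category.
    """
    flags = OutputFlags(parse_errors=parse_errors)
    diagnoses: set[str] = set()
    interventions: set[str] = set()
    seen: set[str] = set()
    for codes in per_subquery_codes:
        for code in codes:
            entry = terms.get(code)
            if entry is None:
                flags.unknown_code_drops += 1
                logger.warning("record %s: unknown code %r dropped", record_id, code)
                continue
            if entry.code in seen:
                flags.duplicate_drops += 1
                continue
            seen.add(entry.code)
            if entry.category.value == "diagnosis":
                diagnoses.add(entry.code)
            else:
                interventions.add(entry.code)
    return ModelOutput(
        record_id=record_id,
        raw_responses=list(raw_responses),
        parsed_codes=[list(c) for c in per_subquery_codes],
        diagnosis_codes=frozenset(diagnoses),
        intervention_codes=frozenset(interventions),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Full pipeline


def map_record(
    record: NursingRecord,
    terms: TerminologySet,
    embedder: Embedder,
    backend: GenerationBackend,
    mode: PromptMode = PromptMode.RAG_FEW_SHOT_RETRIEVED,
    reference_index: DenseIndex | None = None,
    corpus_index: DenseIndex | None = None,
    examples: Sequence[AnnotatedExample] = (),
    static_examples: Sequence[AnnotatedExample] = (),
    k: int = 5,
    rules_text: str = DEFAULT_RULES_TEXT,
    punctuation: str = DEFAULT_PUNCTUATION,
) -> ModelOutput:
    """Map one record end to end: segment → retrieve → prompt → generate →
    parse → validate and aggregate.

    In ``no_rag`` mode the full record is prompted once, without retrieval.
    In RAG modes each subquery gets its own prompt carrying the record's
    retrieved context; record-level aggregation is the union of every
    subquery's validated codes, which favors recall.
    """
    mode = PromptMode(mode)
    if mode is PromptMode.NO_RAG:
        text = record.text.strip()
        subqueries = (
            [Subquery(text=text, origin=SubqueryOrigin.FULL_RECORD, ordinal=0)] if text else []
        )
        window = None
    else:
        if reference_index is None:
            raise ValueError(f"{mode.value} requires a reference index")
        subqueries = segment_record(record, punctuation)
        window = build_context_window(
            record,
            embedder,
            reference_index,
            corpus_index=corpus_index,
            k=k,
            punctuation=punctuation,
            subqueries=subqueries,
        )

    raw_responses: list[str] = []
    parsed: list[list[str]] = []
    parse_errors = 0
    for subquery in subqueries:
        if mode is PromptMode.RAG_FEW_SHOT_RETRIEVED:
            if corpus_index is None:
                raise ValueError("rag_few_shot_retrieved requires a corpus index")
            shots: Sequence[AnnotatedExample] = select_fewshot_examples(
                subquery, examples, corpus_index, embedder, k=k
            )
        elif mode is PromptMode.FEW_SHOT_STATIC:
            shots = static_examples
        else:
            shots = ()
        prompt = render_prompt(
            subquery,
            mode,
            terms,
            window=window if mode is not PromptMode.NO_RAG else None,
            examples=shots if mode in (PromptMode.RAG_FEW_SHOT_RETRIEVED, PromptMode.FEW_SHOT_STATIC) else None,
            rules_text=rules_text,
            record_id=record.record_id,
        )
        raw = generate(prompt, backend)
        codes, failed = parse_output(raw)
        raw_responses.append(raw)
        parsed.append(codes)
        parse_errors += int(failed)

    return validate_and_aggregate(
        record.record_id, parsed, terms, raw_responses=raw_responses, parse_errors=parse_errors
    )


def map_records(
    records: Sequence[NursingRecord],
    terms: TerminologySet,
    embedder: Embedder,
    backend: GenerationBackend,
    **kwargs,
) -> list[ModelOutput]:
    """Map a batch of records; see :func:`map_record`."""
    return [map_record(r, terms, embedder, backend, **kwargs) for r in records]
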