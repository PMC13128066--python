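"""Synthetic terminologies, nursing-style records and deterministic stubs.

Real coded nursing terminologies are licensed content and real nursing
records cannot be redistributed, so every other module is exercised
against generated stand-ins that mirror the structure of the real data:

* a toy terminology of diagnosis and intervention terms, each carrying a
  bank of paraphrase clauses (clinically a term like "risk of infection"
  appears in notes under many equivalent phrasings);
* templated records — clause-delimited concatenations of one paraphrase
  per gold code plus irrelevant "noise" clauses — with their gold code
  sets recorded, alongside a disjoint annotated example corpus (mirroring
  the separation between an expert-annotated evaluation set and a larger
  student-annotated corpus drawn from distinct patients);
* multi-rater presence/absence judgment tables with a controlled
  independent flip rate, for agreement analysis;
* a "one-hot" embedder mapping each paraphrase to the basis vector of
  its term, making retrieval exact by construction; and
* an oracle generation backend that answers with a record's gold codes,
  each dropped — and a spurious known code injected — independently with
  a configurable error rate.

Everything is deterministic given the config (including its seed):
identical configs produce byte-identical outputs.

The default sizes follow the study design the package models: a 176-
diagnosis / 201-intervention vocabulary, a 100-record evaluation set and
a 1500-example annotated corpus.
"""

from __future__ import annotations

import hashlib
import json
import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .evaluation import RatingTable, ratings_from_judgments
from .generation import Prompt
from .retrieval import DEFAULT_PUNCTUATION
from .terminology import (
    AnnotatedExample,
    Category,
    GoldAnnotation,
    NursingRecord,
    SourceVocab,
    TermEntry,
    TerminologySet,
)

__all__ = [
    "SynthConfig",
    "SyntheticTerminology",
    "SyntheticDataset",
    "generate_terminology",
    "generate_records",
    "generate_dataset",
    "generate_ratings",
    "OneHotEmbedder",
    "OracleBackend",
    "oracle_backend",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the emulated study design."""

    n_diagnoses: int = 176
    n_interventions: int = 201
    n_records: int = 100
    n_corpus_examples: int = 1500
    codes_per_record: tuple[int, int] = (1, 4)  # uniform range, per category
    paraphrases_per_term: int = 3
    noise_clause_rate: float = 0.2
    rater_error_rate: float = 0.02
    n_raters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_diagnoses", "n_interventions", "n_records", "n_corpus_examples",
                     "paraphrases_per_term"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.codes_per_record
        if not 1 <= lo <= hi:
            raise ValueError("codes_per_record must be a (lo, hi) range with 1 <= lo <= hi")
        for name in ("noise_clause_rate", "rater_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_raters < 2:
            raise ValueError("n_raters must be >= 2")


# ---------------------------------------------------------------------------
# Terminology generation

_PROBLEMS = [
    "impaired", "risk of compromised", "acute", "chronic", "altered",
    "decreased", "excess", "deficient", "unstable", "ineffective",
    "disturbed", "delayed", "fluctuating", "labile",
]
_DIAG_TOPICS = [
    "skin integrity", "airway clearance", "tissue perfusion", "fluid volume",
    "gas exchange", "physical mobility", "nutritional intake", "comfort level",
    "urinary elimination", "bowel elimination", "sleep pattern",
    "thermoregulation", "verbal communication", "cardiac output",
]
_ACTIONS = [
    "monitor", "assess", "document", "maintain", "support", "reposition for",
    "administer care for", "teach about", "evaluate", "protect",
    "schedule checks of", "coordinate care for", "record trends in",
    "inspect", "manage",
]
_IV_TOPICS = [
    "vital signs", "wound site", "oxygen therapy", "pressure areas",
    "intravenous line", "pain control", "feeding tolerance", "fall safety",
    "medication response", "hygiene needs", "fluid balance",
    "respiratory status", "mental status", "catheter care",
]

_DIAG_TEMPLATES = [
    "{label}", "noted {label}", "{label} observed this shift", "evidence of {label}",
]
_IV_TEMPLATES = [
    "{label}", "{label} performed", "continue to {label}", "{label} as scheduled",
]

_NOISE_CLAUSES = [
    "family visited at bedside", "patient resting quietly", "call bell within reach",
    "environment kept calm", "routine rounding completed", "shift handover given",
    "no new orders received", "room tidied", "curtains drawn for privacy",
    "chart reviewed with team",
]

_CARE_COMPONENTS = [
    "physiological", "functional", "psychological", "health behavioral",
]


@dataclass
class SyntheticTerminology:
    """A generated terminology plus the paraphrase bank of every term."""

    terms: TerminologySet
    paraphrases: dict[str, list[str]] = field(default_factory=dict)

    def clause_lookup(self) -> dict[str, str]:
        """Exact clause text → code, over labels and all paraphrases."""
        lookup: dict[str, str] = {}
        for entry in self.terms:
            lookup[entry.label] = entry.code
            lookup[entry.embedding_text] = entry.code
            for p in self.paraphrases.get(entry.code, []):
                lookup[p] = entry.code
        return lookup


def _label_inventory(adjectives: Sequence[str], topics: Sequence[str], count: int) -> list[str]:
    labels = [f"{a} {t}" for t in topics for a in adjectives]
    if count > len(labels):
        raise ValueError(
            f"cannot generate {count} unique labels from {len(labels)} combinations"
        )
    return labels[:count]


def generate_terminology(cfg: SynthConfig) -> SyntheticTerminology:
    """Generate a toy coded vocabulary with per-term paraphrase banks.

    Codes follow a regular pattern (D0001…, I0001…); labels are unique
    adjective/action × topic phrases; each term's paraphrases are distinct
    templated rewordings that contain the label verbatim, so any clause
    built from the bank identifies its term unambiguously.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    synth = SyntheticTerminology(terms=TerminologySet())
    specs = [
        (Category.DIAGNOSIS, "D", cfg.n_diagnoses, _PROBLEMS, _DIAG_TOPICS, _DIAG_TEMPLATES),
        (Category.INTERVENTION, "I", cfg.n_interventions, _ACTIONS, _IV_TOPICS, _IV_TEMPLATES),
    ]
    for category, prefix, count, adjectives, topics, templates in specs:
        for i, label in enumerate(_label_inventory(adjectives, topics, count), start=1):
            code = f"{prefix}{i:04d}"
            component = _CARE_COMPONENTS[(i - 1) % len(_CARE_COMPONENTS)]
            synth.terms.add(
                TermEntry(
                    code=code,
                    label=label,
                    category=category,
                    care_component=component,
                    source_vocab=SourceVocab.CCC,
                )
            )
            n_templates = min(cfg.paraphrases_per_term, len(templates))
            chosen = rng.choice(len(templates), size=n_templates, replace=False)
            synth.paraphrases[code] = [templates[j].format(label=label) for j in sorted(chosen)]
    return synth


# ---------------------------------------------------------------------------
# Records, gold annotations and the annotated corpus

_JOINERS = [". ", "; ", ", "]


def _sample_codes(rng: np.random.Generator, codes: Sequence[str], lo: int, hi: int) -> list[str]:
    n = min(int(rng.integers(lo, hi + 1)), len(codes))
    picked = rng.choice(len(codes), size=n, replace=False)
    return [codes[int(i)] for i in sorted(picked)]


def _compose_text(rng: np.random.Generator, clauses: list[str]) -> str:
    order = rng.permutation(len(clauses))
    shuffled = [clauses[int(i)] for i in order]
    parts: list[str] = []
    for i, clause in enumerate(shuffled):
        parts.append(clause)
        if i < len(shuffled) - 1:
            parts.append(_JOINERS[int(rng.integers(0, len(_JOINERS)))])
    return "".join(parts) + "."


@dataclass
class SyntheticDataset:
    """Records with gold annotations, plus the disjoint example corpus."""

    terminology: SyntheticTerminology
    records: list[NursingRecord]
    gold: list[GoldAnnotation]
    corpus: list[AnnotatedExample]


def generate_records(
    synth: SyntheticTerminology, cfg: SynthConfig
) -> tuple[list[NursingRecord], list[GoldAnnotation], list[AnnotatedExample]]:
    """Generate evaluation records with gold sets and an example corpus.

    Each record concatenates one paraphrase clause per gold code (both
    categories) with Binomial(n_clauses, noise_clause_rate) irrelevant
    noise clauses, in shuffled order with mixed clause delimiters. The
    annotated corpus is generated independently (no shared records) with
    1–2 codes per example.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    dx_codes = [e.code for e in synth.terms.entries_of(Category.DIAGNOSIS)]
    iv_codes = [e.code for e in synth.terms.entries_of(Category.INTERVENTION)]
    lo, hi = cfg.codes_per_record

    records: list[NursingRecord] = []
    gold: list[GoldAnnotation] = []
    for r in range(1, cfg.n_records + 1):
        g_dx = _sample_codes(rng, dx_codes, lo, hi)
        g_iv = _sample_codes(rng, iv_codes, lo, hi)
        clauses = []
        for code in g_dx + g_iv:
            bank = synth.paraphrases[code]
            clauses.append(bank[int(rng.integers(0, len(bank)))])
        n_noise = int(rng.binomial(len(clauses), cfg.noise_clause_rate))
        for _ in range(n_noise):
            clauses.append(_NOISE_CLAUSES[int(rng.integers(0, len(_NOISE_CLAUSES)))])
        records.append(NursingRecord(record_id=f"R{r:04d}", text=_compose_text(rng, clauses)))
        gold.append(
            GoldAnnotation(
                record_id=f"R{r:04d}",
                diagnosis_codes=frozenset(g_dx),
                intervention_codes=frozenset(g_iv),
            )
        )

    all_codes = dx_codes + iv_codes
    corpus: list[AnnotatedExample] = []
    for e in range(1, cfg.n_corpus_examples + 1):
        codes = _sample_codes(rng, all_codes, 1, 2)
        clauses = [
            synth.paraphrases[c][int(rng.integers(0, len(synth.paraphrases[c])))] for c in codes
        ]
        corpus.append(
            AnnotatedExample(
                example_id=f"E{e:04d}",
                text=_compose_text(rng, clauses),
                codes=frozenset(codes),
            )
        )
    return records, gold, corpus


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Terminology + records + gold + corpus in one deterministic call."""
    synth = generate_terminology(cfg)
    records, gold, corpus = generate_records(synth, cfg)
    return SyntheticDataset(terminology=synth, records=records, gold=gold, corpus=corpus)


# ---------------------------------------------------------------------------
# Multi-rater tables


def generate_ratings(
    gold: Iterable[GoldAnnotation],
    code_universe: Sequence[str],
    n_raters: int = 3,
    rater_error_rate: float = 0.02,
    seed: int = 0,
) -> RatingTable:
    """Simulate raters judging code presence on every record.

    Items are record × code binary presence judgments over the given code
    universe; every rater independently flips each true judgment with the
    given error rate. With rate 0 all raters agree perfectly; with rate
    0.5 judgments are pure noise and kappa is near 0.
    """
    if n_raters < 2:
        raise ValueError("n_raters must be >= 2")
    gold = list(gold)
    truth = np.array(
        [[int(code in g.codes()) for code in code_universe] for g in gold], dtype=np.int64
    ).reshape(-1)
    rng = np.random.default_rng([seed, 3])
    flips = rng.random((truth.shape[0], n_raters)) < rater_error_rate
    judgments = np.where(flips, 1 - truth[:, None], truth[:, None])
    return ratings_from_judgments(judgments, n_categories=2)


# ---------------------------------------------------------------------------
# Deterministic stand-in components

_SPLIT_RE = re.compile("[" + re.escape(DEFAULT_PUNCTUATION) + "]")


class OneHotEmbedder:
    """Maps each paraphrase clause to the basis vector of its term.

    Built from a synthetic terminology's clause lookup; a text is resolved
    by exact clause match, falling back to splitting on clause punctuation
    and summing the basis vectors of every matched clause. Unmatched text
    embeds to the zero vector. With this embedder, dense retrieval is
    exact by construction, which isolates downstream stages in tests.
    """

    def __init__(self, synth: SyntheticTerminology):
        self._codes = synth.terms.codes
        self._code_index = {c: i for i, c in enumerate(self._codes)}
        self.dim = len(self._codes)
        self._lookup = synth.clause_lookup()

    def _vector_for(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim, dtype=np.float64)
        text = text.strip()
        code = self._lookup.get(text)
        if code is not None:
            v[self._code_index[code]] = 1.0
            return v
        for clause in _SPLIT_RE.split(text):
            clause = clause.strip()
            if not clause:
                continue
            code = self._lookup.get(clause)
            if code is not None:
                v[self._code_index[code]] += 1.0
        return v

    def embed(self, texts: list[str]) -> np.ndarray:
        return np.stack([self._vector_for(t) for t in texts]) if texts else np.zeros((0, self.dim))

    @property
    def fingerprint(self) -> str:
        return f"one-hot(dim={self.dim})"


def _record_seed(seed: int, record_id: str) -> int:
    digest = hashlib.blake2b(record_id.encode("utf-8"), digest_size=4).digest()
    return (seed * 2654435761 + int.from_bytes(digest, "big")) % (2**31)


class OracleBackend:
    """Generation stub answering with a record's (noised) gold codes.

    Per record, each gold code is dropped with probability ``error_rate``
    and, independently at the same rate, a spurious known non-gold code is
    injected. The noisy set is drawn once per record from a seed derived
    from (seed, record_id), so output is identical across repeated prompts
    of the same record and invariant to processing order. At error rate 0
    the emitted array is exactly the gold set; at 1 it contains no gold
    code.
    """

    def __init__(
        self,
        gold: Iterable[GoldAnnotation],
        terms: TerminologySet,
        error_rate: float = 0.0,
        seed: int = 0,
    ):
        if not 0.0 <= error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        self._gold = {g.record_id: g for g in gold}
        self._all_codes = terms.codes
        self.error_rate = float(error_rate)
        self.seed = int(seed)
        self._cache: dict[str, str] = {}

    def _response_for(self, record_id: str) -> str:
        gold = self._gold.get(record_id)
        if gold is None:
            return "[]"
        rng = np.random.default_rng(_record_seed(self.seed, record_id))
        emitted: list[str] = []
        gold_codes = sorted(gold.codes())
        non_gold = [c for c in self._all_codes if c not in gold.codes()]
        for code in gold_codes:
            if rng.random() >= self.error_rate:
                emitted.append(code)
            if non_gold and rng.random() < self.error_rate:
                emitted.append(non_gold[int(rng.integers(0, len(non_gold)))])
        return json.dumps(sorted(set(emitted)))

    def complete(self, prompt: Prompt) -> str:
        rid = prompt.record_id
        if rid not in self._cache:
            self._cache[rid] = self._response_for(rid)
        return self._cache[rid]

    @property
    def fingerprint(self) -> str:
        return f"oracle(error_rate={self.error_rate},seed={self.seed})"


def oracle_backend(
    gold: Iterable[GoldAnnotation],
    terms: TerminologySet,
    error_rate: float = 0.0,
    seed: int = 0,
) -> OracleBackend:
    """Convenience constructor for :class:`OracleBackend`."""
    return OracleBackend(gold, terms, error_rate=error_rate, seed=seed)
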