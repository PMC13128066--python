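"""Stage 1: dense candidate retrieval over terminology entries and examples.

A free-text record is segmented on Chinese and English punctuation into
text chunks, and the whole record is kept as an additional subquery, so
both fine-grained clauses and record-level context participate in
retrieval. Subqueries, terminology reference entries and annotated-corpus
examples are embedded into dense vectors, L2-normalized, and scored by a
single matrix product — entry (i, j) of the score matrix is the cosine
similarity between subquery i and candidate j. For each subquery the top-k
candidates are retrieved separately from the reference entries and from
the annotated corpus (k=5 by default), then merged across subqueries and
sources and deduplicated, keeping each item's maximum score, to form the
record's context window.

Retrieval quality is measured by Recall@k: the macro-averaged fraction of
a record's gold codes found among its top-k retrieved reference entries,
computed over the merged reference ranking.
"""

from __future__ import annotations

import json
import logging
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .embedders import Embedder, check_matrix
from .terminology import (
    AnnotatedExample,
    Category,
    GoldAnnotation,
    NursingRecord,
    TerminologySet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PUNCTUATION",
    "SubqueryOrigin",
    "Subquery",
    "EmbeddingMatrix",
    "HitSource",
    "RetrievalHit",
    "ContextWindow",
    "RetrievalEvalResult",
    "DenseIndex",
    "segment_record",
    "embed",
    "l2_normalize",
    "similarity_matrix",
    "retrieve_top_k",
    "build_reference_index",
    "build_corpus_index",
    "build_context_window",
    "recall_at_k",
]

#: Chinese full-width sentence/clause delimiters plus their ASCII kin.
DEFAULT_PUNCTUATION = "。！？；，、.!?;,"

_SCORE_ATOL = 1e-9


class SubqueryOrigin(str, Enum):
    FULL_RECORD = "full_record"
    CHUNK = "chunk"


@dataclass(frozen=True)
class Subquery:
    """One retrieval unit: a punctuation-delimited chunk or the full record."""

    text: str
    origin: SubqueryOrigin
    ordinal: int

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("subquery text must be non-empty after trimming")


@dataclass
class EmbeddingMatrix:
    """Dense vectors for a list of items, with their identifiers in parallel."""

    matrix: np.ndarray
    item_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-dimensional")
        if self.matrix.shape[0] != len(self.item_ids):
            raise ValueError("item_ids length must match the number of rows")

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return self.matrix.shape[0]


class HitSource(str, Enum):
    REFERENCE = "reference"
    CORPUS = "corpus"


@dataclass(frozen=True)
class RetrievalHit:
    """One retrieved candidate with its cosine similarity score."""

    item_id: str
    source: HitSource
    score: float

    def __post_init__(self) -> None:
        if not -1.0 - _SCORE_ATOL <= self.score <= 1.0 + _SCORE_ATOL:
            raise ValueError(f"cosine score {self.score} outside [-1, 1]")


@dataclass
class ContextWindow:
    """Merged, deduplicated, score-ordered retrieval results for a record."""

    record_id: str
    hits: list[RetrievalHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [h.item_id for h in self.hits]
        if len(ids) != len(set(ids)):
            raise ValueError("context window contains duplicate item_ids")
        scores = [h.score for h in self.hits]
        if any(a < b - _SCORE_ATOL for a, b in zip(scores, scores[1:])):
            raise ValueError("context window hits must be sorted by descending score")

    def items(self, source: HitSource | None = None) -> list[str]:
        if source is None:
            return [h.item_id for h in self.hits]
        return [h.item_id for h in self.hits if h.source is source]


@dataclass(frozen=True)
class RetrievalEvalResult:
    """Recall@k per retrieval window size; non-decreasing in k."""

    recall_at_k: Mapping[int, float]
    n_records: int

    def __post_init__(self) -> None:
        ks = sorted(self.recall_at_k)
        vals = [self.recall_at_k[k] for k in ks]
        if any(v2 < v1 - 1e-12 for v1, v2 in zip(vals, vals[1:])):
            raise ValueError("recall@k must be non-decreasing in k")


# ---------------------------------------------------------------------------
# Segmentation


def segment_record(
    record: NursingRecord,
    punctuation: str = DEFAULT_PUNCTUATION,
) -> list[Subquery]:
    """Split a record on clause punctuation; keep the full text as a subquery.

    Chunks are trimmed and empties dropped. When the text contains no
    delimiter the lone chunk would duplicate the full record, so a single
    full-record subquery is returned. Empty or whitespace-only text yields
    an empty list with a warning.
    """
    text = record.text.strip()
    if not text:
        logger.warning("record %s has empty text; no subqueries", record.record_id)
        return []
    pattern = "[" + re.escape(punctuation) + "]"
    chunks = [c.strip() for c in re.split(pattern, text)]
    chunks = [c for c in chunks if c]
    if len(chunks) <= 1 and (not chunks or chunks[0] == text):
        return [Subquery(text=text, origin=SubqueryOrigin.FULL_RECORD, ordinal=0)]
    subqueries = [
        Subquery(text=c, origin=SubqueryOrigin.CHUNK, ordinal=i) for i, c in enumerate(chunks)
    ]
    subqueries.append(
        Subquery(text=text, origin=SubqueryOrigin.FULL_RECORD, ordinal=len(chunks))
    )
    return subqueries


# ---------------------------------------------------------------------------
# Embedding and similarity


def embed(texts: Sequence[str], embedder: Embedder, item_ids: Sequence[str] | None = None) -> EmbeddingMatrix:
    """Embed texts into an (unnormalized) matrix, one row per text."""
    if item_ids is None:
        item_ids = [str(i) for i in range(len(texts))]
    if len(texts) == 0:
        matrix = np.zeros((0, embedder.dim), dtype=np.float64)
    else:
        matrix = check_matrix(embedder.embed(list(texts)), len(texts), embedder.dim)
    return EmbeddingMatrix(matrix=matrix, item_ids=list(item_ids), normalized=False)


def l2_normalize(m: EmbeddingMatrix) -> EmbeddingMatrix:
    """Scale each non-zero row to unit Euclidean norm.

    Zero rows (texts the embedder mapped to nothing) are left zero — their
    cosine similarity against everything is then 0 — and logged.
    """
    norms = np.linalg.norm(m.matrix, axis=1)
    zero = norms == 0.0
    if zero.any():
        logger.warning("%d zero embedding row(s) left unnormalized", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    return EmbeddingMatrix(matrix=m.matrix / safe[:, None], item_ids=list(m.item_ids), normalized=True)


def similarity_matrix(queries: EmbeddingMatrix, refs: EmbeddingMatrix) -> np.ndarray:
    """Cosine similarity via one matrix product of normalized vectors.

    Returns a (n_queries × n_refs) array; entry (i, j) is the cosine
    similarity between query i and reference j. Both inputs must already be
    normalized and share a dimensionality.
    """
    if not (queries.normalized and refs.normalized):
        raise ValueError("similarity_matrix requires L2-normalized inputs")
    if queries.dim != refs.dim:
        raise ValueError(f"dimension mismatch: {queries.dim} != {refs.dim}")
    return queries.matrix @ refs.matrix.T


def retrieve_top_k(scores: np.ndarray, item_ids: Sequence[str], k: int, source: HitSource) -> list[RetrievalHit]:
    """Top-k items of one query's score row, descending score.

    Ties break by ascending item ordinal (stable sort), so results are
    reproducible. If fewer than k items exist, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or scores.shape[0] != len(item_ids):
        raise ValueError("scores must be a 1-D row aligned with item_ids")
    order = np.argsort(-scores, kind="stable")[:k]
    return [
        RetrievalHit(item_id=item_ids[i], source=source, score=float(np.clip(scores[i], -1.0, 1.0)))
        for i in order
    ]


# ---------------------------------------------------------------------------
# Indexes


@dataclass
class DenseIndex:
    """A normalized embedding matrix searchable by cosine similarity."""

    embeddings: EmbeddingMatrix
    source: HitSource
    embedder_fingerprint: str = ""

    def __post_init__(self) -> None:
        if not self.embeddings.normalized:
            raise ValueError("DenseIndex requires normalized embeddings")

    def __len__(self) -> int:
        return len(self.embeddings)

    def search(self, queries: EmbeddingMatrix, k: int) -> list[list[RetrievalHit]]:
        """Per-query top-k hits."""
        if len(self.embeddings) == 0:
            return [[] for _ in range(len(queries))]
        sims = similarity_matrix(queries, self.embeddings)
        return [
            retrieve_top_k(sims[i], self.embeddings.item_ids, k, self.source)
            for i in range(sims.shape[0])
        ]

    # -- persistence: text matrix + JSON sidecar --------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.embeddings.matrix, fmt="%.17g")
        sidecar = {
            "dim": self.embeddings.dim,
            "embedder_fingerprint": self.embedder_fingerprint,
            "item_ids": self.embeddings.item_ids,
            "normalized": self.embeddings.normalized,
            "source": self.source.value,
        }
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, ensure_ascii=False, sort_keys=True, indent=2) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "DenseIndex":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text(encoding="utf-8"))
        matrix = np.loadtxt(path, ndmin=2)
        if matrix.size == 0:
            matrix = matrix.reshape(0, sidecar["dim"])
        emb = EmbeddingMatrix(matrix=matrix, item_ids=sidecar["item_ids"], normalized=sidecar["normalized"])
        return cls(
            embeddings=emb,
            source=HitSource(sidecar["source"]),
            embedder_fingerprint=sidecar.get("embedder_fingerprint", ""),
        )


def build_reference_index(terms: TerminologySet, embedder: Embedder) -> DenseIndex:
    """Embed every terminology entry (label — description) and normalize."""
    texts = [e.embedding_text for e in terms]
    emb = l2_normalize(embed(texts, embedder, item_ids=[e.code for e in terms]))
    return DenseIndex(embeddings=emb, source=HitSource.REFERENCE, embedder_fingerprint=embedder.fingerprint)


def build_corpus_index(examples: Sequence[AnnotatedExample], embedder: Embedder) -> DenseIndex:
    """Embed annotated examples from their raw text and normalize."""
    emb = l2_normalize(
        embed([e.text for e in examples], embedder, item_ids=[e.example_id for e in examples])
    )
    return DenseIndex(embeddings=emb, source=HitSource.CORPUS, embedder_fingerprint=embedder.fingerprint)


# ---------------------------------------------------------------------------
# Context windows


def _merge_hits(hit_lists: Iterable[list[RetrievalHit]]) -> list[RetrievalHit]:
    """Union of hits, deduplicated by item_id keeping the maximum score.

    The final order is descending score, ties broken by first appearance
    (which follows subquery order, then rank) for reproducibility.
    """
    best: dict[str, RetrievalHit] = {}
    arrival: dict[str, int] = {}
    counter = 0
    for hits in hit_lists:
        for hit in hits:
            counter += 1
            prev = best.get(hit.item_id)
            if prev is None:
                best[hit.item_id] = hit
                arrival[hit.item_id] = counter
            elif hit.score > prev.score:
                best[hit.item_id] = hit
    return sorted(best.values(), key=lambda h: (-h.score, arrival[h.item_id]))


def build_context_window(
    record: NursingRecord,
    embedder: Embedder,
    reference_index: DenseIndex,
    corpus_index: DenseIndex | None = None,
    k: int = 5,
    punctuation: str = DEFAULT_PUNCTUATION,
    subqueries: Sequence[Subquery] | None = None,
) -> ContextWindow:
    """Retrieve per subquery from each source; merge, dedup, sort by score.

    Each subquery contributes its top-k reference entries and (when a corpus
    index is supplied) its top-k annotated examples. Items retrieved by
    several subqueries appear once with their maximum score. A record that
    segments to zero subqueries yields an empty window with a warning.
    """
    if subqueries is None:
        subqueries = segment_record(record, punctuation)
    if not subqueries:
        logger.warning("record %s produced no subqueries; empty context window", record.record_id)
        return ContextWindow(record_id=record.record_id, hits=[])
    queries = l2_normalize(embed([s.text for s in subqueries], embedder))
    per_source: list[list[RetrievalHit]] = []
    for index in (reference_index, corpus_index):
        if index is None or len(index) == 0:
            continue
        per_source.extend(index.search(queries, k))
    return ContextWindow(record_id=record.record_id, hits=_merge_hits(per_source))


# ---------------------------------------------------------------------------
# Recall@k


def recall_at_k(
    ranked_codes: Mapping[str, Sequence[str]],
    gold: Iterable[GoldAnnotation],
    ks: Iterable[int] = (1, 3, 5, 10),
    category: Category | None = None,
) -> RetrievalEvalResult:
    """Macro-averaged fraction of gold codes among the top-k retrieved codes.

    ``ranked_codes`` maps each record id to its merged reference ranking
    (best first). Records with empty gold sets carry no signal and are
    skipped; if every gold set is empty the metric is undefined and a
    ``ValueError`` is raised. Gold codes never retrieved contribute 0 at
    every k, so recall is monotone non-decreasing in k by construction.
    """
    ks = sorted(set(int(k) for k in ks))
    if not ks or ks[0] < 1:
        raise ValueError("ks must contain integers >= 1")
    per_record: dict[int, list[float]] = {k: [] for k in ks}
    for g in gold:
        gold_codes = g.codes(category)
        if not gold_codes:
            continue
        ranking = list(ranked_codes.get(g.record_id, ()))
        for k in ks:
            top = set(ranking[:k])
            per_record[k].append(len(gold_codes & top) / len(gold_codes))
    n = len(per_record[ks[0]])
    if n == 0:
        raise ValueError("recall@k undefined: every gold set is empty")
    return RetrievalEvalResult(
        recall_at_k={k: float(np.mean(v)) for k, v in per_record.items()},
        n_records=n,
    )
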