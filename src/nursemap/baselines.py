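"""Lexical and embedding-similarity baselines for terminology ranking.

Two rule-driven reference systems bracket the retrieval-augmented mapper:

* a TF-IDF baseline — record and terminology-entry texts become term
  frequency–inverse document frequency vectors and candidates are ranked
  by cosine similarity (lexical matching);
* an embedding-cosine baseline — the same ranking computed over dense
  sentence embeddings from any adapter satisfying the retrieval module's
  embedder contract, so a contextual ("BERT-style") baseline is an
  adapter choice rather than separate code.

Tokenization for TF-IDF defaults to character bigrams, which needs no word
segmenter and therefore treats Chinese and English text uniformly; a
whitespace-token analyzer is available for purely English corpora.

Rankings become predicted code sets through an explicit
:class:`PredictionRule` — keep the top-n codes, or every code scoring at
least a threshold — since a ranking alone is not a set prediction.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.preprocessing import normalize

from .embedders import Embedder
from .retrieval import build_reference_index, embed, l2_normalize
from .terminology import NursingRecord, TerminologySet

__all__ = [
    "TfidfModel",
    "PredictionRule",
    "tfidf_fit",
    "rank_terms",
    "apply_rule",
    "baseline_predictions",
]


class TfidfModel:
    """Fitted TF-IDF vectorizer with L2-normalized document vectors.

    Standard smoothed logarithmic IDF: idf(t) = ln((1 + N) / (1 + df(t))) + 1
    over N fitting documents, raw term counts as TF, and each document
    vector scaled to unit Euclidean norm.
    """

    def __init__(self, analyzer: str = "char", ngram: int = 2):
        if analyzer not in {"char", "word"}:
            raise ValueError("analyzer must be 'char' or 'word'")
        self.analyzer = analyzer
        self.ngram = int(ngram)
        kwargs = (
            {"analyzer": "char", "ngram_range": (self.ngram, self.ngram)}
            if analyzer == "char"
            else {"analyzer": "word", "token_pattern": r"(?u)\S+"}
        )
        self._vectorizer = TfidfVectorizer(
            norm="l2", smooth_idf=True, sublinear_tf=False, lowercase=False, **kwargs
        )
        self._fitted = False

    def fit(self, documents: Sequence[str]) -> "TfidfModel":
        docs = [d for d in documents if d.strip()]
        if not docs:
            raise ValueError("TF-IDF fitting requires at least one non-empty document")
        self._vectorizer.fit(docs)
        self._fitted = True
        return self

    def transform(self, texts: Sequence[str]) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("TfidfModel is not fitted")
        return self._vectorizer.transform(texts).toarray()

    @property
    def vocabulary(self) -> dict[str, int]:
        return dict(self._vectorizer.vocabulary_)

    @property
    def idf(self) -> np.ndarray:
        return self._vectorizer.idf_.copy()


def tfidf_fit(documents: Sequence[str], analyzer: str = "char", ngram: int = 2) -> TfidfModel:
    """Fit a TF-IDF model on a document collection."""
    return TfidfModel(analyzer=analyzer, ngram=ngram).fit(documents)


@dataclass(frozen=True)
class PredictionRule:
    """Rule converting a ranking into a predicted set: top-n or threshold."""

    kind: str  # "top_n" | "threshold"
    n: int | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "top_n":
            if self.n is None or self.n < 1:
                raise ValueError("top_n rule requires n >= 1")
        elif self.kind == "threshold":
            if self.tau is None or not -1.0 <= self.tau <= 1.0:
                raise ValueError("threshold rule requires tau in [-1, 1]")
        else:
            raise ValueError(f"unknown rule kind: {self.kind!r}")

    @classmethod
    def parse(cls, spec: str) -> "PredictionRule":
        """Parse 'top_n:5' or 'threshold:0.3'."""
        kind, _, value = spec.partition(":")
        if kind == "top_n":
            return cls(kind="top_n", n=int(value))
        if kind == "threshold":
            return cls(kind="threshold", tau=float(value))
        raise ValueError(f"unknown rule spec: {spec!r}")


def rank_terms(
    record: NursingRecord,
    terms: TerminologySet,
    scorer: TfidfModel | Embedder,
) -> list[tuple[str, float]]:
    """Score every terminology entry against the record; sort descending.

    The output is a permutation of the terminology's codes with cosine
    scores; ties break stably by terminology order, so rankings are
    reproducible.
    """
    entry_texts = [e.embedding_text for e in terms]
    codes = terms.codes
    if isinstance(scorer, TfidfModel):
        vectors = scorer.transform([record.text] + entry_texts)
        vectors = normalize(vectors, norm="l2", copy=False)
        scores = vectors[0] @ vectors[1:].T
    else:
        ref = build_reference_index(terms, scorer)
        query = l2_normalize(embed([record.text], scorer))
        scores = (query.matrix @ ref.embeddings.matrix.T)[0]
    order = np.argsort(-np.asarray(scores), kind="stable")
    return [(codes[i], float(scores[i])) for i in order]


def apply_rule(ranked: Sequence[tuple[str, float]], rule: PredictionRule) -> set[str]:
    """Turn a ranked (code, score) list into a predicted code set."""
    if rule.kind == "top_n":
        return {code for code, _ in ranked[: rule.n]}
    return {code for code, score in ranked if score >= rule.tau}


def baseline_predictions(
    records: Sequence[NursingRecord],
    terms: TerminologySet,
    scorer: TfidfModel | Embedder,
    rule: PredictionRule,
) -> dict[str, set[str]]:
    """Predicted code set per record under one scorer and decision rule."""
    return {r.record_id: apply_rule(rank_terms(r, terms, scorer), rule) for r in records}
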