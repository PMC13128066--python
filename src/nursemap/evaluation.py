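"""Set-based mapping metrics and multi-rater agreement.

Each record is treated as a set of terminology codes. For gold set G and
predicted set P:

    TP = |G ∩ P|,  FP = |P \\ G|,  FN = |G \\ P|
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)
    IoU       = TP / (TP + FP + FN) = |G ∩ P| / |G ∪ P|

IoU rewards recovering the full combination of codes on a record, not
just individual hits. Overall performance is the macro-average (unweighted
mean) of each per-record metric; diagnoses and interventions are evaluated
separately. Degenerate records follow a disclosed convention: when both
sets are empty every metric is 1.0 (the prediction is exactly right);
when exactly one is empty every metric is 0.0. This keeps macro-averaging
total. A useful algebraic identity, F1 = 2·IoU / (1 + IoU), holds for
every non-degenerate record and is enforced as an invariant in the tests.

Inter-rater agreement among a fixed panel of raters uses Fleiss' kappa:
κ = (Po − Pe) / (1 − Pe), with Po the mean per-item observed agreement and
Pe the chance agreement from squared category proportions. The default
unit of analysis for rating a coding task is the record × code presence
judgment over the code universe in use, which makes raw agreement high
even at moderate κ because most judgments are absences.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .terminology import Category, GoldAnnotation

__all__ = [
    "RecordMetrics",
    "MacroMetrics",
    "RatingTable",
    "AgreementResult",
    "DegenerateAgreementError",
    "record_metrics",
    "macro_metrics",
    "fleiss_kappa",
    "kappa_from_agreement",
    "evaluate_run",
    "ratings_from_judgments",
]


@dataclass(frozen=True)
class RecordMetrics:
    """Set-based counts and metrics for one record."""

    record_id: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    iou: float


@dataclass(frozen=True)
class MacroMetrics:
    """Unweighted means of per-record metrics."""

    n_records: int
    precision: float
    recall: float
    f1: float
    iou: float

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Report-style view at table precision; internals stay full precision."""
        return {
            "n_records": self.n_records,
            "precision": round(self.precision, ndigits),
            "recall": round(self.recall, ndigits),
            "f1": round(self.f1, ndigits),
            "iou": round(self.iou, ndigits),
        }


class DegenerateAgreementError(ValueError):
    """Fleiss kappa is undefined: chance agreement Pe equals 1."""


def record_metrics(gold: Iterable[str], predicted: Iterable[str], record_id: str = "") -> RecordMetrics:
    """Per-record precision/recall/F1/IoU from set arithmetic.

    Conventions for degenerate sets: G = P = ∅ gives all metrics 1.0;
    exactly one empty set gives all 0.0.
    """
    g, p = set(gold), set(predicted)
    tp = len(g & p)
    fp = len(p - g)
    fn = len(g - p)
    if not g and not p:
        precision = recall = f1 = iou = 1.0
    elif not g or not p:
        precision = recall = f1 = iou = 0.0
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
        iou = tp / (tp + fp + fn)
    return RecordMetrics(
        record_id=record_id, tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1, iou=iou,
    )


def macro_metrics(per_record: Sequence[RecordMetrics]) -> MacroMetrics:
    """Macro-average: the unweighted mean of each metric across records."""
    if not per_record:
        raise ValueError("macro_metrics requires at least one record")
    return MacroMetrics(
        n_records=len(per_record),
        precision=float(np.mean([m.precision for m in per_record])),
        recall=float(np.mean([m.recall for m in per_record])),
        f1=float(np.mean([m.f1 for m in per_record])),
        iou=float(np.mean([m.iou for m in per_record])),
    )


# ---------------------------------------------------------------------------
# Fleiss kappa


@dataclass
class RatingTable:
    """Items × categories matrix of rater counts; every row sums to n_raters."""

    counts: np.ndarray
    n_raters: int
    category_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("rating counts must be a 2-D items × categories matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("rating counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("rating counts must be non-negative")
        if self.n_raters < 2:
            raise ValueError("Fleiss kappa needs at least 2 raters")
        if self.counts.shape[0] < 1:
            raise ValueError("rating table needs at least 1 item")
        row_sums = self.counts.sum(axis=1)
        if not np.all(row_sums == self.n_raters):
            raise ValueError("every row must sum to n_raters")


@dataclass(frozen=True)
class AgreementResult:
    """Fleiss kappa with its observed/expected agreement components."""

    observed_agreement: float
    expected_agreement: float
    kappa: float

    @property
    def one_minus_expected(self) -> float:
        return 1.0 - self.expected_agreement


def kappa_from_agreement(po: float, pe: float) -> float:
    """Chance-corrected agreement κ = (Po − Pe) / (1 − Pe); needs Pe < 1."""
    if not (0.0 <= po <= 1.0 and 0.0 <= pe <= 1.0):
        raise ValueError("Po and Pe must lie in [0, 1]")
    if pe >= 1.0:
        raise DegenerateAgreementError("kappa undefined: expected agreement Pe >= 1")
    return (po - pe) / (1.0 - pe)


def fleiss_kappa(table: RatingTable) -> AgreementResult:
    """Fleiss' kappa for agreement among a fixed number of raters.

    Per-item agreement is the fraction of concordant rater pairs,
    P_i = (Σ_j n_ij² − n) / (n (n − 1)); Po is the mean over items and
    Pe = Σ_j p_j² with p_j the overall proportion of ratings in category j.
    When every rating falls in a single category, Pe = 1 and kappa is
    undefined (a :class:`DegenerateAgreementError` is raised).
    """
    counts = table.counts.astype(np.float64)
    n = float(table.n_raters)
    p_item = ((counts**2).sum(axis=1) - n) / (n * (n - 1.0))
    po = float(p_item.mean())
    p_cat = counts.sum(axis=0) / counts.sum()
    pe = float((p_cat**2).sum())
    kappa = kappa_from_agreement(po, pe)
    return AgreementResult(observed_agreement=po, expected_agreement=pe, kappa=kappa)


def ratings_from_judgments(judgments: np.ndarray, n_categories: int = 2) -> RatingTable:
    """Build a rating table from an items × raters matrix of category labels.

    The default two-category layout fits binary presence/absence judgments
    (e.g. "rater r marked code c present on record i"), the unit of
    analysis used for coding-agreement studies in this package.
    """
    judgments = np.asarray(judgments)
    if judgments.ndim != 2:
        raise ValueError("judgments must be items × raters")
    n_items, n_raters = judgments.shape
    counts = np.zeros((n_items, n_categories), dtype=np.int64)
    for j in range(n_categories):
        counts[:, j] = (judgments == j).sum(axis=1)
    return RatingTable(counts=counts, n_raters=n_raters)


# ---------------------------------------------------------------------------
# Run evaluation


def evaluate_run(
    predictions: Mapping[str, Iterable[str]] | Iterable,
    gold: Iterable[GoldAnnotation],
    category: Category,
) -> tuple[MacroMetrics, list[RecordMetrics]]:
    """Join predictions to gold by record id and compute per-record + macro
    metrics for one category.

    ``predictions`` is either a mapping record_id → predicted code set, or
    an iterable of objects exposing ``record_id`` and per-category code
    sets (e.g. the generation stage's outputs). Records missing a
    prediction are scored as empty sets and counted in a warning; a
    duplicated record id is an integrity error.
    """
    import logging

    category = Category(category)
    if isinstance(predictions, Mapping):
        pred_map = {rid: set(codes) for rid, codes in predictions.items()}
    else:
        pred_map = {}
        for output in predictions:
            rid = output.record_id
            if rid in pred_map:
                raise ValueError(f"duplicate record id in predictions: {rid!r}")
            codes = (
                output.diagnosis_codes if category is Category.DIAGNOSIS else output.intervention_codes
            )
            pred_map[rid] = set(codes)

    gold_list = list(gold)
    gold_ids = [g.record_id for g in gold_list]
    if len(gold_ids) != len(set(gold_ids)):
        raise ValueError("duplicate record id in gold annotations")

    missing = [g.record_id for g in gold_list if g.record_id not in pred_map]
    if missing:
        logging.getLogger(__name__).warning(
            "%d record(s) missing predictions, scored as empty sets", len(missing)
        )
    per_record = [
        record_metrics(g.codes(category), pred_map.get(g.record_id, set()), record_id=g.record_id)
        for g in gold_list
    ]
    return macro_metrics(per_record), per_record
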