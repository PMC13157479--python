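"""Term-level validation metrics for predicted vs ground-truth HPO sets.

Each record contributes a predicted set *P* and a manually annotated truth
set *T* of canonical HPO codes.  With tp = |P∩T|, fp = |P∖T|, fn = |T∖P|:

    Jaccard  = tp / (tp + fp + fn)
    Precision = tp / (tp + fp)      Recall = tp / (tp + fn)
    F1 = 2·tp / (2·tp + fp + fn)    and identically  J = F1 / (2 − F1)

Aggregation reports BOTH views found in validation studies of this kind:
medians of the per-record metrics (the headline), and micro metrics pooled
over the raw counts across all records.  Degenerate records follow the
convention: both sets empty → all metrics 1.0 (a perfectly normal record,
correctly predicted as such); exactly one side empty → 0.0.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .catalog import canonicalize_code, is_sentinel

__all__ = ["RecordMetrics", "EvaluationReport", "record_metrics", "evaluate_corpus", "render_report"]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class RecordMetrics:
    record_id: str
    tp: int
    fp: int
    fn: int
    jaccard: float
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationReport:
    per_record: list[RecordMetrics]
    median_jaccard: float
    median_precision: float
    median_recall: float
    median_f1: float
    mean_predicted_terms: float
    mean_truth_terms: float
    total_predicted_terms: int
    total_truth_terms: int
    micro_precision: float
    micro_recall: float
    micro_f1: float
    micro_jaccard: float

    @property
    def n_records(self) -> int:
        return len(self.per_record)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "median": {
                "jaccard": self.median_jaccard,
                "precision": self.median_precision,
                "recall": self.median_recall,
                "f1": self.median_f1,
            },
            "mean_terms_per_record": {
                "predicted": self.mean_predicted_terms,
                "truth": self.mean_truth_terms,
            },
            "total_terms": {
                "predicted": self.total_predicted_terms,
                "truth": self.total_truth_terms,
            },
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
                "jaccard": self.micro_jaccard,
            },
            "per_record": [vars(m) for m in self.per_record],
        }


def _canonical_set(codes, side: str, record_id: str) -> set[str]:
    out = set()
    for c in codes:
        code = canonicalize_code(c)
        if is_sentinel(code):
            raise EvaluationError(
                f"record {record_id!r}: ignore sentinel in {side} set — "
                "sentinel matches must never surface as annotations"
            )
        out.add(code)
    return out


def record_metrics(pred, truth, record_id: str = "") -> RecordMetrics:
    """Set-overlap metrics for one record (degenerate cases per module doc)."""
    p = _canonical_set(pred, "predicted", record_id)
    t = _canonical_set(truth, "truth", record_id)
    tp = len(p & t)
    fp = len(p - t)
    fn = len(t - p)
    if not p and not t:
        jac = prec = rec = f1 = 1.0
    else:
        jac = tp / (tp + fp + fn)
        prec = tp / (tp + fp) if p else 0.0
        rec = tp / (tp + fn) if t else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn)
    return RecordMetrics(record_id, tp, fp, fn, jac, prec, rec, f1)


def evaluate_corpus(
    predictions: Mapping[str, set], truths: Mapping[str, set]
) -> EvaluationReport:
    """Per-record metrics plus median and micro aggregates over a corpus.

    The record-id universe is the union of both inputs; a record missing on
    one side is treated as an empty set there (and flagged by the caller's
    logging if desired).  Medians are standard order-statistic medians
    (mean of the middle two for even n).
    """
    ids = sorted(set(predictions) | set(truths))
    if not ids:
        raise EvaluationError("empty corpus: no records to evaluate")
    per_record = [
        record_metrics(predictions.get(rid, set()), truths.get(rid, set()), rid) for rid in ids
    ]
    tp = sum(m.tp for m in per_record)
    fp = sum(m.fp for m in per_record)
    fn = sum(m.fn for m in per_record)
    total_pred = tp + fp
    total_truth = tp + fn
    n = len(per_record)
    return EvaluationReport(
        per_record=per_record,
        median_jaccard=statistics.median(m.jaccard for m in per_record),
        median_precision=statistics.median(m.precision for m in per_record),
        median_recall=statistics.median(m.recall for m in per_record),
        median_f1=statistics.median(m.f1 for m in per_record),
        mean_predicted_terms=total_pred / n,
        mean_truth_terms=total_truth / n,
        total_predicted_terms=total_pred,
        total_truth_terms=total_truth,
        micro_precision=tp / total_pred if total_pred else (1.0 if not total_truth else 0.0),
        micro_recall=tp / total_truth if total_truth else (1.0 if not total_pred else 0.0),
        micro_f1=2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 1.0,
        micro_jaccard=tp / (tp + fp + fn) if (tp + fp + fn) else 1.0,
    )


_MD_ROWS = [
    ("HPO terms per medical record (mean)", "mean_predicted_terms", "mean_truth_terms"),
    ("Identified HPO terms in total", "total_predicted_terms", "total_truth_terms"),
]
_MD_MEDIANS = [
    ("Jaccard similarity: median", "median_jaccard"),
    ("Precision: median", "median_precision"),
    ("Recall: median", "median_recall"),
    ("F1-score: median", "median_f1"),
]
_MD_MICRO = [
    ("Precision: micro", "micro_precision"),
    ("Recall: micro", "micro_recall"),
    ("F1-score: micro", "micro_f1"),
    ("Jaccard: micro", "micro_jaccard"),
]


def _fmt(value) -> str:
    return str(value) if isinstance(value, int) else f"{value:.2f}"


def render_report(report: EvaluationReport, outdir: str | Path) -> tuple[Path, Path]:
    """Write ``report.json`` (machine) and ``report.md`` (validation-table
    layout, values to two decimals) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    json_path.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    lines = [
        f"# Validation report (n = {report.n_records})",
        "",
        "| Metric | Pipeline | Ground truth |",
        "| --- | --- | --- |",
    ]
    for label, pred_attr, truth_attr in _MD_ROWS:
        lines.append(
            f"| {label} | {_fmt(getattr(report, pred_attr))} | {_fmt(getattr(report, truth_attr))} |"
        )
    for label, attr in _MD_MEDIANS + _MD_MICRO:
        lines.append(f"| {label} | {_fmt(getattr(report, attr))} | |")
    md_path = outdir / "report.md"
    md_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return json_path, md_path
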