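"""Record, truth and annotation serialization (JSONL and CSV)."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

from .catalog import canonicalize_code
from .retrieval import Annotation
from .stages import ClinicalRecord

__all__ = [
    "read_records",
    "read_records_jsonl",
    "read_records_csv",
    "write_records_jsonl",
    "read_truth",
    "write_truth_jsonl",
    "write_annotations_jsonl",
    "read_annotations_jsonl",
    "write_predictions_jsonl",
]

_RECORD_FIELDS = ("record_id", "anterior_text", "posterior_text", "language")


def _record_from_mapping(row: Mapping[str, str], origin: str) -> ClinicalRecord:
    try:
        return ClinicalRecord(
            record_id=str(row["record_id"]),
            anterior_text=row.get("anterior_text", "") or "",
            posterior_text=row.get("posterior_text", "") or "",
            language=row.get("language", "de") or "de",
        )
    except KeyError as exc:
        raise ValueError(f"{origin}: record row missing field {exc}") from exc


def read_records_jsonl(path: str | Path) -> list[ClinicalRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if line.strip():
            records.append(_record_from_mapping(json.loads(line), f"{path}:{lineno}"))
    _check_unique(records, path)
    return records


def read_records_csv(path: str | Path) -> list[ClinicalRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        records = [_record_from_mapping(row, str(path)) for row in csv.DictReader(fh)]
    _check_unique(records, path)
    return records


def read_records(path: str | Path) -> list[ClinicalRecord]:
    """Dispatch on extension: ``.csv`` → CSV, anything else → JSONL."""
    path = Path(path)
    return read_records_csv(path) if path.suffix.lower() == ".csv" else read_records_jsonl(path)


def _check_unique(records, path) -> None:
    ids = [r.record_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record_id(s): {dupes}")


def write_records_jsonl(records: Iterable[ClinicalRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        json.dumps({f: getattr(r, f) for f in _RECORD_FIELDS}, ensure_ascii=False, sort_keys=True)
        for r in records
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


def read_truth(path: str | Path) -> dict[str, set[str]]:
    """Ground-truth sets: JSONL rows ``{"record_id": ..., "hpo_ids": [...]}``."""
    truth: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        row = json.loads(line)
        rid = str(row["record_id"])
        if rid in truth:
            raise ValueError(f"{path}:{lineno}: duplicate record_id {rid!r}")
        truth[rid] = {canonicalize_code(c) for c in row["hpo_ids"]}
    return truth


def write_truth_jsonl(truth: Mapping[str, set], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        json.dumps({"record_id": rid, "hpo_ids": sorted(truth[rid])}, sort_keys=True)
        for rid in sorted(truth)
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


write_predictions_jsonl = write_truth_jsonl  # same schema, different role


def write_annotations_jsonl(annotations: Iterable[Annotation], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        json.dumps(
            {
                "record_id": a.record_id,
                "scope": a.scope,
                "segment_text": a.text,
                "hpo_id": a.curie,
                "similarity": round(a.similarity, 6),
                "tier": a.tier,
                "matched_surface": a.matched_surface,
            },
            ensure_ascii=False,
            sort_keys=True,
        )
        for a in annotations
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


def read_annotations_jsonl(path: str | Path) -> list[Annotation]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        row = json.loads(line)
        out.append(
            Annotation(
                record_id=row["record_id"],
                scope=row["scope"],
                text=row["segment_text"],
                code=canonicalize_code(row["hpo_id"]),
                similarity=row["similarity"],
                tier=row["tier"],
                matched_surface=row["matched_surface"],
            )
        )
    return out
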