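"""Expert-in-the-loop catalog augmentation.

Whenever retrieval returns a wrong code for a surface form, a reviewer logs
a correction; applying the log attaches each corrected surface to its
reviewed code as a local-layer synonym, so every future occurrence resolves
exactly.  Phenotypes that simply do not exist in the ontology yet are
logged with the ``MISSING`` marker and a proposed label, and can be
exported as a submission-ready TSV for the upstream ontology maintainers.

Corrections are applied all-or-nothing per batch: conflicting corrections
for one surface (or against an existing local mapping) abort the whole
batch, keeping catalog states reviewable.  Logs carry a provenance tag so
callers can keep corrections mined from a held-out validation corpus out
of the catalog (training/validation separation is enforced at the CLI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .catalog import (
    CatalogError,
    ConflictError,
    IGNORE_SENTINEL,
    SynonymCatalog,
    add_synonym,
    canonicalize_code,
    normalize_surface,
)

__all__ = [
    "MISSING",
    "CorrectionEntry",
    "CorrectionLog",
    "log_correction",
    "apply_corrections",
    "export_missing_terms",
    "import_missing_terms",
    "save_correction_log",
    "load_correction_log",
]

#: Marker for phenotypes absent from the ontology (no correct code exists).
MISSING = "MISSING"

_MISSING_HEADER = "surface\tproposed_label\treviewer\ttimestamp"


@dataclass(frozen=True)
class CorrectionEntry:
    surface: str
    predicted_code: str
    correct_code: str  # canonical code, or MISSING
    reviewer: str = ""
    proposed_label: str = ""
    timestamp: str = ""
    scope: str = "both"

    @property
    def is_missing(self) -> bool:
        return self.correct_code == MISSING

    def key(self) -> tuple[str, str]:
        return (normalize_surface(self.surface), self.correct_code)


@dataclass
class CorrectionLog:
    """Append-only list of corrections with a corpus provenance tag."""

    entries: list[CorrectionEntry] = field(default_factory=list)
    source_tag: str = "training"

    def __len__(self) -> int:
        return len(self.entries)

    def missing(self) -> list[CorrectionEntry]:
        return [e for e in self.entries if e.is_missing]


def log_correction(
    log: CorrectionLog,
    surface: str,
    predicted: str,
    correct: str,
    *,
    reviewer: str = "",
    proposed_label: str = "",
    timestamp: str = "",
    scope: str = "both",
) -> CorrectionLog:
    """Append one reviewed correction; duplicates (surface, correct) dedupe.

    ``predicted`` is the code the retriever returned (the ignore sentinel
    stands for "no prediction"); ``correct`` is the reviewed code, or
    :data:`MISSING` with a ``proposed_label`` when the phenotype is absent
    from the ontology altogether.  ``predicted == correct`` is a no-op
    entry and rejected.
    """
    if not normalize_surface(surface):
        raise CatalogError("correction surface must be non-empty")
    predicted = canonicalize_code(predicted)
    if correct == MISSING:
        if not proposed_label.strip():
            raise CatalogError(f"MISSING entry for {surface!r} needs a proposed label")
    else:
        correct = canonicalize_code(correct)
        if correct == IGNORE_SENTINEL:
            raise CatalogError("the ignore sentinel cannot be a correction target")
        if predicted == correct:
            raise CatalogError(
                f"correction for {surface!r} is a no-op: predicted and correct are both {correct}"
            )
    entry = CorrectionEntry(surface, predicted, correct, reviewer, proposed_label, timestamp, scope)
    if entry.key() not in {e.key() for e in log.entries}:
        log.entries.append(entry)
    return log


def apply_corrections(catalog: SynonymCatalog, log: CorrectionLog) -> tuple[SynonymCatalog, int]:
    """Attach every non-MISSING correction as a local synonym (all-or-nothing).

    Returns the new catalog and the number of synonyms actually added
    (re-applying an already-applied log is idempotent and adds zero).
    Conflicting corrections for one surface — within the batch or against
    an existing local mapping to a different code — raise
    :class:`ConflictError` and nothing is applied.
    """
    fixes = [e for e in log.entries if not e.is_missing]
    by_surface: dict[str, CorrectionEntry] = {}
    conflicts = []
    for e in fixes:
        key = normalize_surface(e.surface)
        prior = by_surface.get(key)
        if prior is not None and prior.correct_code != e.correct_code:
            conflicts.append(f"{e.surface!r}: {prior.correct_code} vs {e.correct_code}")
        by_surface.setdefault(key, e)
        existing = catalog.lookup(e.surface)
        if existing is not None and existing.layer == "local" and existing.code != e.correct_code:
            conflicts.append(
                f"{e.surface!r}: log says {e.correct_code} but local layer maps to {existing.code}"
            )
    if conflicts:
        raise ConflictError(
            "conflicting corrections, nothing applied: " + "; ".join(sorted(set(conflicts)))
        )
    applied = 0
    for e in by_surface.values():
        before = catalog
        catalog = add_synonym(catalog, e.surface, e.correct_code, scope=e.scope)
        if catalog is not before:
            applied += 1
    return catalog, applied


# ---------------------------------------------------------------------------
# Missing-term export (submission file for the upstream ontology)


def export_missing_terms(log: CorrectionLog, path: str | Path) -> Path:
    path = Path(path)
    rows = sorted(
        (e.surface, e.proposed_label, e.reviewer, e.timestamp) for e in log.missing()
    )
    lines = [_MISSING_HEADER] + ["\t".join(r) for r in rows]
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    except OSError as exc:
        raise CatalogError(f"cannot write missing-term export to {path}: {exc}") from exc
    return path


def import_missing_terms(path: str | Path) -> list[CorrectionEntry]:
    """Re-read a missing-term export (round-trips with the exporter)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    entries = []
    for line in lines[1:]:
        surface, proposed, reviewer, timestamp = line.split("\t")
        entries.append(
            CorrectionEntry(surface, IGNORE_SENTINEL, MISSING, reviewer, proposed, timestamp)
        )
    return entries


# ---------------------------------------------------------------------------
# Log persistence (append-only JSONL)


def save_correction_log(log: CorrectionLog, path: str | Path) -> Path:
    path = Path(path)
    lines = [json.dumps({"source_tag": log.source_tag}, sort_keys=True)]
    lines += [json.dumps(vars(e), sort_keys=True) for e in log.entries]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_correction_log(path: str | Path) -> CorrectionLog:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return CorrectionLog()
    header = json.loads(lines[0])
    log = CorrectionLog(source_tag=header.get("source_tag", "training"))
    for line in lines[1:]:
        if line.strip():
            log.entries.append(CorrectionEntry(**json.loads(line)))
    return log
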