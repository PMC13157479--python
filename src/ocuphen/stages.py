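"""Pre-retrieval text stages: translation, segmentation, exclusion/negation.

A clinical letter arrives as free text in two fields — findings for the
anterior and posterior segments of the eye — in German or English.  Before
any finding can be linked to an ontology code it passes three stages:

1. **translate** — German text is rendered into English so that one
   (largely English) synonym catalog serves retrieval.
2. **segment** — each field is cut into discrete findings, one candidate
   phenotype per segment.
3. **classify** — segments describing normal findings or explicitly
   ruled-out (negated) pathologies are flagged so that only pathological
   segments reach the retrieval stage.

Each stage accepts a pluggable :class:`GenerationBackend` (an LLM wrapper
in production) plus a prompt template; without a backend, deterministic
rule-based fallbacks run instead: a phrase-lexicon substitution translator,
a punctuation/paren-aware splitter, and trigger-list negation/normal
classification scoped to the whole segment.  The fallbacks make the entire
pipeline reproducible byte-for-byte, which is what the test-bench and the
synthetic corpora exercise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Protocol, Sequence

__all__ = [
    "ClinicalRecord",
    "Segment",
    "GenerationBackend",
    "LexiconTranslationBackend",
    "StageError",
    "translate",
    "segment",
    "classify_segment",
    "pathological_segments",
    "load_lexicon_pairs",
    "load_phrase_list",
    "get_prompt",
    "default_translation_lexicon",
    "negation_triggers",
    "normal_markers",
]

log = logging.getLogger(__name__)

STATUSES = ("pathological", "normal", "negated")


class StageError(RuntimeError):
    """A stage failed for one record; the record is skipped, not the corpus."""

    def __init__(self, record_id: str, stage: str, message: str):
        super().__init__(f"record {record_id!r}, stage {stage}: {message}")
        self.record_id = record_id
        self.stage = stage


@dataclass(frozen=True)
class ClinicalRecord:
    """One letter: free-text anterior/posterior findings plus language tag."""

    record_id: str
    anterior_text: str = ""
    posterior_text: str = ""
    language: str = "de"

    def __post_init__(self) -> None:
        if self.language not in ("de", "en"):
            raise ValueError(f"record {self.record_id}: unsupported language {self.language!r}")


@dataclass(frozen=True)
class Segment:
    """One extracted finding with its position and (once classified) status."""

    record_id: str
    scope: str
    text: str
    ordinal: int
    status: str | None = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("empty segment text")
        if self.status is not None and self.status not in STATUSES:
            raise ValueError(f"unknown segment status {self.status!r}")


class GenerationBackend(Protocol):
    """Contract for a text-generation backend: deterministic for a fixed
    configuration, prompt template applied by the caller."""

    tag: str

    def generate(self, prompt: str, text: str) -> str: ...


# ---------------------------------------------------------------------------
# Packaged configuration (prompts and lexicons are data, not code)


def _data_text(relpath: str) -> str:
    return (resources.files("ocuphen") / "data" / relpath).read_text(encoding="utf-8")


def load_phrase_list(text: str) -> list[str]:
    """Parse a one-phrase-per-line lexicon; ``#`` starts a comment line."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def load_lexicon_pairs(text: str) -> dict[str, str]:
    """Parse a two-column TSV lexicon (source phrase → replacement)."""
    pairs: dict[str, str] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        src, _, dst = line.partition("\t")
        if src and dst:
            pairs[src] = dst
    return pairs


def get_prompt(stage: str) -> str:
    """Packaged prompt template for ``translate`` / ``segment`` / ``classify``.

    Templates are plain text with an ``{input}`` placeholder and are meant
    to be edited by domain experts; they are configuration, not code.
    """
    return _data_text(f"prompts/{stage}.txt")


def default_translation_lexicon() -> dict[str, str]:
    return load_lexicon_pairs(_data_text("lexicons/de_en.tsv"))


def negation_triggers() -> list[str]:
    return load_phrase_list(_data_text("lexicons/negation_triggers.txt"))


def normal_markers() -> list[str]:
    return load_phrase_list(_data_text("lexicons/normal_findings.txt"))


def _phrase_patterns(phrases: Sequence[str]) -> list[re.Pattern[str]]:
    # word-boundary match that also works for phrases with punctuation
    return [
        re.compile(r"(?<!\w)" + re.escape(p) + r"(?!\w)", re.IGNORECASE)
        for p in phrases
    ]


# ---------------------------------------------------------------------------
# Stage 1 — translation


class LexiconTranslationBackend:
    """Deterministic fallback translator: longest-match phrase substitution.

    Every lexicon phrase is replaced on word boundaries, longest phrase
    first; tokens absent from the lexicon pass through verbatim.  This is
    sufficient for catalog-derived German surface forms and negation
    particles; it makes no attempt at grammar.
    """

    tag = "lexicon-substitution"

    def __init__(self, lexicon: dict[str, str] | None = None):
        self.lexicon = dict(lexicon) if lexicon is not None else default_translation_lexicon()
        ordered = sorted(self.lexicon, key=len, reverse=True)
        self._patterns = [(re.compile(r"(?<!\w)" + re.escape(p) + r"(?!\w)", re.IGNORECASE), self.lexicon[p]) for p in ordered]

    def generate(self, prompt: str, text: str) -> str:  # prompt unused by rules
        out = text
        for pattern, replacement in self._patterns:
            out = pattern.sub(replacement, out)
        return out


def translate(
    record: ClinicalRecord,
    backend: GenerationBackend | None = None,
    prompt: str | None = None,
) -> ClinicalRecord:
    """Stage 1: return an English-language copy of ``record``.

    English records pass through unchanged (identity).  For German records
    both text fields are rewritten by the backend; the record id is
    preserved.  Backend exceptions surface as :class:`StageError` carrying
    the record id so callers can skip and continue.
    """
    if record.language == "en":
        return record
    if backend is None:
        backend = _default_translator()
    if prompt is None:
        prompt = get_prompt("translate")
    try:
        return replace(
            record,
            anterior_text=backend.generate(prompt, record.anterior_text),
            posterior_text=backend.generate(prompt, record.posterior_text),
            language="en",
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(record.record_id, "translate", str(exc)) from exc


_TRANSLATOR: LexiconTranslationBackend | None = None


def _default_translator() -> LexiconTranslationBackend:
    global _TRANSLATOR
    if _TRANSLATOR is None:
        _TRANSLATOR = LexiconTranslationBackend()
    return _TRANSLATOR


# ---------------------------------------------------------------------------
# Stage 2 — segmentation

_OPEN, _CLOSE = "([{", ")]}"


def _fallback_split(text: str) -> list[str]:
    """Split on sentence ends, semicolons, line breaks, and commas outside
    parentheses; trim whitespace; drop empty pieces."""
    parts: list[str] = []
    buf: list[str] = []
    depth = 0
    n = len(text)
    for i, ch in enumerate(text):
        if ch in _OPEN:
            depth += 1
        elif ch in _CLOSE:
            depth = max(0, depth - 1)
        if depth == 0 and (
            ch in ",;\n"
            or (ch == "." and (i + 1 == n or text[i + 1].isspace()))
        ):
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return [p.strip() for p in parts if p.strip()]


def segment(
    text: str,
    scope: str,
    record_id: str = "",
    backend: GenerationBackend | None = None,
    prompt: str | None = None,
) -> list[Segment]:
    """Stage 2: cut one free-text field into discrete finding segments.

    Order is preserved and no empty segments are emitted.  With a backend,
    the generated output is taken one segment per line and sanity-checked:
    if more than half of the input's alphanumeric characters vanish, a
    warning is logged (the segments are still returned).
    """
    if not text.strip():
        return []
    if backend is None:
        pieces = _fallback_split(text)
    else:
        if prompt is None:
            prompt = get_prompt("segment")
        try:
            raw = backend.generate(prompt, text)
        except Exception as exc:
            raise StageError(record_id, "segment", str(exc)) from exc
        pieces = [line.strip() for line in raw.splitlines() if line.strip()]
        kept = sum(c.isalnum() for c in "".join(pieces))
        total = sum(c.isalnum() for c in text)
        if total and kept < 0.5 * total:
            log.warning(
                "record %s (%s): backend segmentation kept %d/%d alphanumeric characters",
                record_id, scope, kept, total,
            )
    return [
        Segment(record_id=record_id, scope=scope, text=piece, ordinal=i)
        for i, piece in enumerate(pieces)
    ]


# ---------------------------------------------------------------------------
# Stage 3 — exclusion and negation


class _RuleClassifier:
    def __init__(self, triggers: Sequence[str], markers: Sequence[str]):
        self.negation = _phrase_patterns(triggers)
        self.normal = _phrase_patterns(markers)

    def classify(self, text: str) -> str:
        if any(p.search(text) for p in self.negation):
            return "negated"
        if any(p.search(text) for p in self.normal):
            return "normal"
        return "pathological"


_CLASSIFIER: _RuleClassifier | None = None


def _default_classifier() -> _RuleClassifier:
    global _CLASSIFIER
    if _CLASSIFIER is None:
        _CLASSIFIER = _RuleClassifier(negation_triggers(), normal_markers())
    return _CLASSIFIER


def classify_segment(
    seg: Segment,
    backend: GenerationBackend | None = None,
    prompt: str | None = None,
    *,
    triggers: Sequence[str] | None = None,
    markers: Sequence[str] | None = None,
) -> Segment:
    """Stage 3: assign ``pathological`` / ``normal`` / ``negated``.

    Fallback rules, in order: a negation trigger anywhere in the segment
    makes it ``negated`` (negation scope is the whole segment — segments
    are already atomic findings); else a normal-finding marker makes it
    ``normal``; else ``pathological``.  Trigger lists are packaged data and
    user-extensible via ``triggers``/``markers``.
    """
    if backend is None:
        if triggers is not None or markers is not None:
            clf = _RuleClassifier(
                triggers if triggers is not None else negation_triggers(),
                markers if markers is not None else normal_markers(),
            )
        else:
            clf = _default_classifier()
        status = clf.classify(seg.text)
    else:
        if prompt is None:
            prompt = get_prompt("classify")
        try:
            raw = backend.generate(prompt, seg.text)
        except Exception as exc:
            raise StageError(seg.record_id, "classify", str(exc)) from exc
        word = raw.strip().split()[0].lower().strip(".,:") if raw.strip() else ""
        if word not in STATUSES:
            raise StageError(seg.record_id, "classify", f"unparseable label {raw!r}")
        status = word
    return replace(seg, status=status)


# ---------------------------------------------------------------------------
# Composition


def pathological_segments(
    records: Iterable[ClinicalRecord],
    *,
    translation_backend: GenerationBackend | None = None,
    segmentation_backend: GenerationBackend | None = None,
    classification_backend: GenerationBackend | None = None,
    prompts: dict[str, str] | None = None,
    errors: list[StageError] | None = None,
) -> list[Segment]:
    """Run translate → segment → classify per record; keep pathological segments.

    Stage failures skip the affected record (collected into ``errors`` and
    logged) rather than aborting the corpus.
    """
    prompts = prompts or {}
    out: list[Segment] = []
    for record in records:
        try:
            if not (record.anterior_text.strip() or record.posterior_text.strip()):
                raise StageError(record.record_id, "input", "both text fields empty")
            english = translate(record, translation_backend, prompts.get("translate"))
            for scope, text in (
                ("anterior", english.anterior_text),
                ("posterior", english.posterior_text),
            ):
                for seg in segment(
                    text, scope, record.record_id, segmentation_backend, prompts.get("segment")
                ):
                    classified = classify_segment(
                        seg, classification_backend, prompts.get("classify")
                    )
                    if classified.status == "pathological":
                        out.append(classified)
        except StageError as exc:
            log.warning("skipping record: %s", exc)
            if errors is not None:
                errors.append(exc)
    return out
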