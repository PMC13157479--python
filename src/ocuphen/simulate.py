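"""Synthetic bilingual ophthalmology corpora with known ground truth.

The generator emulates the statistical shape of a real validation corpus:
each record draws k ~ Poisson(mean findings ≈ 2.5) pathological findings
whose surface forms come from the synonym catalog (with a configurable
probability, a German variant from the packaged lexicon is planted
instead), interleaved with normal and negated distractor phrases, split
across anterior- and posterior-segment free-text fields.  The truth for a
record is the set of HPO codes of its planted findings.

``synonym_miss_rate`` replaces a planted surface by an out-of-catalog
paraphrase while keeping its code in the truth set — the controlled
failure mode that the augmentation loop is designed to repair.

Everything is driven by one seed; identical configuration and seed yield a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .catalog import (
    SynonymCatalog,
    is_sentinel,
    load_local_catalog_text,
    merge,
    normalize_surface,
    HpoTerm,
)
from .stages import ClinicalRecord, default_translation_lexicon

__all__ = [
    "GeneratorConfig",
    "PlantedFinding",
    "SyntheticCorpus",
    "GeneratorError",
    "generate_corpus",
    "build_fixture_catalog",
    "fixture_catalog_path",
]


class GeneratorError(ValueError):
    pass


# Normal-finding distractors; each contains a normal marker so the
# exclusion stage removes it deterministically.
_NORMAL_EN = (
    "Cornea clear",
    "Lens unremarkable",
    "Fundus within normal limits",
    "Anterior chamber quiet",
    "Optic disc normal",
)
_NORMAL_DE = (
    "Hornhaut klar",
    "Linse unauffällig",
    "Fundus regelrecht",
    "Vorderkammer reizfrei",
)

#: English phrases in the translation lexicon that are particles, not findings.
_NON_FINDING_TARGETS = {"no", "not", "without", "ruled out", "no evidence of"}


@dataclass
class GeneratorConfig:
    """Study-shaped corpus parameters.

    ``mean_findings`` defaults to 2.5 pathological findings per record, the
    per-record average such validation corpora exhibit; distractor and
    language probabilities are per record-field / per finding.
    """

    n_records: int
    seed: int = 0
    mean_findings: float = 2.5
    p_negated: float = 0.2
    p_normal: float = 0.3
    p_german_surface: float = 0.5
    synonym_miss_rate: float = 0.0
    catalog: SynonymCatalog | None = None

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise GeneratorError("n_records must be positive")
        if self.mean_findings < 0:
            raise GeneratorError("mean_findings must be non-negative")
        for name in ("p_negated", "p_normal", "p_german_surface", "synonym_miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorError(f"{name} must be a probability, got {v}")


@dataclass(frozen=True)
class PlantedFinding:
    """Provenance of one planted pathological finding."""

    record_id: str
    scope: str
    code: str
    surface: str        # canonical catalog surface (English)
    text: str           # text as planted (German variant or paraphrase)
    german: bool
    missed: bool        # True when replaced by an out-of-catalog paraphrase


@dataclass
class SyntheticCorpus:
    records: list[ClinicalRecord]
    truth: dict[str, set[str]]
    findings: list[PlantedFinding]


def fixture_catalog_path(scope: str):
    """Filesystem path of the packaged site-catalog TSV for one eye segment."""
    if scope not in ("anterior", "posterior"):
        raise GeneratorError(f"no packaged catalog for scope {scope!r}")
    return resources.files("ocuphen") / "data" / "catalog" / f"{scope}.tsv"


def build_fixture_catalog() -> SynonymCatalog:
    """The packaged desk-scale catalog: both site-local eye-segment catalogs
    (ignore-sentinel rows included) merged over one standard-layer ontology
    term — retinal detachment (HP:0000541) with its German exact synonym."""
    standard = SynonymCatalog(
        [
            HpoTerm(
                "0000541",
                "Retinal detachment",
                ("Amotio retinae",),
                layer="standard",
                scope="both",
                provenance="ontology",
            )
        ]
    )
    local_terms = []
    for scope in ("anterior", "posterior"):
        text = fixture_catalog_path(scope).read_text(encoding="utf-8")
        local_terms.extend(load_local_catalog_text(text, scope=scope, provenance="fixture").terms)
    return merge(standard, SynonymCatalog(local_terms))


def _plantable(catalog: SynonymCatalog) -> dict[str, list[tuple[str, str]]]:
    """code → [(surface, scope)] for findings safe to plant verbatim.

    Sentinel rows are never planted (they carry no truth code) and surfaces
    containing segmentation delimiters are excluded, so a planted finding
    always survives the splitter as one segment.
    """
    pool: dict[str, list[tuple[str, str]]] = {}
    for e in catalog.entries():
        if is_sentinel(e.code):
            continue
        if any(ch in e.surface for ch in ",;\n"):
            continue
        pool.setdefault(e.code, []).append((e.surface, e.scope))
    return pool


def _german_variants() -> dict[str, str]:
    """normalized English surface → German variant, from the packaged lexicon."""
    variants: dict[str, str] = {}
    for german, english in default_translation_lexicon().items():
        if english.lower() in _NON_FINDING_TARGETS:
            continue
        variants.setdefault(normalize_surface(english), german)
    return variants


def _paraphrase(surface: str) -> str:
    # out-of-catalog rewording: exact-tier lookup must fail on it
    return f"evidence of {surface.lower()} noted"


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate records plus ground truth under ``config`` (deterministic)."""
    catalog = config.catalog if config.catalog is not None else build_fixture_catalog()
    pool = _plantable(catalog)
    if not pool:
        raise GeneratorError("catalog has no plantable (non-sentinel) entries")
    scopes_present = {s for variants in pool.values() for _, s in variants}
    if not {"anterior", "both"} & scopes_present or not {"posterior", "both"} & scopes_present:
        raise GeneratorError("catalog must cover both anterior and posterior scopes")
    codes = sorted(pool)
    german = _german_variants()
    rng = np.random.default_rng(config.seed)

    records: list[ClinicalRecord] = []
    truth: dict[str, set[str]] = {}
    findings: list[PlantedFinding] = []

    for i in range(config.n_records):
        rid = f"rec-{i:05d}"
        k = int(rng.poisson(config.mean_findings))
        k = min(k, len(codes))
        chosen = rng.choice(len(codes), size=k, replace=False) if k else []
        fields: dict[str, list[str]] = {"anterior": [], "posterior": []}
        any_german = False
        planted: list[PlantedFinding] = []
        for ci in chosen:
            code = codes[int(ci)]
            variants = pool[code]
            surface, scope = variants[int(rng.integers(len(variants)))]
            if scope == "both":
                scope = "anterior" if rng.random() < 0.5 else "posterior"
            missed = rng.random() < config.synonym_miss_rate
            use_german = False
            if missed:
                text = _paraphrase(surface)
            else:
                variant = german.get(normalize_surface(surface))
                use_german = variant is not None and rng.random() < config.p_german_surface
                text = variant if use_german else surface
            any_german = any_german or use_german
            fields[scope].append(text)
            planted.append(PlantedFinding(rid, scope, code, surface, text, use_german, missed))

        for scope in ("anterior", "posterior"):
            if rng.random() < config.p_normal:
                if rng.random() < config.p_german_surface:
                    fields[scope].append(_NORMAL_DE[int(rng.integers(len(_NORMAL_DE)))])
                    any_german = True
                else:
                    fields[scope].append(_NORMAL_EN[int(rng.integers(len(_NORMAL_EN)))])
            if rng.random() < config.p_negated:
                distractor_code = codes[int(rng.integers(len(codes)))]
                surface, _ = pool[distractor_code][0]
                if rng.random() < config.p_german_surface:
                    fields[scope].append(f"kein {surface}")
                    any_german = True
                else:
                    fields[scope].append(f"no {surface}")

        if not fields["anterior"] and not fields["posterior"]:
            fields["anterior"].append(_NORMAL_EN[int(rng.integers(len(_NORMAL_EN)))])
        for scope in ("anterior", "posterior"):
            order = rng.permutation(len(fields[scope]))
            fields[scope] = [fields[scope][int(j)] for j in order]

        records.append(
            ClinicalRecord(
                record_id=rid,
                anterior_text="; ".join(fields["anterior"]),
                posterior_text="; ".join(fields["posterior"]),
                language="de" if any_german else "en",
            )
        )
        truth[rid] = {p.code for p in planted}
        findings.extend(planted)

    return SyntheticCorpus(records=records, truth=truth, findings=findings)
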