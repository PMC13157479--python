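"""Layered HPO synonym catalogs.

The Human Phenotype Ontology (HPO) assigns each phenotypic abnormality a
CURIE of the form ``HP:NNNNNNN``.  Clinical sites extend the ontology's own
labels and exact synonyms (the *standard* layer) with a curated *local*
layer of dialect surface forms — e.g. a German clinic mapping
``Amotio retinae`` onto the retinal-detachment concept — grown through an
expert-in-the-loop error-correction workflow.  This module holds the data
model for that layered mapping:

* :func:`canonicalize_code` — numeric HPO identifiers, zero-padded to seven
  digits, plus the ignore sentinel ``"0"`` marking surface forms whose
  segments should never produce an annotation.
* :class:`HpoTerm` — one concept (or one local surface entry) with its
  label, exact synonyms, layer, eye-segment scope and provenance.
* :class:`SynonymCatalog` — a collection of terms with a derived
  surface-form index; local entries take precedence over standard ones,
  and two local entries claiming the same surface with different codes are
  a hard error.

Loaders cover OBO 1.2 (via :mod:`obonet`), the HPO JSON graph dialect, and
the site-local two-column ``code<TAB>surface`` format; :func:`export_catalog`
writes a stable, diffable five-column TSV that round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "IGNORE_SENTINEL",
    "CatalogError",
    "CodeError",
    "ConflictError",
    "CatalogParseError",
    "HpoTerm",
    "SynonymCatalog",
    "CatalogEntry",
    "normalize_surface",
    "canonicalize_code",
    "to_curie",
    "is_sentinel",
    "load_hpo_subset",
    "load_local_catalog",
    "merge",
    "add_synonym",
    "export_catalog",
    "export_catalog_text",
    "catalog_checksum",
]

#: Catalog code marking a surface form whose segment is deliberately ignored.
IGNORE_SENTINEL = "0"

LAYERS = ("standard", "local")
SCOPES = ("anterior", "posterior", "both")
PROVENANCES = ("ontology", "local-augmentation", "fixture")

EXPORT_HEADER = "hpo_id\tsurface\tscope\tlayer\tprovenance"


class CatalogError(ValueError):
    """Base class for catalog construction and parsing errors."""


class CodeError(CatalogError):
    """Raised for identifiers that are neither digits nor the sentinel."""


class ConflictError(CatalogError):
    """Raised when one surface form would map to two different codes."""


class CatalogParseError(CatalogError):
    """Raised for malformed ontology or catalog files."""


_WS_RE = re.compile(r"\s+")
_TERMINAL_PUNCT = ".,;:!?"


def normalize_surface(text: str) -> str:
    """Normalize a surface form for exact-tier lookup.

    Unicode NFC, lowercase, trimmed, internal whitespace collapsed to single
    spaces, terminal punctuation stripped.  Idempotent.
    """
    s = unicodedata.normalize("NFC", text)
    s = _WS_RE.sub(" ", s.strip()).lower()
    s = s.rstrip(_TERMINAL_PUNCT).rstrip()
    return s


def canonicalize_code(value: str | int) -> str:
    """Canonicalize an HPO identifier to 7-digit zero-padded form.

    Accepts any all-digit string (site catalogs print codes unpadded, e.g.
    ``541`` or ``11457``), an ``HP:``-prefixed CURIE, or an integer.  The
    ignore sentinel ``"0"`` is preserved verbatim.  Idempotent.
    """
    s = str(value).strip()
    if s.upper().startswith("HP:"):
        s = s[3:].strip()
    if s == IGNORE_SENTINEL:
        return IGNORE_SENTINEL
    if not s.isdigit():
        raise CodeError(f"not a numeric HPO code or sentinel: {value!r}")
    if len(s) > 7:
        raise CodeError(f"HPO code wider than 7 digits: {value!r}")
    padded = s.zfill(7)
    if padded == "0000000":
        raise CodeError(f"all-zero code is reserved; use the sentinel {IGNORE_SENTINEL!r}")
    return padded


def is_sentinel(code: str) -> bool:
    return code == IGNORE_SENTINEL


def to_curie(code: str) -> str:
    """Display form ``HP:NNNNNNN``; the sentinel has no CURIE."""
    code = canonicalize_code(code)
    if is_sentinel(code):
        raise CodeError("the ignore sentinel has no CURIE form")
    return f"HP:{code}"


@dataclass(frozen=True)
class HpoTerm:
    """One catalog concept: a code with a primary label and exact synonyms.

    ``layer`` distinguishes ontology-derived entries (``standard``) from
    site-curated ones (``local``); ``scope`` restricts a local entry to the
    anterior or posterior eye segment.  Standard-layer terms can never carry
    the ignore sentinel.
    """

    code: str
    primary_label: str
    synonyms: tuple[str, ...] = ()
    layer: str = "standard"
    scope: str = "both"
    provenance: str = "ontology"

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", canonicalize_code(self.code))
        if not self.primary_label or not normalize_surface(self.primary_label):
            raise CatalogError(f"term {self.code}: empty primary label")
        if self.layer not in LAYERS:
            raise CatalogError(f"term {self.code}: unknown layer {self.layer!r}")
        if self.scope not in SCOPES:
            raise CatalogError(f"term {self.code}: unknown scope {self.scope!r}")
        if self.provenance not in PROVENANCES:
            raise CatalogError(f"term {self.code}: unknown provenance {self.provenance!r}")
        if self.layer == "standard" and is_sentinel(self.code):
            raise CatalogError("standard-layer terms may not carry the ignore sentinel")
        # drop synonyms that duplicate each other or the label after normalization
        seen = {normalize_surface(self.primary_label)}
        deduped = []
        for syn in self.synonyms:
            key = normalize_surface(syn)
            if not key:
                raise CatalogError(f"term {self.code}: empty synonym")
            if key not in seen:
                seen.add(key)
                deduped.append(syn)
        object.__setattr__(self, "synonyms", tuple(deduped))

    def surfaces(self) -> tuple[str, ...]:
        return (self.primary_label, *self.synonyms)


class CatalogEntry(NamedTuple):
    """One (surface form → code) row, the unit of the exported TSV."""

    code: str
    surface: str
    scope: str
    layer: str
    provenance: str


@dataclass(frozen=True)
class _IndexEntry:
    code: str
    surface: str
    layer: str
    scope: str
    provenance: str


class SynonymCatalog:
    """Terms plus a derived normalized-surface → code index.

    The index is rebuilt from the terms at construction, so it always
    round-trips; a local entry shadows a standard entry for the same
    surface, while two local entries with different codes for one surface
    raise :class:`ConflictError` (the augmentation loop assumes exactly one
    reviewed code per surface).
    """

    def __init__(self, terms: Iterable[HpoTerm] = ()):
        self.terms: tuple[HpoTerm, ...] = tuple(terms)
        self.surface_index: dict[str, _IndexEntry] = self._build_index(self.terms)

    @staticmethod
    def _build_index(terms: Sequence[HpoTerm]) -> dict[str, _IndexEntry]:
        index: dict[str, _IndexEntry] = {}
        for layer in LAYERS:  # standard first so local may shadow it
            for term in terms:
                if term.layer != layer:
                    continue
                for surface in term.surfaces():
                    key = normalize_surface(surface)
                    entry = _IndexEntry(term.code, surface, term.layer, term.scope, term.provenance)
                    prior = index.get(key)
                    if prior is None:
                        index[key] = entry
                        continue
                    if prior.code == entry.code:
                        continue  # same mapping from another row; keep first
                    if prior.layer == "standard" and entry.layer == "local":
                        index[key] = entry  # local precedence
                    elif prior.layer == entry.layer == "local":
                        raise ConflictError(
                            f"surface {surface!r} maps to both {prior.code} and {entry.code} "
                            "in the local layer"
                        )
                    # else: entry is standard under an existing local/standard
                    # mapping with a different code; a standard-vs-standard
                    # clash is also a load error per the one-code-per-surface rule
                    elif prior.layer == entry.layer == "standard":
                        raise ConflictError(
                            f"surface {surface!r} maps to both {prior.code} and {entry.code} "
                            "in the standard layer"
                        )
        return index

    # -- queries ---------------------------------------------------------

    def lookup(self, surface: str) -> _IndexEntry | None:
        """Exact-tier resolution of a (raw or normalized) surface form."""
        return self.surface_index.get(normalize_surface(surface))

    def __len__(self) -> int:
        return len(self.terms)

    def __bool__(self) -> bool:
        return bool(self.terms)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(t.code for t in self.terms)

    def entries(self) -> list[CatalogEntry]:
        """All (code, surface) rows, stable-sorted and deduplicated."""
        rows = {
            CatalogEntry(t.code, s, t.scope, t.layer, t.provenance)
            for t in self.terms
            for s in t.surfaces()
        }
        return sorted(rows)

    def local_synonym_count(self) -> int:
        return sum(len(t.surfaces()) for t in self.terms if t.layer == "local")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SynonymCatalog):
            return NotImplemented
        return self.entries() == other.entries()

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SynonymCatalog({len(self.terms)} terms, {len(self.surface_index)} surfaces)"


# ---------------------------------------------------------------------------
# Loaders


_OBO_SYNONYM_RE = re.compile(r'^"(?P<text>.*)"\s*(?P<scope>[A-Z_]*)')


def _load_obo(path: Path) -> list[HpoTerm]:
    import obonet

    text = path.read_text(encoding="utf-8")
    ids = re.findall(r"(?m)^id:\s*(\S+)", text)
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CatalogParseError(f"{path}: duplicate concept id(s): {sorted(dupes)}")
    try:
        graph = obonet.read_obo(path.as_posix())
    except Exception as exc:  # malformed stanza, bad header, ...
        raise CatalogParseError(f"{path}: not parseable as OBO: {exc}") from exc
    terms = []
    for node_id, data in graph.nodes(data=True):
        if not str(node_id).upper().startswith("HP:"):
            continue
        label = data.get("name")
        if not label:
            continue  # obsolete/unnamed stubs carry no usable surface
        synonyms = []
        for raw in data.get("synonym", []):
            m = _OBO_SYNONYM_RE.match(raw)
            if m and m.group("scope") in ("EXACT", ""):
                synonyms.append(m.group("text"))
        terms.append(HpoTerm(node_id, label, tuple(synonyms), layer="standard", scope="both"))
    return terms


def _load_hpo_json(path: Path) -> list[HpoTerm]:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
        graphs = doc["graphs"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise CatalogParseError(f"{path}: not an HPO JSON graph document: {exc}") from exc
    terms = []
    seen: set[str] = set()
    for graph in graphs:
        for node in graph.get("nodes", []):
            node_id = str(node.get("id", ""))
            frag = node_id.rsplit("/", 1)[-1]
            if not frag.startswith("HP_"):
                continue
            meta = node.get("meta") or {}
            if meta.get("deprecated"):
                continue
            label = node.get("lbl")
            if not label:
                continue
            code = canonicalize_code(frag[3:])
            if code in seen:
                raise CatalogParseError(f"{path}: duplicate concept id HP:{code}")
            seen.add(code)
            synonyms = tuple(
                s["val"]
                for s in meta.get("synonyms", [])
                if s.get("pred") in (None, "hasExactSynonym") and s.get("val")
            )
            terms.append(HpoTerm(code, label, synonyms, layer="standard", scope="both"))
    return terms


def load_hpo_subset(path: str | Path) -> SynonymCatalog:
    """Load the standard layer from an OBO 1.2 or HPO JSON-dialect file.

    One :class:`HpoTerm` per ontology concept, with its primary label and
    exact synonyms; ``layer="standard"``, ``scope="both"``.
    """
    path = Path(path)
    head = path.read_text(encoding="utf-8", errors="replace").lstrip()[:1]
    if path.suffix.lower() == ".json" or head == "{":
        terms = _load_hpo_json(path)
    else:
        terms = _load_obo(path)
    return SynonymCatalog(terms)


def _parse_local_rows(
    lines: Iterable[str], scope: str | None, provenance: str, origin: str
) -> list[HpoTerm]:
    terms = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if lineno == 1 and line.startswith("hpo_id\t"):
            continue  # exported five-column header
        fields = line.split("\t")
        if len(fields) == 5:
            code_s, surface, row_scope, row_layer, row_prov = fields
        elif len(fields) == 2:
            code_s, surface = fields
            if scope is None:
                raise CatalogParseError(
                    f"{origin}:{lineno}: two-column row but no scope given to the loader"
                )
            row_scope, row_layer, row_prov = scope, "local", provenance
        else:
            raise CatalogParseError(
                f"{origin}:{lineno}: expected 2 or 5 tab-separated fields, got {len(fields)}"
            )
        if not surface.strip():
            raise CatalogParseError(f"{origin}:{lineno}: empty surface form")
        try:
            code = canonicalize_code(code_s)
        except CodeError as exc:
            raise CatalogParseError(f"{origin}:{lineno}: {exc}") from exc
        try:
            terms.append(
                HpoTerm(code, surface, (), layer=row_layer, scope=row_scope, provenance=row_prov)
            )
        except CatalogError as exc:
            raise CatalogParseError(f"{origin}:{lineno}: {exc}") from exc
    return terms


def load_local_catalog(
    path: str | Path,
    scope: str | None = None,
    provenance: str = "fixture",
) -> SynonymCatalog:
    """Load a site-local synonym catalog from TSV.

    Two formats are accepted: the raw two-column ``code<TAB>surface`` site
    format (``scope`` must then be ``anterior`` or ``posterior``; codes may
    be unpadded digits or the ignore sentinel), and the five-column format
    written by :func:`export_catalog`, which carries its own scope, layer
    and provenance per row and round-trips exactly.
    """
    path = Path(path)
    if scope is not None and scope not in ("anterior", "posterior"):
        raise CatalogError(f"local catalog scope must be anterior or posterior, got {scope!r}")
    lines = path.read_text(encoding="utf-8").splitlines()
    terms = _parse_local_rows(lines, scope, provenance, origin=str(path))
    return SynonymCatalog(terms)


def load_local_catalog_text(
    text: str, scope: str | None = None, provenance: str = "fixture", origin: str = "<text>"
) -> SynonymCatalog:
    """As :func:`load_local_catalog`, from an in-memory string."""
    return SynonymCatalog(_parse_local_rows(text.splitlines(), scope, provenance, origin))


# ---------------------------------------------------------------------------
# Combination and augmentation


def merge(base: SynonymCatalog, local: SynonymCatalog) -> SynonymCatalog:
    """Overlay ``local`` on ``base``; local entries win surface collisions.

    Raises :class:`ConflictError` if two local entries claim one surface
    with different codes.
    """
    return SynonymCatalog(base.terms + local.terms)


def add_synonym(
    catalog: SynonymCatalog, surface: str, code: str, scope: str = "both"
) -> SynonymCatalog:
    """Return a catalog where ``surface`` resolves exactly to ``code``.

    This is the unit step of the error-correction loop: a misretrieved
    surface form is attached to its reviewed code as a local-layer synonym
    (provenance ``local-augmentation``).  Adding an already-present
    (surface, code) pair is a no-op; a surface already locally mapped to a
    *different* code raises :class:`ConflictError` — the caller must retract
    the earlier mapping first.
    """
    if not normalize_surface(surface):
        raise CatalogError("cannot add an empty surface form")
    code = canonicalize_code(code)
    prior = catalog.lookup(surface)
    if prior is not None:
        if prior.code == code:
            return catalog  # idempotent
        if prior.layer == "local":
            raise ConflictError(
                f"surface {surface!r} already maps to {prior.code} in the local layer; "
                f"retract it before remapping to {code}"
            )
    term = HpoTerm(
        code, surface, (), layer="local", scope=scope, provenance="local-augmentation"
    )
    return SynonymCatalog(catalog.terms + (term,))


# ---------------------------------------------------------------------------
# Export


def export_catalog_text(catalog: SynonymCatalog) -> str:
    """Render the canonical five-column TSV (UTF-8 text, LF, stable sort)."""
    lines = [EXPORT_HEADER]
    for e in catalog.entries():
        lines.append(f"{e.code}\t{e.surface}\t{e.scope}\t{e.layer}\t{e.provenance}")
    return "\n".join(lines) + "\n"


def export_catalog(catalog: SynonymCatalog, path: str | Path) -> Path:
    """Write the catalog TSV to ``path`` and return the path."""
    path = Path(path)
    try:
        path.write_text(export_catalog_text(catalog), encoding="utf-8", newline="\n")
    except OSError as exc:
        raise CatalogError(f"cannot write catalog to {path}: {exc}") from exc
    return path


def catalog_checksum(catalog: SynonymCatalog) -> str:
    """SHA-256 of the canonical TSV rendering; identifies catalog content."""
    return hashlib.sha256(export_catalog_text(catalog).encode("utf-8")).hexdigest()
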