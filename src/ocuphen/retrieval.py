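"""Dense retrieval: map each pathological finding to exactly one HPO code.

Every surface form of the merged catalog (standard labels and exact
synonyms, local dialect entries, ignore-sentinel rows) is embedded once
into a fixed-dimension vector space.  A query segment is resolved in two
tiers:

* **exact** — if the normalized segment text equals a catalog surface, that
  surface's code is returned with similarity 1.0.  This makes the
  augmentation loop's guarantee deterministic: once a surface has been
  attached to its reviewed code, retrieval of that surface can never drift.
* **embedding** — otherwise the single nearest neighbour (K=1) by cosine
  similarity over *all* index entries wins.  There is no abstention
  threshold by default: every pathological segment is assigned its closest
  catalog entry.  The similarity is recorded so callers may post-filter
  (``min_similarity``).

Cosine ties are broken in favour of the local layer (the curated site
authority), then the lexicographically smallest code.  A winning
ignore-sentinel entry yields no annotation.

The default :class:`HashingNgramEmbedder` is a deterministic signed
character-n-gram hashing embedder; any model exposing the
:class:`EmbeddingBackend` contract (e.g. a sentence-transformer wrapper)
can be swapped in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np

from .catalog import (
    SynonymCatalog,
    canonicalize_code,
    catalog_checksum,
    export_catalog,
    is_sentinel,
    load_local_catalog,
    normalize_surface,
    to_curie,
)
from .stages import ClinicalRecord, GenerationBackend, Segment, StageError, pathological_segments

__all__ = [
    "EmbeddingBackend",
    "HashingNgramEmbedder",
    "EmbeddingIndex",
    "Annotation",
    "RetrievalError",
    "build_index",
    "map_segment",
    "annotate_record",
    "annotate_corpus",
    "save_index",
    "load_index",
]


class RetrievalError(RuntimeError):
    pass


class EmbeddingBackend(Protocol):
    """Text → fixed-length vector, deterministic for a fixed configuration.

    ``instruction`` mirrors instruction-tuned embedders; the default is the
    empty string and the fallback backend ignores it.
    """

    tag: str
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingNgramEmbedder:
    """Deterministic signed character-n-gram hashing embedder.

    Character n-grams of the normalized, space-padded text are hashed
    (BLAKE2b, fixed seed) into ``dim`` buckets with a sign bit, counted,
    and L2-normalized.  Lexically similar strings therefore land close in
    cosine space; identical strings map to identical vectors; there is no
    model download and no nondeterminism.
    """

    def __init__(self, dim: int = 256, ngram: int = 3, seed: int = 17, instruction: str = ""):
        if dim <= 0 or ngram <= 0:
            raise ValueError("dim and ngram must be positive")
        self.dim = int(dim)
        self.ngram = int(ngram)
        self.seed = int(seed)
        self.instruction = instruction
        self.tag = f"hash-ngram/dim={self.dim},n={self.ngram},seed={self.seed}"

    def _buckets(self, text: str) -> Iterable[tuple[int, float]]:
        padded = f" {normalize_surface(self.instruction + ' ' + text if self.instruction else text)} "
        n = self.ngram
        for i in range(max(len(padded) - n + 1, 0)):
            gram = padded[i : i + n]
            h = int.from_bytes(
                hashlib.blake2b(f"{self.seed}|{gram}".encode("utf-8"), digest_size=8).digest(),
                "big",
            )
            yield h % self.dim, 1.0 if (h >> 32) & 1 else -1.0

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        for idx, sign in self._buckets(text):
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec

    def config(self) -> dict:
        return {"dim": self.dim, "ngram": self.ngram, "seed": self.seed,
                "instruction": self.instruction}


@dataclass(frozen=True)
class Annotation:
    """One segment → HPO assignment; never carries the ignore sentinel."""

    record_id: str
    scope: str
    text: str
    code: str
    similarity: float
    tier: str
    matched_surface: str

    def __post_init__(self) -> None:
        if is_sentinel(self.code):
            raise RetrievalError("annotations may not carry the ignore sentinel")
        if self.tier not in ("exact", "embedding"):
            raise RetrievalError(f"unknown tier {self.tier!r}")
        if not -1.0 - 1e-9 <= self.similarity <= 1.0 + 1e-9:
            raise RetrievalError(f"similarity out of range: {self.similarity}")

    @property
    def curie(self) -> str:
        return to_curie(self.code)


@dataclass
class EmbeddingIndex:
    """Ordered catalog surfaces with their vectors (rows L2-normalized)."""

    surfaces: list[str]
    codes: list[str]
    layers: list[str]
    matrix: np.ndarray
    backend: EmbeddingBackend
    catalog_checksum: str

    def __len__(self) -> int:
        return len(self.surfaces)


def build_index(catalog: SynonymCatalog, backend: EmbeddingBackend) -> EmbeddingIndex:
    """Embed every catalog surface form once, in the catalog's stable order."""
    if not catalog:
        raise RetrievalError("cannot build an index over an empty catalog")
    entries = catalog.entries()
    surfaces, codes, layers, rows = [], [], [], []
    for e in entries:
        vec = np.asarray(backend.embed(e.surface), dtype=np.float64)
        if vec.ndim != 1 or vec.size == 0:
            raise RetrievalError(f"backend returned a zero-length vector for surface {e.surface!r}")
        if vec.size != backend.dim:
            raise RetrievalError(
                f"backend dimension mismatch for surface {e.surface!r}: "
                f"{vec.size} != {backend.dim}"
            )
        norm = np.linalg.norm(vec)
        rows.append(vec / norm if norm > 0 else vec)
        surfaces.append(e.surface)
        codes.append(e.code)
        layers.append(e.layer)
    return EmbeddingIndex(
        surfaces=surfaces,
        codes=codes,
        layers=layers,
        matrix=np.vstack(rows),
        backend=backend,
        catalog_checksum=catalog_checksum(catalog),
    )


def _tie_break_key(index: EmbeddingIndex, i: int) -> tuple[int, str]:
    return (0 if index.layers[i] == "local" else 1, index.codes[i])


def map_segment(
    seg: Segment | str,
    index: EmbeddingIndex,
    catalog: SynonymCatalog,
    *,
    exact_only: bool = False,
    min_similarity: float | None = None,
) -> Annotation | None:
    """Resolve one pathological segment to at most one HPO code.

    Returns ``None`` for an ignore verdict (the winning entry carries the
    sentinel), for a similarity below ``min_similarity``, or — under
    ``exact_only`` — when no exact-tier surface matches.
    """
    if len(index) == 0:
        raise RetrievalError("empty index")
    if isinstance(seg, Segment):
        record_id, scope, text = seg.record_id, seg.scope, seg.text
    else:
        record_id, scope, text = "", "both", seg

    hit = catalog.lookup(text)
    if hit is not None:
        if is_sentinel(hit.code):
            return None
        return Annotation(record_id, scope, text, hit.code, 1.0, "exact", hit.surface)
    if exact_only:
        return None

    query = np.asarray(index.backend.embed(text), dtype=np.float64)
    norm = np.linalg.norm(query)
    if norm > 0:
        query = query / norm
    sims = index.matrix @ query
    best = float(sims.max())
    tied = np.flatnonzero(sims == sims.max())
    winner = min(tied, key=lambda i: _tie_break_key(index, i))
    if min_similarity is not None and best < min_similarity:
        return None
    if is_sentinel(index.codes[winner]):
        return None
    return Annotation(
        record_id, scope, text, index.codes[winner], best, "embedding", index.surfaces[winner]
    )


def annotate_record(
    record: ClinicalRecord,
    catalog: SynonymCatalog,
    index: EmbeddingIndex,
    *,
    exact_only: bool = False,
    min_similarity: float | None = None,
    translation_backend: GenerationBackend | None = None,
    segmentation_backend: GenerationBackend | None = None,
    classification_backend: GenerationBackend | None = None,
    errors: list[StageError] | None = None,
) -> tuple[set[str], list[Annotation]]:
    """Full pipeline for one record.

    Returns the record-level prediction — the *set* of distinct codes
    (duplicate segment hits collapse, matching the set semantics of the
    evaluation metrics) — together with the per-segment annotation detail.
    """
    segments = pathological_segments(
        [record],
        translation_backend=translation_backend,
        segmentation_backend=segmentation_backend,
        classification_backend=classification_backend,
        errors=errors,
    )
    annotations = []
    for seg in segments:
        ann = map_segment(
            seg, index, catalog, exact_only=exact_only, min_similarity=min_similarity
        )
        if ann is not None:
            annotations.append(ann)
    return {a.code for a in annotations}, annotations


def annotate_corpus(
    records: Iterable[ClinicalRecord],
    catalog: SynonymCatalog,
    index: EmbeddingIndex,
    **kwargs,
) -> tuple[dict[str, set[str]], list[Annotation]]:
    """Annotate many records; returns ({record_id: code set}, all annotations)."""
    predictions: dict[str, set[str]] = {}
    details: list[Annotation] = []
    for record in records:
        codes, annotations = annotate_record(record, catalog, index, **kwargs)
        predictions[record.record_id] = codes
        details.extend(annotations)
    return predictions, details


# ---------------------------------------------------------------------------
# Persistence: entries TSV + binary vector matrix + JSON sidecar


def save_index(index: EmbeddingIndex, catalog: SynonymCatalog, dirpath: str | Path) -> Path:
    """Persist an index as a self-contained directory.

    ``entries.tsv`` (surface/code/layer), ``vectors.npy``, ``catalog.tsv``
    (the full catalog, so annotation needs only this directory) and
    ``meta.json`` with the backend configuration and a catalog checksum.
    """
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    lines = ["surface\tcode\tlayer"]
    lines += [f"{s}\t{c}\t{l}" for s, c, l in zip(index.surfaces, index.codes, index.layers)]
    (dirpath / "entries.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    np.save(dirpath / "vectors.npy", index.matrix)
    export_catalog(catalog, dirpath / "catalog.tsv")
    backend = index.backend
    meta = {
        "backend_tag": backend.tag,
        "dim": backend.dim,
        "catalog_checksum": index.catalog_checksum,
    }
    if isinstance(backend, HashingNgramEmbedder):
        meta["backend_config"] = backend.config()
    (dirpath / "meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return dirpath


def load_index(dirpath: str | Path) -> tuple[EmbeddingIndex, SynonymCatalog]:
    """Load a persisted index directory; verifies the catalog checksum."""
    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "meta.json").read_text(encoding="utf-8"))
    if "backend_config" not in meta:
        raise RetrievalError(
            f"index at {dirpath} was built with backend {meta.get('backend_tag')!r}, "
            "which cannot be reinstantiated from the sidecar"
        )
    backend = HashingNgramEmbedder(**meta["backend_config"])
    catalog = load_local_catalog(dirpath / "catalog.tsv")
    if catalog_checksum(catalog) != meta["catalog_checksum"]:
        raise RetrievalError(f"index at {dirpath}: catalog checksum mismatch")
    surfaces, codes, layers = [], [], []
    entry_lines = (dirpath / "entries.tsv").read_text(encoding="utf-8").splitlines()[1:]
    for line in entry_lines:
        s, c, l = line.split("\t")
        surfaces.append(s)
        codes.append(canonicalize_code(c))
        layers.append(l)
    matrix = np.load(dirpath / "vectors.npy")
    index = EmbeddingIndex(surfaces, codes, layers, matrix, backend, meta["catalog_checksum"])
    if matrix.shape != (len(surfaces), backend.dim):
        raise RetrievalError(f"index at {dirpath}: vector matrix shape mismatch")
    return index, catalog
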