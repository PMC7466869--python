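"""Token-aligned layered document representation.

A document is a base sequence of tokens plus any number of named *artifact
layers* (tags, concepts, lemmas, ...) and *relation layers* (edges between
two token spans).  Every annotation is aligned to the base layer by a span:
a 0-based start token index and a length in tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List

#: Reserved name of the base token layer.
TEXT_LAYER = "text"


class UnknownLayerError(KeyError):
    """Raised when a layer name is not present in a document or index."""


@dataclass(frozen=True, order=True)
class Span:
    """Half-open token range ``[start, start + length)`` on the base layer."""

    start: int
    length: int

    @property
    def end(self) -> int:
        """Exclusive end index (``start + length``)."""
        return self.start + self.length

    def overlaps(self, other: "Span") -> bool:
        """True iff the two token ranges intersect."""
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Artifact:
    """One item of an artifact layer: an opaque value anchored to a span."""

    value: str
    span: Span


@dataclass(frozen=True)
class RelationArtifact:
    """A labeled edge between two spans (e.g. a dependency-parse arc).

    Only the two spans are stored, never references to artifacts in other
    layers; the base position of a relation is its target span.
    """

    value: str
    source: Span
    target: Span

    @property
    def base(self) -> Span:
        return self.target


@dataclass
class LayeredDocument:
    """Base tokens plus aligned artifact layers and relation layers."""

    doc_id: str
    tokens: List[str]
    layers: Dict[str, List[Artifact]] = field(default_factory=dict)
    relation_layers: Dict[str, List[RelationArtifact]] = field(default_factory=dict)

    def layer_names(self) -> List[str]:
        return [TEXT_LAYER] + sorted(self.layers) + sorted(self.relation_layers)


def text_artifacts(doc: LayeredDocument) -> Iterator[Artifact]:
    """View of the base layer as unit-length artifacts."""
    for i, tok in enumerate(doc.tokens):
        yield Artifact(tok, Span(i, 1))


def _check_span(span: Span, n_tokens: int, where: str, out: List[str]) -> None:
    if span.start < 0:
        out.append(f"{where}: span start {span.start} < 0")
    if span.length < 1:
        out.append(f"{where}: span length {span.length} < 1")
    if span.start + span.length > n_tokens:
        out.append(
            f"{where}: span end {span.start + span.length} > token count {n_tokens}"
        )


def validate_document(doc: LayeredDocument) -> List[str]:
    """Check every integrity rule; return a description per violation.

    Validation reports rather than raises: an empty list means the document
    is valid.  Each message names the layer, item index, and broken rule.
    """
    violations: List[str] = []
    n = len(doc.tokens)

    if TEXT_LAYER in doc.layers or TEXT_LAYER in doc.relation_layers:
        violations.append(f"layer name {TEXT_LAYER!r} is reserved for the base layer")
    shared = set(doc.layers) & set(doc.relation_layers)
    for name in sorted(shared):
        violations.append(
            f"layer {name!r}: name used for both an artifact and a relation layer"
        )

    for name, artifacts in doc.layers.items():
        prev_key = None
        for i, art in enumerate(artifacts):
            where = f"layer {name!r} artifact {i}"
            if not art.value:
                violations.append(f"{where}: empty value")
            _check_span(art.span, n, where, violations)
            key = (art.span.start, art.span.length)
            if prev_key is not None and key < prev_key:
                violations.append(f"{where}: not sorted by (start, length)")
            prev_key = key

    for name, relations in doc.relation_layers.items():
        for i, rel in enumerate(relations):
            where = f"relation layer {name!r} relation {i}"
            if not rel.value:
                violations.append(f"{where}: empty label")
            _check_span(rel.source, n, where + " source", violations)
            _check_span(rel.target, n, where + " target", violations)

    return violations


def layer_size(doc: LayeredDocument, layer: str) -> int:
    """Number of artifacts in ``layer`` (token count for the base layer)."""
    if layer == TEXT_LAYER:
        return len(doc.tokens)
    if layer in doc.layers:
        return len(doc.layers[layer])
    if layer in doc.relation_layers:
        return len(doc.relation_layers[layer])
    raise UnknownLayerError(f"document {doc.doc_id!r} has no layer {layer!r}")


def sort_layer(artifacts: List[Artifact]) -> List[Artifact]:
    """Stable sort by (start, length); idempotent."""
    return sorted(artifacts, key=lambda a: (a.span.start, a.span.length))
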