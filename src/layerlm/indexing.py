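"""Per-layer positional inverted indexes with span payloads.

Each artifact layer becomes an inverted index mapping value -> postings,
where every posting keeps the full list of spans in that document.  The
document and collection statistics needed by Dirichlet-smoothed scoring
(|D|_a, |**D**|_a, #t_D, #t_C) are stored at build time; collection phrase
counts are deliberately NOT precomputed (phrase vocabulary is unbounded)
and are evaluated lazily by the scoring engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .annotation_io import TokenizerConfig
from .layer_model import (
    LayeredDocument,
    Span,
    TEXT_LAYER,
    UnknownLayerError,
)

FORMAT_VERSION = 1

SpanPair = Tuple[Span, Span]


@dataclass
class Posting:
    doc_id: str
    spans: List[Span] = field(default_factory=list)


@dataclass
class RelationPosting:
    doc_id: str
    pairs: List[SpanPair] = field(default_factory=list)


@dataclass
class LayerIndex:
    """Inverted index plus size statistics for one artifact layer."""

    name: str
    postings: Dict[str, List[Posting]] = field(default_factory=dict)
    doc_layer_sizes: Dict[str, int] = field(default_factory=dict)
    collection_layer_size: int = 0
    collection_freq: Dict[str, int] = field(default_factory=dict)

    def audit(self) -> List[str]:
        """Recompute stats from postings; report every mismatch."""
        problems = []
        for value, plist in self.postings.items():
            total = sum(len(p.spans) for p in plist)
            if total != self.collection_freq.get(value, 0):
                problems.append(
                    f"layer {self.name!r}: collection_freq[{value!r}] = "
                    f"{self.collection_freq.get(value, 0)} but postings hold {total}"
                )
        if sum(self.doc_layer_sizes.values()) != self.collection_layer_size:
            problems.append(
                f"layer {self.name!r}: collection size {self.collection_layer_size} "
                f"!= sum of doc sizes {sum(self.doc_layer_sizes.values())}"
            )
        return problems


@dataclass
class RelationLayerIndex:
    """Relations stored doc-major (for wildcard lookups) and by label."""

    name: str
    postings: Dict[str, List[RelationPosting]] = field(default_factory=dict)
    doc_relations: Dict[str, List[Tuple[str, Span, Span]]] = field(default_factory=dict)
    doc_layer_sizes: Dict[str, int] = field(default_factory=dict)
    collection_layer_size: int = 0
    collection_freq: Dict[str, int] = field(default_factory=dict)


@dataclass
class CollectionIndex:
    """All layer indexes of a corpus plus the shared doc-id registry."""

    layers: Dict[str, LayerIndex] = field(default_factory=dict)
    relation_layers: Dict[str, RelationLayerIndex] = field(default_factory=dict)
    doc_ids: List[str] = field(default_factory=list)
    stopwords: frozenset = frozenset()
    count_stopped_tokens: bool = True

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def layer(self, name: str) -> LayerIndex:
        try:
            return self.layers[name]
        except KeyError:
            raise UnknownLayerError(f"layer {name!r} is not indexed")

    def relation_layer(self, name: str) -> RelationLayerIndex:
        try:
            return self.relation_layers[name]
        except KeyError:
            raise UnknownLayerError(f"relation layer {name!r} is not indexed")

    def doc_layer_size(self, layer: str, doc_id: str) -> int:
        if layer in self.layers:
            return self.layers[layer].doc_layer_sizes.get(doc_id, 0)
        if layer in self.relation_layers:
            return self.relation_layers[layer].doc_layer_sizes.get(doc_id, 0)
        raise UnknownLayerError(f"layer {layer!r} is not indexed")

    def collection_layer_size(self, layer: str) -> int:
        if layer in self.layers:
            return self.layers[layer].collection_layer_size
        if layer in self.relation_layers:
            return self.relation_layers[layer].collection_layer_size
        raise UnknownLayerError(f"layer {layer!r} is not indexed")


def build_index(
    docs: Sequence[LayeredDocument],
    config: TokenizerConfig | None = None,
    *,
    count_stopped_tokens: bool = True,
) -> CollectionIndex:
    """Index every layer present in any document.

    Base tokens are indexed under the reserved layer name "text", normalized
    per ``config``.  Stopwords stay in the index (spans must remain valid);
    with ``count_stopped_tokens=False`` they are excluded from |D|_text and
    |**D**|_text.
    """
    config = config or TokenizerConfig()
    index = CollectionIndex(
        stopwords=frozenset(config.stopwords),
        count_stopped_tokens=count_stopped_tokens,
    )
    seen = set()
    text_index = LayerIndex(TEXT_LAYER)
    index.layers[TEXT_LAYER] = text_index

    for doc in docs:
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        index.doc_ids.append(doc.doc_id)

        countable = 0
        for i, raw in enumerate(doc.tokens):
            tok = raw.lower() if config.lowercase else raw
            _add_occurrence(text_index, tok, doc.doc_id, Span(i, 1))
            if count_stopped_tokens or tok not in config.stopwords:
                countable += 1
        text_index.doc_layer_sizes[doc.doc_id] = countable
        text_index.collection_layer_size += countable

        for name, artifacts in doc.layers.items():
            layer = index.layers.setdefault(name, LayerIndex(name))
            for art in artifacts:
                _add_occurrence(layer, art.value, doc.doc_id, art.span)
            layer.doc_layer_sizes[doc.doc_id] = len(artifacts)
            layer.collection_layer_size += len(artifacts)

        for name, relations in doc.relation_layers.items():
            rlayer = index.relation_layers.setdefault(name, RelationLayerIndex(name))
            stored = []
            for rel in relations:
                plist = rlayer.postings.setdefault(rel.value, [])
                if not plist or plist[-1].doc_id != doc.doc_id:
                    plist.append(RelationPosting(doc.doc_id))
                plist[-1].pairs.append((rel.source, rel.target))
                rlayer.collection_freq[rel.value] = (
                    rlayer.collection_freq.get(rel.value, 0) + 1
                )
                stored.append((rel.value, rel.source, rel.target))
            rlayer.doc_relations[doc.doc_id] = stored
            rlayer.doc_layer_sizes[doc.doc_id] = len(relations)
            rlayer.collection_layer_size += len(relations)

    # Postings are per-doc in input order; sort occurrence lists by start.
    for layer in index.layers.values():
        for plist in layer.postings.values():
            for posting in plist:
                posting.spans.sort(key=lambda s: (s.start, s.length))
    for rlayer in index.relation_layers.values():
        for plist in rlayer.postings.values():
            for posting in plist:
                posting.pairs.sort(key=lambda p: (p[0].start, p[0].length))
    return index


def _add_occurrence(layer: LayerIndex, value: str, doc_id: str, span: Span) -> None:
    plist = layer.postings.setdefault(value, [])
    if not plist or plist[-1].doc_id != doc_id:
        plist.append(Posting(doc_id))
    plist[-1].spans.append(span)
    layer.collection_freq[value] = layer.collection_freq.get(value, 0) + 1


def term_lookup(
    index: CollectionIndex, layer: str, value: str, doc_id: str
) -> Tuple[int, List[Span]]:
    """(#t_D, spans) of ``value`` in one document; (0, []) when absent."""
    lidx = index.layer(layer)
    for posting in lidx.postings.get(value, ()):
        if posting.doc_id == doc_id:
            return len(posting.spans), list(posting.spans)
    return 0, []


def relation_lookup(
    index: CollectionIndex, layer: str, doc_id: str, label_pattern: str = "*"
) -> List[SpanPair]:
    """All (source, target) span pairs in the doc whose label matches."""
    rlayer = index.relation_layer(layer)
    out = []
    for label, source, target in rlayer.doc_relations.get(doc_id, ()):
        if label_pattern == "*" or label == label_pattern:
            out.append((source, target))
    return out


def audit_index(index: CollectionIndex) -> List[str]:
    """Stats audit across all layers (empty list = consistent)."""
    problems = []
    for layer in index.layers.values():
        problems.extend(layer.audit())
    for rlayer in index.relation_layers.values():
        for value, plist in rlayer.postings.items():
            total = sum(len(p.pairs) for p in plist)
            if total != rlayer.collection_freq.get(value, 0):
                problems.append(
                    f"relation layer {rlayer.name!r}: freq mismatch for {value!r}"
                )
        if sum(rlayer.doc_layer_sizes.values()) != rlayer.collection_layer_size:
            problems.append(f"relation layer {rlayer.name!r}: size mismatch")
    return problems


# ---------------------------------------------------------------------------
# Serialization (JSON text with a format-version header)
# ---------------------------------------------------------------------------

def index_to_dict(index: CollectionIndex) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "doc_ids": index.doc_ids,
        "stopwords": sorted(index.stopwords),
        "count_stopped_tokens": index.count_stopped_tokens,
        "layers": {
            name: {
                "postings": {
                    value: [
                        [p.doc_id, [[s.start, s.length] for s in p.spans]]
                        for p in plist
                    ]
                    for value, plist in layer.postings.items()
                },
                "doc_layer_sizes": layer.doc_layer_sizes,
                "collection_layer_size": layer.collection_layer_size,
                "collection_freq": layer.collection_freq,
            }
            for name, layer in index.layers.items()
        },
        "relation_layers": {
            name: {
                "doc_relations": {
                    doc_id: [
                        [v, s.start, s.length, t.start, t.length]
                        for v, s, t in rels
                    ]
                    for doc_id, rels in rlayer.doc_relations.items()
                },
                "doc_layer_sizes": rlayer.doc_layer_sizes,
                "collection_layer_size": rlayer.collection_layer_size,
                "collection_freq": rlayer.collection_freq,
            }
            for name, rlayer in index.relation_layers.items()
        },
    }


def index_from_dict(obj: dict) -> CollectionIndex:
    version = obj.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported index format version {version!r}")
    index = CollectionIndex(
        doc_ids=list(obj["doc_ids"]),
        stopwords=frozenset(obj.get("stopwords", ())),
        count_stopped_tokens=obj.get("count_stopped_tokens", True),
    )
    for name, payload in obj["layers"].items():
        layer = LayerIndex(
            name,
            postings={
                value: [
                    Posting(doc_id, [Span(s, ln) for s, ln in spans])
                    for doc_id, spans in plist
                ]
                for value, plist in payload["postings"].items()
            },
            doc_layer_sizes=dict(payload["doc_layer_sizes"]),
            collection_layer_size=payload["collection_layer_size"],
            collection_freq=dict(payload["collection_freq"]),
        )
        index.layers[name] = layer
    for name, payload in obj["relation_layers"].items():
        rlayer = RelationLayerIndex(
            name,
            doc_relations={
                doc_id: [
                    (v, Span(ss, sl), Span(ts, tl))
                    for v, ss, sl, ts, tl in rels
                ]
                for doc_id, rels in payload["doc_relations"].items()
            },
            doc_layer_sizes=dict(payload["doc_layer_sizes"]),
            collection_layer_size=payload["collection_layer_size"],
            collection_freq=dict(payload["collection_freq"]),
        )
        for doc_id, rels in rlayer.doc_relations.items():
            for value, source, target in rels:
                plist = rlayer.postings.setdefault(value, [])
                if not plist or plist[-1].doc_id != doc_id:
                    plist.append(RelationPosting(doc_id))
                plist[-1].pairs.append((source, target))
        index.relation_layers[name] = rlayer
    return index


def save_index(index: CollectionIndex, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(index_to_dict(index), fh, sort_keys=True)


def load_index(path) -> CollectionIndex:
    with open(path, "r", encoding="utf-8") as fh:
        return index_from_dict(json.load(fh))
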