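"""Independent brute-force reference implementation used by the tests.

Operates directly on LayeredDocument objects — never touches the inverted
index or the scoring engine — so it provides a second route for every
count, probability, score, and AP value.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Set, Tuple

from layerlm.layer_model import Artifact, LayeredDocument, Span
from layerlm.query_language import ListNode, Phrase, Query, Relation, Term, WILDCARD


def artifacts_of(doc: LayeredDocument, layer: str) -> List[Artifact]:
    if layer == "text":
        return [Artifact(t, Span(i, 1)) for i, t in enumerate(doc.tokens)]
    return list(doc.layers.get(layer, []))


def layer_size(doc: LayeredDocument, layer: str) -> int:
    if layer == "text":
        return len(doc.tokens)
    if layer in doc.layers:
        return len(doc.layers[layer])
    return len(doc.relation_layers.get(layer, []))


def term_count(doc: LayeredDocument, layer: str, value: str) -> int:
    return sum(1 for a in artifacts_of(doc, layer) if a.value == value)


def term_prob(
    docs: Sequence[LayeredDocument], doc: LayeredDocument, term: Term, mu: float
) -> float:
    t_c = sum(term_count(d, term.layer, term.value) for d in docs)
    coll = sum(layer_size(d, term.layer) for d in docs)
    if t_c == 0 or coll == 0:
        return 0.0
    t_d = term_count(doc, term.layer, term.value)
    return (t_d + mu * t_c / coll) / (layer_size(doc, term.layer) + mu)


def _component_candidates(
    doc: LayeredDocument, component
) -> List[Tuple[Tuple[str, int], Span]]:
    """(identity, span) per matching artifact; identity = (layer, position)."""
    members = component.members if isinstance(component, ListNode) else (component,)
    out = []
    for term in members:
        for idx, art in enumerate(artifacts_of(doc, term.layer)):
            if art.value == term.value:
                out.append(((term.layer, idx), art.span))
    return out


def phrase_count(
    doc: LayeredDocument, components, window: int, ordered: bool
) -> int:
    """Enumerate every artifact tuple and filter by the window rules."""
    cands = [_component_candidates(doc, c) for c in components]
    count = 0
    for tup in itertools.product(*cands):
        ids = [i for i, _ in tup]
        if len(set(ids)) != len(ids):
            continue
        spans = [s for _, s in tup]
        if ordered:
            ok = all(spans[i + 1].start >= spans[i].end for i in range(len(spans) - 1))
            ok = ok and spans[-1].start - spans[0].end <= window
        else:
            first = min(spans, key=lambda s: (s.start, s.end))
            ok = all(s.start <= first.end + window for s in spans)
        if ok:
            count += 1
    return count


def _phrase_layers(phrase: Phrase) -> List[str]:
    layers = []
    for comp in phrase.components:
        members = comp.members if isinstance(comp, ListNode) else (comp,)
        for term in members:
            if term.layer not in layers:
                layers.append(term.layer)
    return layers


def phrase_prob(
    docs: Sequence[LayeredDocument], doc: LayeredDocument, phrase: Phrase, mu: float
) -> float:
    ph_c = sum(
        phrase_count(d, phrase.components, phrase.window, phrase.ordered) for d in docs
    )
    if ph_c == 0:
        return 0.0
    layers = _phrase_layers(phrase)
    coll = max(sum(layer_size(d, n) for d in docs) for n in layers)
    if coll == 0:
        return 0.0
    ph_d = phrase_count(doc, phrase.components, phrase.window, phrase.ordered)
    d_size = max(layer_size(doc, n) for n in layers)
    return (ph_d + mu * ph_c / coll) / (d_size + mu)


def relation_count(doc: LayeredDocument, rel: Relation) -> int:
    def matches(pattern, span: Span) -> bool:
        if pattern == WILDCARD:
            return True
        return any(
            a.value == pattern.value and span.overlaps(a.span)
            for a in artifacts_of(doc, pattern.layer)
        )

    count = 0
    for r in doc.relation_layers.get(rel.layer, []):
        if rel.label_pattern != WILDCARD and r.value != rel.label_pattern:
            continue
        if matches(rel.source, r.source) and matches(rel.target, r.target):
            count += 1
    return count


def relation_prob(
    docs: Sequence[LayeredDocument], doc: LayeredDocument, rel: Relation, mu: float
) -> float:
    t_c = sum(relation_count(d, rel) for d in docs)
    coll = sum(layer_size(d, rel.layer) for d in docs)
    if t_c == 0 or coll == 0:
        return 0.0
    return (relation_count(doc, rel) + mu * t_c / coll) / (
        layer_size(doc, rel.layer) + mu
    )


def node_prob(docs, doc, node, mu: float) -> float:
    if isinstance(node, Term):
        return term_prob(docs, doc, node, mu)
    if isinstance(node, ListNode):
        p = 1.0
        for m in node.members:
            p *= term_prob(docs, doc, m, mu)
        return p
    if isinstance(node, Phrase):
        return phrase_prob(docs, doc, node, mu)
    if isinstance(node, Relation):
        return relation_prob(docs, doc, node, mu)
    raise TypeError(node)


def doc_score(docs, doc, query: Query, mu: float) -> float:
    total = 0.0
    for node in query.nodes:
        p = node_prob(docs, doc, node, mu)
        if p > 0.0:
            total += node.weight * math.log(p)
    return total


def rank_docs(docs, query: Query, mu: float) -> List[str]:
    scored = [(doc.doc_id, doc_score(docs, doc, query, mu)) for doc in docs]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [d for d, _ in scored]


def average_precision(ranking: Sequence[str], relevant: Set[str]) -> float:
    hits, total = 0, 0.0
    for r, doc_id in enumerate(ranking, start=1):
        if doc_id in relevant:
            hits += 1
            total += hits / r
    return total / len(relevant)


def mean_ap(
    run: Dict[str, Sequence[str]], relevant_by_topic: Dict[str, Set[str]]
) -> float:
    aps = [
        average_precision(run.get(t, []), rel)
        for t, rel in relevant_by_topic.items()
        if rel
    ]
    return sum(aps) / len(aps) if aps else 0.0
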