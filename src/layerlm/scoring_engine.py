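"""Dirichlet-smoothed scoring of term, list, phrase, and relation queries.

Term probability (per layer a, pseudo-count mu):

    P(t|D) = (#t_D + mu * #t_C / |**D**|_a) / (|D|_a + mu)

Phrase probability uses the same shape with cross-layer phrase counts and,
for the denominators, the size of the largest layer stipulated in the
phrase.  Collection phrase/relation counts are evaluated lazily over all
documents and memoized per query node.

Document score is the weighted sum of log-probabilities; nodes with zero
collection evidence are skipped (never scored as -inf).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .indexing import CollectionIndex, relation_lookup, term_lookup
from .layer_model import Span, UnknownLayerError
from .query_language import (
    ListNode,
    Phrase,
    Query,
    QueryNode,
    Relation,
    Term,
    WILDCARD,
    render_node,
)

logger = logging.getLogger(__name__)

PhraseComponent = Union[Term, ListNode]


@dataclass(frozen=True)
class SmoothingConfig:
    """Dirichlet pseudo-count, globally and with per-layer overrides."""

    mu: float = 2000.0
    per_layer: Tuple[Tuple[str, float], ...] = ()
    #: use the product of layer sizes instead of their max in the phrase
    #: denominator (non-default alternative; untested against any reference)
    product_denominator: bool = False

    def __post_init__(self):
        if self.mu <= 0 or any(m <= 0 for _, m in self.per_layer):
            raise ValueError("all mu values must be positive")

    def mu_for(self, layer: str) -> float:
        for name, value in self.per_layer:
            if name == layer:
                return value
        return self.mu


@dataclass
class ScoredDoc:
    doc_id: str
    score: float
    contributions: List[Tuple[QueryNode, float, float]] = field(default_factory=list)
    """(node, log-probability, weight) for each node that contributed."""


def _component_terms(component: PhraseComponent) -> Tuple[Term, ...]:
    if isinstance(component, Term):
        return (component,)
    if isinstance(component, ListNode):
        return component.members
    raise TypeError(f"phrase components must be terms or lists, got {component!r}")


def _candidates(
    index: CollectionIndex, component: PhraseComponent, doc_id: str
) -> List[Tuple[Tuple[str, str, int], Span]]:
    """Artifacts matching a phrase component, each with a stable identity.

    A List matches wherever any of its members match.  Identity keys keep
    duplicate artifacts (same value and span indexed twice) distinct.
    """
    out = []
    for term in _component_terms(component):
        _, spans = term_lookup(index, term.layer, term.value, doc_id)
        for i, span in enumerate(spans):
            out.append(((term.layer, term.value, i), span))
    return out


def count_phrase_matches(
    index: CollectionIndex,
    components: Sequence[PhraseComponent],
    window: int,
    ordered: bool,
    doc_id: str,
) -> int:
    """#ph_D: number of qualifying artifact tuples in one document.

    A tuple (a_1..a_k) of pairwise-distinct artifacts, a_i matching
    component i, qualifies when every member's start index falls within
    ``window`` tokens of the end of the earliest member (the last artifact
    may end outside the window).  Ordered phrases additionally require
    non-overlapping, sequential artifacts in component order, with the last
    start within ``window`` of the first end.
    """
    if len(components) < 2:
        raise ValueError("a phrase needs at least 2 components")
    if window < 1:
        raise ValueError("window must be >= 1")
    candidate_lists = [_candidates(index, c, doc_id) for c in components]
    if any(not lst for lst in candidate_lists):
        return 0
    count = 0
    for tup in itertools.product(*candidate_lists):
        keys = [key for key, _ in tup]
        if len(set(keys)) != len(keys):
            continue
        spans = [span for _, span in tup]
        if ordered:
            if any(spans[i + 1].start < spans[i].end for i in range(len(spans) - 1)):
                continue
            if spans[-1].start - spans[0].end > window:
                continue
        else:
            first = min(spans, key=lambda s: (s.start, s.end))
            if any(s.start > first.end + window for s in spans):
                continue
        count += 1
    return count


def _relation_count(
    index: CollectionIndex, rel: Relation, doc_id: str
) -> int:
    """#t_D for a relation query: relations whose label matches and whose
    source/target spans overlap some artifact matching the patterns."""

    def pattern_spans(pattern) -> Optional[List[Span]]:
        if pattern == WILDCARD:
            return None  # matches unconditionally
        _, spans = term_lookup(index, pattern.layer, pattern.value, doc_id)
        return spans

    src_spans = pattern_spans(rel.source)
    tgt_spans = pattern_spans(rel.target)
    count = 0
    for source, target in relation_lookup(index, rel.layer, doc_id, rel.label_pattern):
        if src_spans is not None and not any(source.overlaps(s) for s in src_spans):
            continue
        if tgt_spans is not None and not any(target.overlaps(s) for s in tgt_spans):
            continue
        count += 1
    return count


class Scorer:
    """Scores documents against parsed queries over a CollectionIndex.

    Collection-wide phrase and relation counts are memoized per node across
    calls, so ranking a query over the whole corpus stays linear in corpus
    size.
    """

    def __init__(self, index: CollectionIndex, config: SmoothingConfig | None = None):
        self.index = index
        self.config = config or SmoothingConfig()
        self._phrase_collection_cache: Dict[tuple, int] = {}
        self._relation_collection_cache: Dict[tuple, int] = {}

    # -- term ---------------------------------------------------------------

    def score_term(self, term: Term, doc_id: str) -> float:
        layer = self.index.layer(term.layer)
        coll_size = layer.collection_layer_size
        t_c = layer.collection_freq.get(term.value, 0)
        if t_c == 0:
            return 0.0
        if coll_size == 0:
            logger.warning("layer %r has collection size 0", term.layer)
            return 0.0
        t_d, _ = term_lookup(self.index, term.layer, term.value, doc_id)
        d_size = layer.doc_layer_sizes.get(doc_id, 0)
        mu = self.config.mu_for(term.layer)
        return (t_d + mu * t_c / coll_size) / (d_size + mu)

    # -- list ---------------------------------------------------------------

    def score_list(self, lst: ListNode, doc_id: str) -> float:
        """Standalone list = members scored individually (product)."""
        if not lst.members:
            raise ValueError("empty list query")
        prob = 1.0
        for member in lst.members:
            prob *= self.score_term(member, doc_id)
        return prob

    # -- phrase -------------------------------------------------------------

    def _phrase_key(self, phrase: Phrase) -> tuple:
        return (render_node(Phrase(phrase.window, phrase.ordered, phrase.components)),)

    def _phrase_layers(self, phrase: Phrase) -> List[str]:
        layers = []
        for comp in phrase.components:
            for term in _component_terms(comp):
                if term.layer not in layers:
                    layers.append(term.layer)
        return layers

    def collection_phrase_count(self, phrase: Phrase) -> int:
        key = self._phrase_key(phrase)
        if key not in self._phrase_collection_cache:
            self._phrase_collection_cache[key] = sum(
                count_phrase_matches(
                    self.index, phrase.components, phrase.window, phrase.ordered, d
                )
                for d in self.index.doc_ids
            )
        return self._phrase_collection_cache[key]

    def score_phrase(self, phrase: Phrase, doc_id: str) -> float:
        layers = self._phrase_layers(phrase)
        for name in layers:
            self.index.layer(name)  # raise early on unindexed layers
        ph_c = self.collection_phrase_count(phrase)
        if ph_c == 0:
            return 0.0
        ph_d = count_phrase_matches(
            self.index, phrase.components, phrase.window, phrase.ordered, doc_id
        )
        if self.config.product_denominator:
            d_size = math.prod(self.index.doc_layer_size(n, doc_id) for n in layers)
            coll_size = math.prod(self.index.collection_layer_size(n) for n in layers)
        else:
            d_size = max(self.index.doc_layer_size(n, doc_id) for n in layers)
            coll_size = max(self.index.collection_layer_size(n) for n in layers)
        if coll_size == 0:
            logger.warning("phrase layers %r have collection size 0", layers)
            return 0.0
        mu = self.config.mu
        return (ph_d + mu * ph_c / coll_size) / (d_size + mu)

    # -- relation -----------------------------------------------------------

    def collection_relation_count(self, rel: Relation) -> int:
        key = (render_node(Relation(rel.layer, rel.label_pattern, rel.source, rel.target)),)
        if key not in self._relation_collection_cache:
            self._relation_collection_cache[key] = sum(
                _relation_count(self.index, rel, d) for d in self.index.doc_ids
            )
        return self._relation_collection_cache[key]

    def score_relation(self, rel: Relation, doc_id: str) -> float:
        rlayer = self.index.relation_layer(rel.layer)
        t_c = self.collection_relation_count(rel)
        if t_c == 0:
            return 0.0
        coll_size = rlayer.collection_layer_size
        if coll_size == 0:
            logger.warning("relation layer %r has collection size 0", rel.layer)
            return 0.0
        t_d = _relation_count(self.index, rel, doc_id)
        d_size = rlayer.doc_layer_sizes.get(doc_id, 0)
        mu = self.config.mu_for(rel.layer)
        return (t_d + mu * t_c / coll_size) / (d_size + mu)

    # -- document -----------------------------------------------------------

    def score_node(self, node: QueryNode, doc_id: str) -> float:
        if isinstance(node, Term):
            return self.score_term(node, doc_id)
        if isinstance(node, ListNode):
            return self.score_list(node, doc_id)
        if isinstance(node, Phrase):
            return self.score_phrase(node, doc_id)
        if isinstance(node, Relation):
            return self.score_relation(node, doc_id)
        raise TypeError(f"not a query node: {node!r}")

    def score_document(self, query: Query, doc_id: str) -> ScoredDoc:
        """Weighted log-probability sum; zero-evidence nodes are dropped."""
        total = 0.0
        contributions = []
        for node in query.nodes:
            prob = self.score_node(node, doc_id)
            if prob <= 0.0:
                logger.debug("skipping zero-evidence node %s", render_node(node))
                continue
            log_p = math.log(prob)
            total += node.weight * log_p
            contributions.append((node, log_p, node.weight))
        return ScoredDoc(doc_id, total, contributions)

    def rank(self, query: Query, k: int = 1000) -> List[ScoredDoc]:
        """Score all docs; descending score, ties by ascending doc_id."""
        if k < 1:
            raise ValueError("k must be >= 1")
        scored = [self.score_document(query, d) for d in self.index.doc_ids]
        scored.sort(key=lambda s: (-s.score, s.doc_id))
        return scored[:k]


# Functional wrappers -------------------------------------------------------

def score_term(index, term, doc_id, config=None) -> float:
    return Scorer(index, config).score_term(term, doc_id)


def score_list(index, lst, doc_id, config=None) -> float:
    return Scorer(index, config).score_list(lst, doc_id)


def score_phrase(index, phrase, doc_id, config=None) -> float:
    return Scorer(index, config).score_phrase(phrase, doc_id)


def score_relation(index, rel, doc_id, config=None) -> float:
    return Scorer(index, config).score_relation(rel, doc_id)


def score_document(index, query, doc_id, config=None) -> ScoredDoc:
    return Scorer(index, config).score_document(query, doc_id)


def rank(index, query, config=None, k: int = 1000) -> List[ScoredDoc]:
    return Scorer(index, config).rank(query, k)
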