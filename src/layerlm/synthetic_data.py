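"""Synthetic layered corpora with clinical-pipeline-like structure.

Generates documents whose base tokens come from a topic-mixture unigram
model, with concept (cui/tui) layers produced by deterministic dictionary
tagging, 1:1 lemma and POS layers, and random dependency trees per
sentence.  Topic relevance is planted at generation time, so qrels are
ground truth and retrieval-independent.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotation_io import Qrels, Topic, strip_plural
from .layer_model import Artifact, LayeredDocument, RelationArtifact, Span, sort_layer


@dataclass
class ConceptDictionary:
    """Surface form (1-3 token phrase) -> (CUI, TUI), plus a lemma map.

    CUIs are unique per surface form; each CUI maps to exactly one TUI
    (many-to-one grouping of concepts into semantic types).
    """

    entries: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    lemma_map: Dict[str, str] = field(default_factory=dict)

    def lemma(self, token: str) -> str:
        return self.lemma_map.get(token, strip_plural(token))

    def tag(self, tokens: Sequence[str], max_len: int = 3) -> List[Tuple[str, str, Span]]:
        """Deterministic dictionary NER: at every position emit all entries
        matching there (longest included), so overlapping concepts such as
        a phrase and its head word are both annotated.

        Returns (cui, tui, span) sorted by (start, length).
        """
        found = []
        for i in range(len(tokens)):
            for n in range(1, min(max_len, len(tokens) - i) + 1):
                surface = " ".join(tokens[i : i + n])
                if surface in self.entries:
                    cui, tui = self.entries[surface]
                    found.append((cui, tui, Span(i, n)))
        found.sort(key=lambda t: (t[2].start, t[2].length))
        return found


#: Worked-example dictionary binding obstetrics / hepatitis concepts used
#: throughout the docs and tests to their surface forms.
FIXTURE_DICTIONARY = ConceptDictionary(
    entries={
        "pregnancy": ("C0032961", "T040"),
        "preterm delivery": ("C0151526", "T046"),
        "delivery": ("C0011209", "T040"),
        "hepatitis": ("C0019158", "T047"),
        "hepatitis c": ("C0019196", "T047"),
        "hiv": ("C0019682", "T005"),
    },
    lemma_map={"given": "give", "gave": "give", "presented": "present"},
)


def annotate_concepts(
    tokens: Sequence[str], dictionary: ConceptDictionary
) -> Tuple[List[Artifact], List[Artifact]]:
    """(cui layer, tui layer) from dictionary tagging of a token sequence."""
    cuis, tuis = [], []
    for cui, tui, span in dictionary.tag(tokens):
        cuis.append(Artifact(cui, span))
        tuis.append(Artifact(tui, span))
    return sort_layer(cuis), sort_layer(tuis)


def make_demo_document(doc_id: str = "demo") -> LayeredDocument:
    """Four-token obstetrics example with all layer kinds populated.

    Base tokens "pregnancy with preterm delivery"; concepts from the
    fixture dictionary; POS tags; and a dependency arc from the head
    "pregnancy" (span (0,1)) to the dependent "delivery" (span (3,1)).
    """
    tokens = ["pregnancy", "with", "preterm", "delivery"]
    cuis, tuis = annotate_concepts(tokens, FIXTURE_DICTIONARY)
    return LayeredDocument(
        doc_id=doc_id,
        tokens=tokens,
        layers={
            "cui": cuis,
            "tui": tuis,
            "pos": [
                Artifact("NN", Span(0, 1)),
                Artifact("IN", Span(1, 1)),
                Artifact("JJ", Span(2, 1)),
                Artifact("NN", Span(3, 1)),
            ],
            "lemma": [
                Artifact(FIXTURE_DICTIONARY.lemma(t), Span(i, 1))
                for i, t in enumerate(tokens)
            ],
        },
        relation_layers={
            "dep": [RelationArtifact("prep_with", Span(0, 1), Span(3, 1))]
        },
    )


DEFAULT_POS_TAGS = ("NN", "VB", "JJ", "IN", "DT", "NNP", "RB")
DEFAULT_RELATION_LABELS = ("nsubj", "dobj", "amod", "prep", "conj")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 20
    tokens_per_doc: Tuple[int, int] = (20, 50)
    vocab_size: int = 200
    n_concepts: int = 20
    n_topics: int = 5
    topic_concept_count: int = 2
    planting_rate: float = 0.5
    pos_tags: Tuple[str, ...] = DEFAULT_POS_TAGS
    relation_labels: Tuple[str, ...] = DEFAULT_RELATION_LABELS
    sentence_length: int = 10

    def validate(self) -> None:
        if self.n_docs < 0 or not (0.0 <= self.planting_rate <= 1.0):
            raise ValueError("bad corpus size or planting rate")
        for value in (
            self.vocab_size,
            self.n_concepts,
            self.n_topics,
            self.topic_concept_count,
            self.sentence_length,
        ):
            if value < 1:
                raise ValueError("all generator counts must be >= 1")
        lo, hi = self.tokens_per_doc
        if lo < 1 or hi < lo:
            raise ValueError("tokens_per_doc must be a nondecreasing positive range")
        if self.topic_concept_count > self.n_concepts:
            raise ValueError("topic concept sets cannot exceed the concept inventory")


@dataclass
class SyntheticCorpus:
    """Generated documents plus the ground truth recorded at generation."""

    docs: List[LayeredDocument]
    dictionary: ConceptDictionary
    topic_concepts: List[List[str]]  # per topic: surface forms
    doc_topics: Dict[str, Optional[int]]  # doc_id -> planted topic index


def _make_vocabulary(cfg: GeneratorConfig, rng: random.Random) -> List[str]:
    vocab = []
    for i in range(cfg.vocab_size):
        word = f"w{i:04d}"
        # some plural-looking forms so the lemma layer is non-trivial
        if rng.random() < 0.15:
            word += "s"
        vocab.append(word)
    return vocab


def _make_dictionary(
    cfg: GeneratorConfig, vocab: List[str], rng: random.Random
) -> ConceptDictionary:
    if cfg.vocab_size < cfg.n_concepts:
        raise ValueError("vocabulary smaller than the requested concept inventory")
    dictionary = ConceptDictionary()
    n_tuis = max(1, cfg.n_concepts // 3)
    used = set()
    i = 0
    while len(dictionary.entries) < cfg.n_concepts:
        length = rng.choice((1, 2, 3))
        surface = " ".join(rng.choice(vocab) for _ in range(length))
        if surface in used:
            continue
        used.add(surface)
        cui = f"C{1000000 + i:07d}"
        tui = f"T{(i % n_tuis) + 1:03d}"
        dictionary.entries[surface] = (cui, tui)
        i += 1
    for token in vocab:
        dictionary.lemma_map[token] = strip_plural(token)
    return dictionary


def _random_tree_relations(
    start: int, length: int, labels: Tuple[str, ...], rng: random.Random
) -> List[RelationArtifact]:
    """Uniformly random recursive-attachment tree over one sentence."""
    if length < 2:
        return []
    order = list(range(start, start + length))
    rng.shuffle(order)
    relations = []
    for pos, dependent in enumerate(order[1:], start=1):
        head = order[rng.randrange(pos)]
        relations.append(
            RelationArtifact(rng.choice(labels), Span(head, 1), Span(dependent, 1))
        )
    relations.sort(key=lambda r: (r.source.start, r.target.start, r.value))
    return relations


def generate_corpus(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Deterministic corpus generation: identical seed, identical corpus."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    vocab = _make_vocabulary(cfg, rng)
    dictionary = _make_dictionary(cfg, vocab, rng)

    # Zipf-ish background unigram distribution over the vocabulary.
    weights = [1.0 / (r + 1) for r in range(len(vocab))]

    surfaces = sorted(dictionary.entries)
    topic_concepts = [
        rng.sample(surfaces, cfg.topic_concept_count) for _ in range(cfg.n_topics)
    ]

    docs: List[LayeredDocument] = []
    doc_topics: Dict[str, Optional[int]] = {}
    for d in range(cfg.n_docs):
        doc_id = f"doc{d:04d}"
        n_tokens = rng.randint(*cfg.tokens_per_doc)
        tokens = rng.choices(vocab, weights=weights, k=n_tokens)

        topic: Optional[int] = None
        if rng.random() < cfg.planting_rate:
            topic = rng.randrange(cfg.n_topics)
            for surface in topic_concepts[topic]:
                for _ in range(rng.choice((1, 2))):
                    pos = rng.randrange(len(tokens) + 1)
                    tokens[pos:pos] = surface.split()
        doc_topics[doc_id] = topic

        cuis, tuis = annotate_concepts(tokens, dictionary)
        lemma = [
            Artifact(dictionary.lemma(t), Span(i, 1)) for i, t in enumerate(tokens)
        ]
        pos_layer = [
            Artifact(rng.choice(cfg.pos_tags), Span(i, 1))
            for i in range(len(tokens))
        ]
        relations: List[RelationArtifact] = []
        for s_start in range(0, len(tokens), cfg.sentence_length):
            s_len = min(cfg.sentence_length, len(tokens) - s_start)
            relations.extend(
                _random_tree_relations(s_start, s_len, cfg.relation_labels, rng)
            )
        layers = {"lemma": lemma, "pos": pos_layer}
        if cuis:
            layers["cui"] = cuis
            layers["tui"] = tuis
        docs.append(
            LayeredDocument(
                doc_id=doc_id,
                tokens=tokens,
                layers=layers,
                relation_layers={"dep": relations} if relations else {},
            )
        )

    return SyntheticCorpus(docs, dictionary, topic_concepts, doc_topics)


def generate_topics_and_qrels(
    cfg: GeneratorConfig, corpus: SyntheticCorpus
) -> Tuple[List[Topic], Qrels]:
    """Topics rendered from planted concept sets; qrels from ground truth."""
    if cfg.n_topics > len(corpus.topic_concepts):
        raise ValueError("more topics requested than planted assignments")
    topics = []
    grades = {}
    for t in range(cfg.n_topics):
        topic_id = str(100 + t)
        text = " ".join(corpus.topic_concepts[t])
        topics.append(Topic(topic_id, text))
        for doc in corpus.docs:
            grade = 1 if corpus.doc_topics[doc.doc_id] == t else 0
            grades[(topic_id, doc.doc_id)] = grade
    return topics, Qrels(grades)
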