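"""I/O for layered-document JSONL and TREC-style evaluation files.

Also provides the base-layer tokenizer: whitespace splitting with
surrounding punctuation stripped, optional lowercasing, an optional
plural-``s`` stemmer, and an optional stopped view.  Stopwords are never
removed from stored documents (that would invalidate spans); stopping only
filters the scoring/query vocabulary when explicitly requested.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .layer_model import (
    Artifact,
    LayeredDocument,
    RelationArtifact,
    Span,
    validate_document,
)

#: Small default English stopword list; replaceable via TokenizerConfig.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be but by for from had has have in is it of on or
    that the this to was were which with""".split()
)

_STRIP_CHARS = string.punctuation + string.whitespace


class FormatError(ValueError):
    """Malformed input file; message carries line number / doc id."""


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenization settings, applied identically at index and query time."""

    lowercase: bool = True
    stopwords: frozenset = frozenset()
    stemmer: str = "none"  # "none" | "suffix-s"

    def __post_init__(self):
        if self.stemmer not in ("none", "suffix-s"):
            raise ValueError(f"unknown stemmer {self.stemmer!r}")


def strip_plural(token: str) -> str:
    """Minimal plural-s stemmer (used by the lemma-layer generator)."""
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


def tokenize(
    text: str, config: TokenizerConfig | None = None, *, stopped: bool = False
) -> List[str]:
    """Split on whitespace, strip surrounding punctuation, lowercase.

    ``stopped=True`` additionally removes configured stopwords — use only
    for query/scoring vocabulary, never for the stored base layer.
    """
    config = config or TokenizerConfig()
    out = []
    for raw in text.split():
        tok = raw.strip(_STRIP_CHARS)
        if not tok:
            continue
        if config.lowercase:
            tok = tok.lower()
        if config.stemmer == "suffix-s":
            tok = strip_plural(tok)
        if stopped and tok in config.stopwords:
            continue
        out.append(tok)
    return out


# ---------------------------------------------------------------------------
# Layered-document JSONL
# ---------------------------------------------------------------------------

def document_to_dict(doc: LayeredDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "tokens": list(doc.tokens),
        "layers": {
            name: [[a.value, a.span.start, a.span.length] for a in arts]
            for name, arts in doc.layers.items()
        },
        "relations": {
            name: [
                [
                    r.value,
                    r.source.start,
                    r.source.length,
                    r.target.start,
                    r.target.length,
                ]
                for r in rels
            ]
            for name, rels in doc.relation_layers.items()
        },
    }


def document_from_dict(obj: dict) -> LayeredDocument:
    layers = {
        name: [Artifact(v, Span(s, ln)) for v, s, ln in triples]
        for name, triples in obj.get("layers", {}).items()
    }
    relations = {
        name: [
            RelationArtifact(v, Span(ss, sl), Span(ts, tl))
            for v, ss, sl, ts, tl in quints
        ]
        for name, quints in obj.get("relations", {}).items()
    }
    return LayeredDocument(
        doc_id=obj["doc_id"],
        tokens=list(obj["tokens"]),
        layers=layers,
        relation_layers=relations,
    )


def read_layered_jsonl(path) -> List[LayeredDocument]:
    """Read and validate a layered-document JSONL file.

    Rejects the whole file on the first malformed line or invariant
    violation, naming the line number / doc id.
    """
    docs = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                doc = document_from_dict(obj)
            except (ValueError, KeyError, TypeError) as exc:
                raise FormatError(f"{path}: line {lineno}: malformed document: {exc}")
            violations = validate_document(doc)
            if violations:
                raise FormatError(
                    f"{path}: line {lineno}: document {doc.doc_id!r} invalid: "
                    + "; ".join(violations)
                )
            docs.append(doc)
    return docs


def write_layered_jsonl(docs: Iterable[LayeredDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            violations = validate_document(doc)
            if violations:
                raise FormatError(
                    f"refusing to write invalid document {doc.doc_id!r}: "
                    + "; ".join(violations)
                )
            fh.write(json.dumps(document_to_dict(doc), sort_keys=True))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Topics, qrels, runs (TREC conventions)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Topic:
    topic_id: str
    text: str


@dataclass
class Qrels:
    """Relevance judgments: (topic_id, doc_id) -> integer grade >= 0."""

    grades: Dict[Tuple[str, str], int] = field(default_factory=dict)

    def topics(self) -> List[str]:
        return sorted({t for t, _ in self.grades})

    def relevant_docs(self, topic_id: str) -> Set[str]:
        """Docs with grade >= 1 (binary relevance convention)."""
        return {d for (t, d), g in self.grades.items() if t == topic_id and g >= 1}


def read_topics(path) -> List[Topic]:
    """TSV: topic_id <tab> text. Duplicate ids are rejected."""
    topics, seen = [], set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 'id<TAB>text'")
            tid, text = parts
            if tid in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate topic id {tid!r}")
            seen.add(tid)
            topics.append(Topic(tid, text))
    return topics


def write_topics(topics: Iterable[Topic], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in topics:
            fh.write(f"{t.topic_id}\t{t.text}\n")


def read_qrels(path) -> Qrels:
    """TREC qrels: ``topic 0 docid grade`` per line."""
    grades: Dict[Tuple[str, str], int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'topic 0 docid grade'"
                )
            topic, _, doc_id, grade_s = parts
            try:
                grade = int(grade_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer grade")
            if grade < 0:
                raise FormatError(f"{path}: line {lineno}: negative grade")
            key = (topic, doc_id)
            if key in grades:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate judgment for {key}"
                )
            grades[key] = grade
    return Qrels(grades)


def write_qrels(qrels: Qrels, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (topic, doc_id), grade in sorted(qrels.grades.items()):
            fh.write(f"{topic} 0 {doc_id} {grade}\n")


def write_run(
    run: Dict[str, Sequence[Tuple[str, float]]], path, tag: str = "layerlm"
) -> None:
    """Write a TREC run file: ``topic Q0 docid rank score tag``.

    ``run`` maps topic id -> [(doc_id, score), ...]; each list is emitted in
    descending score order with ranks starting at 1.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for topic in sorted(run):
            entries = sorted(run[topic], key=lambda e: (-e[1], e[0]))
            for rank, (doc_id, score) in enumerate(entries, start=1):
                fh.write(f"{topic} Q0 {doc_id} {rank} {score:.6f} {tag}\n")


def read_run(path) -> Dict[str, List[Tuple[str, float]]]:
    """Read a TREC run file back into topic -> ranked (doc_id, score) lists."""
    run: Dict[str, List[Tuple[str, float]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'topic Q0 docid rank score tag'"
                )
            topic, _, doc_id, _, score_s, _ = parts
            try:
                score = float(score_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric score")
            run.setdefault(topic, []).append((doc_id, score))
    for entries in run.values():
        entries.sort(key=lambda e: (-e[1], e[0]))
    return run


def load_stopwords(path) -> frozenset:
    """One stopword per line; blank lines and ``#`` comments ignored."""
    words = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            word = line.strip()
            if word and not word.startswith("#"):
                words.add(word)
    return frozenset(words)
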