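import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from layerlm.annotation_io import TokenizerConfig
from layerlm.indexing import build_index
from layerlm.layer_model import Artifact, LayeredDocument, RelationArtifact, Span
from layerlm.synthetic_data import (
    GeneratorConfig,
    generate_corpus,
    make_demo_document,
)


@pytest.fixture
def demo_doc():
    """4-token worked example with cui/tui/pos/lemma layers and one dep arc."""
    return make_demo_document()


@pytest.fixture
def tiny_doc():
    return LayeredDocument(doc_id="t1", tokens=["a", "b", "a"])


@pytest.fixture
def small_corpus():
    """Deterministic 8-doc synthetic corpus with all layer kinds."""
    cfg = GeneratorConfig(
        seed=7, n_docs=8, tokens_per_doc=(15, 30), vocab_size=40, n_concepts=10,
        n_topics=3, planting_rate=0.6,
    )
    return generate_corpus(cfg)


@pytest.fixture
def small_index(small_corpus):
    return build_index(small_corpus.docs, TokenizerConfig())


def make_doc(doc_id, tokens, layers=None, relations=None):
    """Terse builder: layers as {name: [(value, start, length), ...]}."""
    return LayeredDocument(
        doc_id=doc_id,
        tokens=list(tokens),
        layers={
            name: [Artifact(v, Span(s, ln)) for v, s, ln in items]
            for name, items in (layers or {}).items()
        },
        relation_layers={
            name: [
                RelationArtifact(v, Span(ss, sl), Span(ts, tl))
                for v, ss, sl, ts, tl in items
            ]
            for name, items in (relations or {}).items()
        },
    )
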