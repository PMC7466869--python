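import math
import random

import pytest

from layerlm.indexing import build_index
from layerlm.layer_model import UnknownLayerError
from layerlm.query_language import (
    ListNode,
    Phrase,
    Relation,
    Term,
    WILDCARD,
    parse_query,
)
from layerlm.scoring_engine import (
    Scorer,
    SmoothingConfig,
    count_phrase_matches,
    rank,
    score_document,
    score_list,
    score_phrase,
    score_relation,
    score_term,
)

import oracle
from conftest import make_doc


MU10 = SmoothingConfig(mu=10.0)


@pytest.fixture
def ab_corpus():
    """Two tiny text-only docs with known counts."""
    docs = [
        make_doc("d1", ["a", "b", "a", "c", "a", "b", "a", "b", "c", "a"]),
        make_doc("d2", ["b"] * 90),
    ]
    return docs, build_index(docs)


class TestScoreTerm:
    def test_hand_computed_eq1(self):
        # #t_D=2, |D|_a=10, #t_C=5, |**D**|_a=100, mu=10 -> 0.125
        docs = [
            make_doc("d1", ["a", "x", "a"] + ["f"] * 7),
            make_doc("d2", ["a", "a", "a"] + ["g"] * 87),
        ]
        idx = build_index(docs)
        assert idx.layers["text"].collection_layer_size == 100
        assert idx.layers["text"].collection_freq["a"] == 5
        p = score_term(idx, Term("text", "a"), "d1", MU10)
        assert p == pytest.approx((2 + 10 * 0.05) / (10 + 10), abs=1e-12)
        assert p == pytest.approx(0.125, abs=1e-12)

    def test_out_of_collection_value(self, ab_corpus):
        _, idx = ab_corpus
        assert score_term(idx, Term("text", "zzz"), "d1", MU10) == 0.0

    def test_mle_limit(self, ab_corpus):
        docs, idx = ab_corpus
        p = score_term(idx, Term("text", "a"), "d1", SmoothingConfig(mu=1e-12))
        assert p == pytest.approx(5 / 10, rel=1e-6)

    def test_collection_limit(self, ab_corpus):
        docs, idx = ab_corpus
        big = SmoothingConfig(mu=1e12)
        for doc_id in ("d1", "d2"):
            p = score_term(idx, Term("text", "a"), doc_id, big)
            assert p == pytest.approx(5 / 100, rel=1e-6)

    def test_unknown_layer(self, ab_corpus):
        _, idx = ab_corpus
        with pytest.raises(UnknownLayerError):
            score_term(idx, Term("nope", "a"), "d1", MU10)

    def test_per_layer_mu_override(self, demo_doc):
        idx = build_index([demo_doc])
        cfg = SmoothingConfig(mu=10.0, per_layer=(("cui", 1.0),))
        p_cui = score_term(idx, Term("cui", "C0032961"), "demo", cfg)
        assert p_cui == pytest.approx((1 + 1 * (1 / 3)) / (3 + 1), abs=1e-12)

    def test_normalization(self, small_corpus, small_index):
        """Eq.-1 probabilities form a proper distribution per layer."""
        scorer = Scorer(small_index, MU10)
        for layer_name, layer in small_index.layers.items():
            for doc in small_corpus.docs:
                total = sum(
                    scorer.score_term(Term(layer_name, v), doc.doc_id)
                    for v in layer.collection_freq
                )
                assert total == pytest.approx(1.0, abs=1e-9)


class TestPhraseCounting:
    def test_adjacent_ordered(self, demo_doc):
        idx = build_index([demo_doc])
        comps = (Term("text", "preterm"), Term("text", "delivery"))
        assert count_phrase_matches(idx, comps, 8, True, "demo") == 1

    def test_order_violation(self, demo_doc):
        idx = build_index([demo_doc])
        comps = (Term("text", "delivery"), Term("text", "preterm"))
        assert count_phrase_matches(idx, comps, 8, True, "demo") == 0
        # unordered direction-free: still a match
        assert count_phrase_matches(idx, comps, 8, False, "demo") == 1

    def test_window_measured_from_end_of_first(self):
        # spans: x at 0 len 1 (end 1), y at 3 len 1 -> gap start-end = 2
        doc = make_doc("d", ["x", "q", "q", "y", "q"])
        idx = build_index([doc])
        comps = (Term("text", "x"), Term("text", "y"))
        assert count_phrase_matches(idx, comps, 2, True, "d") == 1
        assert count_phrase_matches(idx, comps, 1, True, "d") == 0

    def test_last_artifact_may_end_outside_window(self):
        doc = make_doc("d", ["x", "y", "z"], {"ne": [("LONG", 1, 2)]})
        idx = build_index([doc])
        comps = (Term("text", "x"), Term("ne", "LONG"))
        # LONG starts at 1 (within window) but ends at 3
        assert count_phrase_matches(idx, comps, 1, True, "d") == 1

    def test_overlap_forbidden_when_ordered(self):
        doc = make_doc("d", ["x", "y"], {"ne": [("LONG", 0, 2)]})
        idx = build_index([doc])
        comps = (Term("ne", "LONG"), Term("text", "y"))
        assert count_phrase_matches(idx, comps, 8, True, "d") == 0
        assert count_phrase_matches(idx, comps, 8, False, "d") == 1

    def test_tuple_counting_counts_all_pairs(self):
        doc = make_doc("d", ["x", "x", "y", "y"])
        idx = build_index([doc])
        comps = (Term("text", "x"), Term("text", "y"))
        assert count_phrase_matches(idx, comps, 8, True, "d") == 4

    def test_same_value_components_use_distinct_artifacts(self):
        doc = make_doc("d", ["x", "q", "x"])
        idx = build_index([doc])
        comps = (Term("text", "x"), Term("text", "x"))
        # ordered: (0,2) only; unordered: (0,2) and (2,0)
        assert count_phrase_matches(idx, comps, 8, True, "d") == 1
        assert count_phrase_matches(idx, comps, 8, False, "d") == 2

    def test_list_component_is_disjunctive(self, demo_doc):
        idx = build_index([demo_doc])
        lst = ListNode((Term("cui", "C0151526"), Term("text", "nothere")))
        comps = (Term("text", "pregnancy"), lst)
        assert count_phrase_matches(idx, comps, 8, True, "demo") == 1

    def test_bad_arguments(self, demo_doc):
        idx = build_index([demo_doc])
        with pytest.raises(ValueError):
            count_phrase_matches(idx, (Term("text", "a"),), 8, True, "demo")
        with pytest.raises(ValueError):
            count_phrase_matches(
                idx, (Term("text", "a"), Term("text", "b")), 0, True, "demo"
            )

    def test_cross_layer_matches_bruteforce(self, small_corpus, small_index):
        rng = random.Random(0)
        docs = small_corpus.docs
        for _ in range(30):
            doc = rng.choice(docs)
            layers = ["text", "lemma", "pos"] + (["cui"] if "cui" in doc.layers else [])
            comps = []
            for _ in range(rng.choice((2, 2, 3))):
                layer = rng.choice(layers)
                arts = oracle.artifacts_of(doc, layer)
                comps.append(Term(layer, rng.choice(arts).value))
            w = rng.randint(1, 16)
            o = rng.random() < 0.5
            assert count_phrase_matches(small_index, comps, w, o, doc.doc_id) == \
                oracle.phrase_count(doc, comps, w, o)

    def test_window_monotonicity_and_ordering_bound(self, small_corpus, small_index):
        rng = random.Random(1)
        doc = small_corpus.docs[0]
        for _ in range(10):
            arts = oracle.artifacts_of(doc, "text")
            comps = (Term("text", rng.choice(arts).value),
                     Term("text", rng.choice(arts).value))
            prev = 0
            for w in range(1, 17):
                ordered = count_phrase_matches(small_index, comps, w, True, doc.doc_id)
                unordered = count_phrase_matches(small_index, comps, w, False, doc.doc_id)
                assert unordered >= ordered
                assert ordered >= prev
                prev = ordered


class TestScorePhrase:
    def test_hand_computed_eq2(self):
        doc = make_doc("d", ["pregnancy", "with", "preterm", "delivery"])
        idx = build_index([doc])
        phrase = Phrase(8, True, (Term("text", "preterm"), Term("text", "delivery")))
        p = score_phrase(idx, phrase, "d", MU10)
        # #ph_D=1, #ph_C=1, |D|=|**D**|=4, mu=10 -> (1 + 10*0.25)/(4+10)
        assert p == pytest.approx(0.25, abs=1e-12)

    def test_never_cooccurring_phrase(self, ab_corpus):
        _, idx = ab_corpus
        phrase = Phrase(2, True, (Term("text", "c"), Term("text", "zzz")))
        assert score_phrase(idx, phrase, "d1", MU10) == 0.0

    def test_mixed_layer_uses_largest_layer_size(self, demo_doc):
        idx = build_index([demo_doc])
        phrase = Phrase(8, True, (Term("text", "pregnancy"), Term("cui", "C0151526")))
        p = score_phrase(idx, phrase, "demo", MU10)
        # layers text (size 4) and cui (size 3): max = 4 in both denominators
        assert p == pytest.approx((1 + 10 * (1 / 4)) / (4 + 10), abs=1e-12)

    def test_mixed_layer_matches_bruteforce(self, small_corpus, small_index):
        rng = random.Random(2)
        docs = small_corpus.docs
        scorer = Scorer(small_index, MU10)
        for _ in range(10):
            doc = rng.choice(docs)
            layers = ["text", "lemma"] + (["cui"] if "cui" in doc.layers else [])
            comps = tuple(
                Term(l, rng.choice(oracle.artifacts_of(doc, l)).value)
                for l in rng.sample(layers, 2)
            )
            phrase = Phrase(rng.randint(1, 12), rng.random() < 0.5, comps)
            assert scorer.score_phrase(phrase, doc.doc_id) == pytest.approx(
                oracle.phrase_prob(docs, doc, phrase, 10.0), abs=1e-12
            )

    def test_product_denominator_flag(self, demo_doc):
        idx = build_index([demo_doc])
        phrase = Phrase(8, True, (Term("text", "pregnancy"), Term("cui", "C0151526")))
        cfg = SmoothingConfig(mu=10.0, product_denominator=True)
        p = score_phrase(idx, phrase, "demo", cfg)
        assert p == pytest.approx((1 + 10 * (1 / 12)) / (12 + 10), abs=1e-12)


class TestScoreList:
    def test_standalone_equals_product_of_terms(self, small_corpus, small_index):
        scorer = Scorer(small_index, MU10)
        doc = small_corpus.docs[0]
        t1 = Term("text", doc.tokens[0])
        t2 = Term("lemma", doc.layers["lemma"][1].value)
        lst = ListNode((t1, t2))
        expected = scorer.score_term(t1, doc.doc_id) * scorer.score_term(t2, doc.doc_id)
        assert scorer.score_list(lst, doc.doc_id) == pytest.approx(expected, rel=1e-12)

    def test_singleton_identity(self, small_corpus, small_index):
        scorer = Scorer(small_index, MU10)
        doc = small_corpus.docs[0]
        term = Term("text", doc.tokens[0])
        assert scorer.score_list(ListNode((term,)), doc.doc_id) == \
            scorer.score_term(term, doc.doc_id)

    def test_empty_list_rejected(self, small_index):
        with pytest.raises(ValueError):
            score_list(small_index, ListNode(()), "doc0000", MU10)


class TestScoreRelation:
    @pytest.fixture
    def rel_corpus(self):
        docs = [
            make_doc(
                "r1",
                ["doctor", "gave", "plavix", "today"],
                {
                    "lemma": [("doctor", 0, 1), ("give", 1, 1), ("plavix", 2, 1),
                              ("today", 3, 1)],
                    "pos": [("NN", 0, 1), ("VB", 1, 1), ("NNP", 2, 1), ("RB", 3, 1)],
                },
                {"dep": [("nsubj", 1, 1, 0, 1), ("dobj", 1, 1, 2, 1)]},
            ),
            make_doc(
                "r2",
                ["nurse", "gave", "advice"],
                {
                    "lemma": [("nurse", 0, 1), ("give", 1, 1), ("advice", 2, 1)],
                    "pos": [("NN", 0, 1), ("VB", 1, 1), ("NN", 2, 1)],
                },
                {"dep": [("dobj", 1, 1, 2, 1)]},
            ),
        ]
        return docs, build_index(docs)

    def test_lemma_give_proper_noun_child(self, rel_corpus):
        docs, idx = rel_corpus
        rel = Relation("dep", WILDCARD, Term("lemma", "give"), Term("pos", "NNP"))
        scorer = Scorer(idx, MU10)
        assert scorer.collection_relation_count(rel) == 1
        p1 = scorer.score_relation(rel, "r1")
        # #t_D=1, |D|_dep=2, #t_C=1, |**D**|_dep=3
        assert p1 == pytest.approx((1 + 10 * (1 / 3)) / (2 + 10), abs=1e-12)
        p2 = scorer.score_relation(rel, "r2")
        assert p2 == pytest.approx((0 + 10 * (1 / 3)) / (1 + 10), abs=1e-12)

    def test_wildcards_count_layer_size(self, rel_corpus):
        docs, idx = rel_corpus
        rel = Relation("dep", WILDCARD, WILDCARD, WILDCARD)
        scorer = Scorer(idx)
        for doc in docs:
            from layerlm.scoring_engine import _relation_count
            assert _relation_count(idx, rel, doc.doc_id) == \
                len(doc.relation_layers["dep"])

    def test_label_pattern_filters(self, rel_corpus):
        docs, idx = rel_corpus
        from layerlm.scoring_engine import _relation_count
        rel = Relation("dep", "dobj", WILDCARD, WILDCARD)
        assert _relation_count(idx, rel, "r1") == 1
        assert _relation_count(idx, rel, "r2") == 1
        rel = Relation("dep", "nsubj", WILDCARD, WILDCARD)
        assert _relation_count(idx, rel, "r2") == 0

    def test_matches_bruteforce(self, small_corpus, small_index):
        rng = random.Random(3)
        docs = small_corpus.docs
        scorer = Scorer(small_index, MU10)
        labels = ["nsubj", "dobj", "amod", "prep", "conj", WILDCARD]
        for _ in range(15):
            doc = rng.choice(docs)
            def pat():
                if rng.random() < 0.3:
                    return WILDCARD
                layer = rng.choice(["lemma", "pos", "text"])
                return Term(layer, rng.choice(oracle.artifacts_of(doc, layer)).value)
            rel = Relation("dep", rng.choice(labels), pat(), pat())
            assert scorer.score_relation(rel, doc.doc_id) == pytest.approx(
                oracle.relation_prob(docs, doc, rel, 10.0), abs=1e-12
            )

    def test_unknown_relation_layer(self, small_index):
        with pytest.raises(UnknownLayerError):
            score_relation(small_index, Relation("nope", "*", WILDCARD, WILDCARD),
                           "doc0000", MU10)


class TestScoreDocument:
    def test_text_terms_reduce_to_query_likelihood(self, ab_corpus):
        docs, idx = ab_corpus
        query = parse_query("a b")
        for doc in docs:
            got = score_document(idx, query, doc.doc_id, MU10).score
            want = sum(
                math.log(oracle.term_prob(docs, doc, t, 10.0)) for t in query.nodes
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_all_oov_query(self, ab_corpus):
        docs, idx = ab_corpus
        query = parse_query("zzz qqq")
        for doc in docs:
            sd = score_document(idx, query, doc.doc_id, MU10)
            assert sd.score == 0.0 and sd.contributions == []

    def test_doubling_weights_preserves_order(self, small_corpus, small_index):
        doc = small_corpus.docs[0]
        base = parse_query(f"{doc.tokens[0]} {doc.tokens[1]}^2")
        doubled = parse_query(f"{doc.tokens[0]}^2 {doc.tokens[1]}^4")
        r1 = [s.doc_id for s in rank(small_index, base, MU10)]
        r2 = [s.doc_id for s in rank(small_index, doubled, MU10)]
        assert r1 == r2

    def test_score_is_weighted_sum_of_contributions(self, small_corpus, small_index):
        doc = small_corpus.docs[0]
        query = parse_query(f"{doc.tokens[0]}^0.85 {doc.tokens[2]}^0.1")
        sd = score_document(small_index, query, doc.doc_id, MU10)
        assert sd.score == pytest.approx(
            sum(w * lp for _, lp, w in sd.contributions), abs=1e-12
        )

    def test_unindexed_layer_raises(self, small_index):
        with pytest.raises(UnknownLayerError, match="nope"):
            score_document(small_index, parse_query("nope:x"), "doc0000", MU10)


class TestRank:
    def test_unique_containing_doc_ranks_first(self):
        docs = [make_doc("a", ["x", "y"]), make_doc("b", ["y", "z"]),
                make_doc("c", ["needle", "y"])]
        idx = build_index(docs)
        ranked = rank(idx, parse_query("needle"), MU10)
        assert ranked[0].doc_id == "c"

    def test_tie_break_by_doc_id(self):
        docs = [make_doc("b", ["x"]), make_doc("a", ["x"])]
        idx = build_index(docs)
        ranked = rank(idx, parse_query("x"), MU10)
        assert [s.doc_id for s in ranked] == ["a", "b"]

    def test_k_cutoff_and_validation(self, small_index):
        ranked = rank(small_index, parse_query("w0001"), MU10, k=3)
        assert len(ranked) == 3
        with pytest.raises(ValueError):
            rank(small_index, parse_query("w0001"), MU10, k=0)

    def test_equals_bruteforce_ranking(self, small_corpus, small_index):
        docs = small_corpus.docs
        query = parse_query(f"{docs[0].tokens[0]} {docs[1].tokens[0]}")
        got = [s.doc_id for s in rank(small_index, query, MU10)]
        assert got == oracle.rank_docs(docs, query, 10.0)
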