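import numpy as np
import pytest

from clinmine import EntitySpan, GenConfig, RelationRule, generate_corpus
from clinmine.encoder import EmbedderParams
from clinmine.relations import (
    DEFAULT_DESCRIPTORS,
    NO_RELATION,
    REConfig,
    REParams,
    RelationDescriptor,
    RelationError,
    RelationInstance,
    classify_relation,
    embed_text,
    extract_relations,
    mark_instance,
    re_distance,
    strip_markers,
    train_re,
)
from clinmine.synthetic import relation_instances


class TestMarking:
    def test_marker_insertion_order(self):
        inst = RelationInstance(
            ("fever", "after", "covid"),
            head=EntitySpan(2, 3, "Disease"),
            tail=EntitySpan(0, 1, "Symptom"),
        )
        assert mark_instance(inst) == (
            "[E2]", "fever", "[/E2]", "after", "[E1]", "covid", "[/E1]"
        )

    def test_adjacent_spans_bracket_correctly(self):
        inst = RelationInstance(
            ("covid", "fever"), EntitySpan(0, 1, "D"), EntitySpan(1, 2, "S")
        )
        assert mark_instance(inst) == (
            "[E1]", "covid", "[/E1]", "[E2]", "fever", "[/E2]"
        )

    def test_identical_spans_rejected(self):
        with pytest.raises(RelationError):
            RelationInstance(("a",), EntitySpan(0, 1, "D"), EntitySpan(0, 1, "S"))

    def test_mark_strip_round_trip(self):
        inst = RelationInstance(
            ("a", "b", "c", "d"), EntitySpan(0, 2, "D"), EntitySpan(3, 4, "S")
        )
        assert strip_markers(mark_instance(inst)) == inst.tokens


class TestEmbedding:
    @pytest.fixture()
    def emb(self):
        return EmbedderParams(dim=16, vocab_buckets=128, window=0, seed=2)

    def test_unit_norm(self, emb):
        v = embed_text(["fever", "cough"], emb)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_deterministic(self, emb):
        a = embed_text(["x", "y"], emb)
        b = embed_text(["x", "y"], EmbedderParams(16, 128, 0, 2))
        np.testing.assert_array_equal(a, b)

    def test_single_token_is_normalized_table_row(self, emb):
        from clinmine.encoder import token_bucket

        v = embed_text(["fever"], emb)
        row = emb.table[token_bucket("fever", 128)]
        np.testing.assert_allclose(v, row / np.linalg.norm(row), atol=1e-12)

    def test_distance_identities(self):
        u = np.array([1.0, 0.0])
        assert re_distance(u, u) == pytest.approx(0.0)
        assert re_distance(u, -u) == pytest.approx(2.0)
        assert re_distance(u, np.array([0.0, 1.0])) == pytest.approx(1.0)
        with pytest.raises(RelationError):
            re_distance(u, np.zeros(2))


def _labeled_instances(seed=0, n_docs=100, rules=None):
    cfg = GenConfig(n_docs=n_docs, seed=seed,
                    relation_rules=rules or GenConfig().relation_rules)
    corpus = generate_corpus(cfg)
    return [
        RelationInstance(s.texts, r.head, r.tail, r.label)
        for s, r in relation_instances(corpus)
    ]


class TestTraining:
    def test_loss_decreases(self):
        insts = _labeled_instances(n_docs=40)
        _, log = train_re(insts, DEFAULT_DESCRIPTORS, REConfig(seed=0, epochs=6))
        assert log[5] < log[0]

    def test_same_seed_identical_parameters(self):
        insts = _labeled_instances(n_docs=20)
        p1, _ = train_re(insts, DEFAULT_DESCRIPTORS, REConfig(seed=3, epochs=3))
        p2, _ = train_re(insts, DEFAULT_DESCRIPTORS, REConfig(seed=3, epochs=3))
        np.testing.assert_array_equal(p1.embedder.table, p2.embedder.table)

    def test_missing_descriptor_rejected(self):
        insts = _labeled_instances(n_docs=20)
        with pytest.raises(RelationError, match="descriptor"):
            train_re(insts, DEFAULT_DESCRIPTORS[:1], REConfig(seed=0, epochs=1))

    def test_holdout_accuracy_on_cue_token_relations(self):
        insts = _labeled_instances(n_docs=120, seed=1)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(insts))
        cut = int(0.7 * len(insts))
        train = [insts[i] for i in idx[:cut]]
        test = [insts[i] for i in idx[cut:]]
        params, _ = train_re(train, DEFAULT_DESCRIPTORS, REConfig(seed=1, epochs=20))
        acc = np.mean(
            [classify_relation(t, DEFAULT_DESCRIPTORS, params)[0] == t.label
             for t in test]
        )
        assert acc >= 0.9


class TestClassification:
    def test_exact_descriptor_match_gives_zero_distance(self):
        emb = EmbedderParams(8, 64, 0, 5)
        params = REParams(emb, threshold=2.0)
        desc = RelationDescriptor("rel", ("alpha", "beta"))
        inst = RelationInstance(("alpha", "beta"), EntitySpan(0, 1, "A"),
                                EntitySpan(1, 2, "B"))
        # descriptor equal to the *marked* instance text
        marked = mark_instance(inst)
        desc_same = RelationDescriptor("rel", marked)
        label, dist = classify_relation(inst, [desc_same, desc], params)
        assert label == "rel"
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_zero_threshold_without_exact_match_is_no_relation(self):
        emb = EmbedderParams(8, 64, 0, 5)
        params = REParams(emb, threshold=0.0)
        desc = RelationDescriptor("rel", ("unrelated", "words"))
        inst = RelationInstance(("alpha", "beta"), EntitySpan(0, 1, "A"),
                                EntitySpan(1, 2, "B"))
        label, _ = classify_relation(inst, [desc], params)
        assert label == NO_RELATION

    def test_tie_breaks_to_first_descriptor(self):
        emb = EmbedderParams(8, 64, 0, 5)
        params = REParams(emb, threshold=2.0)
        d1 = RelationDescriptor("first", ("same", "text"))
        d2 = RelationDescriptor("second", ("same", "text"))
        inst = RelationInstance(("a", "b"), EntitySpan(0, 1, "A"),
                                EntitySpan(1, 2, "B"))
        label, _ = classify_relation(inst, [d1, d2], params)
        assert label == "first"

    def test_duplicate_descriptors_do_not_change_outcome(self):
        insts = _labeled_instances(n_docs=30)
        params, _ = train_re(insts, DEFAULT_DESCRIPTORS, REConfig(seed=0, epochs=5))
        doubled = list(DEFAULT_DESCRIPTORS) + list(DEFAULT_DESCRIPTORS)
        for inst in insts[:20]:
            assert (classify_relation(inst, DEFAULT_DESCRIPTORS, params)[0]
                    == classify_relation(inst, doubled, params)[0])


class TestExtraction:
    def _trained(self):
        insts = _labeled_instances(n_docs=120, seed=2)
        params, _ = train_re(insts, DEFAULT_DESCRIPTORS,
                             REConfig(seed=2, epochs=20))
        return params

    def test_sentence_without_pairs_yields_nothing(self):
        from clinmine.corpus import AnnotatedSentence, Corpus

        params = self._trained()
        c = Corpus([AnnotatedSentence("d", 0, ("just", "filler"))])
        rules = {("Drug", "Symptom"): ["drug-causes-effect"]}
        assert extract_relations(c, [frozenset()], rules, DEFAULT_DESCRIPTORS,
                                 params) == []

    def test_recall_on_planted_relations(self):
        params = self._trained()
        cfg = GenConfig(n_docs=60, seed=9)
        corpus = generate_corpus(cfg)
        gold = relation_instances(corpus)
        rules = {
            ("Disease", "Symptom"): ["symptom-follows-disease"],
            ("Drug", "Symptom"): ["drug-causes-effect"],
        }
        records = extract_relations(corpus, [s.spans for s in corpus], rules,
                                    DEFAULT_DESCRIPTORS, params)
        found = {(r["doc_id"], r["sent_id"], tuple(r["head"]), tuple(r["tail"]),
                  r["label"]) for r in records}
        hits = sum(
            1 for s, rel in gold
            if (s.doc_id, s.sent_id,
                (rel.head.start, rel.head.end, rel.head.label),
                (rel.tail.start, rel.tail.end, rel.tail.label),
                rel.label) in found
        )
        assert hits / len(gold) >= 0.8

    def test_lowering_threshold_never_extracts_more(self):
        params = self._trained()
        cfg = GenConfig(n_docs=30, seed=4)
        corpus = generate_corpus(cfg)
        rules = {
            ("Disease", "Symptom"): ["symptom-follows-disease"],
            ("Drug", "Symptom"): ["drug-causes-effect"],
        }
        counts = []
        for theta in (1.2, 0.8, 0.4, 0.0):
            params.threshold = theta
            counts.append(len(extract_relations(
                corpus, [s.spans for s in corpus], rules,
                DEFAULT_DESCRIPTORS, params)))
        assert counts == sorted(counts, reverse=True)


def test_one_shot_accuracy_beats_chance():
    """One labeled example per class still organizes the space better than
    guessing among the descriptors."""
    rules = (
        RelationRule("Disease", "Symptom", "rel-a", 0.25, "cue-alpha"),
        RelationRule("Drug", "Symptom", "rel-b", 0.25, "cue-beta"),
        RelationRule("Disease", "Drug", "rel-c", 0.25, "cue-gamma"),
        RelationRule("Symptom", "SDOH", "rel-d", 0.25, "cue-delta"),
    )
    descriptors = [
        RelationDescriptor("rel-a", ("relation", "marked", "by", "cue-alpha")),
        RelationDescriptor("rel-b", ("relation", "marked", "by", "cue-beta")),
        RelationDescriptor("rel-c", ("relation", "marked", "by", "cue-gamma")),
        RelationDescriptor("rel-d", ("relation", "marked", "by", "cue-delta")),
    ]
    insts = _labeled_instances(seed=6, n_docs=150, rules=rules)
    by_label = {}
    for inst in insts:
        by_label.setdefault(inst.label, []).append(inst)
    assert set(by_label) == {"rel-a", "rel-b", "rel-c", "rel-d"}
    train = [v[0] for v in by_label.values()]  # exactly one shot per class
    test = [i for v in by_label.values() for i in v[1:]]
    params, _ = train_re(train, descriptors, REConfig(seed=6, epochs=30))
    acc = np.mean(
        [classify_relation(t, descriptors, params)[0] == t.label for t in test]
    )
    assert acc > 1.0 / len(descriptors)
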