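import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinmine import EntitySpan, entity_prf, fleiss_kappa, kfold, split_70_15_15, two_sample_t
from clinmine.evaluation import EvaluationError, token_accuracy


def S(*triples):
    return {EntitySpan(a, b, lab) for a, b, lab in triples}


class TestEntityPRF:
    def test_perfect_prediction(self):
        gold = [S((0, 2, "D"))]
        report = entity_prf(gold, gold)
        assert (report.precision, report.recall, report.f1) == (1.0, 1.0, 1.0)

    def test_hand_example_half_recall(self):
        gold = [S((0, 2, "D"), (3, 4, "S"))]
        pred = [S((0, 2, "D"))]
        report = entity_prf(gold, pred)
        assert report.precision == 1.0
        assert report.recall == 0.5
        assert report.f1 == pytest.approx(2 / 3)

    def test_boundary_mismatch_scores_zero(self):
        report = entity_prf([S((0, 2, "D"))], [S((0, 1, "D"))])
        assert (report.precision, report.recall, report.f1) == (0.0, 0.0, 0.0)

    def test_label_mismatch_scores_zero(self):
        report = entity_prf([S((0, 2, "D"))], [S((0, 2, "S"))])
        assert report.f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            entity_prf([S()], [S(), S()])

    def test_per_label_breakdown(self):
        gold = [S((0, 1, "D"), (2, 3, "S"))]
        pred = [S((0, 1, "D"), (2, 3, "D"))]
        report = entity_prf(gold, pred)
        assert report.per_label["D"][0] == 0.5  # precision: 1 of 2 D preds
        assert report.per_label["S"][1] == 0.0  # recall: S missed

    def test_agrees_with_independent_reference_scorer(self, rng):
        """Cross-check against a from-scratch exact-match scorer over many
        random prediction sets."""
        labels = ["D", "S", "X"]
        for _ in range(100):
            n_sent = int(rng.integers(1, 6))
            gold, pred = [], []
            for _s in range(n_sent):
                def rand_spans():
                    out, cur = set(), 0
                    while cur < 8:
                        if rng.random() < 0.4:
                            end = cur + int(rng.integers(1, 3))
                            out.add(EntitySpan(cur, min(end, 8),
                                               labels[int(rng.integers(3))]))
                            cur = end
                        else:
                            cur += 1
                    return out
                gold.append(rand_spans())
                pred.append(rand_spans())
            report = entity_prf(gold, pred)
            # independent reference: flatten with sentence index, then count
            g_all = {(i, s.start, s.end, s.label) for i, ss in enumerate(gold)
                     for s in ss}
            p_all = {(i, s.start, s.end, s.label) for i, ss in enumerate(pred)
                     for s in ss}
            tp = len(g_all & p_all)
            ref_p = tp / len(p_all) if p_all else 0.0
            ref_r = tp / len(g_all) if g_all else 0.0
            ref_f = 2 * ref_p * ref_r / (ref_p + ref_r) if ref_p + ref_r else 0.0
            assert report.precision == pytest.approx(ref_p)
            assert report.recall == pytest.approx(ref_r)
            assert report.f1 == pytest.approx(ref_f)

    def test_token_accuracy(self):
        assert token_accuracy([("O", "B-D")], [("O", "O")]) == 0.5


class TestSplits:
    def test_sizes_70_15_15(self, medium_corpus):
        train, dev, test = split_70_15_15(medium_corpus, seed=0)
        n = len(medium_corpus.doc_ids)
        assert len(train.doc_ids) == int(0.70 * n)
        assert len(dev.doc_ids) == int(0.15 * n)
        assert len(test.doc_ids) == n - int(0.70 * n) - int(0.15 * n)

    def test_partition_and_document_grouping(self, small_corpus):
        parts = split_70_15_15(small_corpus, seed=1)
        all_docs = [d for p in parts for d in p.doc_ids]
        assert sorted(all_docs) == sorted(small_corpus.doc_ids)
        assert len(all_docs) == len(set(all_docs))
        assert sum(len(p) for p in parts) == len(small_corpus)

    def test_same_seed_same_split(self, small_corpus):
        a = split_70_15_15(small_corpus, seed=5)
        b = split_70_15_15(small_corpus, seed=5)
        for x, y in zip(a, b):
            assert x.doc_ids == y.doc_ids

    def test_too_few_documents_rejected(self, tiny_corpus):
        two = tiny_corpus.subset(tiny_corpus.doc_ids[:2])
        with pytest.raises(EvaluationError):
            split_70_15_15(two, seed=0)


class TestKFold:
    def test_fold_sizes_balanced(self, small_corpus):
        folds = kfold(small_corpus, k=5, seed=0)
        sizes = [len(test.doc_ids) for _, test in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(small_corpus.doc_ids)

    def test_folds_partition_corpus(self, small_corpus):
        folds = kfold(small_corpus, k=5, seed=2)
        seen = [d for _, test in folds for d in test.doc_ids]
        assert sorted(seen) == sorted(small_corpus.doc_ids)
        for train, test in folds:
            assert not set(train.doc_ids) & set(test.doc_ids)

    def test_leave_one_out(self, tiny_corpus):
        n = len(tiny_corpus.doc_ids)
        folds = kfold(tiny_corpus, k=n, seed=0)
        assert all(len(test.doc_ids) == 1 for _, test in folds)

    def test_k_below_two_rejected(self, tiny_corpus):
        with pytest.raises(EvaluationError):
            kfold(tiny_corpus, k=1, seed=0)


class TestWelch:
    def test_identical_samples(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_swap_negates_t_keeps_p(self):
        t1, p1 = two_sample_t([1, 2, 3], [4, 6, 8])
        t2, p2 = two_sample_t([4, 6, 8], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_textbook_value(self):
        # means 2 and 5, each sample variance 1, n=3:
        # t = (2-5)/sqrt(1/3 + 1/3) = -3.674235..., Welch df = 4
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346141747673, abs=1e-12)
        assert p == pytest.approx(0.021311641128756713, abs=1e-9)

    def test_constant_equal_samples_defined(self):
        assert two_sample_t([2, 2], [2, 2]) == (0.0, 1.0)


class TestFleissKappa:
    def test_perfect_agreement(self):
        table = np.array([[3, 0], [0, 3], [3, 0]])
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_derived_two_item_table(self):
        # rows (2,0), (0,2): P_bar = 1, P_e = 0.5 -> kappa = 1
        assert fleiss_kappa([[2, 0], [0, 2]]) == pytest.approx(1.0)
        # rows (1,1), (1,1): P_bar = 0, P_e = 0.5 -> kappa = -1
        assert fleiss_kappa([[1, 1], [1, 1]]) == pytest.approx(-1.0)

    def test_invariant_to_category_permutation(self, rng):
        table = rng.multinomial(4, [0.3, 0.4, 0.3], size=10)
        k1 = fleiss_kappa(table)
        k2 = fleiss_kappa(table[:, [2, 0, 1]])
        assert k1 == pytest.approx(k2)

    def test_degenerate_single_category(self):
        assert fleiss_kappa([[4, 0], [4, 0]]) == 1.0

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        for _ in range(20):
            table = rng.multinomial(5, [0.2, 0.5, 0.3], size=8)
            assert fleiss_kappa(table) == pytest.approx(sm_kappa(table))


@st.composite
def rating_tables(draw):
    n_raters = draw(st.integers(2, 5))
    n_items = draw(st.integers(2, 8))
    n_cats = draw(st.integers(2, 4))
    table = []
    for _ in range(n_items):
        votes = draw(
            st.lists(st.integers(0, n_cats - 1), min_size=n_raters,
                     max_size=n_raters)
        )
        row = [votes.count(c) for c in range(n_cats)]
        table.append(row)
    return table


@settings(max_examples=100, derandomize=True)
@given(rating_tables())
def test_fleiss_kappa_bounded(rows):
    """kappa lies in [-1, 1] on every valid rating table."""
    assert -1.0 - 1e-9 <= fleiss_kappa(np.array(rows)) <= 1.0 + 1e-9
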