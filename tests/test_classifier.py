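"""CDR3 encoding, kernel, GP classifier behavior and AUROC."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from leukimm.classifier import (
    ClassifierConfig,
    TCRSpecificityClassifier,
    auroc,
    cross_validate,
    encode_cdr3,
    kernel_matrix,
    predict_repertoire,
    train,
)
from leukimm.repertoire import Clonotype, Repertoire
from leukimm.simulate import RepertoireSimConfig, make_repertoire


class TestEncode:
    def test_center_gap_layout(self):
        v = encode_cdr3("CASSLG", max_len=8).reshape(8, 20)
        occupied = np.flatnonzero(np.abs(v).sum(axis=1) > 0)
        np.testing.assert_array_equal(occupied, [0, 1, 2, 5, 6, 7])
        # residue order preserved around the central gap
        np.testing.assert_allclose(v[0], encode_cdr3("C", 1).reshape(1, 20)[0])
        np.testing.assert_allclose(v[7], encode_cdr3("G", 1).reshape(1, 20)[0])

    def test_full_length_has_no_gap(self):
        v = encode_cdr3("CASSLGYE", max_len=8).reshape(8, 20)
        assert (np.abs(v).sum(axis=1) > 0).all()

    def test_rows_unit_norm(self):
        v = encode_cdr3("W", max_len=1).reshape(1, 20)
        assert np.linalg.norm(v[0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", ["CASS1F", "CASSBF", ""])
    def test_illegal_inputs(self, bad):
        with pytest.raises(ValueError):
            encode_cdr3(bad, max_len=22)

    def test_too_long_errors(self):
        with pytest.raises(ValueError, match="longer"):
            encode_cdr3("C" * 23, max_len=22)


class TestKernel:
    def test_diagonal_is_signal_variance(self):
        X = np.random.default_rng(0).normal(size=(5, 8))
        K = kernel_matrix(X, X, lengthscale=2.0, signal_variance=3.0)
        np.testing.assert_allclose(np.diag(K), 3.0)

    def test_large_lengthscale_limit(self):
        X = np.random.default_rng(1).normal(size=(4, 6))
        K = kernel_matrix(X, X, lengthscale=1e8, signal_variance=2.0)
        np.testing.assert_allclose(K, 2.0, rtol=1e-10)

    def test_symmetric_and_psd(self):
        X = np.random.default_rng(2).normal(size=(50, 10))
        K = kernel_matrix(X, X, lengthscale=1.5, signal_variance=1.2)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestAUROC:
    def test_worked_examples(self):
        assert auroc([0.9, 0.2], [1, 0]) == 1.0
        assert auroc([0.5, 0.5, 0.5], [1, 0, 1]) == 0.5
        assert auroc([0.9, 0.4, 0.2, 0.6], [1, 1, 0, 0]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # rounded to force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert auroc(scores, labels) == pytest.approx(brute, abs=1e-12)
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a1 = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(a1, abs=1e-12)
        assert auroc(3 * scores - 7, labels) == pytest.approx(a1, abs=1e-12)


def _planted_sets(n_pos, n_neg, seed, mutation_rate=0.0, jitter=0, lengths=(14, 14)):
    cfg = RepertoireSimConfig(
        n_clones=n_pos + n_neg + 50,
        total_reads=(n_pos + n_neg + 50) * 10,
        n_specific=n_pos,
        mutation_rate=mutation_rate,
        core_position_jitter=jitter,
        cdr3_length_range=lengths,
        seed=seed,
    )
    rep, labels = make_repertoire(cfg)
    seqs = np.array(rep.cdr3s(), dtype=object)
    return list(seqs[labels]), list(seqs[~labels][:n_neg])


class TestTraining:
    def test_separable_toy_reaches_training_auroc_one(self):
        pos, neg = _planted_sets(30, 60, seed=10)
        clf = train(pos, neg, ClassifierConfig(seed=0))
        p = clf.predict_proba(pos + neg)[:, 1]
        assert auroc(p, [1] * 30 + [0] * 60) == 1.0

    def test_too_few_examples(self):
        with pytest.raises(ValueError, match="at least 10"):
            train(["CASSF"] * 5, ["CASRF"] * 20)

    def test_identical_positives_and_controls_give_prior(self):
        # same sequences in both classes at 1:2 -> probability near 1/3
        base, _ = _planted_sets(30, 0, seed=11)
        clf = TCRSpecificityClassifier(iterations=2000).fit(
            base * 3, [1] * 30 + [0] * 60
        )
        p = clf.predict_proba(base)[:, 1]
        np.testing.assert_allclose(p, 1 / 3, atol=0.05)

    def test_permuted_labels_give_chance_heldout(self):
        pos, neg = _planted_sets(60, 140, seed=12)
        seqs = np.array(pos + neg, dtype=object)
        rng = np.random.default_rng(0)
        y = rng.permutation([1] * 60 + [0] * 140)
        clf = TCRSpecificityClassifier(iterations=2000).fit(
            list(seqs[:150]), y[:150]
        )
        held = auroc(clf.predict_proba(list(seqs[150:]))[:, 1], y[150:])
        assert 0.25 <= held <= 0.75  # chance level, modest-n sampling noise

    def test_deterministic_given_seed(self):
        pos, neg = _planted_sets(15, 30, seed=13)
        c1 = train(pos, neg, ClassifierConfig(iterations=100, seed=5))
        c2 = train(pos, neg, ClassifierConfig(iterations=100, seed=5))
        np.testing.assert_array_equal(
            c1.predict_proba(pos + neg), c2.predict_proba(pos + neg)
        )

    def test_save_load_roundtrip(self, tmp_path):
        pos, neg = _planted_sets(15, 30, seed=14)
        clf = train(pos, neg, ClassifierConfig(iterations=100, seed=1))
        clf.save(tmp_path / "model.json")
        back = TCRSpecificityClassifier.load(tmp_path / "model.json")
        np.testing.assert_allclose(
            clf.predict_proba(pos + neg), back.predict_proba(pos + neg), atol=1e-10
        )


class TestCrossValidate:
    def test_folds_partition_data(self):
        pos, neg = _planted_sets(20, 40, seed=15)
        report = cross_validate(pos, neg, ClassifierConfig(iterations=50, folds=5, seed=0))
        folds = report.fold_assignments
        assert len(folds) == 60
        assert set(folds) == set(range(5))
        assert report.mean_auroc == pytest.approx(np.mean(report.fold_aurocs))

    def test_separable_data_perfect_cv(self):
        pos, neg = _planted_sets(30, 60, seed=10)
        report = cross_validate(pos, neg, ClassifierConfig(iterations=400, folds=5, seed=0))
        assert report.mean_auroc == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def trained_clf():
    """Classifier trained on a noisy planted design (mutation 5%, jitter 1)."""
    pos, neg = _planted_sets(
        100, 200, seed=17, mutation_rate=0.05, jitter=1, lengths=(11, 17)
    )
    return train(pos, neg, ClassifierConfig(seed=0))


class TestPredictRepertoire:
    def test_fraction_is_read_weighted(self, trained_clf):
        # probe clones drawn from a disjoint generator seed: one planted,
        # one background
        posp, negp = _planted_sets(5, 5, seed=99, lengths=(11, 17))
        rep = Repertoire(
            "r", [Clonotype(posp[0], count=30), Clonotype(negp[0], count=70)]
        ).recompute_frequencies()
        probs, frac, count = predict_repertoire(trained_clf, rep, threshold=0.5)
        assert probs[0] > 0.5 > probs[1]
        assert frac == pytest.approx(0.3)
        assert count == 1

    def test_threshold_above_max_gives_zero(self, trained_clf):
        posp, _ = _planted_sets(5, 5, seed=99, lengths=(11, 17))
        rep = Repertoire("r", [Clonotype(posp[0], count=10)]).recompute_frequencies()
        _, frac, count = predict_repertoire(trained_clf, rep, threshold=0.999999)
        assert frac == 0.0 and count == 0

    def test_recovers_planted_read_fraction(self, trained_clf):
        # 5% of reads planted with the training motif; classifier trained on
        # disjoint planted sequences should recover a fraction near 0.05
        sp_cfg = RepertoireSimConfig(
            n_clones=60, total_reads=1000, n_specific=60, seed=21,
            mutation_rate=0.05, core_position_jitter=1,
        )
        bg_cfg = RepertoireSimConfig(n_clones=940, total_reads=19_000, seed=22)
        sp, _ = make_repertoire(sp_cfg)
        bg, _ = make_repertoire(bg_cfg)
        rep = Repertoire(
            "mix", sp.clonotypes + bg.clonotypes
        ).recompute_frequencies()
        _, frac, _ = predict_repertoire(trained_clf, rep, threshold=0.5)
        assert 0.03 <= frac <= 0.07
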