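"""Backend training contracts: normalization, determinism, balance,
augmentation arithmetic, and learnability."""

import numpy as np
import pytest

from chemtaste import smiles as sm
from chemtaste.classifiers.base import TrainConfig, TrainedModel, train, train_augmented
from chemtaste.classifiers.token_nn import TokenNNConfig, TokenTasteNet
from chemtaste.classifiers.tokenizer import Vocab
from chemtaste.labels import LABEL_ORDER, TasteLabel
from chemtaste.records import MoleculeRecord
from chemtaste.synthetic import RuleSet, generate_dataset


def _tiny_records():
    return [
        sm.standardize(MoleculeRecord("CC(=O)O", {TasteLabel.SOUR})),
        sm.standardize(MoleculeRecord("OCC(O)CO", {TasteLabel.SWEET})),
        sm.standardize(MoleculeRecord("CCC(=O)N", {TasteLabel.UMAMI})),
        sm.standardize(MoleculeRecord("c1ccccc1", {TasteLabel.BITTER})),
        sm.standardize(MoleculeRecord("CCCCCC", {TasteLabel.UNDEFINED})),
    ]


class TestTrainContracts:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TrainConfig(backend="gbt"))

    def test_single_class_rejected(self):
        recs = [sm.standardize(MoleculeRecord("C" * n, {TasteLabel.UNDEFINED})) for n in (2, 3, 4)]
        with pytest.raises(ValueError, match="2 classes"):
            train(recs, TrainConfig(backend="rf"))

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            TrainConfig(backend="svm")

    @pytest.mark.parametrize("backend", ["gbt", "rf", "balanced_rf"])
    def test_probability_normalization_tree_backends(self, backend, clean_split):
        config = TrainConfig(backend=backend, n_trees=30, seed=0)
        model = train(clean_split.train[:200], config)
        for rec in clean_split.test[:50]:
            p = model.predict_proba(rec.canonical_smiles)
            assert p.shape == (5,)
            assert np.all(p >= 0) and np.all(p <= 1)
            assert abs(p.sum() - 1.0) < 1e-9

    def test_probability_normalization_token_backend(self, token_model, clean_split):
        for rec in clean_split.test[:50]:
            p = token_model.predict_proba(rec.canonical_smiles)
            assert abs(p.sum() - 1.0) < 1e-9

    def test_tree_prediction_form_invariant(self, gbt_model):
        assert np.allclose(
            gbt_model.predict_proba("CCO"), gbt_model.predict_proba("OCC")
        )

    def test_same_config_same_seed_identical(self, clean_split):
        probe = [r.canonical_smiles for r in clean_split.test[:20]]
        preds = []
        for _ in range(2):
            model = train(
                clean_split.train[:200],
                TrainConfig(backend="token_lm", learning_rate=1e-2, epochs=3, seed=5),
            )
            preds.append(np.stack([model.predict_proba(s) for s in probe]))
        assert np.array_equal(preds[0], preds[1])

    def test_argmax_tie_breaks_to_lowest_index(self):
        class Uniform:
            backend = "stub"

            def predict_proba(self, smiles):
                return np.full(5, 0.2)

        model = TrainedModel.__new__(TrainedModel)
        model.backend = "stub"
        model.impl = None
        model.predict_proba = lambda s: np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        assert TrainedModel.predict_label(model, "CCO") is TasteLabel.SWEET


class TestBalancedRandomForest:
    def test_each_bootstrap_balanced(self):
        recs = generate_dataset(300, RuleSet(class_mix=(0.8, 0.05, 0.05, 0.05, 0.05)), seed=1)
        model = train(recs, TrainConfig(backend="balanced_rf", n_trees=10, seed=0))
        labels = np.array([r.label.index for rec in [recs] for r in rec])
        for idx in model.impl.resampled_indices_:
            counts = np.bincount(labels[idx], minlength=5)
            present = counts[counts > 0]
            assert len(set(present.tolist())) == 1  # equal per-class counts


class TestLearnability:
    def test_gbt_separable_training_accuracy(self, clean_split, gbt_model):
        correct = sum(
            gbt_model.predict_label(r.canonical_smiles) is r.label
            for r in clean_split.train[:200]
        )
        assert correct / 200 == 1.0

    def test_token_lm_overfits_two_samples(self):
        recs = [
            sm.standardize(MoleculeRecord("CC(=O)O", {TasteLabel.SOUR})),
            sm.standardize(MoleculeRecord("CCCCCC", {TasteLabel.UNDEFINED})),
        ]
        model = train(
            recs,
            TrainConfig(backend="token_lm", learning_rate=5e-2, epochs=300, seed=0),
        )
        assert model.predict_proba("CC(=O)O")[TasteLabel.SOUR.index] > 0.99
        assert model.predict_proba("CCCCCC")[TasteLabel.UNDEFINED.index] > 0.99

    def test_token_lm_training_loss_decreases(self, clean_split):
        vocab_src = [r.canonical_smiles for r in clean_split.train[:150]]
        net = TokenTasteNet(
            Vocab.from_corpus(vocab_src),
            TokenNNConfig(learning_rate=1e-2, epochs=5, seed=0),
        )
        labels = [r.label.index for r in clean_split.train[:150]]
        history = net.fit(vocab_src, labels)
        assert history["train_loss"][-1] < history["train_loss"][0]


class TestAugmentation:
    def test_row_arithmetic_and_class_proportions(self):
        recs = generate_dataset(100, RuleSet(), seed=3)
        from chemtaste.classifiers.base import _augment_rows, _training_rows

        xs, ys = _training_rows(recs)
        ax, ay = _augment_rows(xs, ys, 10, seed=0)
        assert len(ax) == 1000
        before = np.bincount(ys, minlength=5) / len(ys)
        after = np.bincount(ay, minlength=5) / len(ay)
        assert np.allclose(before, after)

    def test_augmented_rows_canonicalize_to_parent(self):
        recs = generate_dataset(20, RuleSet(), seed=4)
        from chemtaste.classifiers.base import _augment_rows, _training_rows

        xs, ys = _training_rows(recs)
        ax, _ = _augment_rows(xs, ys, 5, seed=0)
        for i, parent in enumerate(xs):
            for v in ax[i * 5 : (i + 1) * 5]:
                assert sm.canonicalize(v) == sm.canonicalize(parent)

    def test_augmentation_requires_token_backend(self, clean_split):
        with pytest.raises(ValueError, match="token_lm"):
            train(clean_split.train[:50], TrainConfig(backend="gbt", augmentation_fold=10))

    def test_train_augmented_requires_fold(self, clean_split):
        with pytest.raises(ValueError, match="augmentation_fold"):
            train_augmented(clean_split.train[:50], TrainConfig(backend="token_lm"))


class TestFormRobustness:
    def test_augmentation_reduces_label_flips_on_noncanonical_input(self):
        """A positional token model trained on canonical SMILES only flips
        labels when fed alternative forms; uniform 10-fold augmentation
        brings the flip rate to at most 5% and strictly below the
        unaugmented rate."""
        from chemtaste.synthetic import flip_labels

        recs = generate_dataset(1200, RuleSet(), seed=11)
        from chemtaste.curation import split_dataset

        split = split_dataset(recs, 0.15, seed=5)
        noisy_train = flip_labels(split.train, 0.1, seed=3)
        plain = train(
            noisy_train,
            TrainConfig(backend="token_lm", learning_rate=1e-2, epochs=20,
                        use_positional=True, seed=0),
        )
        augmented = train(
            noisy_train,
            TrainConfig(backend="token_lm", learning_rate=1e-2, epochs=2,
                        augmentation_fold=10, use_positional=True, seed=0),
        )

        def flip_rate(model):
            flips = 0
            for i, r in enumerate(split.test):
                canon_label = model.predict_label(r.canonical_smiles)
                variant = sm.enumerate_random_smiles(r.canonical_smiles, 3, seed=123 + i)[-1]
                flips += model.predict_label(variant) is not canon_label
            return flips / len(split.test)

        rate_plain, rate_aug = flip_rate(plain), flip_rate(augmented)
        assert rate_aug <= 0.05
        assert rate_plain > rate_aug


class TestSerialization:
    def test_token_model_round_trip(self, token_model, clean_split, tmp_path):
        path = tmp_path / "model.bin"
        token_model.save(path)
        back = TrainedModel.load(path)
        for rec in clean_split.test[:10]:
            assert np.allclose(
                back.predict_proba(rec.canonical_smiles),
                token_model.predict_proba(rec.canonical_smiles),
            )

    def test_tree_model_round_trip(self, gbt_model, clean_split, tmp_path):
        path = tmp_path / "model.bin"
        gbt_model.save(path)
        back = TrainedModel.load(path)
        for rec in clean_split.test[:10]:
            assert np.allclose(
                back.predict_proba(rec.canonical_smiles),
                gbt_model.predict_proba(rec.canonical_smiles),
            )
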