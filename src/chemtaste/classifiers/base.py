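"""Training configuration, backend dispatch, and the trained-model surface.

Every backend maps a SMILES string to a normalized probability vector over
the five taste classes. Tree backends (gbt, rf, balanced_rf) featurize the
*canonical* molecular graph and are therefore invariant to the SMILES form;
the token_lm backend reads the string itself and is not — which is exactly
what SMILES augmentation and the consensus confidence metric exploit.
"""

from __future__ import annotations

import io
import json
import pickle
import zipfile
from dataclasses import asdict as _dc_asdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..labels import ABSTAIN, LABEL_ORDER, N_CLASSES, TasteLabel
from .. import smiles as sm
from ..featurization import DEFAULT_DESCRIPTORS, featurize
from .tokenizer import Vocab
from .token_nn import TokenNNConfig, TokenTasteNet
from .trees import BalancedRandomForest, make_gbt, make_rf

BACKENDS = ("gbt", "rf", "balanced_rf", "token_lm")

_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Hyperparameters for all backends; unused fields are ignored.

    Defaults mirror the reference training protocol: 150 trees for the
    forests; for the token model a batch size of 16, weight decay 0.01,
    20 epochs unaugmented or 2 epochs with 10-fold augmentation. The
    default learning rate of 1e-5 is a fine-tuning rate appropriate for a
    large pre-trained checkpoint; a small model trained from scratch needs
    a larger one (1e-2 is a reasonable start).
    """

    backend: str = "gbt"
    n_trees: int = 150
    max_depth: int = 6
    gbt_learning_rate: float = 0.3
    learning_rate: float = 1e-5
    batch_size: int = 16
    weight_decay: float = 0.01
    epochs: int = 20
    augmentation_fold: int = 0
    radius: int = 2
    n_bits: int = 1024
    use_descriptors: bool = False
    descriptor_names: tuple = DEFAULT_DESCRIPTORS
    embed_dim: int = 32
    hidden_dim: int = 64
    max_len: int = 160
    use_positional: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; choose from {BACKENDS}")
        if self.epochs < 1 or self.n_trees < 1 or self.batch_size < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0 or self.gbt_learning_rate <= 0:
            raise ValueError("learning rates must be positive")


class TrainedModel:
    """A fitted backend plus everything needed to score a SMILES string."""

    def __init__(self, backend: str, config: TrainConfig, impl, vocab: Vocab | None = None):
        self.backend = backend
        self.config = config
        self.impl = impl
        self.vocab = vocab

    # ------------------------------------------------------------- scoring
    def _features(self, smiles: str) -> np.ndarray:
        canon = sm.canonicalize(smiles)
        return featurize(
            canon,
            radius=self.config.radius,
            n_bits=self.config.n_bits,
            use_descriptors=self.config.use_descriptors,
            descriptor_names=self.config.descriptor_names,
        ).combined

    def predict_proba(self, smiles: str) -> np.ndarray:
        """Normalized probability vector over the five classes."""
        if self.backend == "token_lm":
            p = self.impl.predict_proba_smiles(smiles)
        else:
            p = self.impl.predict_proba(self._features(smiles)[None, :])[0]
        total = p.sum()
        if not np.isfinite(total) or total <= 0:
            raise RuntimeError(f"degenerate probability vector for {smiles!r}")
        return p / total

    def predict_label(self, smiles: str) -> TasteLabel:
        """Argmax label; exact ties resolve to the lowest label index."""
        return LABEL_ORDER[int(np.argmax(self.predict_proba(smiles)))]

    # ------------------------------------------------------- serialization
    def save(self, path) -> None:
        """Write a versioned archive: config JSON + parameter blob."""
        meta = {
            "format_version": _FORMAT_VERSION,
            "backend": self.backend,
            "canonicalization": sm.CANONICALIZATION_SPEC,
            "label_order": [l.value for l in LABEL_ORDER],
            "config": {
                **_dc_asdict(self.config),
                "descriptor_names": list(self.config.descriptor_names),
            },
        }
        with zipfile.ZipFile(Path(path), "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            if self.backend == "token_lm":
                zf.writestr("vocab.json", json.dumps(self.vocab.to_dict()))
                buf = io.BytesIO()
                np.savez(buf, **self.impl.state_arrays())
                zf.writestr("params.npz", buf.getvalue())
            else:
                zf.writestr("estimator.pkl", pickle.dumps(self.impl))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            cfg_dict = meta["config"]
            cfg_dict["descriptor_names"] = tuple(cfg_dict["descriptor_names"])
            config = TrainConfig(**cfg_dict)
            if meta["backend"] == "token_lm":
                vocab = Vocab.from_dict(json.loads(zf.read("vocab.json")))
                net = TokenTasteNet(vocab, _token_nn_config(config))
                with np.load(io.BytesIO(zf.read("params.npz"))) as arrs:
                    net.load_state_arrays(dict(arrs))
                return cls("token_lm", config, net, vocab)
            impl = pickle.loads(zf.read("estimator.pkl"))
            return cls(meta["backend"], config, impl)


def _token_nn_config(config: TrainConfig) -> TokenNNConfig:
    return TokenNNConfig(
        embed_dim=config.embed_dim,
        hidden_dim=config.hidden_dim,
        max_len=config.max_len,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        weight_decay=config.weight_decay,
        epochs=config.epochs,
        use_positional=config.use_positional,
        seed=config.seed,
    )


def _training_rows(records) -> tuple[list[str], np.ndarray]:
    """Flatten records to single-label (smiles, label index) rows."""
    xs, ys = [], []
    for rec in records:
        s = rec.canonical_smiles or rec.raw_smiles
        for lab in rec.labels:
            xs.append(s)
            ys.append(lab.index)
    return xs, np.asarray(ys, dtype=int)


def train(records, config: TrainConfig) -> TrainedModel:
    """Fit the configured backend on labeled records.

    With ``augmentation_fold`` k >= 1 and the token_lm backend, every
    training molecule is expanded to k synonymous SMILES carrying its
    label before fitting. The expansion factor is uniform across classes:
    augmenting classes unevenly is a known failure mode that drives the
    model to the majority label, so it is not supported.

    Raises
    ------
    ValueError
        On an empty training set or a single-class training set.
    """
    xs, ys = _training_rows(records)
    if len(xs) == 0:
        raise ValueError("empty training set")
    if len(set(ys.tolist())) < 2:
        raise ValueError("training set must contain at least 2 classes")

    if config.backend == "token_lm":
        if config.augmentation_fold >= 1:
            xs, ys = _augment_rows(xs, ys, config.augmentation_fold, config.seed)
        vocab = Vocab.from_corpus(xs)
        net = TokenTasteNet(vocab, _token_nn_config(config))
        net.fit(xs, ys)
        return TrainedModel("token_lm", config, net, vocab)

    if config.augmentation_fold >= 1:
        raise ValueError("SMILES augmentation applies only to the token_lm backend")
    X = np.stack(
        [
            featurize(
                s,
                radius=config.radius,
                n_bits=config.n_bits,
                use_descriptors=config.use_descriptors,
                descriptor_names=config.descriptor_names,
            ).combined
            for s in xs
        ]
    )
    if config.backend == "gbt":
        present = np.unique(ys)
        remap = {c: i for i, c in enumerate(present)}
        impl = make_gbt(config.n_trees, config.max_depth, config.gbt_learning_rate, config.seed)
        impl.fit(X, np.asarray([remap[c] for c in ys]))
        impl.classes_override = present  # restore 5-class indexing
        model = TrainedModel("gbt", config, impl)
    elif config.backend == "rf":
        impl = make_rf(config.n_trees, config.seed)
        impl.fit(X, ys)
        model = TrainedModel("rf", config, impl)
    elif config.backend == "balanced_rf":
        impl = BalancedRandomForest(n_trees=config.n_trees, seed=config.seed)
        impl.fit(X, ys)
        model = TrainedModel("balanced_rf", config, impl)
    else:  # pragma: no cover
        raise AssertionError(config.backend)
    return model


def _augment_rows(xs, ys, k: int, seed: int):
    """Uniform k-fold synonymous-SMILES expansion of every training row."""
    if k < 1:
        raise ValueError(f"augmentation_fold must be >= 1, got {k}")
    out_x, out_y = [], []
    for i, (s, y) in enumerate(zip(xs, ys)):
        canon = sm.canonicalize(s)
        for variant in sm.enumerate_random_smiles(canon, k, seed=(seed + i) % 2**31):
            out_x.append(variant)
            out_y.append(y)
    return out_x, np.asarray(out_y, dtype=int)


def train_augmented(records, config: TrainConfig) -> TrainedModel:
    """Convenience wrapper: train the token model on augmented rows."""
    if config.augmentation_fold < 1:
        raise ValueError("train_augmented requires augmentation_fold >= 1")
    return train(records, config)
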