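"""A compact token-level neural classifier over SMILES strings.

The network reads the tokenized string directly, so unlike the
fingerprint-based tree backends it sees the *representation* of the
molecule, not its graph: two SMILES forms of the same molecule are
different inputs. That sensitivity is what makes training-time SMILES
augmentation meaningful and what the test-time consensus vote measures.

Architecture: learned token embeddings plus learned positional embeddings,
a width-3 convolutional tanh layer (each position sees its left and right
neighbor, so bigram evidence such as a carbonyl ``=O`` lands on the atom
tokens that carry it), masked mean pooling over positions, and a linear
head producing one logit per taste class. All forward and backward passes
are explicit numpy, which gives exact analytic gradients with respect to
the embedded input — the quantity integrated-gradients attribution needs.
The smooth tanh nonlinearity keeps the attribution path integral
well-behaved under Riemann discretization.

Training follows the standard fine-tuning recipe: categorical
cross-entropy, mini-batches, decoupled weight decay (AdamW), an internal
evaluation split, and selection of the checkpoint with the lowest
evaluation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..labels import N_CLASSES
from .tokenizer import Vocab


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class TokenNNConfig:
    embed_dim: int = 32
    hidden_dim: int = 64
    max_len: int = 160
    learning_rate: float = 1e-2
    batch_size: int = 16
    weight_decay: float = 0.01
    epochs: int = 20
    eval_fraction: float = 0.1
    use_positional: bool = False
    seed: int = 0


class TokenTasteNet:
    """Token-embedding classifier with explicit backprop."""

    def __init__(self, vocab: Vocab, config: TokenNNConfig):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h, L, V = config.embed_dim, config.hidden_dim, config.max_len, len(vocab)
        scale = 0.1
        self.params = {
            "E": rng.normal(0, scale, (V, d)),
            "P": rng.normal(0, scale, (L, d)),
            "Wl": rng.normal(0, scale, (d, h)),
            "Wc": rng.normal(0, scale, (d, h)),
            "Wr": rng.normal(0, scale, (d, h)),
            "b1": np.zeros(h),
            "W2": rng.normal(0, scale, (h, N_CLASSES)),
            "b2": np.zeros(N_CLASSES),
        }
        self.params["E"][Vocab.PAD] = 0.0
        if not config.use_positional:
            self.params["P"][:] = 0.0

    # ---------------------------------------------------------------- embed
    def encode(self, smiles: str) -> np.ndarray:
        ids = self.vocab.encode(smiles)[: self.config.max_len]
        return np.asarray(ids, dtype=np.int64)

    def embed(self, ids: np.ndarray) -> np.ndarray:
        """Input representation: token embedding + positional embedding, (L, d)."""
        return self.params["E"][ids] + self.params["P"][: len(ids)]

    def embed_tokens(self, ids: np.ndarray) -> np.ndarray:
        """Token-content embeddings only, (L, d) — the attribution input.

        Attribution scales token content from a zero baseline while the
        positional embeddings stay fixed along the path, so attribution
        mass reflects what the token *is*, not where it sits.
        """
        return self.params["E"][ids].copy()

    def logits_from_token_embedding(self, X_tok: np.ndarray) -> np.ndarray:
        return self.logits_from_embedded(X_tok + self.params["P"][: len(X_tok)])

    def grad_logit_wrt_token_embedding(self, X_tok: np.ndarray, target: int) -> np.ndarray:
        # positions enter additively, so the gradient passes through unchanged
        return self.grad_logit_wrt_embedded(
            X_tok + self.params["P"][: len(X_tok)], target
        )

    # -------------------------------------------------------------- forward
    @staticmethod
    def _shift_left(X: np.ndarray) -> np.ndarray:
        """X[t+1] at position t (zero past the end); works on (L,d) or (B,L,d)."""
        out = np.zeros_like(X)
        out[..., :-1, :] = X[..., 1:, :]
        return out

    @staticmethod
    def _shift_right(X: np.ndarray) -> np.ndarray:
        """X[t-1] at position t (zero before the start)."""
        out = np.zeros_like(X)
        out[..., 1:, :] = X[..., :-1, :]
        return out

    def _preactivation(self, X: np.ndarray) -> np.ndarray:
        p = self.params
        return (
            self._shift_right(X) @ p["Wl"]
            + X @ p["Wc"]
            + self._shift_left(X) @ p["Wr"]
            + p["b1"]
        )

    def logits_from_embedded(self, X: np.ndarray) -> np.ndarray:
        """Class logits from an embedded sequence (L, d); differentiable in X."""
        H = np.tanh(self._preactivation(X))
        pooled = H.mean(axis=0)
        return pooled @ self.params["W2"] + self.params["b2"]

    def grad_logit_wrt_embedded(self, X: np.ndarray, target: int) -> np.ndarray:
        """d logit[target] / dX, shape (L, d) — analytic, used by attribution."""
        p = self.params
        H = np.tanh(self._preactivation(X))
        dpre = (1.0 - H**2) * (p["W2"][:, target] / X.shape[0])
        # H_t depends on X_{t-1} (Wl), X_t (Wc), X_{t+1} (Wr)
        return (
            self._shift_left(dpre @ p["Wl"].T)
            + dpre @ p["Wc"].T
            + self._shift_right(dpre @ p["Wr"].T)
        )

    def predict_proba_smiles(self, smiles: str) -> np.ndarray:
        ids = self.encode(smiles)
        if len(ids) == 0:
            return np.full(N_CLASSES, 1.0 / N_CLASSES)
        return _softmax(self.logits_from_embedded(self.embed(ids)))

    # ------------------------------------------------------------- training
    def _batch_arrays(self, id_lists, max_len):
        B = len(id_lists)
        ids = np.zeros((B, max_len), dtype=np.int64)
        mask = np.zeros((B, max_len), dtype=float)
        for i, seq in enumerate(id_lists):
            ids[i, : len(seq)] = seq
            mask[i, : len(seq)] = 1.0
        return ids, mask

    def _forward_backward(self, ids, mask, y):
        """One mini-batch step; returns (mean loss, gradients dict)."""
        p = self.params
        B, L = ids.shape
        lengths = mask.sum(axis=1, keepdims=True)  # (B,1)
        X = (p["E"][ids] + p["P"][:L][None, :, :]) * mask[:, :, None]
        Xl, Xr = self._shift_right(X), self._shift_left(X)
        pre = Xl @ p["Wl"] + X @ p["Wc"] + Xr @ p["Wr"] + p["b1"]
        H = np.tanh(pre) * mask[:, :, None]
        pooled = H.sum(axis=1) / lengths
        logits = pooled @ p["W2"] + p["b2"]
        probs = _softmax(logits)
        loss = -np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean()

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {
            "W2": pooled.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dpooled = dlogits @ p["W2"].T
        dH = (dpooled[:, None, :] / lengths[:, :, None]) * mask[:, :, None]
        dpre = dH * (1.0 - np.tanh(pre) ** 2)
        dpref = dpre.reshape(B * L, -1)
        grads["Wl"] = Xl.reshape(B * L, -1).T @ dpref
        grads["Wc"] = X.reshape(B * L, -1).T @ dpref
        grads["Wr"] = Xr.reshape(B * L, -1).T @ dpref
        grads["b1"] = dpref.sum(axis=0)
        dX = (
            self._shift_left(dpre @ p["Wl"].T)
            + dpre @ p["Wc"].T
            + self._shift_right(dpre @ p["Wr"].T)
        ) * mask[:, :, None]
        gE = np.zeros_like(p["E"])
        np.add.at(gE, ids.reshape(-1), dX.reshape(B * L, -1))
        gE[Vocab.PAD] = 0.0
        grads["E"] = gE
        gP = np.zeros_like(p["P"])
        gP[:L] = dX.sum(axis=0)
        grads["P"] = gP
        return loss, grads

    def _eval_loss(self, id_lists, y):
        total = 0.0
        for seq, yi in zip(id_lists, y):
            if len(seq) == 0:
                total += np.log(N_CLASSES)
                continue
            probs = _softmax(self.logits_from_embedded(self.embed(np.asarray(seq))))
            total += -np.log(max(probs[yi], 1e-12))
        return total / len(id_lists)

    def fit(self, smiles_list, labels, verbose: bool = False) -> dict:
        """Train with AdamW and best-checkpoint-by-eval-loss selection.

        Returns a history dict with per-epoch train and eval losses.
        """
        cfg = self.config
        id_lists = [list(self.encode(s)) for s in smiles_list]
        y = np.asarray(labels, dtype=np.int64)
        rng = np.random.default_rng(cfg.seed + 1)

        n = len(id_lists)
        order = rng.permutation(n)
        n_eval = max(1, int(round(cfg.eval_fraction * n))) if n >= 10 else 0
        eval_idx = order[:n_eval]
        train_idx = order[n_eval:]
        train_ids = [id_lists[i] for i in train_idx]
        train_y = y[train_idx]
        eval_ids = [id_lists[i] for i in eval_idx]
        eval_y = y[eval_idx]

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v2 = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        best_params = {k: p.copy() for k, p in self.params.items()}
        history = {"train_loss": [], "eval_loss": []}

        for epoch in range(cfg.epochs):
            perm = rng.permutation(len(train_ids))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(perm), cfg.batch_size):
                batch = perm[start : start + cfg.batch_size]
                seqs = [train_ids[i] for i in batch]
                maxlen = max((len(s) for s in seqs), default=1) or 1
                ids, mask = self._batch_arrays(seqs, maxlen)
                loss, grads = self._forward_backward(ids, mask, train_y[batch])
                epoch_loss += loss
                n_batches += 1
                step += 1
                for k in self.params:
                    if k == "P" and not cfg.use_positional:
                        continue
                    g = grads[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v2[k] = beta2 * v2[k] + (1 - beta2) * g**2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v2[k] / (1 - beta2**step)
                    self.params[k] -= cfg.learning_rate * (
                        mhat / (np.sqrt(vhat) + eps)
                    )
                    if k in ("Wl", "Wc", "Wr", "W2", "E", "P"):
                        self.params[k] -= cfg.learning_rate * cfg.weight_decay * self.params[k]
                self.params["E"][Vocab.PAD] = 0.0
            train_loss = epoch_loss / max(n_batches, 1)
            eval_loss = (
                self._eval_loss(eval_ids, eval_y) if n_eval else train_loss
            )
            history["train_loss"].append(train_loss)
            history["eval_loss"].append(eval_loss)
            if eval_loss < best_loss:
                best_loss = eval_loss
                best_params = {k: p.copy() for k, p in self.params.items()}
            if verbose:
                print(f"epoch {epoch + 1}: train {train_loss:.4f} eval {eval_loss:.4f}")

        self.params = best_params
        return history

    # ------------------------------------------------------- serialization
    def state_arrays(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(arrays[k])
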