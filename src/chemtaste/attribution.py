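"""Integrated-gradients attribution, mapped from SMILES tokens to atoms.

For a scoring function F, input x and baseline x', the attribution of
feature i is

    (x_i - x'_i) * integral_0^1 dF/dx_i (x' + a (x - x')) da,

approximated with a midpoint Riemann sum over ``n_steps`` points. The
method satisfies the completeness property — attributions sum to
F(x) - F(x') in the limit — which :func:`completeness_gap` measures as a
numerical diagnostic, and the sensitivity axiom (a feature that alone
changes the output receives nonzero attribution).

For the token model, x is the embedded token sequence and the baseline is
the zero embedding. Per-token attributions (summed over embedding
dimensions) are mapped onto atoms through the tokenizer's token-to-atom
index map; attribution mass on non-atom tokens (bonds, ring digits,
parentheses) is reported separately as a residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labels import TasteLabel
from .classifiers.tokenizer import tokenize


@dataclass
class AttributionConfig:
    n_steps: int = 64
    baseline: np.ndarray | None = None  # None = zero baseline

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")


@dataclass
class AtomAttribution:
    smiles: str
    target_label: TasteLabel
    atom_scores: np.ndarray
    residual_nonatom: float

    @property
    def total(self) -> float:
        return float(self.atom_scores.sum() + self.residual_nonatom)


class UnsupportedBackendError(TypeError):
    """Raised when attribution is requested for a gradient-free backend."""


def integrated_gradients(value_fn, grad_fn, x, cfg: AttributionConfig) -> np.ndarray:
    """Midpoint-rule integrated gradients of a differentiable scorer.

    Parameters
    ----------
    value_fn : callable
        Maps an input array to a scalar score F(x) (used only by
        :func:`completeness_gap`; accepted here for interface symmetry).
    grad_fn : callable
        Maps an input array to dF/dx of the same shape.
    x : ndarray
        The input representation.
    cfg : AttributionConfig
        Baseline and path discretization.
    """
    x = np.asarray(x, dtype=float)
    baseline = cfg.baseline if cfg.baseline is not None else np.zeros_like(x)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != x.shape:
        raise ValueError(f"baseline shape {baseline.shape} != input shape {x.shape}")
    delta = x - baseline
    grad_sum = np.zeros_like(x)
    for m in range(cfg.n_steps):
        alpha = (m + 0.5) / cfg.n_steps
        g = np.asarray(grad_fn(baseline + alpha * delta), dtype=float)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient along integration path")
        grad_sum += g
    return delta * grad_sum / cfg.n_steps


def completeness_gap(value_fn, grad_fn, x, cfg: AttributionConfig) -> float:
    """|sum of attributions - (F(x) - F(baseline))|, a quality diagnostic."""
    x = np.asarray(x, dtype=float)
    baseline = cfg.baseline if cfg.baseline is not None else np.zeros_like(x)
    attr = integrated_gradients(value_fn, grad_fn, x, cfg)
    return float(abs(attr.sum() - (value_fn(x) - value_fn(baseline))))


def atom_attributions(
    model,
    smiles: str,
    target_label: TasteLabel,
    cfg: AttributionConfig | None = None,
) -> AtomAttribution:
    """Per-atom signed attribution of the target-class logit.

    Positive scores support the target label, negative scores detract.
    Only the token_lm backend has a gradient path; tree backends raise
    :class:`UnsupportedBackendError` (see
    :func:`permutation_feature_importance` for a non-equivalent fallback).
    """
    cfg = cfg or AttributionConfig()
    if getattr(model, "backend", None) != "token_lm":
        raise UnsupportedBackendError(
            "atom attribution requires the token_lm backend; tree backends "
            "have no gradient path (use permutation_feature_importance instead)"
        )
    net = model.impl
    ids = net.encode(smiles)
    tokens = tokenize(smiles)[: len(ids)]
    x = net.embed_tokens(ids)
    target = target_label.index
    attr = integrated_gradients(
        lambda z: float(net.logits_from_token_embedding(z)[target]),
        lambda z: net.grad_logit_wrt_token_embedding(z, target),
        x,
        cfg,
    )
    token_scores = attr.sum(axis=1)  # sum over embedding dimensions
    n_atoms = sum(1 for _, a in tokens if a is not None)
    atom_scores = np.zeros(n_atoms)
    residual = 0.0
    for (tok, atom_idx), score in zip(tokens, token_scores):
        if atom_idx is None:
            residual += float(score)
        else:
            atom_scores[atom_idx] = float(score)
    return AtomAttribution(
        smiles=smiles,
        target_label=target_label,
        atom_scores=atom_scores,
        residual_nonatom=residual,
    )


def export_heatmap(attr: AtomAttribution, path, draw: bool = False) -> None:
    """Write per-atom scores as a JSON sidecar; optionally draw a depiction.

    The JSON round-trips scores exactly. With ``draw=True`` a 2D depiction
    with green (positive) / red (negative) atom shading is written next to
    the sidecar as a PNG using RDKit similarity maps.
    """
    path = Path(path)
    payload = {
        "smiles": attr.smiles,
        "target_label": attr.target_label.value,
        "atom_scores": [float(s) for s in attr.atom_scores],
        "residual_nonatom": float(attr.residual_nonatom),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    if draw:
        _draw_similarity_map(attr, path.with_suffix(".png"))


def load_heatmap(path) -> AtomAttribution:
    payload = json.loads(Path(path).read_text())
    return AtomAttribution(
        smiles=payload["smiles"],
        target_label=TasteLabel.from_string(payload["target_label"]),
        atom_scores=np.asarray(payload["atom_scores"], dtype=float),
        residual_nonatom=float(payload["residual_nonatom"]),
    )


def _draw_similarity_map(attr: AtomAttribution, png_path) -> None:  # pragma: no cover
    from rdkit import Chem
    from rdkit.Chem.Draw import SimilarityMaps
    import matplotlib

    matplotlib.use("Agg")
    mol = Chem.MolFromSmiles(attr.smiles)
    fig = SimilarityMaps.GetSimilarityMapFromWeights(
        mol, [float(s) for s in attr.atom_scores]
    )
    fig.savefig(str(png_path), bbox_inches="tight")


def permutation_feature_importance(model, records, seed: int = 0, n_repeats: int = 5):
    """Permutation importance for tree backends over fingerprint features.

    This is a global, feature-level diagnostic and is *not* equivalent to
    integrated gradients: it ranks fingerprint bits/descriptors by how much
    shuffling them degrades accuracy, with no per-atom or per-molecule
    resolution.
    """
    from sklearn.inspection import permutation_importance as _perm

    if getattr(model, "backend", None) == "token_lm":
        raise UnsupportedBackendError(
            "permutation importance applies to feature-vector (tree) backends"
        )
    X = np.stack([model._features(r.canonical_smiles or r.raw_smiles) for r in records])
    y = np.asarray([r.label.index for r in records])
    est = model.impl.estimator if hasattr(model.impl, "estimator") else model.impl
    override = getattr(model.impl, "classes_override", None)
    if override is not None:  # estimator was fit on remapped labels
        remap = {c: i for i, c in enumerate(override)}
        y = np.asarray([remap[c] for c in y])
    result = _perm(est, X, y, n_repeats=n_repeats, random_state=seed)
    return result.importances_mean
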