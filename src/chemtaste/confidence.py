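"""Test-time-augmentation consensus with abstention.

A molecule is predicted on k synonymous SMILES strings; the modal label is
accepted only when its multiplicity reaches the agreement threshold
(default: strict unanimity, threshold = k), otherwise the model abstains.
For backends that are invariant to SMILES form (the fingerprint tree
models) every vote is identical and support is trivially 1.0; for the
token model, disagreement across forms is an inexpensive signal of
prediction unreliability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .labels import ABSTAIN, TasteLabel
from . import smiles as sm


@dataclass
class ConsensusResult:
    per_variant_labels: list[TasteLabel]
    accepted_label: object  # TasteLabel or ABSTAIN
    agreement: int
    k: int
    threshold: int

    @property
    def accepted(self) -> bool:
        return self.accepted_label is not ABSTAIN


def consensus_predict(
    model,
    smiles: str,
    k: int = 10,
    threshold: int | None = None,
    seed: int = 0,
) -> ConsensusResult:
    """Vote over k synonymous SMILES; abstain unless agreement >= threshold.

    Votes are argmax labels of each variant prediction. A tie for the modal
    label is resolved conservatively by abstaining, even when the tied
    multiplicity reaches the threshold. ``threshold=None`` means strict
    unanimity (threshold = k).
    """
    if threshold is None:
        threshold = k
    if not 1 <= threshold <= k:
        raise ValueError(f"threshold must be in [1, {k}], got {threshold}")
    canon = sm.canonicalize(smiles)
    variants = sm.enumerate_random_smiles(canon, k, seed=seed)
    labels = [model.predict_label(v) for v in variants]
    counts = Counter(labels)
    modal_label, agreement = max(
        counts.items(), key=lambda kv: (kv[1], -kv[0].index)
    )
    tied = sum(1 for c in counts.values() if c == agreement) > 1
    accepted = agreement >= threshold and not tied
    return ConsensusResult(
        per_variant_labels=labels,
        accepted_label=modal_label if accepted else ABSTAIN,
        agreement=agreement,
        k=k,
        threshold=threshold,
    )


def support_fraction(results: list[ConsensusResult]) -> float:
    """Fraction of consensus results carrying an accepted (non-abstain) label."""
    if not results:
        raise ValueError("support_fraction of an empty result list")
    return sum(r.accepted for r in results) / len(results)
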