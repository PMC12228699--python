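"""Molecule records: one SMILES with taste label(s) and provenance."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .labels import TasteLabel


@dataclass
class MoleculeRecord:
    """A molecule-taste association as one dataset row.

    Multi-taste molecules appear as several records sharing a canonical
    SMILES but carrying different labels (the dataset convention); the
    ``labels`` set therefore usually holds a single label per row.

    Attributes
    ----------
    raw_smiles : str
        SMILES string as found in the source file.
    labels : frozenset[TasteLabel]
        Non-empty set of taste labels for this row.
    source : str
        Free-text provenance tag.
    canonical_smiles : str | None
        Canonical form; ``None`` until standardization.
    mol_weight_da : float | None
        Molecular weight in Daltons; ``None`` until standardization.
    """

    raw_smiles: str
    labels: frozenset = field(default_factory=frozenset)
    source: str = ""
    canonical_smiles: str | None = None
    mol_weight_da: float | None = None

    def __post_init__(self):
        self.labels = frozenset(self.labels)
        if not self.labels:
            raise ValueError("MoleculeRecord requires at least one label")
        for lab in self.labels:
            if not isinstance(lab, TasteLabel):
                raise TypeError(f"labels must be TasteLabel, got {lab!r}")

    @property
    def label(self) -> TasteLabel:
        """The single label of a single-label row (raises if ambiguous)."""
        if len(self.labels) != 1:
            raise ValueError("record carries multiple labels")
        return next(iter(self.labels))

    def with_label(self, label: TasteLabel) -> "MoleculeRecord":
        return replace(self, labels=frozenset({label}))
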