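"""SMILES validity, canonicalization, synonymous-SMILES enumeration, and
dataset CSV I/O.

Canonicalization uses RDKit's default sanitization + canonical SMILES
writer; the algorithm identity is pinned in :data:`CANONICALIZATION_SPEC`
so a dataset can record exactly which convention produced its canonical
strings. Synonymous (randomized) SMILES are alternative traversals of the
same molecular graph; every variant canonicalizes back to its source, which
is the property both training-time augmentation and the test-time consensus
rely on.
"""

from __future__ import annotations

import csv
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .labels import TasteLabel
from .records import MoleculeRecord

RDLogger.DisableLog("rdApp.*")  # parse failures are reported via our own errors

#: Identity of the canonicalization convention, recorded in config metadata.
CANONICALIZATION_SPEC = "rdkit-default-sanitize+canonical-smiles"


class SmilesParseError(ValueError):
    """A string could not be parsed into a molecular graph."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"invalid SMILES: {smiles!r}")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def is_valid(smiles) -> bool:
    """True iff a molecular graph can be constructed from the string.

    Never raises; any unparsable input (including empty or non-string)
    returns ``False``.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return False
    return Chem.MolFromSmiles(smiles) is not None


def canonicalize(smiles: str) -> str:
    """Deterministic canonical SMILES of a valid input; idempotent.

    Raises
    ------
    SmilesParseError
        If the input cannot be parsed, naming the offending string.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def mol_weight(smiles: str) -> float:
    """Average molecular weight in Daltons."""
    return float(Descriptors.MolWt(_mol_from_smiles(smiles)))


def enumerate_random_smiles(canonical_smiles: str, k: int, seed: int) -> list[str]:
    """Draw ``k`` synonymous SMILES by randomized atom-order traversal.

    Every returned string canonicalizes back to the input. Output is
    deterministic for a fixed ``(smiles, k, seed)``. Duplicates are allowed
    when the molecule admits fewer than ``k`` distinct representations
    (methane only ever yields ``"C"``); downstream consensus voting handles
    repeats naturally.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    mol = _mol_from_smiles(canonical_smiles)
    # RDKit's vectorized random-SMILES writer is seed-deterministic.
    return list(Chem.MolToRandomSmilesVect(mol, k, randomSeed=int(seed)))


def read_dataset(path) -> list[MoleculeRecord]:
    """Read a molecule-taste CSV into records.

    The file must be UTF-8, comma-separated, with a header containing at
    least ``smiles`` and ``label`` columns (``source``, ``canonical_smiles``
    and ``mol_weight_da`` are optional). One label per row; multi-taste
    molecules appear as duplicated rows. Unknown label strings are rejected
    with the offending row number — notably ``salty``, which must be
    re-labeled ``undefined`` upstream rather than silently accepted.
    """
    path = Path(path)
    records: list[MoleculeRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header required")
        fields = [f.strip().lower() for f in reader.fieldnames]
        for col in ("smiles", "label"):
            if col not in fields:
                raise ValueError(f"{path}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            row = {k.strip().lower(): v for k, v in row.items() if k}
            try:
                label = TasteLabel.from_string(row["label"])
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from None
            mw = row.get("mol_weight_da")
            records.append(
                MoleculeRecord(
                    raw_smiles=row["smiles"].strip(),
                    labels=frozenset({label}),
                    source=(row.get("source") or "").strip(),
                    canonical_smiles=(row.get("canonical_smiles") or None),
                    mol_weight_da=float(mw) if mw else None,
                )
            )
    return records


def write_dataset(records: list[MoleculeRecord], path) -> None:
    """Write records as CSV; read∘write round-trips exactly.

    Columns ``canonical_smiles`` and ``mol_weight_da`` are included whenever
    any record carries them. Multi-label records are expanded to one row per
    label.
    """
    path = Path(path)
    with_canon = any(r.canonical_smiles is not None for r in records)
    header = ["smiles", "label", "source"]
    if with_canon:
        header += ["canonical_smiles", "mol_weight_da"]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            for label in sorted(rec.labels, key=lambda l: l.index):
                row = [rec.raw_smiles, label.value, rec.source]
                if with_canon:
                    row += [
                        rec.canonical_smiles or "",
                        "" if rec.mol_weight_da is None else repr(rec.mol_weight_da),
                    ]
                writer.writerow(row)


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Fill ``canonical_smiles`` and ``mol_weight_da`` from the raw SMILES."""
    canon = canonicalize(record.raw_smiles)
    from dataclasses import replace

    return replace(record, canonical_smiles=canon, mol_weight_da=mol_weight(canon))
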