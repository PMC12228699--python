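"""Dataset curation: the filter cascade, deduplication, reporting, and a
leakage-safe train/test split.

Filters run in a fixed order — invalid → multi-fragment → charged →
overweight → duplicate — so each removed row is attributed to exactly one
stage and curation reports are reproducible. The rationale per stage:

* invalid strings cannot yield a molecular graph;
* multiple *uncharged* fragments usually mean a solvent accompanies the
  tastant (charged fragment pairs such as Na+/Cl- are left to the charge
  filter instead);
* any formally charged atom flags a substance with missing counter ions;
* molecules at or above 2000 Da are outside the small-molecule scope;
* duplicates are collapsed on the (canonical SMILES, label) pair, so a
  multi-taste molecule keeps one row per distinct label.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from rdkit import Chem

from .labels import TasteLabel
from .records import MoleculeRecord
from . import smiles as sm


@dataclass
class CurationConfig:
    max_da: float = 2000.0
    corrections: dict[str, TasteLabel] = field(default_factory=dict)


@dataclass
class CurationReport:
    """Per-stage removal counts; conserves n_input = n_output + removals."""

    n_input: int = 0
    removed_invalid: int = 0
    removed_multifragment: int = 0
    removed_charged: int = 0
    removed_overweight: int = 0
    removed_duplicate: int = 0
    n_output: int = 0

    def validate(self) -> None:
        removed = (
            self.removed_invalid
            + self.removed_multifragment
            + self.removed_charged
            + self.removed_overweight
            + self.removed_duplicate
        )
        if self.n_input != self.n_output + removed:
            raise ValueError(f"report does not conserve counts: {self}")
        if min(asdict(self).values()) < 0:
            raise ValueError(f"negative count in report: {self}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class SplitAssignment:
    train: list[MoleculeRecord]
    test: list[MoleculeRecord]
    test_fraction: float
    seed: int


def filter_invalid(records):
    """Partition records into (kept, removed) by SMILES parseability."""
    kept, removed = [], []
    for rec in records:
        (kept if sm.is_valid(rec.raw_smiles) else removed).append(rec)
    return kept, removed


def _n_fragments(mol: Chem.Mol) -> int:
    return len(Chem.GetMolFrags(mol))


def _has_charged_atom(mol: Chem.Mol) -> bool:
    return any(a.GetFormalCharge() != 0 for a in mol.GetAtoms())


def filter_multifragment(records):
    """Remove records whose graph has >= 2 fragments, all uncharged.

    Solvent-containing entries ("CCO.O") fall here; salt pairs with charged
    fragments ("[Na+].[Cl-]") are deliberately passed through for the
    charge filter to catch.
    """
    kept, removed = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.raw_smiles)
        frags = Chem.GetMolFrags(mol, asMols=True)
        multi_neutral = len(frags) >= 2 and all(
            not _has_charged_atom(f) for f in frags
        )
        (removed if multi_neutral else kept).append(rec)
    return kept, removed


def filter_charged(records):
    """Remove records containing any formally charged atom.

    Zwitterions with zero net charge are also excluded: a charged atom
    anywhere signals either missing counter ions or a protonation-state
    convention the rest of the dataset does not share.
    """
    kept, removed = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.raw_smiles)
        (removed if _has_charged_atom(mol) else kept).append(rec)
    return kept, removed


def filter_weight(records, max_da: float = 2000.0):
    """Remove records with molecular weight >= max_da ("below 2000 Da")."""
    kept, removed = [], []
    for rec in records:
        mw = rec.mol_weight_da
        if mw is None:
            mw = sm.mol_weight(rec.raw_smiles)
        (removed if mw >= max_da else kept).append(rec)
    return kept, removed


def deduplicate(records):
    """Collapse rows with identical (canonical_smiles, label) pairs.

    Rows sharing a canonical SMILES but differing in label are retained as
    distinct rows — the multi-taste convention. The first occurrence's
    source wins. Records must be standardized.
    """
    seen: set[tuple[str, TasteLabel]] = set()
    kept, removed_count = [], 0
    for rec in records:
        key = (rec.canonical_smiles, rec.label)
        if key in seen:
            removed_count += 1
        else:
            seen.add(key)
            kept.append(rec)
    return kept, removed_count


def apply_corrections(records, corrections: dict[str, TasteLabel]):
    """Re-label records whose canonical SMILES appears in the corrections map."""
    if not corrections:
        return list(records)
    return [
        rec.with_label(corrections[rec.canonical_smiles])
        if rec.canonical_smiles in corrections
        else rec
        for rec in records
    ]


def curate(records, config: CurationConfig | None = None):
    """Run the full cascade and return (curated records, CurationReport)."""
    config = config or CurationConfig()
    report = CurationReport(n_input=len(records))

    kept, removed = filter_invalid(records)
    report.removed_invalid = len(removed)

    kept, removed = filter_multifragment(kept)
    report.removed_multifragment = len(removed)

    kept, removed = filter_charged(kept)
    report.removed_charged = len(removed)

    kept = [sm.standardize(rec) for rec in kept]

    kept, removed = filter_weight(kept, config.max_da)
    report.removed_overweight = len(removed)

    kept = apply_corrections(kept, config.corrections)

    kept, n_dup = deduplicate(kept)
    report.removed_duplicate = n_dup

    report.n_output = len(kept)
    report.validate()
    return kept, report


def read_corrections(path) -> dict[str, TasteLabel]:
    """Read a corrections CSV with columns canonical_smiles,label."""
    out: dict[str, TasteLabel] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            out[row["canonical_smiles"].strip()] = TasteLabel.from_string(row["label"])
    return out


def split_dataset(records, test_fraction: float = 0.15, seed: int = 0) -> SplitAssignment:
    """Grouped, seeded train/test split with no canonical-SMILES leakage.

    Rows are grouped by canonical SMILES before assignment so that the
    duplicate rows of a multi-taste molecule always land in the same
    partition; the test size is the rounded fraction of molecule groups.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        if rec.canonical_smiles is None:
            raise ValueError("split requires standardized records")
        groups.setdefault(rec.canonical_smiles, []).append(rec)
    keys = sorted(groups)
    rng = random.Random(seed)
    rng.shuffle(keys)
    n_test = int(round(test_fraction * len(keys)))
    test_keys = set(keys[:n_test])
    train, test = [], []
    for key in keys:
        (test if key in test_keys else train).extend(groups[key])
    return SplitAssignment(train=train, test=test, test_fraction=test_fraction, seed=seed)
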