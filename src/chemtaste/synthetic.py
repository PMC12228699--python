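"""Seeded generators for rule-based tastant datasets and curation fixtures.

Real taste datasets associate structure with taste only noisily and
indirectly; for testing we need the opposite — datasets whose
structure-to-label mapping is exact and known. The generator assembles
molecules from a scaffold-plus-functional-group grammar whose decorations
encode taste the way food chemistry heuristics do:

* carboxylic acid → sour (acidic protons, pKa in the sour-tasting range),
* amide → umami (the signature group of savory peptides/nucleotide analogs),
* polyol (vicinal diols) → sweet (sugar-like hydroxyl patterns),
* fused/plain aromatic ring systems → bitter (polyphenol-like scaffolds),
* plain alkanes → undefined (water-insoluble, tasteless).

At zero label noise, re-applying the rule set to a generated molecule
reproduces its label exactly. The default class mix is imbalanced the way
curated taste data is (sweet-dominated, umami rare).

The curation-fixture generator plants file defects (invalid strings,
solvent-carrying multi-fragment entries, charged species, overweight
polymers, duplicate rewrites) in exact known counts so the filter cascade
can be audited end to end.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .labels import LABEL_ORDER, TasteLabel
from .records import MoleculeRecord
from . import smiles as sm


@dataclass
class Rule:
    smarts: str
    label: TasteLabel

    def matches(self, mol) -> bool:
        patt = Chem.MolFromSmarts(self.smarts)
        return mol.HasSubstructMatch(patt)


#: SMARTS of a carboxylic acid (the sour decoration); exported for tests.
CARBOXYL_SMARTS = "[CX3](=O)[OX2H1]"


@dataclass
class RuleSet:
    """Ordered substructure rules; the first matching rule assigns the label."""

    rules: tuple = (
        Rule(CARBOXYL_SMARTS, TasteLabel.SOUR),
        Rule("[CX3](=O)[NX3]", TasteLabel.UMAMI),
        Rule("[OX2H][CX4][CX4][OX2H]", TasteLabel.SWEET),
        Rule("c1ccccc1", TasteLabel.BITTER),
    )
    default_label: TasteLabel = TasteLabel.UNDEFINED
    label_noise: float = 0.0
    class_mix: tuple = (0.60, 0.20, 0.10, 0.05, 0.05)  # label order

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError(f"label_noise must be in [0, 0.5), got {self.label_noise}")
        if len(self.class_mix) != len(LABEL_ORDER):
            raise ValueError("class_mix needs one proportion per class")
        if min(self.class_mix) < 0 or abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must be a distribution, got {self.class_mix}")

    def apply(self, smiles: str) -> TasteLabel:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise sm.SmilesParseError(smiles)
        for rule in self.rules:
            if rule.matches(mol):
                return rule.label
        return self.default_label


# --------------------------------------------------------------- molecule grammar

def _alkyl(rng: random.Random, n_carbons: int) -> str:
    """Random branched alkyl fragment with the given carbon count."""
    if n_carbons <= 1:
        return "C"
    rest = n_carbons - 1
    if rest >= 2 and rng.random() < 0.5:
        left = rng.randint(1, rest - 1) if rest > 1 else 1
        return f"C({_alkyl(rng, left)}){_alkyl(rng, rest - left)}"
    return "C" + _alkyl(rng, rest)


def _make_sour(rng) -> str:
    return _alkyl(rng, rng.randint(1, 10)) + "C(=O)O"


def _make_umami(rng) -> str:
    tail = "C" * rng.randint(0, 2)
    return _alkyl(rng, rng.randint(1, 9)) + "C(=O)N" + tail


def _make_sweet(rng) -> str:
    n_diol = rng.randint(1, 4)
    tail = _alkyl(rng, rng.randint(1, 6))
    return "OC" + "C(O)" * n_diol + tail


def _make_bitter(rng) -> str:
    core = rng.choice(["c1ccccc1", "c1ccc2ccccc2c1", "Oc1ccccc1", "Oc1ccc2ccccc2c1"])
    tail = _alkyl(rng, rng.randint(1, 6)) if rng.random() < 0.8 else ""
    # a tail prefixed to a phenol core forms an aryl ether; still aromatic-bitter
    return tail + core


def _make_undefined(rng) -> str:
    return _alkyl(rng, rng.randint(3, 12))


_MAKERS = {
    TasteLabel.SOUR: _make_sour,
    TasteLabel.UMAMI: _make_umami,
    TasteLabel.SWEET: _make_sweet,
    TasteLabel.BITTER: _make_bitter,
    TasteLabel.UNDEFINED: _make_undefined,
}


def generate_dataset(n: int, ruleset: RuleSet | None = None, seed: int = 0):
    """Generate n labeled, standardized molecule records.

    Class identities are drawn from ``ruleset.class_mix``; each molecule is
    assembled by the matching grammar and its label assigned by re-applying
    the rule set (so at zero noise the labels are exactly rule-consistent).
    Label noise flips each label to a uniformly random other class with the
    configured probability.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ruleset = ruleset or RuleSet()
    rng = random.Random(seed)
    records = []
    for _ in range(n):
        target = rng.choices(LABEL_ORDER, weights=ruleset.class_mix, k=1)[0]
        smiles = _MAKERS[target](rng)
        label = ruleset.apply(smiles)
        assert label is target, (
            f"grammar/rule mismatch: {smiles} built for {target} labeled {label}"
        )
        if ruleset.label_noise and rng.random() < ruleset.label_noise:
            label = rng.choice([l for l in LABEL_ORDER if l is not label])
        records.append(
            sm.standardize(
                MoleculeRecord(
                    raw_smiles=smiles, labels=frozenset({label}), source="synthetic"
                )
            )
        )
    return records


def flip_labels(records, fraction: float, seed: int):
    """Return records with a fraction of labels flipped to a random other class.

    Models training-set label noise while leaving the evaluation labels
    clean — the usual situation with heterogeneous source databases, where
    training annotations are noisy but the quantity of interest is the true
    taste.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    rng = random.Random(seed)
    out = []
    for rec in records:
        if rng.random() < fraction:
            out.append(
                rec.with_label(rng.choice([l for l in LABEL_ORDER if l is not rec.label]))
            )
        else:
            out.append(rec)
    return out


# --------------------------------------------------------------- curation fixture

def make_curation_fixture(
    n_clean: int,
    n_invalid: int,
    n_multifragment: int,
    n_charged: int,
    n_overweight: int,
    n_duplicate: int,
    seed: int,
    path,
) -> Path:
    """Write a CSV with exactly the planted defect counts.

    Every defect is caught by exactly one filter stage: invalid strings are
    unparsable; multi-fragment rows pair a neutral molecule with water;
    charged rows carry a formally charged atom in a single fragment;
    overweight rows are long alkane chains crossing 2000 Da; duplicates are
    non-canonical rewrites of clean rows with the same label, detectable
    only after canonicalization. Curating the file yields a report equal to
    the planted counts and ``n_clean`` output rows.
    """
    if min(n_clean, n_invalid, n_multifragment, n_charged, n_overweight, n_duplicate) < 0:
        raise ValueError("planted counts must be nonnegative")
    if n_duplicate > 0 and n_clean == 0:
        raise ValueError("duplicates need clean rows to duplicate")
    rng = random.Random(seed)
    ruleset = RuleSet()

    clean: list[MoleculeRecord] = []
    seen = set()
    guard = 0
    while len(clean) < n_clean:
        guard += 1
        if guard > 100 * max(n_clean, 1):
            raise RuntimeError("could not generate enough distinct clean molecules")
        rec = generate_dataset(1, ruleset, seed=rng.randrange(2**31))[0]
        key = (rec.canonical_smiles, rec.label)
        if key in seen:
            continue
        seen.add(key)
        clean.append(rec)

    rows: list[tuple[str, str, str]] = [
        (r.raw_smiles, r.label.value, "clean") for r in clean
    ]
    for i in range(n_invalid):
        rows.append((f"C{1 + i % 9}" + "C" * (2 + i // 9), "undefined", "invalid"))
    for i in range(n_multifragment):
        rows.append(("C" * (2 + i) + ".O", "undefined", "multifragment"))
    for i in range(n_charged):
        rows.append(("C" * (1 + i) + "[NH3+]", "undefined", "charged"))
    for i in range(n_overweight):
        rows.append(("C" * (150 + 5 * i), "undefined", "overweight"))
    for i in range(n_duplicate):
        parent = clean[i % len(clean)]
        variants = sm.enumerate_random_smiles(parent.canonical_smiles, 10, seed=seed + i)
        rewrite = next(
            (v for v in variants if v != parent.raw_smiles), parent.canonical_smiles
        )
        rows.append((rewrite, parent.label.value, "duplicate"))

    rng.shuffle(rows)
    path = Path(path)
    records = [
        MoleculeRecord(
            raw_smiles=s, labels=frozenset({TasteLabel.from_string(lab)}), source=src
        )
        for s, lab, src in rows
    ]
    sm.write_dataset(records, path)
    return path
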