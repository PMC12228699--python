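"""Fingerprint and descriptor features for the tree-based backends.

The default representation is a 1024-bit radius-2 Morgan (circular)
fingerprint, optionally concatenated with 15 molecular descriptors.
Features are computed from the parsed molecular graph, so every SMILES form
of the same molecule maps to the same vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from rdkit.Chem import Descriptors, GraphDescriptors, rdFingerprintGenerator

from .smiles import _mol_from_smiles

logger = logging.getLogger(__name__)

# Adjacency/topology-flavored descriptor registry. The default set of 15
# leans on connectivity and ring structure, with a few H-bonding counts that
# taste studies routinely use; any user-supplied list of registry names (or
# an extended registry) can replace it through config.
DESCRIPTOR_REGISTRY = {
    "mol_weight": Descriptors.MolWt,
    "heavy_atom_count": Descriptors.HeavyAtomCount,
    "ring_count": Descriptors.RingCount,
    "aromatic_ring_count": Descriptors.NumAromaticRings,
    "rotatable_bonds": Descriptors.NumRotatableBonds,
    "h_bond_donors": Descriptors.NumHDonors,
    "h_bond_acceptors": Descriptors.NumHAcceptors,
    "heteroatom_count": Descriptors.NumHeteroatoms,
    "fraction_csp3": Descriptors.FractionCSP3,
    "tpsa": Descriptors.TPSA,
    "logp": Descriptors.MolLogP,
    "balaban_j": GraphDescriptors.BalabanJ,
    "bertz_complexity": GraphDescriptors.BertzCT,
    "chi0": GraphDescriptors.Chi0,
    "kappa1": Descriptors.Kappa1,
}

DEFAULT_DESCRIPTORS = tuple(DESCRIPTOR_REGISTRY)
assert len(DEFAULT_DESCRIPTORS) == 15


@dataclass
class FeatureVector:
    bits: np.ndarray
    descriptors: np.ndarray | None = None

    @property
    def combined(self) -> np.ndarray:
        if self.descriptors is None:
            return self.bits.astype(float)
        return np.concatenate([self.bits.astype(float), self.descriptors])


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Binary Morgan fingerprint; identical for all SMILES forms of a molecule."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return arr


def descriptor_vector(smiles: str, descriptor_names=DEFAULT_DESCRIPTORS) -> np.ndarray:
    """Descriptor values in the order given; non-finite values become 0.

    Raises
    ------
    KeyError
        If a name is not in the registry.
    """
    # compute on the canonical atom ordering: some descriptors accumulate
    # floating-point sums in atom order, and bit-identical values across
    # SMILES forms matter for caching and reproducibility
    from .smiles import canonicalize

    mol = _mol_from_smiles(canonicalize(smiles))
    out = np.empty(len(descriptor_names), dtype=float)
    for i, name in enumerate(descriptor_names):
        try:
            fn = DESCRIPTOR_REGISTRY[name]
        except KeyError:
            raise KeyError(
                f"unknown descriptor {name!r}; known: {sorted(DESCRIPTOR_REGISTRY)}"
            ) from None
        val = float(fn(mol))
        if not math.isfinite(val):
            logger.warning("descriptor %s non-finite for %s; using 0", name, smiles)
            val = 0.0
        out[i] = val
    return out


def featurize(
    smiles: str,
    radius: int = 2,
    n_bits: int = 1024,
    use_descriptors: bool = False,
    descriptor_names=DEFAULT_DESCRIPTORS,
) -> FeatureVector:
    bits = morgan_fingerprint(smiles, radius=radius, n_bits=n_bits)
    desc = descriptor_vector(smiles, descriptor_names) if use_descriptors else None
    return FeatureVector(bits=bits, descriptors=desc)
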