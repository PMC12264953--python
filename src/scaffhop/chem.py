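"""Chemistry primitives shared by every other module.

Thin, deterministic wrappers around RDKit: SMILES canonicalization,
extended-connectivity fingerprints (ECFP, radius 3, 2048 bits), Jaccard
(Tanimoto) distance on bit sets, Bemis-Murcko frameworks and the handful of
molecular descriptors used by the design filter.

Conventions fixed once for the whole package:

* the canonical SMILES dialect is RDKit's default canonicalization;
* heavy-atom counts exclude hydrogens *and* dummy atoms (``[*]``), so that
  attachment points never inflate fragment sizes;
* fingerprints are plain ECFPs — no stereochemistry, no feature invariants —
  and dummy atoms participate like any other atom, which keeps reference and
  design scaffolds (both carrying attachment dummies) comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: Reserved Bemis-Murcko class for molecules without any ring.
NO_CYCLIC_CLASS = "no cyclic substructure(s)"

ECFP_RADIUS = 3
ECFP_NBITS = 2048


@dataclass(frozen=True)
class Molecule:
    """A parsed, sanitized molecule with its canonical SMILES."""

    canonical_smiles: str
    heavy_atom_count: int
    mol: Chem.Mol = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.heavy_atom_count < 0:
            raise ValueError("negative heavy atom count")


@dataclass(frozen=True)
class FingerprintVector:
    """Sparse ECFP bit set (folded)."""

    on_bits: frozenset[int]
    radius: int = ECFP_RADIUS
    nbits: int = ECFP_NBITS


@dataclass(frozen=True)
class BMFramework:
    """Bemis-Murcko framework and the cyclic class used for diversity counts."""

    framework_smiles: str
    cyclic_class: str


def heavy_atoms(mol: Chem.Mol) -> int:
    """Count non-hydrogen, non-dummy atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def canonicalize(smiles: str) -> Molecule | None:
    """Parse and canonicalize a SMILES string.

    Returns ``None`` for anything RDKit cannot parse and sanitize — invalidity
    is a value here, never an exception, because generated strings are routinely
    malformed.
    """
    if not smiles or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Molecule(
        canonical_smiles=Chem.MolToSmiles(mol),
        heavy_atom_count=heavy_atoms(mol),
        mol=mol,
    )


def from_rdkit(mol: Chem.Mol) -> Molecule:
    """Wrap an already-sanitized RDKit mol."""
    return Molecule(Chem.MolToSmiles(mol), heavy_atoms(mol), mol)


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits, includeChirality=False
        )
    return _FP_GENERATORS[key]


def ecfp(mol: Molecule, radius: int = ECFP_RADIUS, nbits: int = ECFP_NBITS) -> FingerprintVector:
    """Extended-connectivity fingerprint as a sparse bit set."""
    bv = _fp_generator(radius, nbits).GetFingerprint(mol.mol)
    return FingerprintVector(frozenset(bv.GetOnBits()), radius=radius, nbits=nbits)


def jaccard_distance(a: FingerprintVector, b: FingerprintVector) -> float:
    """1 - |a ∩ b| / |a ∪ b| on fingerprint bit sets.

    The score used for scaffold dissimilarity: 0 for identical bit sets,
    1 for disjoint ones. Raises if both sets are empty (undefined).
    """
    union = a.on_bits | b.on_bits
    if not union:
        raise ValueError("Jaccard distance undefined for two empty bit sets")
    return 1.0 - len(a.on_bits & b.on_bits) / len(union)


def bm_framework(mol: Molecule) -> BMFramework:
    """Bemis-Murcko framework (ring systems + linkers, side chains pruned).

    Acyclic molecules all collapse into the single reserved class
    ``"no cyclic substructure(s)"`` so that diversity statistics treat them
    as one scaffold family.
    """
    scaffold = MurckoScaffold.GetScaffoldForMol(mol.mol)
    smi = Chem.MolToSmiles(scaffold)
    return BMFramework(framework_smiles=smi, cyclic_class=smi if smi else NO_CYCLIC_CLASS)


def properties(mol: Molecule) -> dict[str, float]:
    """Descriptors consumed by the design filter.

    Stereocenters are counted including unassigned ones: a generated SMILES
    usually carries no stereo annotations, yet its potential stereocenters
    still complicate synthesis and conformer enumeration.
    """
    centers = Chem.FindMolChiralCenters(
        mol.mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return {
        "molecular_weight": Descriptors.MolWt(mol.mol),
        "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol.mol),
        "stereocenters": len(centers),
    }
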