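"""Deterministic toy chemistry for tests and desk-scale experiments.

Builds miniature scaffold-hopping tasks whose ground truth is known by
construction: a reference molecule assembled as ring core + decorations
joined by single bonds, design sets with controlled decoration inclusion
(all / strict subset / none) across varied ring systems, a synthetic
"bioactive" 3D conformer, and a small SMILES corpus for language-model
training. Everything is regenerable from a seed — no stored data files.

The toy corpus mimics one essential feature of a drug-like training set for
these experiments: decoration-bearing molecules occur but molecules carrying
*all* decorations on one core are rare, so decoration inclusion is something
an agent must actually learn. It does not emulate real pharmacology,
property distributions, or synthesis-aware chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import chem
from .chem import Molecule
from .scaffoldfinder import Decoration, find_scaffold

__all__ = ["FixtureTask", "make_task", "make_conformer_pair"]

# ring cores with two substitution slots; names label the ring family
_CORES: list[tuple[str, str]] = [
    ("benzene", "c1cc({a})ccc1{b}"),
    ("pyridine", "c1nc({a})ccc1{b}"),
    ("thiophene", "c1sc({a})cc1{b}"),
    ("furan", "c1oc({a})cc1{b}"),
    ("cyclohexane", "C1CC({a})CCC1{b}"),
    ("pyrimidine", "c1nc({a})ncc1{b}"),
    ("pyrazole", "Cn1ncc({a})c1{b}"),
    ("cyclopentane", "C1CC({a})CC1{b}"),
]

#: default decorations: ethyl and aminomethyl, written with the attachment dummy
DEFAULT_DECORATIONS = ("[*]CC", "[*]CN")

# substituents guaranteed not to contain (or complete) any default decoration
_NEUTRAL = ("C", "F", "Cl", "OC", "O")


@dataclass(frozen=True)
class FixtureTask:
    reference: Molecule
    reference_conformer: Chem.Mol
    decorations: tuple[Decoration, ...]
    positive_designs: tuple[str, ...]
    partial_designs: tuple[str, ...]
    negative_designs: tuple[str, ...]
    corpus: tuple[str, ...]


def _fill(template: str, a: str, b: str) -> str | None:
    mol = Chem.MolFromSmiles(template.format(a=a, b=b))
    return Chem.MolToSmiles(mol) if mol is not None else None


def _embed(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    AllChem.MMFFOptimizeMolecule(mol)
    return mol


def make_task(
    seed: int = 42,
    n_scaffolds: int = 6,
    n_designs: int = 24,
    decoration_smiles: tuple[str, ...] = DEFAULT_DECORATIONS,
    corpus_size: int = 1000,
) -> FixtureTask:
    """Build a complete toy task; byte-identical for a fixed seed.

    Positives carry every decoration on ``n_scaffolds`` different ring
    systems (verified to decompose with ``S_s = 1`` at ``alpha = 1`` at
    construction time); partials carry a strict subset; negatives none.
    """
    rng = np.random.default_rng(seed)
    decorations = tuple(Decoration.from_smiles(s) for s in decoration_smiles)
    bodies = [s.replace("[*]", "") for s in decoration_smiles]
    cores = _CORES[:n_scaffolds]

    reference_smiles = _fill(cores[0][1], bodies[0], bodies[1])
    reference = chem.canonicalize(reference_smiles)
    assert reference is not None

    positives: list[str] = []
    partials: list[str] = []
    negatives: list[str] = []
    for _, template in cores:
        for a, b in ((bodies[0], bodies[1]), (bodies[1], bodies[0])):
            smi = _fill(template, a, b)
            if smi is not None and smi not in positives:
                positives.append(smi)
        for body in bodies:
            smi = _fill(template, body, "C")
            if smi is not None and smi not in partials:
                partials.append(smi)
        smi = _fill(template, "C", "F")
        if smi is not None and smi not in negatives:
            negatives.append(smi)
    positives = positives[:n_designs]
    partials = partials[:n_designs]
    negatives = negatives[:n_designs]

    # construction-time ground-truth verification
    for smi in positives:
        mol = chem.canonicalize(smi)
        decomp = find_scaffold(mol, list(decorations), alpha=1.0)
        assert decomp.success_score == 1.0 and decomp.scaffold is not None, smi
    for smi in partials:
        mol = chem.canonicalize(smi)
        s_s = find_scaffold(mol, list(decorations), alpha=1.0).success_score
        assert 0.0 < s_s < 1.0, smi
    for smi in negatives:
        mol = chem.canonicalize(smi)
        s_s = find_scaffold(mol, list(decorations), alpha=1.0).success_score
        assert s_s == 0.0, smi

    corpus = _make_corpus(rng, cores, bodies, corpus_size)
    conformer = _embed(reference.canonical_smiles, seed)
    return FixtureTask(
        reference=reference,
        reference_conformer=conformer,
        decorations=decorations,
        positive_designs=tuple(positives),
        partial_designs=tuple(partials),
        negative_designs=tuple(negatives),
        corpus=tuple(corpus),
    )


_CHAINS = ("CCO", "CCN", "CC(C)O", "CCC", "CC(=O)O", "CCOC", "NCCO", "CC(=O)N", "CCCN", "OCCO")


def _make_corpus(rng: np.random.Generator, cores, bodies, size: int) -> list[str]:
    """Toy drug-like corpus: substituted small rings plus short chains.

    Substituents are drawn so that single decorations are common and
    complete decoration sets are present but rare. Draws are independent, so
    frequent structures repeat — the corpus is a sample from a generative
    process, not a curated unique set.
    """
    pool = list(bodies) + list(_NEUTRAL)
    weights = np.array([2.0] * len(bodies) + [1.0] * len(_NEUTRAL))
    weights /= weights.sum()
    out: list[str] = []
    while len(out) < size:
        if rng.random() < 0.15:
            smi = _CHAINS[rng.integers(len(_CHAINS))]
        else:
            _, template = cores[rng.integers(len(cores))]
            a, b = rng.choice(pool, size=2, p=weights)
            smi = _fill(template, a, b)
        if smi is None:
            continue
        out.append(chem.canonicalize(smi).canonical_smiles)
    return out


def make_conformer_pair(seed: int = 42) -> tuple[Chem.Mol, Chem.Mol]:
    """A rigid molecule's conformer and a rigid-body-transformed copy.

    The pair exercises alignment identity and invariance: any sound 3D
    scorer must give the transformed copy a perfect overlap score.
    """
    mol = _embed("c1ccc(C(N)=O)cc1", seed)  # benzamide: rigid, has features
    moved = Chem.Mol(mol)
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix, plus a large translation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(50.0, 100.0, size=3)
    conf = moved.GetConformer()
    for i in range(moved.GetNumAtoms()):
        pos = np.array(conf.GetAtomPosition(i))
        new = q @ pos + shift
        conf.SetAtomPosition(i, new.tolist())
    return mol, moved
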