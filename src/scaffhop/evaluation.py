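"""Design-set analysis: diversity, distances and quality filtering.

Quantifies what a generative run actually produced:

* **Scaled Shannon Entropy (SSE)** over Bemis-Murcko cyclic-substructure
  classes — 0 when every scaffold is the same, 1 when all are distinct;
* the **retrieval curve** of unique scaffolds versus generated designs
  (how top-heavy is scaffold production?);
* **distance panels** — Jaccard distance of full molecules and of extracted
  scaffolds to the reference (mean ± sd);
* a **quality-filter panel** in the style of standard fragment-linking
  postprocessing: exact decoration inclusion (ScaffoldFinder at alpha = 1),
  PAINS substructure catalog, synthetic-accessibility score, and ring
  aromaticity sanity.
"""

from __future__ import annotations

import math
import os
import sys
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import FilterCatalog, RDConfig

from . import chem
from .chem import Molecule
from .scaffoldfinder import Decoration, find_scaffold

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit-contributed synthetic accessibility score)

__all__ = [
    "DesignSet",
    "DiversityReport",
    "sse",
    "retrieval_curve",
    "quality_filter",
    "distance_panel",
]


@dataclass
class DesignSet:
    """A bag of generated designs (canonical SMILES; duplicates allowed)."""

    smiles: list[str]
    provenance: str = ""

    @classmethod
    def from_raw(cls, raw: list[str], provenance: str = "") -> "DesignSet":
        """Canonicalize, dropping unparseable strings."""
        out = []
        for s in raw:
            mol = chem.canonicalize(s)
            if mol is not None:
                out.append(mol.canonical_smiles)
        return cls(out, provenance)


@dataclass(frozen=True)
class DiversityReport:
    n_valid: int
    unique_fraction: float
    sse: float
    molecule_distance: tuple[float, float]  # mean, sd
    scaffold_distance: tuple[float, float]
    n_decomposed: int
    class_counts: dict[str, int] = field(default_factory=dict)


def sse(class_counts: dict[str, int] | Counter) -> float:
    """Scaled Shannon Entropy of scaffold classes.

    ``SSE = (-sum_i p_i log2 p_i) / log2 n`` with ``p_i = count_i / n`` over
    the cyclic-substructure classes and ``n`` the total number of designs.
    The log2(n) denominator is the only normalization meeting both boundary
    conditions: one class -> 0, all-singleton classes -> 1.
    """
    counts = np.array([c for c in class_counts.values() if c > 0], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("SSE needs at least two designs")
    p = counts / n
    entropy = float(-(p * np.log2(p)).sum())
    return entropy / math.log2(n) + 0.0  # normalize -0.0


def retrieval_curve(designs: DesignSet) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction of designs covered by scaffolds, most common first.

    Returns ``(design_fraction, scaffold_fraction)`` arrays, one point per
    scaffold class; the curve is monotone and ends at (1, 1).
    """
    if not designs.smiles:
        raise ValueError("empty design set")
    classes = Counter()
    for smi in designs.smiles:
        mol = chem.canonicalize(smi)
        classes[chem.bm_framework(mol).cyclic_class] += 1
    counts = np.array(sorted(classes.values(), reverse=True), dtype=float)
    design_frac = np.cumsum(counts) / counts.sum()
    scaffold_frac = np.arange(1, len(counts) + 1) / len(counts)
    return design_frac, scaffold_frac


_PAINS_CATALOG = None


def _pains_catalog():
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog.FilterCatalog(params)
    return _PAINS_CATALOG


def _rings_aromaticity_sane(mol: Chem.Mol) -> bool:
    """Every ring is either fully aromatic or fully non-aromatic."""
    for ring in mol.GetRingInfo().BondRings():
        flags = {mol.GetBondWithIdx(b).GetIsAromatic() for b in ring}
        if len(flags) > 1:
            return False
    return True


def quality_filter(
    designs: DesignSet,
    decorations: list[Decoration],
    sa_max: float = 4.5,
) -> tuple[DesignSet, dict[str, int]]:
    """Apply the postprocessing rule panel; report per-rule eliminations.

    Rules are independent predicates applied in a fixed reporting order
    (decorations, PAINS, synthetic accessibility, ring aromaticity); each
    design is charged to the first rule it fails, and the retained set is
    identical under any rule order. Decoration inclusion is *exact*
    (alpha = 1): fuzzily varied decorations that scored well during
    generation are eliminated here.
    """
    counts = {"decorations": 0, "pains": 0, "synthetic_accessibility": 0, "ring_aromaticity": 0}
    kept = []
    catalog = _pains_catalog()
    for smi in designs.smiles:
        mol = chem.canonicalize(smi)
        if mol is None:
            continue
        if find_scaffold(mol, decorations, alpha=1.0).success_score < 1.0:
            counts["decorations"] += 1
            continue
        if catalog.HasMatch(mol.mol):
            counts["pains"] += 1
            continue
        if sascorer.calculateScore(mol.mol) > sa_max:
            counts["synthetic_accessibility"] += 1
            continue
        if not _rings_aromaticity_sane(mol.mol):
            counts["ring_aromaticity"] += 1
            continue
        kept.append(mol.canonical_smiles)
    return DesignSet(kept, designs.provenance), counts


def distance_panel(
    designs: DesignSet,
    reference: Molecule,
    decorations: list[Decoration],
    alpha: float = 0.9,
) -> DiversityReport:
    """Diversity and distance summary of a design set against the reference.

    Molecule distances use plain ECFPs of the full structures; scaffold
    distances compare ScaffoldFinder scaffolds (dummies retained) and skip —
    but count — designs that do not fully decompose.
    """
    ref_fp = chem.ecfp(reference)
    ref_decomp = find_scaffold(reference, decorations, alpha=1.0)
    if ref_decomp.scaffold is None:
        raise ValueError("reference does not decompose with its own decorations")
    ref_scaffold_fp = chem.ecfp(ref_decomp.scaffold)

    mol_d, scaf_d = [], []
    classes = Counter()
    n_decomposed = 0
    for smi in designs.smiles:
        mol = chem.canonicalize(smi)
        mol_d.append(chem.jaccard_distance(chem.ecfp(mol), ref_fp))
        classes[chem.bm_framework(mol).cyclic_class] += 1
        decomp = find_scaffold(mol, decorations, alpha)
        if decomp.scaffold is not None:
            n_decomposed += 1
            scaf_d.append(chem.jaccard_distance(chem.ecfp(decomp.scaffold), ref_scaffold_fp))

    def mean_sd(values: list[float]) -> tuple[float, float]:
        if not values:
            return (float("nan"), float("nan"))
        arr = np.asarray(values)
        return float(arr.mean()), float(arr.std())

    unique = len(set(designs.smiles))
    return DiversityReport(
        n_valid=len(designs.smiles),
        unique_fraction=unique / len(designs.smiles) if designs.smiles else 0.0,
        sse=sse(classes) if sum(classes.values()) >= 2 else 0.0,
        molecule_distance=mean_sd(mol_d),
        scaffold_distance=mean_sd(scaf_d),
        n_decomposed=n_decomposed,
        class_counts=dict(classes),
    )
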