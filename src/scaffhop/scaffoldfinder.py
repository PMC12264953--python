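"""Fuzzy decoration matching and scaffold extraction.

Given a design molecule and a set of reference *decorations* (peripheral
fragments, each written with one attachment dummy ``[*]``), the algorithm

1. finds the largest common substructure between each decoration and the
   design, letting the dummy atom stand for any heavy atom of degree > 1
   (the scaffold-side attachment atom);
2. among multiple placements picks the most peripheral one — the placement
   leaving the largest remainder on the scaffold side of the cut;
3. test-cleaves the single attachment bond and accepts the match only if the
   molecule splits into two valid pieces whose decoration side has a size
   within the allowance window around the reference decoration's size.

The *allowance* parameter ``alpha`` in (0, 1] controls fuzziness: a cleaved
decoration with ``n_d`` atoms is accepted when ``n_r*alpha <= n_d <=
n_r/alpha`` (bounds inclusive), and the matched substructure itself must keep
at least ``alpha * n_r`` decoration atoms. ``alpha = 1`` demands exact
inclusion.

The fraction of decorations successfully matched is the success score
``S_s``; only when every decoration matches (``S_s = 1``) are all attachment
bonds cut and the remaining core returned as the scaffold, one dummy atom per
cleavage site.

The common-substructure search is exact: because a valid match must contain
the dummy and its anchor atom, the only admissible subgraphs of the
decoration are connected deletions of at most ``n_r - ceil(alpha*n_r)``
peripheral atoms, which are enumerated exhaustively (element-exact,
bond-order-exact, ring atoms matching only ring atoms) rather than
approximated by a generic MCS heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from rdkit import Chem

from .chem import Molecule, from_rdkit, heavy_atoms

__all__ = [
    "Decoration",
    "SizeBounds",
    "DecorationMatch",
    "ScaffoldDecomposition",
    "size_bounds",
    "fuzzy_match",
    "enumerate_matches",
    "select_peripheral",
    "cleave",
    "find_scaffold",
]


@dataclass(frozen=True)
class Decoration:
    """A reference decoration: one fragment, one attachment dummy."""

    fragment_smiles: str
    n_r: int
    mol: Chem.Mol = field(repr=False, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Decoration":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable decoration SMILES: {smiles!r}")
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(
                f"decoration must contain exactly one dummy atom, got {len(dummies)}: {smiles!r}"
            )
        if dummies[0].GetDegree() != 1:
            raise ValueError(f"attachment dummy must be terminal: {smiles!r}")
        n_r = heavy_atoms(mol)
        if n_r < 1:
            raise ValueError(f"decoration needs at least one heavy atom: {smiles!r}")
        return cls(Chem.MolToSmiles(mol), n_r, mol)

    @property
    def dummy_index(self) -> int:
        return next(a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() == 0)

    @property
    def anchor_index(self) -> int:
        """The decoration atom bonded to the dummy."""
        return self.mol.GetAtomWithIdx(self.dummy_index).GetNeighbors()[0].GetIdx()


@dataclass(frozen=True)
class SizeBounds:
    """Permitted size window for a cleaved decoration (bounds inclusive)."""

    m_r: float
    M_r: float

    def permitted_sizes(self) -> list[int]:
        lo = math.ceil(self.m_r - 1e-9)
        hi = math.floor(self.M_r + 1e-9)
        return list(range(lo, hi + 1))

    def contains(self, n_d: int) -> bool:
        return self.m_r - 1e-9 <= n_d <= self.M_r + 1e-9


def size_bounds(n_r: int, alpha: float) -> SizeBounds:
    """Allowance window ``m_r = n_r*alpha``, ``M_r = n_r/alpha``.

    With ``n_r = 10`` and ``alpha = 0.8`` this permits cleaved decorations of
    8 to 12 atoms.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_r < 1:
        raise ValueError(f"n_r must be >= 1, got {n_r}")
    return SizeBounds(m_r=n_r * alpha, M_r=n_r / alpha)


@dataclass(frozen=True)
class DecorationMatch:
    """An accepted placement of one decoration in a design."""

    decoration: Decoration
    matched_atom_indices: frozenset[int]  # decoration-side design atoms in the match
    dummy_partner_index: int  # scaffold-side attachment atom
    anchor_index: int  # decoration-side atom of the cleavage bond
    fragment_atom_indices: frozenset[int]  # full decoration-side component
    n_d: int  # heavy atoms in the cleaved fragment
    remainder_size: int  # heavy atoms on the scaffold side
    bond_index: int


@dataclass(frozen=True)
class ScaffoldDecomposition:
    """Outcome of decomposing one design against a decoration set."""

    success_score: float
    matches: tuple[DecorationMatch, ...]
    scaffold: Molecule | None
    cleaved_smiles: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# decoration subgraph queries


_QUERY_PARAMS = Chem.AdjustQueryParameters.NoAdjustments()
_QUERY_PARAMS.makeDummiesQueries = True  # [*] matches any atom
_QUERY_PARAMS.adjustRingChain = True  # ring atoms match only ring atoms
_QUERY_PARAMS.adjustRingChainFlags = Chem.ADJUST_IGNOREDUMMIES


def _connected(mol: Chem.Mol, kept: set[int], start: int) -> bool:
    seen = {start}
    stack = [start]
    while stack:
        for nb in mol.GetAtomWithIdx(stack.pop()).GetNeighbors():
            j = nb.GetIdx()
            if j in kept and j not in seen:
                seen.add(j)
                stack.append(j)
    return seen == kept


def _subgraph_queries(dec: Decoration, n_keep: int):
    """All connected subgraphs of the decoration with ``n_keep`` heavy atoms.

    Every subgraph retains the dummy and its anchor. Yields
    ``(query_mol, dummy_sub_idx, anchor_sub_idx)``; subgraphs that cannot be
    sanitized (e.g. broken aromatic rings) are skipped.
    """
    all_idx = list(range(dec.mol.GetNumAtoms()))
    protected = {dec.dummy_index, dec.anchor_index}
    removable = [i for i in all_idx if i not in protected]
    n_remove = dec.n_r - n_keep
    seen_smiles: set[str] = set()
    for combo in combinations(removable, n_remove):
        kept = set(all_idx) - set(combo)
        if not _connected(dec.mol, kept, dec.dummy_index):
            continue
        rw = Chem.RWMol(dec.mol)
        for i in sorted(combo, reverse=True):
            rw.RemoveAtom(i)
        # old->new index map after deletions
        remap = {}
        shift = 0
        for i in all_idx:
            if i in kept:
                remap[i] = i - shift
            else:
                shift += 1
        sub = rw.GetMol()
        try:
            Chem.SanitizeMol(sub)
        except Exception:
            continue
        smi = Chem.MolToSmiles(sub)
        if smi in seen_smiles:
            continue
        seen_smiles.add(smi)
        query = Chem.AdjustQueryProperties(sub, _QUERY_PARAMS)
        yield query, remap[dec.dummy_index], remap[dec.anchor_index]


def _decoration_component(
    mol: Chem.Mol, anchor: int, partner: int
) -> frozenset[int] | None:
    """Atoms reachable from ``anchor`` without crossing the cleavage bond.

    Returns ``None`` when the partner is still reachable (the bond sits in a
    ring, so cutting it cannot split the molecule in two).
    """
    seen = {anchor}
    stack = [anchor]
    while stack:
        i = stack.pop()
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nb.GetIdx()
            if i == anchor and j == partner:
                continue
            if j == partner:
                return None
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return frozenset(seen)


def enumerate_matches(
    design: Molecule,
    dec: Decoration,
    used_atoms: set[int] | frozenset[int] = frozenset(),
    alpha: float = 0.9,
) -> list[DecorationMatch]:
    """All valid placements of ``dec`` in ``design`` at the maximal match size.

    Works down from the full decoration to the smallest subgraph the
    allowance permits; the first size with at least one placement passing
    every check (single non-ring attachment bond, partner degree > 1, atoms
    unclaimed, cleaved size within the allowance window) defines the maximum
    common substructure, and all placements at that size are returned.
    """
    bounds = size_bounds(dec.n_r, alpha)
    min_keep = math.ceil(dec.n_r * alpha - 1e-9)
    used = frozenset(used_atoms)
    n_design = design.mol.GetNumAtoms()
    for n_keep in range(dec.n_r, min_keep - 1, -1):
        candidates: dict[tuple[frozenset[int], int], DecorationMatch] = {}
        for query, d_idx, a_idx in _subgraph_queries(dec, n_keep):
            for match in design.mol.GetSubstructMatches(
                query, uniquify=False, maxMatches=5000
            ):
                partner = match[d_idx]
                anchor = match[a_idx]
                bond = design.mol.GetBondBetweenAtoms(partner, anchor)
                if bond is None or bond.GetBondType() != Chem.BondType.SINGLE:
                    continue
                if design.mol.GetAtomWithIdx(partner).GetDegree() <= 1:
                    continue
                matched = frozenset(match) - {partner}
                if (matched | {partner}) & used:
                    continue
                fragment = _decoration_component(design.mol, anchor, partner)
                if fragment is None:  # ring bond: cannot cleave in two
                    continue
                if fragment & used:
                    continue
                n_d = len(fragment)
                if not bounds.contains(n_d):
                    continue
                key = (fragment, bond.GetIdx())
                if key not in candidates:
                    candidates[key] = DecorationMatch(
                        decoration=dec,
                        matched_atom_indices=matched,
                        dummy_partner_index=partner,
                        anchor_index=anchor,
                        fragment_atom_indices=fragment,
                        n_d=n_d,
                        remainder_size=n_design - n_d,
                        bond_index=bond.GetIdx(),
                    )
        if candidates:
            return list(candidates.values())
    return []


def select_peripheral(
    matches: list[DecorationMatch], design: Molecule
) -> DecorationMatch:
    """Pick the most peripheral placement.

    The winner maximizes the atom count on the scaffold side of the cut;
    ties break deterministically on the lowest matched atom index.
    """
    if not matches:
        raise ValueError("select_peripheral requires at least one candidate")
    return min(matches, key=lambda m: (-m.remainder_size, min(m.fragment_atom_indices)))


def fuzzy_match(
    design: Molecule,
    dec: Decoration,
    used_atoms: set[int] | frozenset[int] = frozenset(),
    alpha: float = 0.9,
) -> DecorationMatch | None:
    """Best valid placement of one decoration, or ``None``."""
    candidates = enumerate_matches(design, dec, used_atoms, alpha)
    if not candidates:
        return None
    return select_peripheral(candidates, design)


def cleave(design: Molecule, match: DecorationMatch) -> tuple[Molecule, Molecule] | None:
    """Cut the attachment bond; return (decoration fragment, remainder).

    Both pieces carry a dummy atom at the cut. Returns ``None`` if the cut
    does not produce exactly two valid fragments (e.g. a ring bond).
    """
    fragmented = Chem.FragmentOnBonds(
        design.mol, [match.bond_index], addDummies=True, dummyLabels=[(0, 0)]
    )
    try:
        pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    except Exception:
        return None
    if len(pieces) != 2:
        return None
    frag_sets = Chem.GetMolFrags(fragmented)
    dec_first = match.anchor_index in frag_sets[0]
    dec_mol, rem_mol = (pieces[0], pieces[1]) if dec_first else (pieces[1], pieces[0])
    return from_rdkit(dec_mol), from_rdkit(rem_mol)


def find_scaffold(
    design: Molecule, decorations: list[Decoration], alpha: float = 0.9
) -> ScaffoldDecomposition:
    """Decompose a design into scaffold + decorations.

    Decorations are processed largest first (the most specific fragments
    claim their atoms before smaller, more promiscuous ones). The success
    score is the fraction matched; the scaffold — the remaining core with one
    dummy per cleavage site — is only returned when every decoration matched.
    """
    if not decorations:
        raise ValueError("find_scaffold requires at least one decoration")
    ordered = sorted(decorations, key=lambda d: (-d.n_r, d.fragment_smiles))
    used: set[int] = set()
    accepted: list[DecorationMatch] = []
    for dec in ordered:
        match = fuzzy_match(design, dec, used, alpha)
        if match is not None:
            accepted.append(match)
            used |= match.fragment_atom_indices
    s_s = len(accepted) / len(decorations)
    scaffold = None
    cleaved: tuple[str, ...] = ()
    if accepted and len(accepted) == len(decorations):
        bonds = [m.bond_index for m in accepted]
        fragmented = Chem.FragmentOnBonds(
            design.mol, bonds, addDummies=True, dummyLabels=[(0, 0)] * len(bonds)
        )
        try:
            frag_sets = Chem.GetMolFrags(fragmented)
            pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
        except Exception:
            return ScaffoldDecomposition(s_s, tuple(accepted), None)
        claimed = set().union(*(m.fragment_atom_indices for m in accepted))
        n_design_atoms = design.mol.GetNumAtoms()
        scaffold_piece = None
        cleaved_list = []
        for atom_ids, piece in zip(frag_sets, pieces):
            original = {i for i in atom_ids if i < n_design_atoms}
            if original & claimed:
                cleaved_list.append(Chem.MolToSmiles(piece))
            else:
                scaffold_piece = piece
        if scaffold_piece is not None:
            scaffold = from_rdkit(scaffold_piece)
            cleaved = tuple(sorted(cleaved_list))
    return ScaffoldDecomposition(s_s, tuple(accepted), scaffold, cleaved)
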