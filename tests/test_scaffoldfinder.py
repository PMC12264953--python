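"""Fuzzy decoration matching: size windows, peripheral selection, cleavage,
decomposition invariants on constructed ground truth."""

import pytest

from scaffhop import chem
from scaffhop.scaffoldfinder import (
    Decoration,
    cleave,
    enumerate_matches,
    find_scaffold,
    fuzzy_match,
    select_peripheral,
    size_bounds,
)

ETHYL = Decoration.from_smiles("[*]CC")
AMINOMETHYL = Decoration.from_smiles("[*]CN")
CARBOXYL = Decoration.from_smiles("[*]C(=O)O")


class TestSizeBounds:
    def test_published_window(self):
        # reference decoration of 10 atoms at allowance 0.8: sizes 8..12
        bounds = size_bounds(10, 0.8)
        assert bounds.m_r == 8.0
        assert bounds.M_r == 12.5
        assert bounds.permitted_sizes() == [8, 9, 10, 11, 12]

    def test_alpha_one_is_exact(self):
        bounds = size_bounds(7, 1.0)
        assert bounds.m_r == bounds.M_r == 7
        assert bounds.permitted_sizes() == [7]

    def test_tight_window_keeps_only_exact_size(self):
        assert size_bounds(6, 0.9).permitted_sizes() == [6]

    @pytest.mark.parametrize("alpha", [0.0, -0.5, 1.5])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            size_bounds(5, alpha)


class TestFuzzyMatch:
    def test_ethyl_on_para_substituted_benzene(self):
        design = chem.canonicalize("CCc1ccc(CN)cc1")
        match = fuzzy_match(design, ETHYL, alpha=1.0)
        assert match is not None
        assert match.n_d == 2
        # the dummy partner is a ring carbon with degree > 1
        partner = design.mol.GetAtomWithIdx(match.dummy_partner_index)
        assert partner.GetIsAromatic() and partner.GetDegree() > 1

    def test_absent_substructure(self):
        assert fuzzy_match(chem.canonicalize("c1ccccc1"), ETHYL, alpha=1.0) is None

    def test_degree_condition_rejects_whole_molecule_match(self):
        # ethane IS an ethyl + attachment, but the partner would be nothing
        assert fuzzy_match(chem.canonicalize("CC"), ETHYL, alpha=1.0) is None

    def test_used_atoms_block_rematch(self):
        design = chem.canonicalize("CCc1ccc(CN)cc1")
        first = fuzzy_match(design, ETHYL, alpha=1.0)
        again = fuzzy_match(design, ETHYL, used_atoms=first.fragment_atom_indices, alpha=1.0)
        assert again is None

    def test_fuzzy_window_admits_larger_decoration(self):
        # propyl in place of ethyl: n_d = 3 needs alpha <= 2/3
        design = chem.canonicalize("CCCc1ccc(O)cc1")
        exact = enumerate_matches(design, ETHYL, alpha=1.0)
        # at alpha = 1 the ethyl still matches *inside* the propyl chain
        assert all(m.n_d == 2 for m in exact)
        loose = enumerate_matches(design, ETHYL, alpha=0.66)
        assert any(m.n_d == 3 for m in loose)


class TestSelectPeripheral:
    def test_single_candidate(self):
        design = chem.canonicalize("CCc1ccccc1")
        cands = enumerate_matches(design, ETHYL, alpha=1.0)
        assert select_peripheral(cands, design) in cands

    def test_symmetric_tie_breaks_on_lowest_index(self):
        design = chem.canonicalize("CCc1ccc(CC)cc1")
        cands = enumerate_matches(design, ETHYL, alpha=1.0)
        assert len(cands) == 2
        sizes = {c.remainder_size for c in cands}
        assert len(sizes) == 1  # isomorphic remainders
        best = select_peripheral(cands, design)
        assert min(best.fragment_atom_indices) == min(
            min(c.fragment_atom_indices) for c in cands
        )

    def test_terminal_match_beats_internal(self):
        # ethyl can sit at the chain tip (big remainder) or deeper inside
        # (small remainder) of hexylbenzene at a loose allowance
        design = chem.canonicalize("CCCCCCc1ccc(O)cc1")
        cands = enumerate_matches(design, ETHYL, alpha=0.4)
        best = select_peripheral(cands, design)
        assert best.remainder_size == max(c.remainder_size for c in cands)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            select_peripheral([], chem.canonicalize("CC"))


class TestCleave:
    def test_two_valid_pieces(self):
        design = chem.canonicalize("CCc1ccc(CN)cc1")
        match = fuzzy_match(design, ETHYL, alpha=1.0)
        fragment, remainder = cleave(design, match)
        assert fragment.canonical_smiles == "*CC"
        assert fragment.heavy_atom_count == 2
        assert remainder.heavy_atom_count == design.heavy_atom_count - 2

    def test_ring_embedded_decoration_is_never_matched(self):
        # the only C-C-C path sits in the ring: cutting cannot give two pieces
        assert fuzzy_match(chem.canonicalize("C1CCCCC1"), ETHYL, alpha=1.0) is None


class TestFindScaffold:
    def test_full_decomposition(self):
        design = chem.canonicalize("CCc1ccc(CN)cc1")
        decomp = find_scaffold(design, [ETHYL, AMINOMETHYL], alpha=0.9)
        assert decomp.success_score == 1.0
        assert decomp.scaffold is not None
        assert decomp.scaffold.canonical_smiles == "*c1ccc(*)cc1"
        assert sorted(decomp.cleaved_smiles) == ["*CC", "*CN"]

    def test_partial_decomposition(self):
        design = chem.canonicalize("CCc1ccc(CN)cc1")
        decomp = find_scaffold(design, [ETHYL, CARBOXYL], alpha=0.9)
        assert decomp.success_score == 0.5
        assert decomp.scaffold is None

    def test_no_decorations_present(self):
        decomp = find_scaffold(chem.canonicalize("c1ccccc1"), [ETHYL, AMINOMETHYL])
        assert decomp.success_score == 0.0

    def test_empty_decoration_list_raises(self):
        with pytest.raises(ValueError):
            find_scaffold(chem.canonicalize("CC"), [])


from helpers import constructed_designs

CONSTRUCTED = constructed_designs()


class TestDecompositionInvariants:
    @pytest.mark.parametrize("mol,decorations", CONSTRUCTED)
    def test_reconstruction_at_alpha_one(self, mol, decorations):
        """Scaffold + cleaved decorations account exactly for the design."""
        decomp = find_scaffold(mol, decorations, alpha=1.0)
        assert decomp.success_score == 1.0
        total = decomp.scaffold.heavy_atom_count + sum(m.n_d for m in decomp.matches)
        assert total == mol.heavy_atom_count
        # cleaved fragments are exactly the reference decorations
        assert sorted(decomp.cleaved_smiles) == sorted(
            d.fragment_smiles for d in decorations
        )

    @pytest.mark.parametrize("mol,decorations", CONSTRUCTED[::5])
    def test_alpha_monotonicity(self, mol, decorations):
        """Lowering the allowance never decreases the success score."""
        scores = [
            find_scaffold(mol, decorations, alpha=a).success_score
            for a in (1.0, 0.9, 0.7, 0.5)
        ]
        assert scores == sorted(scores)

    @pytest.mark.parametrize("mol,decorations", CONSTRUCTED[::7])
    def test_match_disjointness(self, mol, decorations):
        decomp = find_scaffold(mol, decorations, alpha=1.0)
        claimed = set()
        for match in decomp.matches:
            assert not (match.fragment_atom_indices & claimed)
            claimed |= match.fragment_atom_indices

    def test_self_decomposition_of_reference(self, task):
        """The reference must decompose exactly with its own decorations."""
        decomp = find_scaffold(task.reference, list(task.decorations), alpha=1.0)
        assert decomp.success_score == 1.0
        assert decomp.scaffold is not None

    def test_fixture_partials_and_negatives(self, task):
        for smi in task.partial_designs:
            s = find_scaffold(
                chem.canonicalize(smi), list(task.decorations), alpha=1.0
            ).success_score
            assert 0.0 < s < 1.0
        for smi in task.negative_designs:
            s = find_scaffold(
                chem.canonicalize(smi), list(task.decorations), alpha=1.0
            ).success_score
            assert s == 0.0


class TestDecorationValidation:
    @pytest.mark.parametrize("bad", ["CC", "[*]C[*]", "[*][H]", "not-smiles"])
    def test_malformed_decorations_rejected(self, bad):
        with pytest.raises(ValueError):
            Decoration.from_smiles(bad)

    def test_n_r_excludes_dummy(self):
        assert Decoration.from_smiles("[*]C(=O)O").n_r == 3
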