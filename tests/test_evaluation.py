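"""Design-set analysis: SSE, retrieval curves, quality panel, distances."""

import numpy as np
import pytest
from scipy import stats

from scaffhop import chem, evaluation
from scaffhop.evaluation import DesignSet, distance_panel, quality_filter, retrieval_curve, sse
from scaffhop.scaffoldfinder import Decoration, find_scaffold


class TestSSE:
    def test_single_class_is_zero(self):
        assert sse({"benzene": 50}) == 0.0

    def test_all_singletons_is_one(self):
        assert sse({f"c{i}": 1 for i in range(50)}) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # 4 designs in 2 classes of 2: 1 bit over log2(4) = 2 bits
        assert sse({"a": 2, "b": 2}) == pytest.approx(0.5)

    def test_fewer_than_two_designs_rejected(self):
        with pytest.raises(ValueError):
            sse({"a": 1})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_entropy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 30, size=rng.integers(2, 12))
        expected = stats.entropy(counts, base=2) / np.log2(counts.sum())
        assert sse({str(i): int(c) for i, c in enumerate(counts)}) == pytest.approx(expected)

    def test_permutation_invariance(self):
        assert sse({"x": 3, "y": 7, "z": 1}) == sse({"a": 7, "b": 1, "c": 3})


class TestRetrievalCurve:
    def test_single_scaffold_is_flat(self):
        designs = DesignSet(["Cc1ccccc1", "CCc1ccccc1", "OCc1ccccc1"])
        design_frac, scaffold_frac = retrieval_curve(designs)
        assert list(design_frac) == [1.0]
        assert list(scaffold_frac) == [1.0]

    def test_all_unique_is_diagonal(self):
        designs = DesignSet(["c1ccccc1", "c1ccncc1", "c1ccsc1", "C1CCCC1"])
        design_frac, scaffold_frac = retrieval_curve(designs)
        assert np.allclose(design_frac, scaffold_frac)

    def test_mixed_set_hand_computed(self):
        # 10 designs over 4 scaffolds with counts 4, 3, 2, 1
        smiles = (
            ["Cc1ccccc1", "CCc1ccccc1", "OCc1ccccc1", "NCc1ccccc1"]
            + ["Cc1ccncc1", "CCc1ccncc1", "OCc1ccncc1"]
            + ["Cc1ccsc1", "CCc1ccsc1"]
            + ["CC1CCCC1"]
        )
        design_frac, scaffold_frac = retrieval_curve(DesignSet(smiles))
        assert np.allclose(design_frac, [0.4, 0.7, 0.9, 1.0])
        assert np.allclose(scaffold_frac, [0.25, 0.5, 0.75, 1.0])
        assert design_frac[-1] == 1.0 and (np.diff(design_frac) >= 0).all()


class TestQualityFilter:
    def test_constructed_positives_pass_every_rule(self, task):
        designs = DesignSet(list(task.positive_designs))
        kept, counts = quality_filter(designs, list(task.decorations))
        assert len(kept.smiles) == len(designs.smiles)
        assert all(v == 0 for v in counts.values())

    def test_pains_motif_eliminated(self, task):
        # both decorations present, but an azo bridge is a PAINS catalog hit
        azo = "CCc1ccc(N=Nc2ccc(CN)cc2)cc1"
        mol = chem.canonicalize(azo)
        assert find_scaffold(mol, list(task.decorations), alpha=1.0).success_score == 1.0
        kept, counts = quality_filter(DesignSet([mol.canonical_smiles]), list(task.decorations))
        assert not kept.smiles
        assert counts["pains"] == 1

    def test_fuzzy_decoration_variant_fails_exact_check(self):
        """A design scoring S_s = 1 under a loose allowance fails alpha = 1."""
        decorations = [Decoration.from_smiles("[*]CCO"), Decoration.from_smiles("[*]CN")]
        variant = chem.canonicalize("CCc1ccc(CN)cc1")  # ethyl where hydroxyethyl belongs
        assert find_scaffold(variant, decorations, alpha=0.66).success_score == 1.0
        assert find_scaffold(variant, decorations, alpha=1.0).success_score < 1.0
        kept, counts = quality_filter(DesignSet([variant.canonical_smiles]), decorations)
        assert not kept.smiles
        assert counts["decorations"] == 1

    def test_retained_set_is_rule_order_insensitive(self, task):
        azo = "CCc1ccc(N=Nc2ccc(CN)cc2)cc1"
        designs = DesignSet(list(task.positive_designs) + [chem.canonicalize(azo).canonical_smiles])
        kept, _ = quality_filter(designs, list(task.decorations))
        # rules are independent predicates: the azo design is the only loss
        assert set(kept.smiles) == set(task.positive_designs)


class TestDistancePanel:
    def test_reference_alone_has_zero_distances(self, task):
        designs = DesignSet([task.reference.canonical_smiles, task.reference.canonical_smiles])
        report = distance_panel(designs, task.reference, list(task.decorations))
        assert report.molecule_distance[0] == 0.0
        assert report.scaffold_distance[0] == 0.0
        assert report.unique_fraction == 0.5

    def test_mean_sd_match_direct_recomputation(self, task):
        designs = DesignSet(list(task.positive_designs))
        report = distance_panel(designs, task.reference, list(task.decorations))
        ref_fp = chem.ecfp(task.reference)
        manual = [
            chem.jaccard_distance(chem.ecfp(chem.canonicalize(s)), ref_fp)
            for s in designs.smiles
        ]
        assert report.molecule_distance[0] == pytest.approx(np.mean(manual))
        assert report.molecule_distance[1] == pytest.approx(np.std(manual))
        assert report.n_decomposed == len(designs.smiles)

    def test_distances_within_unit_interval(self, task):
        designs = DesignSet(list(task.positive_designs) + list(task.negative_designs))
        report = distance_panel(designs, task.reference, list(task.decorations))
        assert 0.0 <= report.molecule_distance[0] <= 1.0
        assert 0.0 <= report.scaffold_distance[0] <= 1.0
        # negatives carry no decorations: excluded from scaffold distances
        assert report.n_decomposed == len(task.positive_designs)

    def test_uniqueness_by_multiset_counting(self):
        designs = DesignSet(["CCO", "CCO", "CCN", "CCC"])
        report = distance_panel(
            designs,
            chem.canonicalize("CCc1ccc(CN)cc1"),
            [Decoration.from_smiles("[*]CC"), Decoration.from_smiles("[*]CN")],
        )
        assert report.unique_fraction == pytest.approx(3 / 4)
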