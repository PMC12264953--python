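"""Staged scoring of de novo designs against a reference molecule.

A design earns its reward in three stages:

1. **Molecule filter** — molecular weight, rotatable bonds and stereocenter
   caps (set comfortably above the reference's own values); failures score 0.
2. **Decoration inclusion** — ScaffoldFinder success score ``S_s``. Designs
   with none of the decorations score 0; designs with some but not all earn a
   flat *partial reward* (0.3 by default) and skip 3D scoring entirely,
   which both shapes the sparse-reward landscape and saves conformer time.
3. **Full scoring** — for ``S_s = 1``: the 2D reward ``S_2D`` is the Jaccard
   distance between the ECFPs of the design scaffold and the reference
   scaffold (*high distance = good hop*), the 3D reward ``S_3D`` is the best
   shape/pharmacophore overlay score of the conformer ensemble, and the final
   reward is their weighted harmonic mean

   ``S_F = (w_2D + w_3D) / (w_2D / S_2D + w_3D / S_3D)``

   so neither objective can be satisfied at the other's expense.

The reference scaffold is obtained once by self-decomposition: running
ScaffoldFinder on the reference with its own decorations at ``alpha = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

from rdkit import Chem

from . import chem
from .chem import Molecule
from .scaffoldfinder import Decoration, ScaffoldDecomposition, find_scaffold

__all__ = [
    "RewardConfig",
    "RewardBreakdown",
    "ReferencePack",
    "molecule_filter",
    "score_2d",
    "final_reward",
    "score_design",
]


@dataclass(frozen=True)
class RewardConfig:
    """Scoring-function parameters.

    Defaults are the published operating point: allowance ``alpha = 0.9``,
    shape/color weights 1.0/1.2, 2D/3D weights 1.5/1.0, partial reward 0.3,
    up to 32 conformers per stereoisomer. Filter thresholds of ``None`` are
    resolved from the reference molecule (+100 g/mol, +3 rotatable bonds,
    +2 stereocenters).
    """

    alpha: float = 0.9
    w_s: float = 1.0
    w_c: float = 1.2
    w_2d: float = 1.5
    w_3d: float = 1.0
    partial_reward: float = 0.3
    mw_max: float | None = None
    rotatable_max: int | None = None
    stereocenter_max: int | None = None
    max_conformers_per_isomer: int = 32
    macrocycle_ring_size: int = 10
    conformer_seed: int = 42

    def __post_init__(self) -> None:
        for name in ("w_s", "w_c", "w_2d", "w_3d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 < self.partial_reward < 1.0:
            raise ValueError("partial_reward must be in (0, 1)")

    def resolve_thresholds(self, reference: Molecule) -> "RewardConfig":
        """Fill unset filter thresholds from the reference's descriptors."""
        props = chem.properties(reference)
        return replace(
            self,
            mw_max=self.mw_max if self.mw_max is not None else props["molecular_weight"] + 100.0,
            rotatable_max=(
                self.rotatable_max
                if self.rotatable_max is not None
                else int(props["rotatable_bonds"]) + 3
            ),
            stereocenter_max=(
                self.stereocenter_max
                if self.stereocenter_max is not None
                else int(props["stereocenters"]) + 2
            ),
        )


@dataclass(frozen=True)
class RewardBreakdown:
    """Per-design scoring trace."""

    filtered: bool
    success_score: float
    s2d: float | None
    s3d: float | None
    final: float


@dataclass(frozen=True)
class ReferencePack:
    """Everything score_design needs about the reference ligand."""

    reference: Molecule
    decorations: tuple[Decoration, ...]
    scaffold: Molecule
    scaffold_fp: chem.FingerprintVector
    conformer: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @classmethod
    def build(
        cls,
        reference: Molecule,
        decorations: list[Decoration],
        conformer: Chem.Mol | None = None,
    ) -> "ReferencePack":
        """Self-decompose the reference (exact matching) to fix its scaffold."""
        decomp = find_scaffold(reference, decorations, alpha=1.0)
        if decomp.success_score < 1.0 or decomp.scaffold is None:
            raise ValueError(
                "reference does not decompose exactly with its own decorations "
                f"(S_s = {decomp.success_score:.2f})"
            )
        return cls(
            reference=reference,
            decorations=tuple(decorations),
            scaffold=decomp.scaffold,
            scaffold_fp=chem.ecfp(decomp.scaffold),
            conformer=conformer,
        )


def molecule_filter(mol: Molecule, cfg: RewardConfig) -> bool:
    """True = pass. Fails when any descriptor exceeds its threshold."""
    if cfg.mw_max is None or cfg.rotatable_max is None or cfg.stereocenter_max is None:
        raise ValueError("filter thresholds unresolved; call cfg.resolve_thresholds first")
    props = chem.properties(mol)
    return (
        props["molecular_weight"] <= cfg.mw_max
        and props["rotatable_bonds"] <= cfg.rotatable_max
        and props["stereocenters"] <= cfg.stereocenter_max
    )


def score_2d(design_scaffold: Molecule, ref_scaffold_fp: chem.FingerprintVector) -> float:
    """Jaccard distance between scaffold ECFPs; higher = better hop."""
    if design_scaffold.mol.GetNumAtoms() == 0:
        raise ValueError("empty design scaffold")
    return chem.jaccard_distance(chem.ecfp(design_scaffold), ref_scaffold_fp)


def final_reward(s2d: float, s3d: float, cfg: RewardConfig) -> float:
    """Weighted harmonic mean of the 2D and 3D rewards.

    Zero whenever either component is zero (the continuous limit), so a
    perfect score on one axis can never mask a failure on the other.
    """
    if s2d <= 0.0 or s3d <= 0.0:
        return 0.0
    return (cfg.w_2d + cfg.w_3d) / (cfg.w_2d / s2d + cfg.w_3d / s3d)


Scorer3D = Callable[[Molecule, Chem.Mol, RewardConfig], float]


def _default_scorer_3d(mol: Molecule, ref_conformer: Chem.Mol, cfg: RewardConfig) -> float:
    from . import shape3d

    return shape3d.best_conformer_score(mol, ref_conformer, cfg)


def score_design(
    design: Molecule,
    reference: ReferencePack,
    cfg: RewardConfig,
    scorer_3d: Scorer3D | None = None,
) -> RewardBreakdown:
    """Run one design through the full staged pipeline.

    ``scorer_3d`` is pluggable; the default generates a conformer ensemble and
    scores it against the reference bioactive conformer. Partial matches
    short-circuit before any 3D work.
    """
    if not molecule_filter(design, cfg):
        return RewardBreakdown(True, 0.0, None, None, 0.0)
    decomp: ScaffoldDecomposition = find_scaffold(
        design, list(reference.decorations), cfg.alpha
    )
    s_s = decomp.success_score
    if s_s == 0.0:
        return RewardBreakdown(False, 0.0, None, None, 0.0)
    if s_s < 1.0 or decomp.scaffold is None:
        return RewardBreakdown(False, s_s, None, None, cfg.partial_reward)
    s2d = score_2d(decomp.scaffold, reference.scaffold_fp)
    if scorer_3d is None:
        if reference.conformer is None:
            raise ValueError("reference pack has no bioactive conformer for 3D scoring")
        scorer_3d = _default_scorer_3d
    s3d = scorer_3d(design, reference.conformer, cfg)
    return RewardBreakdown(False, 1.0, s2d, s3d, final_reward(s2d, s3d, cfg))
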