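"""Conformer ensembles and 3D shape / pharmacophore ("color") scoring.

The 3D reward asks: can the design, in some accessible conformation, occupy
the same volume and present the same pharmacophore features as the reference
ligand's bioactive pose? The open-source backend here:

* enumerates unassigned stereoisomers;
* embeds up to ``max_conformers_per_isomer`` distance-geometry conformers
  (ETKDGv3, fixed seed) and relaxes them with MMFF94 (UFF fallback);
* rigidly aligns each conformer to the reference pose with Gaussian-volume
  shape overlap plus typed feature-map color overlap
  (:mod:`rdkit.Chem.rdShapeAlign`), both reported as Tanimoto-like scores in
  [0, 1];
* combines them per conformer as ``rho = (S_S*w_s + S_C*w_c)/(w_s + w_c)``
  and greedily takes the ensemble maximum as the design's ``S_3D``.

Macrocycles (any ring of >= ``macrocycle_ring_size`` atoms, default 10) are
rejected before embedding. Any scorer exposing ``best_conformer_score`` with
the same identity/rigid-invariance behavior can be swapped in (e.g. a
licensed overlay tool) without touching reward code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)
from rdkit.Chem import rdShapeAlign

from .chem import Molecule, from_rdkit
from .reward import RewardConfig

__all__ = [
    "ShapeColorScore",
    "MacrocycleError",
    "enumerate_stereoisomers",
    "is_macrocycle",
    "generate_conformers",
    "align_and_score",
    "best_conformer_score",
]

MAX_STEREOISOMERS = 8  # 2^3 unassigned centers; beyond that embedding cost explodes


class MacrocycleError(ValueError):
    """Raised when a molecule contains a ring too large for embedding."""


@dataclass(frozen=True)
class ShapeColorScore:
    """Per-conformer overlap scores and their weighted combination."""

    shape: float
    color: float
    rho: float


def combine(shape: float, color: float, cfg: RewardConfig) -> float:
    """Weighted mean ``rho`` of shape and color scores."""
    return (shape * cfg.w_s + color * cfg.w_c) / (cfg.w_s + cfg.w_c)


def enumerate_stereoisomers(mol: Molecule, max_isomers: int = MAX_STEREOISOMERS) -> list[Molecule]:
    """Expand unassigned stereocenters/double bonds; assigned ones are kept."""
    opts = StereoEnumerationOptions(onlyUnassigned=True, maxIsomers=max_isomers, unique=True)
    return [from_rdkit(m) for m in EnumerateStereoisomers(mol.mol, options=opts)]


def is_macrocycle(mol: Molecule, ring_size: int = 10) -> bool:
    return any(len(r) >= ring_size for r in mol.mol.GetRingInfo().AtomRings())


def generate_conformers(
    mol: Molecule,
    max_n: int = 32,
    seed: int = 42,
    macrocycle_ring_size: int = 10,
    max_isomers: int = MAX_STEREOISOMERS,
) -> list[tuple[Chem.Mol, int, int]]:
    """Energy-minimized conformer ensemble across stereoisomers.

    Returns ``(mol_with_hydrogens, conformer_id, isomer_tag)`` triples —
    deterministic for a fixed seed. Macrocycles raise
    :class:`MacrocycleError`; embedding failures simply yield an empty
    ensemble (the design will score 0).
    """
    if is_macrocycle(mol, macrocycle_ring_size):
        raise MacrocycleError(
            f"ring of >= {macrocycle_ring_size} atoms: macrocycles are not embedded"
        )
    out: list[tuple[Chem.Mol, int, int]] = []
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    for tag, isomer in enumerate(enumerate_stereoisomers(mol, max_isomers)):
        molh = Chem.AddHs(isomer.mol)
        ids = AllChem.EmbedMultipleConfs(molh, numConfs=max_n, params=params)
        if not ids:
            continue
        try:
            AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=200)
        except Exception:
            AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=200)
        for cid in ids:
            out.append((molh, int(cid), tag))
    return out


def _start_rotations(n: int = 4, seed: int = 0) -> list[np.ndarray | None]:
    """Identity plus ``n - 1`` fixed random proper rotations (seeded once)."""
    out: list[np.ndarray | None] = [None]
    rng = np.random.default_rng(seed)
    for _ in range(n - 1):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        out.append(q)
    return out


_ROTATIONS = _start_rotations()
# (opt_param, max_preiters) pairs for the overlap optimizer; the second,
# color-heavy setting rescues feature-flipped poses of shape-symmetric probes
_OPTIMIZER_SETTINGS = ((0.5, 3), (0.1, 10))


def _centered_copy(
    mol: Chem.Mol, conf_id: int = -1, rotation: np.ndarray | None = None
) -> Chem.Mol:
    out = Chem.Mol(mol)
    conf = out.GetConformer(conf_id)
    pos = conf.GetPositions()
    pos = pos - pos.mean(axis=0)
    if rotation is not None:
        pos = pos @ rotation.T
    for i, p in enumerate(pos):
        conf.SetAtomPosition(i, p.tolist())
    return out


def align_and_score(
    probe: Chem.Mol,
    ref: Chem.Mol,
    cfg: RewardConfig,
    probe_conf_id: int = -1,
    ref_conf_id: int = -1,
) -> ShapeColorScore:
    """Rigidly align one probe conformer to the reference pose and score it.

    Shape is a Gaussian-volume overlap Tanimoto; color is the analogous
    overlap of typed pharmacophore features (donor, acceptor, charges,
    hydrophobe, aromatic). Both structures are centered first and the
    optimizer is restarted from several fixed orientations and two
    weightings, keeping the pose with the best combined score — near-
    symmetric shapes otherwise strand the search in feature-flipped optima.
    The probe's input pose is irrelevant: centering plus restarts remove any
    rigid rotation/translation.
    """
    if probe.GetNumConformers() == 0:
        raise ValueError("probe has no conformer")
    ref_centered = _centered_copy(ref, ref_conf_id)
    best = ShapeColorScore(0.0, 0.0, 0.0)
    for rotation in _ROTATIONS:
        for opt_param, preiters in _OPTIMIZER_SETTINGS:
            work = _centered_copy(probe, probe_conf_id, rotation)
            shape, color = rdShapeAlign.AlignMol(
                ref_centered, work, -1, -1, True, opt_param, preiters, 30
            )
            shape = min(max(shape, 0.0), 1.0)
            color = min(max(color, 0.0), 1.0)
            rho = combine(shape, color, cfg)
            if rho > best.rho:
                best = ShapeColorScore(shape=shape, color=color, rho=rho)
    return best


def best_conformer_score(mol: Molecule, ref: Chem.Mol, cfg: RewardConfig) -> float:
    """Greedy ensemble maximum of ``rho`` — the design's ``S_3D``.

    Empty ensembles (embedding failure) and macrocycles score 0.
    """
    try:
        ensemble = generate_conformers(
            mol,
            max_n=cfg.max_conformers_per_isomer,
            seed=cfg.conformer_seed,
            macrocycle_ring_size=cfg.macrocycle_ring_size,
        )
    except MacrocycleError:
        return 0.0
    best = 0.0
    for molh, cid, _tag in ensemble:
        score = align_and_score(molh, ref, cfg, probe_conf_id=cid)
        if score.rho > best:
            best = score.rho
    return best
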