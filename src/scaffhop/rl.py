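"""The reinforcement-learning loop.

Each epoch the agent samples a batch of SMILES (64 at temperature 1 by
default), the staged scoring function assigns every design a final reward
``S_F``, a diversity filter zeroes rewards for over-produced Bemis-Murcko
scaffolds and banks high scorers, and the agent takes one gradient step on

    NLL_aug(i) = NLL_prior(i) - sigma * S_F(i)
    loss       = mean_i (NLL_aug(i) - NLL_agent(i))^2

pulling its likelihoods toward the prior's, shifted downward in proportion
to reward (``sigma = 128``). *Inception* adds a few replayed high-scoring
past designs to every update to accelerate the search. Invalid SMILES score
0 but stay in the batch — the agent is still pushed away from them exactly
as from valid low scorers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import chem
from .lstm import Adam, SmilesLSTM
from .reward import ReferencePack, RewardBreakdown, RewardConfig, score_design

__all__ = [
    "RLConfig",
    "DiversityFilter",
    "InceptionMemory",
    "augmented_nll",
    "policy_loss",
    "run",
]


@dataclass(frozen=True)
class RLConfig:
    """Loop hyper-parameters; defaults are the published operating point."""

    sigma: float = 128.0
    batch_size: int = 64
    epochs: int = 2000
    temperature: float = 1.0
    df_bucket_limit: int = 30
    memory_threshold: float = 0.4
    inception_memory_size: int = 100
    inception_sample_size: int = 10
    learning_rate: float = 1e-4
    max_len: int = 100
    seed: int = 42

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class DiversityFilter:
    """Penalizes over-produced scaffolds; banks every high-scoring design.

    Every design with a final reward at or above ``memory_threshold`` enters
    the memory (unique by canonical SMILES) — these are "the designs" an RL
    run produces — and fills its Bemis-Murcko scaffold's bucket. Once a
    scaffold's bucket holds more than ``bucket_limit`` designs, further
    high scorers on that scaffold get their reward zeroed, forcing the agent
    toward fresh scaffolds. Re-generating a design already in memory is also
    zeroed: repetition earns nothing.
    """

    bucket_limit: int = 30
    memory_threshold: float = 0.4
    scaffold_counts: dict[str, int] = field(default_factory=dict)
    memory: dict[str, RewardBreakdown] = field(default_factory=dict)

    def apply(self, smiles: str, breakdown: RewardBreakdown) -> float:
        if breakdown.final < self.memory_threshold:
            return breakdown.final
        mol = chem.canonicalize(smiles)
        if mol is None:
            return breakdown.final
        key = mol.canonical_smiles
        if key in self.memory:
            return 0.0
        self.memory[key] = breakdown
        cls = chem.bm_framework(mol).cyclic_class
        count = self.scaffold_counts.get(cls, 0) + 1
        self.scaffold_counts[cls] = count
        return 0.0 if count > self.bucket_limit else breakdown.final


@dataclass
class InceptionMemory:
    """Bounded replay buffer of the best (smiles, reward, prior NLL) triples."""

    capacity: int = 100
    entries: list[tuple[str, float, float]] = field(default_factory=list)

    def update(self, batch: list[tuple[str, float, float]]) -> None:
        pool = {smi: (smi, r, npr) for smi, r, npr in self.entries}
        for smi, r, npr in batch:
            if r > 0 and smi not in pool:
                pool[smi] = (smi, r, npr)
        ranked = sorted(pool.values(), key=lambda e: (-e[1], e[0]))
        self.entries = ranked[: self.capacity]

    def draw(self, n: int, rng: np.random.Generator) -> list[tuple[str, float, float]]:
        if not self.entries or n <= 0:
            return []
        idx = rng.choice(len(self.entries), size=min(n, len(self.entries)), replace=False)
        return [self.entries[i] for i in idx]


def augmented_nll(nll_prior: float, s_f: float, sigma: float) -> float:
    """``NLL_aug = NLL_prior - sigma * S_F``."""
    return nll_prior - sigma * s_f


def policy_loss(nll_aug: np.ndarray, nll_agent: np.ndarray) -> float:
    """Mean squared difference between augmented and agent NLLs."""
    nll_aug = np.asarray(nll_aug, dtype=np.float64)
    nll_agent = np.asarray(nll_agent, dtype=np.float64)
    if nll_aug.size == 0:
        raise ValueError("policy loss undefined for an empty batch")
    return float(np.mean((nll_aug - nll_agent) ** 2))


RewardFn = Callable[[str], RewardBreakdown]


def make_reward_fn(
    reference: ReferencePack,
    reward_cfg: RewardConfig,
    scorer_3d=None,
) -> RewardFn:
    """Staged scorer over raw SMILES with a canonical-SMILES result cache.

    RL batches repeat molecules heavily once learning takes hold; caching by
    canonical structure makes re-scoring free without changing any result.
    """
    cache: dict[str, RewardBreakdown] = {}
    zero = RewardBreakdown(False, 0.0, None, None, 0.0)

    def score(smiles: str) -> RewardBreakdown:
        mol = chem.canonicalize(smiles)
        if mol is None:
            return zero
        key = mol.canonical_smiles
        if key not in cache:
            cache[key] = score_design(mol, reference, reward_cfg, scorer_3d=scorer_3d)
        return cache[key]

    return score


def run(
    prior: SmilesLSTM,
    reference: ReferencePack,
    cfg: RLConfig,
    reward_cfg: RewardConfig,
    scorer_3d=None,
    callback=None,
) -> tuple[SmilesLSTM, DiversityFilter, pd.DataFrame]:
    """Full RL campaign; returns (agent, diversity-filter memory, epoch log).

    Deterministic for a fixed config: one seeded generator drives sampling
    and inception draws. The epoch log carries, per epoch, the mean final
    reward of the batch, the count of designs scoring >= 0.7, the memory
    size, the policy loss, and the mean agent/prior NLLs, so the learning
    curve and the loss identities can be recomputed post hoc.
    """
    reward_cfg = reward_cfg.resolve_thresholds(reference.reference)
    agent = prior.clone()
    opt = Adam(agent.params, lr=cfg.learning_rate)
    df = DiversityFilter(cfg.df_bucket_limit, cfg.memory_threshold)
    inception = InceptionMemory(cfg.inception_memory_size)
    score = make_reward_fn(reference, reward_cfg, scorer_3d)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for epoch in range(cfg.epochs):
        seqs, nll_agent = agent.sample(
            cfg.batch_size, max_len=cfg.max_len, temperature=cfg.temperature, rng=rng
        )
        smiles = [agent.vocab.decode(s) for s in seqs]
        nll_prior = prior.nll(seqs).astype(np.float64)
        breakdowns = [score(s) for s in smiles]
        rewards = np.array([df.apply(s, b) for s, b in zip(smiles, breakdowns)])
        nll_aug = nll_prior - cfg.sigma * rewards

        replay = inception.draw(cfg.inception_sample_size, rng)
        replay_seqs = [agent.vocab.encode(smi) for smi, _, _ in replay]
        replay_aug = np.array(
            [augmented_nll(npr, r, cfg.sigma) for _, r, npr in replay]
        )
        all_seqs = seqs + replay_seqs
        all_aug = np.concatenate([nll_aug, replay_aug]) if replay else nll_aug
        n_total = len(all_seqs)

        cur_nll = agent.nll(all_seqs).astype(np.float64)
        weights = 2.0 / n_total * (cur_nll - all_aug)
        _, grads = agent.nll_and_grads(all_seqs, weights)
        opt.step(agent.params, grads)

        inception.update(
            [
                (smi, float(r), float(npr))
                for smi, r, npr in zip(smiles, rewards, nll_prior)
            ]
        )
        loss = policy_loss(all_aug, cur_nll)
        rows.append(
            {
                "epoch": epoch,
                # mean_score is the scoring function's average (the learning
                # curve); mean_reward is after diversity-filter zeroing (what
                # the loss sees — repeats and over-full scaffolds earn 0)
                "mean_score": float(np.mean([b.final for b in breakdowns])),
                "mean_reward": float(rewards.mean()),
                "n_high": int((rewards >= 0.7).sum()),
                "n_memory": len(df.memory),
                "loss": loss,
                "mean_nll_agent": float(nll_agent.mean()),
                "mean_nll_prior": float(nll_prior.mean()),
                "mean_nll_aug": float(nll_aug.mean()),
            }
        )
        if callback is not None:
            callback(epoch, rows[-1])
    return agent, df, pd.DataFrame(rows)
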