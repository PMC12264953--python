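"""Shared fixtures: one toy task, one trained prior, one RL campaign.

Everything is generated at test time from seeds; the expensive artifacts
(prior training, the 200-epoch RL run) are session-scoped and shared.
"""

from __future__ import annotations

import pytest

from scaffhop import generator, rl
from scaffhop.fixtures import make_task
from scaffhop.reward import ReferencePack, RewardConfig
from scaffhop.rl import RLConfig


@pytest.fixture(scope="session")
def task():
    return make_task(seed=42)


@pytest.fixture(scope="session")
def prior_with_curve(task):
    curve = []
    model = generator.train_prior(
        list(task.corpus), epochs=10, callback=lambda e, nll: curve.append(nll)
    )
    return model, curve


@pytest.fixture(scope="session")
def prior(prior_with_curve):
    return prior_with_curve[0]


@pytest.fixture(scope="session")
def reference_pack(task):
    return ReferencePack.build(
        task.reference, list(task.decorations), conformer=task.reference_conformer
    )


def constant_3d(mol, ref, cfg):
    """2D-only stub: the 3D stage contributes a perfect score."""
    return 1.0


@pytest.fixture(scope="session")
def rl_campaign(prior, reference_pack, task):
    """200 RL epochs, seed 42, 2D-only scorer — the desk-scale learning run."""
    agent, df, log = rl.run(
        prior,
        reference_pack,
        RLConfig(epochs=200, seed=42),
        RewardConfig(),
        scorer_3d=constant_3d,
    )
    return agent, df, log
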