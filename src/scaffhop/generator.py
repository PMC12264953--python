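"""Training, sampling and fine-tuning of the SMILES language model.

The *prior* is an LSTM trained by maximum likelihood on a corpus of drug-like
SMILES; it defines what "chemically plausible" means for the RL stage.
*Transfer learning* then biases a copy of the prior toward one reference
molecule by continued training on randomized SMILES enumerations of that
single string, stopping at the first epoch where the reference is sampled
with frequency above 5% (measured on a large seeded sample) — biased enough
to find the reference's chemotype quickly, not yet collapsed onto it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import chem
from .lstm import Adam, SmilesLSTM
from .vocab import Vocabulary

__all__ = [
    "GeneratorConfig",
    "SampledBatch",
    "train_prior",
    "sample",
    "nll",
    "finetune",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Network and training hyper-parameters.

    The production-scale recipe uses 3 recurrent layers of 512 units with a
    256-dimensional embedding; the defaults here are a desk-scale setting
    that trains in seconds on a small corpus while keeping the same
    architecture family. Everything is overridable.
    """

    embedding_dim: int = 64
    hidden_dim: int = 128
    num_layers: int = 1
    batch_size: int = 64
    learning_rate: float = 5e-3
    max_len: int = 100
    seed: int = 42


@dataclass(frozen=True)
class SampledBatch:
    """Sampled SMILES with their agent NLLs and validity flags."""

    smiles: list[str]
    nll_agent: np.ndarray
    valid: list[bool]


def train_prior(
    corpus: list[str],
    epochs: int = 10,
    cfg: GeneratorConfig = GeneratorConfig(),
    callback=None,
) -> SmilesLSTM:
    """Maximum-likelihood training on a SMILES corpus.

    Shuffles per epoch from the config seed; ``callback(epoch, mean_nll)``
    receives the running training curve.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    vocab = Vocabulary.from_corpus(corpus)
    model = SmilesLSTM(
        vocab, cfg.embedding_dim, cfg.hidden_dim, cfg.num_layers, seed=cfg.seed
    )
    encoded = [vocab.encode(s) for s in corpus]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    for epoch in range(epochs):
        order = rng.permutation(len(encoded))
        losses = []
        for start in range(0, len(encoded), cfg.batch_size):
            batch = [encoded[i] for i in order[start : start + cfg.batch_size]]
            weights = np.full(len(batch), 1.0 / len(batch), dtype=np.float32)
            seq_nll, grads = model.nll_and_grads(batch, weights)
            opt.step(model.params, grads)
            losses.append(float(seq_nll.mean()))
        if callback is not None:
            callback(epoch, float(np.mean(losses)))
    return model


def sample(
    model: SmilesLSTM, n: int, temperature: float = 1.0, seed: int = 42, max_len: int = 100
) -> SampledBatch:
    """Draw ``n`` SMILES; reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    seqs, nlls = model.sample(n, max_len=max_len, temperature=temperature, rng=rng)
    smiles = [model.vocab.decode(s) for s in seqs]
    valid = [chem.canonicalize(s) is not None for s in smiles]
    return SampledBatch(smiles=smiles, nll_agent=nlls, valid=valid)


def nll(model: SmilesLSTM, smiles: str) -> float:
    """NLL of one SMILES string under the model, in nats."""
    return float(model.nll([model.vocab.encode(smiles)])[0])


def randomized_smiles(smiles: str, n: int, seed: int) -> list[str]:
    """Non-canonical SMILES enumerations of one molecule (training augmentation)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    out = []
    for i in range(n):
        out.append(
            Chem.MolToSmiles(mol, canonical=False, doRandom=True)
            if i
            else Chem.MolToSmiles(mol)
        )
    # doRandom uses RDKit's internal RNG; re-sort deterministically
    rng = np.random.default_rng(seed)
    rng.shuffle(out)
    return out


def finetune(
    prior: SmilesLSTM,
    reference: str,
    max_epochs: int = 20,
    n_samples: int = 10_000,
    frequency_threshold: float = 0.05,
    augment: int = 64,
    learning_rate: float = 1e-3,
    seed: int = 42,
    callback=None,
) -> tuple[SmilesLSTM, list[float]]:
    """Transfer learning toward one reference molecule.

    Each epoch trains on ``augment`` randomized SMILES writings of the
    reference, then samples ``n_samples`` strings and measures how often
    their canonical form equals the reference. Returns the first model whose
    frequency exceeds ``frequency_threshold`` (default 5%), or the last
    one with the recorded frequency curve if the criterion is never met.
    """
    ref_mol = chem.canonicalize(reference)
    if ref_mol is None:
        raise ValueError(f"invalid reference SMILES: {reference!r}")
    ref_canonical = ref_mol.canonical_smiles
    model = prior.clone()
    opt = Adam(model.params, lr=learning_rate)
    frequencies: list[float] = []
    for epoch in range(max_epochs):
        variants = []
        for smi in randomized_smiles(ref_canonical, augment, seed + epoch):
            try:
                variants.append(model.vocab.encode(smi))
            except ValueError:
                continue  # enumeration used a token the corpus never showed
        if not variants:
            raise ValueError("no tokenizable SMILES writing of the reference")
        weights = np.full(len(variants), 1.0 / len(variants), dtype=np.float32)
        _, grads = model.nll_and_grads(variants, weights)
        opt.step(model.params, grads)
        batch = sample(model, n_samples, temperature=1.0, seed=seed + 7919 * epoch)
        hits = sum(
            1
            for s, ok in zip(batch.smiles, batch.valid)
            if ok and chem.canonicalize(s).canonical_smiles == ref_canonical
        )
        freq = hits / n_samples
        frequencies.append(freq)
        if callback is not None:
            callback(epoch, freq)
        if freq > frequency_threshold:
            return model, frequencies
    return model, frequencies


def save_model(model: SmilesLSTM, path: str | Path) -> None:
    """Checkpoint: weights plus embedded vocabulary and shape metadata."""
    meta = {
        "tokens": list(model.vocab.tokens),
        "embedding_dim": model.embedding_dim,
        "hidden_dim": model.hidden_dim,
        "num_layers": model.num_layers,
        "format_version": 1,
    }
    np.savez(path, __meta__=json.dumps(meta), **model.params)


def load_model(path: str | Path) -> SmilesLSTM:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    vocab = Vocabulary.from_tokens(meta["tokens"])
    model = SmilesLSTM(
        vocab, meta["embedding_dim"], meta["hidden_dim"], meta["num_layers"]
    )
    for k in model.params:
        model.params[k] = data[k]
    return model
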