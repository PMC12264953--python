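# scaffhop

Reinforcement-learning **scaffold hopping**: generate molecules that keep a
reference ligand's decorations and 3D shape/pharmacophore while replacing
its core scaffold with a structurally different one.

Medicinal chemists hop scaffolds to escape flat SAR, patent space or
liabilities of a chemical series without losing binding. `scaffhop` frames
this as goal-directed generation: a SMILES LSTM agent is updated, epoch by
epoch, toward designs that score well under a staged reward built around
**ScaffoldFinder**, a fuzzy decoration-matching decomposition.

## The method in brief

Given a reference molecule, its decorations *R* (fragments with one
attachment point each) and its bioactive conformer:

1. **ScaffoldFinder** matches each decoration *r* (size *n_r*) in a design
   by largest common substructure, letting the attachment dummy stand for
   any heavy atom of degree > 1, picks the most peripheral placement, and
   test-cleaves it. A cleaved fragment of *n_d* atoms is accepted when
   *n_r·α ≤ n_d ≤ n_r/α* (allowance *α*, default 0.9; at *α* = 0.8 a
   10-atom decoration admits 8–12 atoms). The success score is
   *S_s = Σ_r δ(r) / |R|*; at *S_s* = 1 the cut core is returned as the
   scaffold.
2. **Staged reward.** Property-filtered designs score 0; partial inclusion
   (0 < *S_s* < 1) earns a flat 0.3 and skips 3D work; full inclusion gets
   *S_2D* — the Jaccard distance between scaffold ECFPs (radius 3,
   2048 bits; higher = better hop) — and *S_3D* — the best conformer
   overlay *ρ = (S_S·w_s + S_C·w_c)/(w_s + w_c)* of Gaussian shape (*S_S*)
   and pharmacophore color (*S_C*) scores — combined as the weighted
   harmonic mean
   *S_F = (w_2D + w_3D) / (w_2D/S_2D + w_3D/S_3D)*,
   with defaults *w_s* = 1.0, *w_c* = 1.2, *w_2D* = 1.5, *w_3D* = 1.0.
3. **RL update.** Per epoch 64 SMILES are sampled at *T* = 1 and the agent
   takes one gradient step on
   *loss = mean_i (NLL_Aug(i) − NLL_Agent(i))²* with
   *NLL_Aug = NLL_Prior − σ·S_F* and *σ* = 128, after a diversity filter
   zeroes rewards for over-produced Bemis–Murcko scaffolds (bucket 30) and
   banks all designs scoring ≥ 0.4. An inception buffer replays past high
   scorers. Transfer learning can pre-bias the prior toward the reference
   until it is sampled with > 5% frequency.

The sequence model (stacked LSTM, weighted-NLL backpropagation through
time, Adam) is implemented in NumPy; chemistry goes through RDKit.

## Worked example

Everything below runs on generated toy chemistry — no external data:

```
$ scaffhop make-fixtures --seed 42 --out fx
fixture task written to fx (reference CCc1ccc(CN)cc1)

$ scaffhop scaffoldfinder --design 'CCc1cc(CN)cs1' --decorations fx/decorations.smi --alpha 0.9
S_s=1.000 scaffold=*c1csc(*)c1
```

The thiophene design contains both reference decorations (ethyl `*CC`,
aminomethyl `*CN`), so the decomposition succeeds (*S_s* = 1.000) and
returns the thiophene-diyl scaffold with two attachment dummies.

```
$ scaffhop score --designs fx/designs.smi --reference-sdf fx/reference.sdf \
        --decorations fx/decorations.smi --out scores.csv
scored 28 designs -> scores.csv
```

with, among others, these rows:

```
        smiles  s_s      s2d      s3d      s_f
CCc1ccc(CN)cc1  1.0 0.000000 1.000000 0.000000
CCc1ccc(CN)cn1  1.0 0.681818 0.888052 0.751640
 CCc1cc(CN)cs1  1.0 0.761905 0.772242 0.766006
CCC1CCC(CN)CC1  1.0 0.947368 0.584955 0.759217
```

The first row is the reference scored against itself: both decorations are
found, the 3D overlay is perfect (*s3d* = 1.0), but the scaffold distance
is zero — a self-copy is the worst possible hop, and the harmonic mean
makes the final score 0. The pyridine, thiophene and cyclohexane analogs
keep the decorations and most of the 3D overlap while moving 2D-away from
the benzene scaffold, earning final scores around 0.75. Partial designs in
the file score a flat 0.3; designs without decorations score 0.

Train a toy prior and run a short RL campaign (the `--no-3d` flag scores
2D-only, with the 3D stage fixed at 1):

```
$ scaffhop train-prior --corpus fx/corpus.smi --epochs 10 --out prior.npz
$ scaffhop rl-run --prior prior.npz --reference-sdf fx/reference.sdf \
        --decorations fx/decorations.smi --epochs 200 --out rl_out --no-3d
200 epochs done: 200 designs in memory, final mean reward 0.211
```

`rl_out/epochs.log` holds the per-epoch learning curve (`mean_score` rises
from ≈0.27 to ≈0.42 over 200 epochs on this task as the agent learns to
include both decorations on fresh scaffolds) and `rl_out/memory.smi` the
banked designs with their scores.

## Layout

| module | contents |
| --- | --- |
| `scaffhop.chem` | canonicalization, ECFPs, Jaccard distance, Bemis–Murcko frameworks, descriptors |
| `scaffhop.scaffoldfinder` | fuzzy decoration matching, peripheral selection, cleavage, scaffold extraction |
| `scaffhop.reward` | molecule filter, partial reward, 2D reward, harmonic-mean final reward |
| `scaffhop.shape3d` | stereoisomer enumeration, conformer ensembles, shape/color overlay scoring |
| `scaffhop.vocab`, `scaffhop.lstm`, `scaffhop.generator` | SMILES tokenizer, NumPy LSTM, prior training / sampling / transfer learning |
| `scaffhop.rl` | diversity filter, inception, augmented-NLL loss, the RL loop |
| `scaffhop.evaluation` | Scaled Shannon Entropy, retrieval curves, distance panels, quality filters |
| `scaffhop.fixtures` | deterministic toy tasks, corpora and conformer pairs |
| `scaffhop.cli`, `scaffhop.config`, `scaffhop.fileio` | `scaffhop` command-line tool, YAML config with hashing, .smi/SDF I/O |

See `docs/methods.md` for the model, its assumptions, parameter meanings
and known limitations.
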