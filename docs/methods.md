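# Methods

`scaffhop` implements a reinforcement-learning approach to *unconstrained
scaffold hopping*: given one reference ligand with a known bioactive 3D pose
and a list of its decorations (peripheral fragments), a SMILES language
model is steered to propose molecules that keep the decorations and the 3D
shape/pharmacophore of the reference while replacing its scaffold with a
2D-dissimilar one.

## Scaffold decomposition (ScaffoldFinder)

A decoration is a fragment SMILES with exactly one attachment dummy `[*]`;
its size `n_r` counts heavy atoms excluding the dummy. For a design and a
decoration the algorithm:

1. finds the largest common substructure between decoration and design in
   which the dummy may stand for any heavy atom of degree > 1. A match is
   accepted only if the dummy is part of it, its counterpart is joined by a
   single (acyclic) bond, and the matched decoration part keeps at least
   `alpha * n_r` atoms;
2. among multiple placements picks the most peripheral one — the placement
   whose cleavage leaves the most atoms on the scaffold side — breaking
   ties on the lowest matched atom index;
3. test-cleaves the attachment bond; the cut must yield exactly two valid
   fragments, and the decoration-side fragment size `n_d` must satisfy
   `n_r * alpha <= n_d <= n_r / alpha`, both bounds inclusive (with
   `n_r = 10`, `alpha = 0.8` this permits 8–12 atoms; the inclusive lower
   bound is required to reproduce that window).

The success score `S_s` is the fraction of decorations matched, with
matched atom sets kept pairwise disjoint (decorations are processed largest
first, because larger fragments are more specific). Only when `S_s = 1` are
all bonds cut and the remaining core returned as the scaffold, one dummy
per cleavage site.

The common-substructure search is exact rather than heuristic: any valid
match must contain the dummy and its anchor atom, so the admissible
subgraphs of the decoration are connected deletions of at most
`n_r - ceil(alpha * n_r)` peripheral atoms. These are enumerated
exhaustively and matched as substructure queries (element-exact,
bond-order-exact, ring atoms matching only ring atoms, the dummy a
wildcard). At the default `alpha = 0.9` this means at most one or two
deletions per decoration; the search is deterministic and fast, and a
generic MCS engine with its timeout semantics is unnecessary. When a cut or
the size window fails for the best-ranked placement, the next placement
(and, failing that, the next smaller match size) is tried — the reported
match is the largest *cleavable* common substructure.

## Staged scoring

Designs are scored in three short-circuiting stages:

1. **Filter.** Molecular weight, rotatable-bond and stereocenter caps. When
   not set explicitly they are derived from the reference: +100 g/mol,
   +3 rotors, +2 stereocenters — "comfortably above" the reference without
   admitting grossly larger molecules. Filtered designs score 0.
2. **Decoration inclusion.** `S_s = 0` scores 0. `0 < S_s < 1` earns the
   flat partial reward 0.3 and skips all 3D work; this both shapes the
   sparse reward landscape (decoration inclusion is learnable before any
   scaffold is good) and saves conformer generation on hopeless designs.
3. **Full reward.** `S_2D` is the Jaccard (Tanimoto) distance between
   ECFPs (radius 3, 2048 bits, no stereo) of the design scaffold and the
   reference scaffold, both carrying their attachment dummies — *distance*,
   so unfamiliar scaffolds score high. `S_3D` is the best conformer overlay
   score (below). The final reward is the weighted harmonic mean
   `S_F = (w_2D + w_3D) / (w_2D/S_2D + w_3D/S_3D)` with `w_2D = 1.5`,
   `w_3D = 1.0`, defined as 0 when either input is 0 (continuous limit), so
   optimizing one objective can never pay for abandoning the other.

The reference scaffold is fixed once by *self-decomposition*: running
ScaffoldFinder on the reference with its own decorations at `alpha = 1`,
which must succeed exactly.

## 3D scoring backend

The open backend enumerates unassigned stereoisomers (capped at 8 — three
free centers — beyond which embedding cost dominates), embeds up to 32
ETKDGv3 conformers per isomer with a fixed seed (42) and relaxes them with
MMFF94. Each conformer is rigidly aligned to the reference pose by
Gaussian-volume shape overlap plus typed feature ("color") overlap, giving
two Tanimoto-like scores in [0, 1], combined per conformer as
`rho = (S_S*w_s + S_C*w_c)/(w_s + w_c)` with `w_s = 1.0`, `w_c = 1.2`
(color is harder to satisfy and is weighted up). `S_3D` is the greedy
ensemble maximum of `rho`.

Two numerical choices matter. Both structures are centered before
alignment, removing translations of any magnitude. And the overlap
optimizer is restarted from four fixed orientations under two
shape/color weightings, keeping the best combined pose: near-symmetric
shapes (e.g. para-substituted rings) otherwise strand the optimizer in a
shape-perfect but feature-flipped pose. The restart orientations are seeded
once at module load, so scoring is deterministic.

Macrocycles (any ring of 10 or more atoms — the cutoff is configurable) are
rejected before embedding and score 0, as do molecules whose embedding
fails. Any scorer exposing the same interface and passing the identity and
rigid-invariance tests can replace this backend (e.g. a licensed overlay
tool); the reward stage is agnostic to it.

## Sequence model and training

The generator is a stacked-LSTM language model over SMILES lexemes
(bracket atoms, two-letter elements and `%nn` ring closures are single
tokens; `tokenize -> detokenize` is the identity on every training string).
It is implemented directly in NumPy — forward pass, backpropagation through
time, Adam with global-norm gradient clipping — because per-sequence NLL
gradients with arbitrary weights are the only primitive the RL loss needs,
and sequence lengths here are short. The backward pass is verified against
central-difference gradients in float64, and sampling is verified against
the model's own likelihoods by a chi-squared test on an enumerable toy
vocabulary.

The *prior* is trained by maximum likelihood; the desk-scale default
architecture (1 layer, 128 hidden units, 64-d embedding) trains on the
1,000-molecule toy corpus in seconds, while the production-scale recipe
(3 layers, 512 units, 256-d embedding, 20 epochs on a ChEMBL-scale corpus)
is reachable through the same configuration object.

*Transfer learning* fine-tunes a copy of the prior toward one reference
molecule. Literal single-string training degenerates, so each epoch trains
on randomized (non-canonical) SMILES writings of the reference; after each
epoch a large seeded sample (10,000 strings by default) measures the
frequency of the reference's canonical form, and the first model exceeding
5% is returned. The frequency is the observable the stopping rule is
defined on; NLL-based equivalents were deliberately avoided because the
frequency is what the criterion quotes.

## Reinforcement learning

Each epoch the agent samples 64 SMILES at temperature 1; every string is
scored (invalid SMILES score 0 but stay in the batch — the update pushes
the agent away from them exactly as from valid low scorers); the diversity
filter adjusts rewards; and one Adam step is taken on

    NLL_aug(i) = NLL_prior(i) - sigma * S_F(i),      sigma = 128
    loss = (1/N) * sum_i (NLL_aug(i) - NLL_agent(i))^2

computed over the batch plus replayed *inception* entries. The loss
gradient is `2/N * (NLL_agent - NLL_aug)` per sequence, fed to the shared
weighted-NLL backward pass. The default learning rate is 1e-4.

**Diversity filter.** Every design with `S_F >= 0.4` is banked in the run's
memory (unique by canonical SMILES) and counted against its Bemis-Murcko
scaffold's bucket; once a bucket holds more than 30 designs, further high
scorers on that scaffold are zeroed, and re-generating a banked design is
always zeroed. Counting *scored* rather than *banked* designs was tried and
rejected: on a task with few scaffold classes it exhausts every bucket with
low scorers and extinguishes the reward signal entirely. Acyclic scaffolds
share the single reserved class "no cyclic substructure(s)".

**Inception.** A bounded buffer (capacity 100) keeps the best-rewarded
designs seen so far; 10 are drawn uniformly each epoch and their squared
loss terms joined to the batch. In paired-seed A/B runs on the fixture task
this measurably accelerates cumulative reward.

The epoch log records both the scoring function's batch average
(`mean_score`, the learning-curve quantity) and the post-filter average
(`mean_reward`, what the loss sees); the two diverge precisely when the
filter is doing its job, since repeats earn 0. It also records enough means
for the augmented-NLL identity to be re-verified post hoc. A fixed
configuration and seed reproduce a run bit-for-bit.

## Evaluation

*Scaled Shannon Entropy* over Bemis-Murcko cyclic-substructure classes:
`SSE = (-sum p_i log2 p_i) / log2 n` with `n` the number of designs. The
`log2 n` denominator is the only normalization meeting both defining
boundary conditions (one class -> 0, all singletons -> 1). The *retrieval
curve* plots the cumulative fraction of designs covered by scaffolds ranked
most-common-first. The *distance panel* reports Jaccard distances of full
molecules (plain ECFPs, no dummies) and of extracted scaffolds to the
reference, mean +/- sd, counting designs that fail to decompose. The
*quality filter* applies, in reporting order: exact decoration inclusion
(ScaffoldFinder at `alpha = 1` — fuzzily varied decorations that scored
during generation fail here by design), the PAINS substructure catalog, the
standard synthetic-accessibility score (default cutoff 4.5), and a ring
aromaticity sanity check (no ring partially aromatic). The rules are
independent predicates, so the retained set is order-insensitive; each
elimination is charged to the first failing rule.

## The fixture task

Tests and desk-scale experiments run on generated toy chemistry: a
reference assembled as ring core + decorations (default: benzene with
ethyl and aminomethyl), positive/partial/negative design sets across eight
ring families — verified at construction time to decompose with exactly the
intended `S_s` — a synthetic "bioactive" conformer (seeded embedding), and
a 1,000-molecule corpus drawn from a generative process in which single
decorations are common but complete decoration sets are rare, so inclusion
must actually be learned. The corpus emulates none of real pharmacology,
property distributions or synthesizability; passing tests demonstrate the
*mechanics* (decomposition correctness, reward algebra, learning dynamics),
not transfer to real targets.

Desk-scale problem sizes used throughout: 1,000-molecule corpus, 10 prior
epochs, 200 RL epochs at batch 64 with the 2D-only scorer (the 3D stage
stubbed to 1.0, exercising stage decoupling). Production-scale settings
(ChEMBL-scale corpus, 20 prior epochs, 2,000 RL epochs, full 3D scoring)
are configuration, not code changes.

## Known limitations

* The open 3D backend approximates, but does not reproduce, commercial
  overlay tools; scores are comparable in range and behavior, not
  numerically.
* Decorations must be single-attachment fragments joined by acyclic single
  bonds; multi-attachment decorations are out of scope.
* The NumPy LSTM is single-threaded; ChEMBL-scale prior training is
  supported in interface but slow compared to GPU frameworks.
* One reference at a time; multi-reference aggregation is not implemented.
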