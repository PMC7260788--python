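# Methods

This note documents the models and procedures scaffdec implements, the
choices made where the design was genuinely open, and what the desk-scale
test conditions do and do not demonstrate.

## Slicing algorithm

A molecule with candidate bond set *B* is cut on every subset of
1..c<sub>max</sub> bonds. Candidates are always single, acyclic bonds
between heavy atoms; with the RECAP rule set they must additionally match at
least one two-atom SMARTS pattern (the cleavable bond is the bond between
the pattern's first two atoms). Cutting *c* bonds of a connected molecule
along acyclic edges always yields *c*+1 fragments; the unique fragment with
*c* attachment points is the scaffold, and the remaining fragments — then
necessarily one attachment each — are the decorations. When no fragment has
*c* attachments the combination is discarded. A single cut is symmetric, so
both orientations (either fragment as scaffold) are generated and filtered
independently.

Defaults mirror the training-set conditions this architecture was designed
for: c<sub>max</sub> = 4 (the largest attachment count that occurs in
focused bioactivity sets of this kind), scaffolds must contain at least one
ring, and decorations must be fragment-like by the rule of 3 — MW ≤ 300 Da,
H-bond donors ≤ 3, acceptors ≤ 3, cLogP ≤ 3, rotatable bonds ≤ 3. Property
conventions the filter's name does not pin down were fixed as: RDKit
descriptors throughout; the attachment dummy has zero mass and contributes
its (negligible) Crippen atom term; the bond to the dummy is terminal and
never counts as rotatable. Under these conventions a benzhydryl fragment
(cLogP 3.33) narrowly fails the filter, so classic tuples whose decorations
are two-ring fragments only appear when the decoration filter is disabled —
the filters are arguments, not policy.

Decoration order is meaningful: `decorations[i]` belongs to the i-th `[*]`
by appearance in the stored scaffold string. Internally each cut bond gets
an isotope label so scaffold attachment points can be paired with the
decoration severed at the same bond after canonicalization; the labels are
stripped before storage. Tuples are deduplicated per molecule on (canonical
scaffold, sorted canonical decorations) but kept as a multiset across the
corpus — the same scaffold arising from two molecules is two training
examples.

The shipped RECAP registry covers the 11 classical bond classes (amide,
ester, amine, urea, ether, olefin, quaternary nitrogen, aromatic
nitrogen–aliphatic carbon, lactam nitrogen–aliphatic carbon, aromatic
carbon–aromatic carbon, sulfonamide) as pragmatic two-atom SMARTS; the file
is plain text and user-replaceable. The olefin class cleaves a double bond
and therefore never selects a cut bond here (cuts are restricted to single
bonds so rejoining is always a single bond); it remains in the registry for
audit parity.

## Generative models

Both models share one cell: embedding → stacked LSTM layers → linear →
softmax over the vocabulary, trained by teacher forcing on the token-level
negative log-likelihood (nats, summed over the sequence including the end
marker). The vocabulary is corpus-derived (atom tokens, bond/branch/ring
tokens, the attachment token `[*]`, the separator `|`, begin/end/pad);
unseen tokens at inference raise an error rather than map to an unknown
class. Sequences in a batch are padded and masked; the mask freezes the
recurrent state at pad steps, which also makes the backward encoder
direction correct on right-padded batches.

The decorator is an encoder–decoder. The encoder is bidirectional; the
forward and backward hidden and cell states are summed per layer and seed
the decoder, and the per-position outputs of both directions are summed to
form the attention memory O<sub>e</sub>. At each decoder step *i* the raw
output O<sub>d,i</sub> attends over the scaffold:

    AW_i  = softmax(O_d,i · O_e^T / sqrt(d))     (pad positions at -inf)
    AC_i  = Σ_p AW_i[p] · O_e[p]
    O'_d,i = tanh(W [O_d,i ; AC_i])

with d the hidden size. The context is implemented as the attention-weighted
sum over encoder positions — the broadcast entry-wise product followed by
summation — because that is the only reading under which
[O<sub>d,i</sub> ; AC<sub>i</sub>] has a fixed width for the projection W.

Randomized SMILES (restricted variant: random atom renumbering with
canonical branching decisions) serve as data augmentation and, at sampling
time, as the mechanism that moves attachment points around the string.
Multi-step training pairs trace one random decoration order per tuple per
epoch, re-randomizing the partial molecule at each step, so the training
target is always the decoration at the first `[*]` of the input string —
the same policy the sampler uses. Decoration *targets* stay canonical by
default: randomizing them too spends model capacity on string variants of
the same fragment and roughly triples the attainable NLL floor on small
sets; `randomize_targets=True` restores two-sided augmentation. Single-step
pairs put all decorations in one target sequence separated by `|`, ordered
by attachment appearance in that particular randomized scaffold string.

Optimization is Adam (lr 10⁻³ full scale, 5·10⁻³ for the tiny preset),
batch 128, dropout between layers (after the embedding and each LSTM layer)
active only in training. Sampling is multinomial from the per-step softmax
until the end token or a 256-token cap (capped sequences are flagged
truncated and discarded by callers); the pad and begin tokens are barred
from the draw, while the reported NLL of a sample uses the unmodified
softmax so it is exactly recomputable by the likelihood functions.

The compute core is a small reverse-mode autodiff engine over NumPy arrays
(`autodiff.py`): matmul, broadcast arithmetic, tanh/sigmoid/exp,
log-softmax, concatenation/slicing, embedding lookup and the two attention
contractions, each with exact gradients (verified against finite
differences), plus Adam. At the hidden sizes this package trains, runtime is
dominated by BLAS, and the engine keeps the package free of a deep-learning
framework dependency.

## Sampling campaigns

Multi-step: per pass, each frontier partial molecule is randomized R times
and each randomized string sampled S times; valid single-attachment
decorations are joined at the first `[*]` of their string; partials are
merged on canonical SMILES *before* the next pass (so duplicate partials
are explored once). For an n-attachment scaffold the worst case is
(R·S)<sup>n</sup> sampler paths; repeats keep the realized number far
smaller. Accounting is exact: every decoder sample is a discard (invalid,
truncated, wrong arity), an intermediate, or a terminal counting 1 toward
one molecule, so counts + discards + intermediates = samples. The frontier
is uncapped for ≤ 2 attachments and capped at 10,000 lowest-NLL partials
otherwise. Defaults R = S = 16; the single-step campaign uses R = 1024
randomized strings × S = 128 samples.

Novel-scaffold pipeline: sample the generator n_total times (desk default
10,000; the full-scale campaign value is 10 million), drop duplicates and
strings without attachment points, drop scaffolds sampled fewer than 10
times (outlier removal) or with ECFP6/2048 Tanimoto similarity above 0.7 to
any training scaffold, Butina-cluster the survivors at similarity 0.2, and
return one representative (the cluster centroid) per cluster, largest
clusters first, ties broken by canonical SMILES.

## Evaluation protocol

Decoys are randomly decorated scaffolds whose MW distribution is matched to
a reference sample, one decoration at a time. The mechanism (the goal, not
the mechanism, is fixed by the protocol): each decoy bootstraps a target MW
from the reference; per attachment point a random subset of pool fragments
competes and the one steering the running weight closest to the target wins
(the last slot scans the whole pool); a decoy is accepted when it lands in
the target's decile stratum, with the best of four attempts kept otherwise.
Panel generation assigns each bootstrap target to a random scaffold whose
reachable weight window contains it, so the pooled decoy marginal tracks
the reference rather than a mixture of per-scaffold truncations. On the
fixture (2,000 decoys against a 200-molecule reference) the two-sample KS
distance is ~0.05.

Enrichment over random is the ratio of predicted-active fractions
(generated over decoys) at an activity threshold of 0.5. The activity model
itself is a pluggable oracle — any deterministic molecule → probability
callable; the shipped oracles (hash-based pseudo-probability, substructure
match) exist to exercise the plumbing, not to predict activity.

RECAP auditing rebuilds each molecule from its scaffold and decorations
with the created bonds tracked through atom map numbers, then tests every
such bond against the SMARTS registry on the assembled molecule. Novelty
decomposition reports, per run: total decorations (with repeats, weighted
by sample count), unique fraction, novel-vs-training fraction (over unique
decorations; decoration identity is the canonical SMILES with an unlabelled
`[*]`), the fraction of distinct molecules with at least one novel
decoration, and optionally membership fractions against a reference
fragment pool. Descriptor profiles use RDKit MolWt, Crippen cLogP, the SA
score and QED.

## Fixture corpus

The toy generator joins ring cores (benzene, pyridine, cyclohexane,
para-phenylene, piperazine, 1,3,5-benzene — one, two and three marked
sites) with small rule-of-3 substituents, drawing core/assignment
combinations round-robin from a seeded shuffle so every core is represented
at any corpus size, and records each molecule's intended tuple in the same
normal form the slicer emits. Because every join is a single bond onto a
ring core, exhaustive all-acyclic slicing provably recovers the intended
tuple, making the corpus a ground-truth oracle for the slicer and a
memorization target for the models.

What desk-scale passing shows: the algorithmic contracts (round trips,
classification, ordering, budgets, audits) hold exactly, and the
architecture can be driven to memorization and exact regeneration on a
10-tuple corpus (tiny preset: 64 hidden units, 1 layer, 600 epochs, ~35 s
on one CPU). What it does not show: generalization to unseen scaffolds,
chemistry-aware decoration quality, or enrichment against a real activity
model — those depend on corpus scale (10⁵–10⁶ tuples) and the full 512 × 3
architecture, which the code supports but the tests do not exercise. The
toy corpus also has none of real data's property spread: its molecules are
small, neutral, achiral and built from a closed fragment set.

## Numerical and degenerate-input conventions

Stereochemistry is stripped on ingestion (configurable); charges and
isotopes are left untouched. Canonicalization is RDKit's; attachment
dummies are always written `[*]`. Molecules whose slicing fails are skipped
and counted, never fatal, in corpus runs. Enrichment with a zero decoy
ratio is flagged infinite (or undefined at 0/0) rather than raised.
Attention over an all-masked memory is an error. NLLs are finite by
construction (log-softmax with max subtraction); sampling draws use a
cumulative-sum inverse method on the exact softmax probabilities.
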