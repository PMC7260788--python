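# scaffdec

SMILES-based scaffold decoration for de-novo molecular design: turn any set
of molecules into scaffold–decoration training data by exhaustive slicing,
train an encoder–decoder generative model that completes scaffolds at
explicit `[*]` attachment points, and evaluate the resulting molecular
series against MW-matched random decoys.

The package is aimed at computational and medicinal chemists who want
*focused* molecule generation: keep a core of interest fixed and generate
chemically sensible substituents for it, optionally constrained to bonds a
synthetic chemist could actually form (RECAP rules).

## What's inside

**Slicing** (`scaffdec.slicer`). For a molecule with candidate bond set *B*
(all single acyclic bonds, or only those matching retrosynthetic SMARTS
patterns), every subset of 1..c<sub>max</sub> bonds is cut. The fragments of
a *c*-bond cut are classified by attachment count: the unique fragment with
*c* attachment points is the scaffold, the rest (one attachment each) are its
decorations; combinations with no such fragment are discarded. Scaffolds are
kept if they contain a ring, decorations if they are fragment-like by the
rule of 3 (MW ≤ 300 Da, HBD ≤ 3, HBA ≤ 3, cLogP ≤ 3, rotatable bonds ≤ 3).
Every emitted tuple rejoins exactly to its source molecule.

**Models** (`scaffdec.model`). Two recurrent generative models over SMILES
tokens, trained with teacher forcing on the sequence NLL
−Σ<sub>i</sub> log P(x<sub>i</sub> | x<sub>&lt;i</sub>):

* a scaffold generator (embedding → stacked LSTM cells → linear + softmax);
* a decorator: a bidirectional LSTM encoder reads a randomized scaffold
  SMILES (directional hidden/cell states summed), and a decoder generates
  the decoration with global attention at every step —
  AW<sub>i</sub> = softmax(O<sub>d,i</sub>·O<sub>e</sub><sup>T</sup>/√d),
  context = Σ<sub>p</sub> AW<sub>i,p</sub> O<sub>e,p</sub>,
  O′<sub>d,i</sub> = tanh(W[O<sub>d,i</sub> ; context]).

The models run on a small NumPy reverse-mode autodiff core
(`scaffdec.autodiff`); the full-scale configuration is 512 hidden units ×
3 layers with dropout 0.2, and a desk-scale preset (64 × 1) trains in
minutes on one CPU.

**Sampling** (`scaffdec.sampling`). The *multi-step* campaign decorates one
attachment point per pass: randomize the partial molecule R times, sample S
decorations per randomized string, join each at the first `[*]` of that
string, deduplicate, repeat until no attachment remains (worst case
(R·S)<sup>n</sup> paths for n attachment points — (16·16)³ = 16,777,216 at
the default R = S = 16). The *single-step* variant emits all decorations in
one sequence separated by `|` (R·S = 1024·128 = 131,072 at its defaults).
A screen-and-cluster pipeline (ECFP6/2048 Tanimoto similarity screen, Butina
clustering) turns a trained scaffold generator into novel decoratable
scaffolds.

**Evaluation** (`scaffdec.evalsuite`). MW-matched random decoys, enrichment
over random (ratio of predicted-active fractions against a pluggable
activity oracle), RECAP-compliance auditing of the bonds created at
attachment points, decoration novelty decomposition, and MW/cLogP/SA/QED
descriptor profiles.

**Fixtures** (`scaffdec.fixtures`). A deterministic toy corpus (ring cores ×
rule-of-3 substituents with recorded ground truth) that makes the whole
pipeline testable on one CPU without downloads.

## Worked example

```python
import numpy as np
from scaffdec import (FixtureSpec, make_toy_corpus, acyclic_rules,
                      slice_corpus, train_decorator, decorate_multistep)

corpus = make_toy_corpus(FixtureSpec(n_molecules=10))
dataset = corpus.truth_dataset()           # 10 scaffold-decoration tuples
model, trace = train_decorator(dataset, mode="multi", epochs=600,
                               rng_seed=42, lr=5e-3)
print(f"mean NLL: epoch 1 = {trace[0]:.2f}, final = {trace[-1]:.2f}")

run = decorate_multistep(model, "[*]c1ccc([*])cc1", R=4, S=4, rng_seed=7)
for smiles, entry in sorted(run.molecules.items())[:3]:
    print(smiles, entry.count, "|".join(entry.decorations))
```

prints (seeds as above):

```
mean NLL: epoch 1 = 14.14, final = 0.58
CCCc1ccc(CCC)cc1 16 [*]CCC|[*]CCC
CCCc1ccc(CCN)cc1 1 [*]CCN|[*]CCC
CCCc1ccc(CCO)cc1 6 [*]CCO|[*]CCC
```

The trained decorator has memorized the fixture: the para-substituted
benzene scaffold is completed predominantly with the decoration pairs it was
trained on (`count` is how often each molecule was sampled out of the
(4·4)² = 256-path budget), and the per-epoch NLL trace shows the collapse
from ~14 nats to well under 1.

A command-line interface mirrors the library:
`scaffdec slice|train-scaffold|train-decorator|decorate|sample-scaffolds|evaluate|make-fixture`.

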