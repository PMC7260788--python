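"""Deterministic toy corpora and model-scale presets.

The toy corpus stands in for a real compound collection: ring cores with
marked substitution sites are combinatorially decorated with small,
fragment-like substituents, and the intended (core, substituents) assignment
is recorded as ground truth. Because every molecule is built by single-bond
joins onto a ring core, exhaustive slicing with all-acyclic rules is
guaranteed to recover the intended scaffold-decoration tuple, which makes the
corpus an oracle for the slicer and a memorization target for tiny models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chemio import AttachmentSmiles, MoleculeRecord, canonicalize
from .model import GeneratorConfig, _label_attachments
from .slicer import (
    ScaffoldDecorationTuple,
    TupleDataset,
    _canonical_scaffold_and_order,
    join_all,
    rule_of_three,
)

__all__ = [
    "FixtureSpec",
    "ToyCorpus",
    "make_toy_corpus",
    "tiny_model_preset",
    "full_model_preset",
    "ModelPreset",
    "DEFAULT_CORES",
    "DEFAULT_SUBSTITUENTS",
]

# Ring cores with 1-3 marked substitution sites (multi-site cores exercise
# attachment ordering, classification and budget arithmetic).
DEFAULT_CORES = (
    "[*]c1ccccc1",
    "[*]c1ccncc1",
    "[*]C1CCCCC1",
    "[*]c1ccc([*])cc1",
    "[*]N1CCN([*])CC1",
    "[*]c1cc([*])cc([*])c1",
)

# Small substituents, all rule-of-3 compliant and joinable at any site.
DEFAULT_SUBSTITUENTS = (
    "[*]C",
    "[*]CC",
    "[*]CCC",
    "[*]CCO",
    "[*]OC",
    "[*]C(C)C",
    "[*]CCN",
    "[*]C(=O)C",
)


def decoy_fragment_pool() -> tuple:
    """A dense, fragment-like decoration pool for decoy generation.

    Stands in for a large public fragment collection: linear and branched
    alkyl chains with alcohol/amine/ether/acetyl variants give molecular
    weights from ~15 to ~160 Da at a 1-16 Da granularity, so a decoy
    generator can steer a decoy's weight close to any realistic target. All
    members carry one attachment and pass the rule of 3.
    """
    fragments = set()
    for n in range(1, 9):
        chain = "C" * n
        fragments.add(f"[*]{chain}")
        fragments.add(f"[*]{chain}O")      # terminal alcohol
        fragments.add(f"[*]{chain}N")      # terminal amine
        fragments.add(f"[*]O{chain}")      # ether-linked
        if n >= 2:
            fragments.add(f"[*]C(C){'C' * (n - 2)}C" if n > 2
                          else "[*]C(C)C")
        if n <= 6:
            fragments.add(f"[*]C(=O){chain}")  # acyl
    # Ring-bearing members extend the reachable weight range without
    # tripping the rotatable-bond cap.
    fragments.update([
        "[*]c1ccccc1", "[*]Cc1ccccc1", "[*]CCc1ccccc1", "[*]CCCc1ccccc1",
        "[*]Cc1ccc(C)cc1", "[*]Cc1ccc(CC)cc1", "[*]Cc1ccc(OC)cc1",
        "[*]Cc1ccc(O)cc1", "[*]Cc1ccc(N)cc1", "[*]Cc1ccccc1C",
        "[*]C1CCCCC1", "[*]CC1CCCCC1", "[*]CCC1CCCCC1", "[*]CC1CCCC1",
        "[*]CCOc1ccccc1", "[*]CCc1ccc(C)cc1", "[*]CCc1ccc(OC)cc1",
    ])
    pool = []
    for frag in sorted(fragments):
        att = AttachmentSmiles.from_smiles(canonicalize(frag))
        if rule_of_three(att):
            pool.append(att.smiles)
    return tuple(sorted(set(pool)))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic toy corpus."""

    cores: tuple = DEFAULT_CORES
    substituents: tuple = DEFAULT_SUBSTITUENTS
    rng_seed: int = 0
    n_molecules: int = 50


@dataclass(frozen=True)
class GroundTruth:
    """The intended tuple for one toy molecule, in slicer-normal form."""

    molecule: str
    scaffold: str
    decorations: tuple

    def as_tuple(self) -> ScaffoldDecorationTuple:
        return ScaffoldDecorationTuple(
            scaffold=AttachmentSmiles.from_smiles(self.scaffold),
            decorations=tuple(AttachmentSmiles.from_smiles(d)
                              for d in self.decorations),
            source=self.molecule)


@dataclass
class ToyCorpus:
    records: List[MoleculeRecord]
    truth: List[GroundTruth]
    spec: FixtureSpec

    def __len__(self) -> int:
        return len(self.records)

    def truth_dataset(self) -> TupleDataset:
        return TupleDataset(tuples=[gt.as_tuple() for gt in self.truth],
                            provenance={"source": "toy-corpus",
                                        "rng_seed": self.spec.rng_seed})

    def save(self, corpus_path, truth_path) -> None:
        with open(corpus_path, "w", encoding="utf-8") as fh:
            for i, rec in enumerate(self.records):
                fh.write(f"{rec.canonical_smiles}\ttoy{i}\n")
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("molecule\tscaffold\tdecorations\n")
            for gt in self.truth:
                fh.write(f"{gt.molecule}\t{gt.scaffold}\t"
                         f"{'|'.join(gt.decorations)}\n")


def _normalized_truth(core: str, assignment: Sequence[str]) -> GroundTruth:
    """Ground truth with the scaffold canonicalized and decorations reordered
    to the attachment-appearance order of the canonical scaffold string —
    the same normal form the slicer emits."""
    mol, n = _label_attachments(canonicalize(core))
    scaffold_smiles, label_order = _canonical_scaffold_and_order(mol)
    decorations = tuple(canonicalize(assignment[lbl - 1]) for lbl in label_order)
    molecule = join_all(scaffold_smiles, decorations)
    return GroundTruth(molecule=molecule, scaffold=scaffold_smiles,
                       decorations=decorations)


def make_toy_corpus(spec: FixtureSpec = FixtureSpec()) -> ToyCorpus:
    """Build a deterministic toy corpus with per-molecule ground truth.

    Per core, all substituent assignments are enumerated in sorted order and
    shuffled with the spec's seed; cores are then drawn round-robin so that
    every core is represented whenever ``n_molecules >= len(cores)``. Only
    *distinct* molecules are kept (symmetric cores can map two assignments to
    one molecule; duplicates are skipped).
    """
    for sub in spec.substituents:
        frag = AttachmentSmiles.from_smiles(sub)
        if not rule_of_three(frag):
            raise ValueError(f"substituent violates the rule of 3: {sub}")
    rng = np.random.default_rng(spec.rng_seed)
    per_core = []
    for core in sorted(spec.cores):
        n_sites = core.count("[*]")
        assignments = list(product(sorted(spec.substituents), repeat=n_sites))
        order = rng.permutation(len(assignments))
        per_core.append([(core, assignments[i]) for i in order])
    interleaved = []
    depth = max(len(group) for group in per_core)
    for level in range(depth):
        for group in per_core:
            if level < len(group):
                interleaved.append(group[level])
    records, truth, seen = [], [], set()
    for core, assignment in interleaved:
        gt = _normalized_truth(core, assignment)
        if gt.molecule in seen:
            continue
        seen.add(gt.molecule)
        records.append(MoleculeRecord(source_smiles=gt.molecule,
                                      canonical_smiles=gt.molecule,
                                      id=f"toy{len(records)}"))
        truth.append(gt)
        if len(records) >= spec.n_molecules:
            break
    if len(records) < spec.n_molecules:
        raise ValueError(
            f"spec can only produce {len(records)} unique molecules, "
            f"requested {spec.n_molecules}")
    return ToyCorpus(records=records, truth=truth, spec=spec)


@dataclass(frozen=True)
class ModelPreset:
    """Architecture + optimization settings, vocabulary supplied later."""

    embedding_dim: int
    hidden_dim: int
    n_layers: int
    dropout: float
    lr: float
    epochs: int

    def to_config(self, vocabulary) -> GeneratorConfig:
        return GeneratorConfig(vocabulary=vocabulary,
                               embedding_dim=self.embedding_dim,
                               hidden_dim=self.hidden_dim,
                               n_layers=self.n_layers,
                               dropout=self.dropout)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "ModelPreset":
        return cls(**json.loads(payload))


def tiny_model_preset() -> ModelPreset:
    """Desk-scale preset: overfits a 10-tuple fixture on one CPU in minutes."""
    return ModelPreset(embedding_dim=32, hidden_dim=64, n_layers=1,
                       dropout=0.0, lr=5e-3, epochs=600)


def full_model_preset() -> ModelPreset:
    """The full-scale architecture: 512 hidden units, 3 layers, dropout 0.2."""
    return ModelPreset(embedding_dim=256, hidden_dim=512, n_layers=3,
                       dropout=0.2, lr=1e-3, epochs=100)
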