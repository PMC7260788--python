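"""Decoration campaigns and novel-scaffold generation.

The multi-step campaign decorates one attachment point per pass: the partial
molecule is randomized R times, each randomized string is sampled S times, the
sampled decoration is joined at the first ``[*]`` of that string, and the
deduplicated partials feed the next pass until no attachment point remains.
Randomization moves the attachment points around the string, so repeated
passes cover all decoration orders. The single-step campaign samples one
sequence per randomized scaffold containing all decorations separated by
``|``, matched to attachment points by order of appearance.

The scaffold pipeline samples a trained scaffold generator at scale, drops
duplicates, scaffolds too similar to the training set (ECFP6/2048 Tanimoto)
and rare samples, clusters the survivors (Butina sphere exclusion) and picks
representatives from the largest clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.ML.Cluster import Butina

from .chemio import (
    ATTACHMENT_TOKEN,
    SEPARATOR_TOKEN,
    AttachmentSmiles,
    SmilesError,
    canonicalize,
    count_attachments,
    mol_from_smiles,
    randomize_smiles,
)
from .model import Decorator, ScaffoldGenerator, sample_decoration_batch, sample_scaffold_batch
from .slicer import JoinError, join, join_all

__all__ = [
    "DecorationRun",
    "MoleculeEntry",
    "ScaffoldPipelineConfig",
    "sampling_budget",
    "decorate_multistep",
    "decorate_singlestep",
    "generate_novel_scaffolds",
]


def sampling_budget(n_attachments: int, R: int, S: int, mode: str = "multi") -> int:
    """Worst-case number of distinct sample paths for a decoration campaign.

    Multi-step: (R*S)^n_attachments — each of R randomized strings sampled S
    times, per decoration step. Single-step: R*S. The sampler always reaches
    far fewer distinct molecules because of repeats.
    """
    if n_attachments < 1:
        raise ValueError("scaffold must have at least one attachment point")
    if R < 1 or S < 1:
        raise ValueError("R and S must be >= 1")
    if mode == "multi":
        return (R * S) ** n_attachments
    if mode == "single":
        return R * S
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class MoleculeEntry:
    """One fully decorated molecule of a run."""

    count: int
    decorations: tuple
    nll: float


@dataclass
class DecorationRun:
    """Provenance-rich result of decorating one scaffold.

    ``molecules`` maps the canonical SMILES of each complete molecule (zero
    remaining attachment points) to its entry. Accounting: every decoder
    sample is either discarded (invalid/truncated/arity mismatch), an
    intermediate (a partial molecule merged into the next frontier), or a
    terminal contributing 1 to one molecule's count, so
    ``sum(counts) + n_discarded + n_intermediate == n_sampled``.
    """

    scaffold: AttachmentSmiles
    molecules: Dict[str, MoleculeEntry]
    parameters: dict
    n_sampled: int = 0
    n_discarded: int = 0
    n_intermediate: int = 0

    @property
    def validity_rate(self) -> float:
        return 1.0 - self.n_discarded / self.n_sampled if self.n_sampled else 1.0

    def total_count(self) -> int:
        return sum(e.count for e in self.molecules.values())

    def save_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for smiles, entry in sorted(self.molecules.items()):
                decs = SEPARATOR_TOKEN.join(entry.decorations)
                fh.write(f"{smiles}\t{self.scaffold.smiles}\t{decs}\t"
                         f"{entry.count}\t{entry.nll:.6f}\n")

    @classmethod
    def load_tsv(cls, path) -> "DecorationRun":
        molecules = {}
        scaffold = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                smiles, scaf, decs, count, nll = line.rstrip("\n").split("\t")
                scaffold = scaf
                molecules[smiles] = MoleculeEntry(
                    count=int(count), decorations=tuple(decs.split(SEPARATOR_TOKEN)),
                    nll=float(nll))
        return cls(scaffold=AttachmentSmiles.from_smiles(scaffold),
                   molecules=molecules, parameters={"source": str(path)})


@dataclass
class _Partial:
    smiles: str  # canonical, with [*] for open positions
    decorations: tuple
    nll: float


def _coerce_scaffold(scaffold) -> AttachmentSmiles:
    if isinstance(scaffold, AttachmentSmiles):
        scaffold = scaffold.smiles
    canonical = canonicalize(scaffold)
    n = count_attachments(canonical)
    if n == 0:
        raise ValueError(f"scaffold has no attachment points: {scaffold!r}")
    return AttachmentSmiles(canonical, n)


def decorate_multistep(model: Decorator, scaffold, R: int = 16, S: int = 16,
                       rng_seed: int = 0, max_frontier: Optional[int] = None) -> DecorationRun:
    """Decorate every attachment point, one per pass (see module docstring).

    ``max_frontier`` caps the number of distinct partial molecules carried
    between passes (by default unlimited for scaffolds with <= 2 attachment
    points, 10,000 otherwise); partials with the lowest accumulated NLL are
    kept when the cap binds.
    """
    if model.mode != "multi":
        raise ValueError("decorate_multistep requires a multi-step decorator")
    scaffold = _coerce_scaffold(scaffold)
    if max_frontier is None:
        max_frontier = 10_000 if scaffold.n_attachments > 2 else 0
    rng = np.random.default_rng(rng_seed)
    run = DecorationRun(scaffold=scaffold, molecules={},
                        parameters={"R": R, "S": S, "mode": "multi",
                                    "rng_seed": rng_seed})
    frontier = {scaffold.smiles: _Partial(scaffold.smiles, (), 0.0)}
    for _step in range(scaffold.n_attachments):
        next_frontier: Dict[str, _Partial] = {}
        for partial in frontier.values():
            for _r in range(R):
                rand = randomize_smiles(partial.smiles, rng)
                samples = sample_decoration_batch(model, rand, S, rng)
                run.n_sampled += S
                for sample in samples:
                    if sample.truncated:
                        run.n_discarded += 1
                        continue
                    try:
                        dec = canonicalize(sample.smiles)
                        if count_attachments(dec) != 1:
                            raise SmilesError("decoration must have one attachment")
                        joined = join(rand, dec, 0)
                    except (SmilesError, JoinError):
                        run.n_discarded += 1
                        continue
                    new = _Partial(joined.smiles,
                                   partial.decorations + (dec,),
                                   partial.nll + sample.nll)
                    if joined.n_attachments == 0:
                        entry = run.molecules.get(new.smiles)
                        if entry is None:
                            run.molecules[new.smiles] = MoleculeEntry(
                                count=1, decorations=new.decorations, nll=new.nll)
                        else:
                            entry.count += 1
                            entry.nll = min(entry.nll, new.nll)
                    else:
                        run.n_intermediate += 1
                        seen = next_frontier.get(new.smiles)
                        if seen is None or new.nll < seen.nll:
                            next_frontier[new.smiles] = new
        if max_frontier and len(next_frontier) > max_frontier:
            kept = sorted(next_frontier.values(), key=lambda p: (p.nll, p.smiles))
            next_frontier = {p.smiles: p for p in kept[:max_frontier]}
        frontier = next_frontier
    return run


def decorate_singlestep(model: Decorator, scaffold, R: int = 1024, S: int = 128,
                        rng_seed: int = 0) -> DecorationRun:
    """Decorate all attachment points in one sampled sequence per draw.

    Each of R randomized scaffold strings is sampled S times; a sample is
    split on ``|`` and part j is joined at the j-th ``[*]`` of that randomized
    string. Samples whose part count differs from the number of attachment
    points are discarded and tallied.
    """
    if model.mode != "single":
        raise ValueError("decorate_singlestep requires a single-step decorator")
    scaffold = _coerce_scaffold(scaffold)
    c = scaffold.n_attachments
    rng = np.random.default_rng(rng_seed)
    run = DecorationRun(scaffold=scaffold, molecules={},
                        parameters={"R": R, "S": S, "mode": "single",
                                    "rng_seed": rng_seed})
    for _r in range(R):
        rand = randomize_smiles(scaffold.smiles, rng)
        samples = sample_decoration_batch(model, rand, S, rng)
        run.n_sampled += S
        for sample in samples:
            if sample.truncated:
                run.n_discarded += 1
                continue
            parts = sample.smiles.split(SEPARATOR_TOKEN)
            try:
                if len(parts) != c:
                    raise SmilesError(f"expected {c} decorations")
                decs = [canonicalize(p) for p in parts]
                if any(count_attachments(d) != 1 for d in decs):
                    raise SmilesError("each decoration must have one attachment")
                molecule = join_all(rand, decs)
            except (SmilesError, JoinError):
                run.n_discarded += 1
                continue
            nll = sample.nll
            entry = run.molecules.get(molecule)
            if entry is None:
                run.molecules[molecule] = MoleculeEntry(
                    count=1, decorations=tuple(decs), nll=nll)
            else:
                entry.count += 1
                entry.nll = min(entry.nll, nll)
    return run


# ---------------------------------------------------------------------------
# novel-scaffold pipeline


@dataclass(frozen=True)
class ScaffoldPipelineConfig:
    """Settings of the novel-scaffold generation pipeline.

    Defaults follow the published campaign settings (similarity screen at
    Tanimoto 0.7, minimum sample count 10, Butina clustering at similarity
    0.2 on ECFP6/2048) with a desk-scale total sample count.
    """

    n_total_samples: int = 10_000
    similarity_threshold: float = 0.7
    min_sample_count: int = 10
    butina_threshold: float = 0.2
    fp_radius: int = 3
    fp_bits: int = 2048
    n_select: int = 5

    def __post_init__(self):
        for name in ("similarity_threshold", "butina_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_total_samples < 1 or self.min_sample_count < 1 or self.n_select < 1:
            raise ValueError("counts must be positive")


def _fingerprints(smiles_list: Sequence[str], radius: int, bits: int):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits)
    return [gen.GetFingerprint(mol_from_smiles(s)) for s in smiles_list]


def generate_novel_scaffolds(generator: ScaffoldGenerator,
                             training_scaffolds: Sequence[str],
                             config: ScaffoldPipelineConfig,
                             rng_seed: int = 0,
                             batch_size: int = 256) -> List[str]:
    """Sample, screen and cluster scaffolds; return representative picks.

    Returns up to ``config.n_select`` canonical scaffold SMILES, one per
    Butina cluster, largest clusters first (ties broken by the canonical
    SMILES of the representative). Emits fewer than requested, with a
    warning, when the screens leave fewer clusters.
    """
    import warnings

    rng = np.random.default_rng(rng_seed)
    counts: Dict[str, int] = {}
    remaining = config.n_total_samples
    while remaining > 0:
        n = min(batch_size, remaining)
        remaining -= n
        for sample in sample_scaffold_batch(generator, n, rng):
            if sample.truncated:
                continue
            try:
                smiles = canonicalize(sample.smiles)
            except SmilesError:
                continue
            if count_attachments(smiles) == 0:
                continue  # not decoratable
            counts[smiles] = counts.get(smiles, 0) + 1
    survivors = sorted(s for s, n in counts.items()
                       if n >= config.min_sample_count)
    if not survivors:
        return []
    train_fps = _fingerprints(list(training_scaffolds), config.fp_radius,
                              config.fp_bits)
    kept = []
    for smiles in survivors:
        fp = _fingerprints([smiles], config.fp_radius, config.fp_bits)[0]
        sims = DataStructs.BulkTanimotoSimilarity(fp, train_fps) if train_fps else []
        if not sims or max(sims) <= config.similarity_threshold:
            kept.append(smiles)
    if not kept:
        return []
    fps = _fingerprints(kept, config.fp_radius, config.fp_bits)
    # Butina wants the condensed lower-triangle distance list.
    dists = []
    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    clusters = Butina.ClusterData(dists, len(fps), 1.0 - config.butina_threshold,
                                  isDistData=True)
    picks = [kept[cluster[0]] for cluster in
             sorted(clusters, key=lambda cl: (-len(cl), kept[cl[0]]))]
    if len(picks) < config.n_select:
        warnings.warn(f"only {len(picks)} clusters available, "
                      f"requested {config.n_select}")
        return picks
    return picks[:config.n_select]
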