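"""Evaluation protocol for decoration campaigns.

Covers the benchmark components used to judge a decorator: molecular-weight
matched decoys (randomly decorated molecules whose MW distribution tracks a
reference sample), enrichment over random against a pluggable activity
oracle, retrosynthetic (RECAP) compliance auditing of the bonds created at
attachment points, novelty decomposition of generated decorations, and
standard descriptor profiling (MW, cLogP, SA score, QED).
"""

from __future__ import annotations

import hashlib
import math
import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, QED

from .chemio import (
    AttachmentSmiles,
    SmilesError,
    canonicalize,
    count_attachments,
    mol_from_smiles,
)
from .sampling import DecorationRun
from .slicer import JoinError, _attach, load_smarts_rules

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

__all__ = [
    "DecoySet",
    "ActivityOracle",
    "HashOracle",
    "SubstructureOracle",
    "NoveltyReport",
    "EnrichmentResult",
    "generate_decoys",
    "enrichment_over_random",
    "active_ratio",
    "recap_compliance",
    "novelty_metrics",
    "descriptor_profile",
]


# ---------------------------------------------------------------------------
# activity oracles


@dataclass(frozen=True)
class ActivityOracle:
    """A deterministic molecule -> probability-of-activity predictor.

    The predictor itself is external to this package (any QSAR model will
    do); molecules with probability >= ``threshold`` count as active.
    """

    predict: Callable[[str], float]
    threshold: float = 0.5

    def __call__(self, smiles: str) -> float:
        p = float(self.predict(smiles))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"oracle probability out of [0,1]: {p}")
        return p

    def is_active(self, smiles: str) -> bool:
        return self(smiles) >= self.threshold


def HashOracle(threshold: float = 0.5, salt: str = "") -> ActivityOracle:
    """Pseudo-random but deterministic oracle derived from the canonical SMILES.

    Useful for exercising enrichment plumbing without a trained model.
    """

    def predict(smiles: str) -> float:
        key = (salt + canonicalize(smiles)).encode()
        digest = hashlib.sha256(key).digest()
        return int.from_bytes(digest[:8], "big") / 2.0 ** 64

    return ActivityOracle(predict=predict, threshold=threshold)


def SubstructureOracle(smarts: str, p_match: float = 0.9,
                       p_miss: float = 0.1,
                       threshold: float = 0.5) -> ActivityOracle:
    """Oracle that scores molecules containing a SMARTS pharmacophore high."""
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")

    def predict(smiles: str) -> float:
        return p_match if mol_from_smiles(smiles).HasSubstructMatch(patt) else p_miss

    return ActivityOracle(predict=predict, threshold=threshold)


def active_ratio(molecules: Iterable[str], oracle: ActivityOracle) -> float:
    mols = list(molecules)
    if not mols:
        raise ValueError("cannot compute an active ratio over zero molecules")
    return sum(oracle.is_active(s) for s in mols) / len(mols)


# ---------------------------------------------------------------------------
# decoys


@dataclass
class DecoySet:
    """Randomly decorated molecules MW-matched to a reference sample."""

    scaffold: AttachmentSmiles
    decoys: List[str]
    decoration_pool_id: str
    target_mw_sample: np.ndarray
    n_shortfall: int = 0


def _mw(smiles: str) -> float:
    return Descriptors.MolWt(mol_from_smiles(smiles))


def generate_decoys(scaffold, pool: Sequence[str], mw_reference: Sequence[float],
                    n: int, rng_seed: int = 0, pool_id: str = "custom",
                    candidates_per_slot: int = 24, max_tries: int = 4,
                    targets: Optional[Sequence[float]] = None) -> DecoySet:
    """Decorate ``scaffold`` randomly from ``pool``, matching a MW distribution.

    One decoration is drawn at a time. Each decoy bootstraps a target MW from
    the reference sample; per attachment point, a handful of random pool
    candidates compete and the one steering the running MW closest to the
    target wins. A finished decoy is accepted when it lands in the target's
    decile stratum of the reference distribution, otherwise redrawn (the best
    attempt is kept after ``max_tries``, counted as a shortfall).
    """
    from .slicer import join_all

    if not pool:
        raise ValueError("decoration pool is empty")
    scaffold = (scaffold if isinstance(scaffold, AttachmentSmiles)
                else AttachmentSmiles.from_smiles(canonicalize(scaffold)))
    c = scaffold.n_attachments
    if c == 0:
        raise ValueError("scaffold has no attachment points")
    rng = np.random.default_rng(rng_seed)
    reference = np.asarray(list(mw_reference), dtype=float)
    deciles = np.quantile(reference, np.linspace(0, 1, 11))
    pool = list(pool)
    pool_mw = np.array([_mw(p) for p in pool])
    scaffold_mw = _mw(scaffold.smiles)

    def stratum(mw: float) -> int:
        return int(np.clip(np.searchsorted(deciles[1:-1], mw), 0, 9))

    # Feasible decoy MW window for this scaffold given the pool extremes;
    # bootstrap targets outside it are redrawn (a scaffold can only reach
    # weights its pool spans, so infeasible targets would pile up at the
    # window edge and distort the match).
    lo = scaffold_mw + c * pool_mw.min()
    hi = scaffold_mw + c * pool_mw.max()

    if targets is not None and len(targets) != n:
        raise ValueError("targets must have length n when given")
    decoys, shortfall = [], 0
    for k in range(n):
        if targets is not None:
            target = float(targets[k])
        else:
            target = float(rng.choice(reference))
            for _redraw in range(20):
                if lo - 1.0 <= target <= hi + 1.0:
                    break
                target = float(rng.choice(reference))
        best, best_err = None, math.inf
        for _attempt in range(max_tries):
            chosen: List[str] = []
            running = scaffold_mw
            ok = True
            for slot in range(c):
                want = (target - running) / (c - slot)
                if slot == c - 1:
                    # last slot: best fit over the whole pool
                    pick = int(np.argmin(np.abs(pool_mw - want)))
                else:
                    idx = rng.integers(0, len(pool), size=min(candidates_per_slot,
                                                              len(pool)))
                    pick = int(idx[np.argmin(np.abs(pool_mw[idx] - want))])
                chosen.append(pool[pick])
                running += pool_mw[pick]
            try:
                molecule = join_all(scaffold, chosen)
            except JoinError:
                ok = False
            if not ok:
                continue
            mw = _mw(molecule)
            err = abs(mw - target)
            if err < best_err:
                best, best_err = molecule, err
            if stratum(mw) == stratum(target):
                break
        else:
            shortfall += 1
        if best is not None:
            decoys.append(best)
    if len(decoys) < n:
        import warnings
        warnings.warn(f"decoy generation produced {len(decoys)}/{n} molecules")
    return DecoySet(scaffold=scaffold, decoys=decoys, decoration_pool_id=pool_id,
                    target_mw_sample=reference, n_shortfall=shortfall)


def generate_decoy_panel(scaffolds: Sequence, pool: Sequence[str],
                         mw_reference: Sequence[float], n: int,
                         rng_seed: int = 0, pool_id: str = "custom",
                         **kwargs) -> List[DecoySet]:
    """MW-matched decoys spread over a panel of scaffolds.

    ``n`` target weights are bootstrapped from the reference first and each is
    routed to a random scaffold whose reachable weight window (scaffold weight
    plus pool extremes per attachment) contains it, so the pooled decoy MW
    marginal tracks the reference rather than a mixture of per-scaffold
    truncations. Returns one :class:`DecoySet` per scaffold that received
    targets.
    """
    scaffolds = [s if isinstance(s, AttachmentSmiles)
                 else AttachmentSmiles.from_smiles(canonicalize(s))
                 for s in scaffolds]
    if not scaffolds:
        raise ValueError("no scaffolds given")
    rng = np.random.default_rng(rng_seed)
    reference = np.asarray(list(mw_reference), dtype=float)
    pool_mw = np.array([_mw(p) for p in pool])
    windows = []
    for s in scaffolds:
        base_mw = _mw(s.smiles)
        windows.append((base_mw + s.n_attachments * pool_mw.min() - 1.0,
                        base_mw + s.n_attachments * pool_mw.max() + 1.0))
    windows = np.array(windows)
    assigned: Dict[int, list] = {}
    for _ in range(n):
        target = float(rng.choice(reference))
        feasible = np.flatnonzero((windows[:, 0] <= target)
                                  & (target <= windows[:, 1]))
        if len(feasible) == 0:
            # fall back to the scaffold whose window edge is nearest
            feasible = [int(np.argmin(np.minimum(np.abs(windows[:, 0] - target),
                                                 np.abs(windows[:, 1] - target))))]
        pick = int(rng.choice(feasible))
        assigned.setdefault(pick, []).append(target)
    sets = []
    for i in sorted(assigned):
        sets.append(generate_decoys(scaffolds[i], pool, reference,
                                    len(assigned[i]), rng_seed=rng_seed + i,
                                    pool_id=pool_id, targets=assigned[i],
                                    **kwargs))
    return sets


# ---------------------------------------------------------------------------
# enrichment over random


@dataclass(frozen=True)
class EnrichmentResult:
    value: float
    flag: Optional[str] = None  # None | "infinite" | "undefined"


def enrichment_over_random(generated_active_ratio: float,
                           decoy_active_ratio: float) -> EnrichmentResult:
    """Ratio of predicted-active fractions, generated over decoys."""
    for name, r in (("generated", generated_active_ratio),
                    ("decoy", decoy_active_ratio)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} active ratio out of [0,1]: {r}")
    if decoy_active_ratio == 0.0:
        if generated_active_ratio == 0.0:
            return EnrichmentResult(value=float("nan"), flag="undefined")
        return EnrichmentResult(value=float("inf"), flag="infinite")
    return EnrichmentResult(value=generated_active_ratio / decoy_active_ratio)


# ---------------------------------------------------------------------------
# RECAP compliance auditing


def _rebuild_with_tracked_bonds(scaffold: AttachmentSmiles | str,
                                decorations: Sequence[str]):
    """Join decorations onto the scaffold, tracking the created bonds.

    Returns (molecule, list of (atom_scaffold, atom_decoration) index pairs in
    the final molecule). Atom identity survives the edits via map numbers.
    """
    scaf_s = scaffold.smiles if isinstance(scaffold, AttachmentSmiles) else scaffold
    scaf_mol = mol_from_smiles(scaf_s)
    dummies = [a.GetIdx() for a in scaf_mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != len(decorations):
        raise JoinError(f"{len(decorations)} decorations for "
                        f"{len(dummies)} attachment points")
    rw = Chem.RWMol(scaf_mol)
    for pos, idx in enumerate(dummies):
        dummy = rw.GetAtomWithIdx(idx)
        dummy.SetIsotope(pos + 1)
        nbrs = dummy.GetNeighbors()
        if len(nbrs) != 1:
            raise JoinError("attachment dummy must have exactly one neighbor")
        nbrs[0].SetAtomMapNum(1000 + pos)
    for pos, dec in enumerate(decorations):
        dec_s = dec.smiles if isinstance(dec, AttachmentSmiles) else dec
        dec_mol = Chem.RWMol(mol_from_smiles(dec_s))
        dec_dummies = [a for a in dec_mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dec_dummies) != 1:
            raise JoinError(f"decoration must have one attachment: {dec_s!r}")
        dec_dummies[0].GetNeighbors()[0].SetAtomMapNum(2000 + pos)
        dummy = next(a.GetIdx() for a in rw.GetAtoms()
                     if a.GetAtomicNum() == 0 and a.GetIsotope() == pos + 1)
        rw = _attach(rw, dummy, dec_mol.GetMol())
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    bonds = []
    for pos in range(len(decorations)):
        a = next(at.GetIdx() for at in mol.GetAtoms()
                 if at.GetAtomMapNum() == 1000 + pos)
        b = next(at.GetIdx() for at in mol.GetAtoms()
                 if at.GetAtomMapNum() == 2000 + pos)
        bonds.append((a, b))
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return mol, bonds


def recap_compliance(molecule: str, scaffold, decorations: Sequence[str],
                     rules=None) -> Dict[str, object]:
    """Audit whether each attachment-point bond matches a RECAP pattern.

    The molecule is rebuilt from (scaffold, decorations) to locate the bonds
    that the decoration process created; each is tested against the RECAP
    SMARTS registry (the shipped file by default, or ``rules`` as a list of
    (name, SMARTS)). Raises a contract error when the rebuilt molecule does
    not match ``molecule``.
    """
    rebuilt, bonds = _rebuild_with_tracked_bonds(scaffold, decorations)
    rebuilt_smiles = canonicalize(Chem.MolToSmiles(rebuilt))
    if rebuilt_smiles != canonicalize(molecule):
        raise ValueError(
            f"molecule {molecule!r} is not the join of the given scaffold and "
            f"decorations (got {rebuilt_smiles!r})")
    patterns = [(name, Chem.MolFromSmarts(s))
                for name, s in (rules if rules is not None else load_smarts_rules())]
    per_bond = []
    for a, b in bonds:
        compliant = False
        matched_rule = None
        for name, patt in patterns:
            for match in rebuilt.GetSubstructMatches(patt):
                pair = (match[0], match[1])
                if pair == (a, b) or pair == (b, a):
                    compliant, matched_rule = True, name
                    break
            if compliant:
                break
        per_bond.append({"atoms": (a, b), "compliant": compliant,
                         "rule": matched_rule})
    return {"per_bond": per_bond,
            "overall": all(b["compliant"] for b in per_bond)}


# ---------------------------------------------------------------------------
# novelty decomposition


@dataclass(frozen=True)
class NoveltyReport:
    """Decomposition of a run's decorations against the training set.

    Unique/novel fractions are computed over decorations (canonical SMILES
    with an unlabelled attachment); molecule-level fractions are over the
    distinct molecules of the run. ``fraction_novel_active`` is only set when
    an oracle is supplied; pool fractions only when a reference pool is.
    """

    n_decorations_total: int
    fraction_unique: float
    fraction_novel_decorations: float
    fraction_molecules_with_novel_decoration: float
    fraction_novel_active: Optional[float] = None
    fraction_all_decorations_in_pool: Optional[float] = None
    fraction_at_most_one_not_in_pool: Optional[float] = None


def novelty_metrics(run: DecorationRun, training_decorations: Iterable[str],
                    reference_pool: Optional[Iterable[str]] = None,
                    oracle: Optional[ActivityOracle] = None) -> NoveltyReport:
    if not run.molecules:
        raise ValueError("cannot compute novelty metrics over an empty run")
    training = {canonicalize(d) for d in training_decorations}
    pool = None if reference_pool is None else {canonicalize(d)
                                                for d in reference_pool}
    n_total = 0
    unique: set = set()
    n_with_novel = 0
    n_novel_active = 0
    n_all_in_pool = 0
    n_at_most_one_out = 0
    for smiles, entry in run.molecules.items():
        decs = [canonicalize(d) for d in entry.decorations]
        n_total += len(decs) * entry.count
        unique.update(decs)
        novel = [d for d in decs if d not in training]
        if novel:
            n_with_novel += 1
            if oracle is not None and oracle.is_active(smiles):
                n_novel_active += 1
        if pool is not None:
            n_out = sum(1 for d in decs if d not in pool)
            n_all_in_pool += n_out == 0
            n_at_most_one_out += n_out <= 1
    n_molecules = len(run.molecules)
    novel_unique = {d for d in unique if d not in training}
    return NoveltyReport(
        n_decorations_total=n_total,
        fraction_unique=len(unique) / n_total if n_total else 0.0,
        fraction_novel_decorations=(len(novel_unique) / len(unique)
                                    if unique else 0.0),
        fraction_molecules_with_novel_decoration=n_with_novel / n_molecules,
        fraction_novel_active=(n_novel_active / n_with_novel
                               if oracle is not None and n_with_novel else
                               (0.0 if oracle is not None else None)),
        fraction_all_decorations_in_pool=(n_all_in_pool / n_molecules
                                          if pool is not None else None),
        fraction_at_most_one_not_in_pool=(n_at_most_one_out / n_molecules
                                          if pool is not None else None),
    )


# ---------------------------------------------------------------------------
# descriptor profiling


def descriptor_profile(molecules: Iterable[str]) -> pd.DataFrame:
    """Per-molecule MW, cLogP, synthetic-accessibility score and QED.

    Molecules that fail to parse get NaN rows flagged in the ``ok`` column.
    """
    rows = []
    for smiles in molecules:
        try:
            mol = mol_from_smiles(smiles)
            rows.append({
                "smiles": smiles,
                "mw": Descriptors.MolWt(mol),
                "clogp": Crippen.MolLogP(mol),
                "sa_score": sascorer.calculateScore(mol),
                "qed": QED.qed(mol),
                "ok": True,
            })
        except Exception:
            rows.append({"smiles": smiles, "mw": np.nan, "clogp": np.nan,
                         "sa_score": np.nan, "qed": np.nan, "ok": False})
    return pd.DataFrame(rows)


def descriptor_histograms(profile: pd.DataFrame, bins: int = 20) -> Dict[str, dict]:
    """Histogram summaries (counts + bin edges) for each descriptor column."""
    out = {}
    for col in ("mw", "clogp", "sa_score", "qed"):
        values = profile.loc[profile["ok"], col].to_numpy()
        counts, edges = np.histogram(values, bins=bins)
        out[col] = {"counts": counts.tolist(), "edges": edges.tolist()}
    return out
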