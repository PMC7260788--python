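"""Exhaustive slicing of molecules into scaffold-decoration tuples.

A molecule is cut on combinations of 1..c_max single acyclic bonds. The
fragments of a c-bond cut are classified: the unique fragment carrying c
attachment points is the scaffold and the remaining fragments (one attachment
each) are its decorations; cuts that produce no such fragment are discarded.
Which bonds are candidates is controlled by a rule set — every single acyclic
bond, or only bonds matching retrosynthetic (RECAP) SMARTS patterns — and the
resulting scaffolds/decorations are screened by filters (ring-containing
scaffolds, fragment-like "rule of 3" decorations by default).

The inverse operation, :func:`join`, attaches a single-attachment decoration
back onto a scaffold attachment point with a single bond; folding it over a
tuple's decorations reproduces the source molecule exactly.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .chemio import (
    ATTACHMENT_TOKEN,
    AttachmentSmiles,
    MoleculeRecord,
    SmilesError,
    canonicalize,
    mol_from_smiles,
    mol_to_smiles,
    strip_attachment_labels,
)

__all__ = [
    "ALL_ACYCLIC",
    "SlicingRuleSet",
    "ScaffoldDecorationTuple",
    "TupleDataset",
    "JoinError",
    "candidate_bonds",
    "classify_fragments",
    "exhaustive_slice",
    "rule_of_three",
    "has_ring",
    "join",
    "join_all",
    "slice_corpus",
    "load_smarts_rules",
    "recap_rules",
    "acyclic_rules",
]

ALL_ACYCLIC = "ALL_ACYCLIC"


class JoinError(ValueError):
    """Raised when a decoration cannot be attached to a scaffold."""


def has_ring(fragment: AttachmentSmiles) -> bool:
    from rdkit.Chem import rdMolDescriptors
    return rdMolDescriptors.CalcNumRings(mol_from_smiles(fragment.smiles)) >= 1


def rule_of_three(fragment: AttachmentSmiles) -> bool:
    """Fragment-likeness filter on a single-attachment decoration.

    True iff MW <= 300 Da, H-bond donors <= 3, H-bond acceptors <= 3,
    cLogP <= 3 and rotatable bonds <= 3. The attachment dummy contributes no
    mass and is treated as an open valence; the bond to it is terminal and
    therefore never counted as rotatable.
    """
    if fragment.n_attachments != 1:
        raise ValueError(
            f"rule of 3 applies to single-attachment fragments, got "
            f"{fragment.n_attachments} in {fragment.smiles!r}")
    mol = mol_from_smiles(fragment.smiles)
    return (Descriptors.MolWt(mol) <= 300.0
            and Lipinski.NumHDonors(mol) <= 3
            and Lipinski.NumHAcceptors(mol) <= 3
            and Crippen.MolLogP(mol) <= 3.0
            and Lipinski.NumRotatableBonds(mol) <= 3)


@dataclass(frozen=True)
class SlicingRuleSet:
    """Bond-selection rules plus scaffold/decoration filters for slicing.

    ``bond_patterns`` is either the :data:`ALL_ACYCLIC` sentinel (every single
    non-ring bond is a candidate) or a list of ``(name, SMARTS)`` pairs where
    each SMARTS matches exactly one bond between its first two mapped atoms.
    RECAP-style patterns are additionally constrained to single acyclic bonds.
    """

    bond_patterns: object = ALL_ACYCLIC
    max_cuts: int = 4
    scaffold_filters: tuple = (has_ring,)
    decoration_filters: tuple = (rule_of_three,)
    name: str = "acyclic"

    def __post_init__(self):
        if self.max_cuts < 1:
            raise ValueError("max_cuts must be >= 1")
        if self.bond_patterns is not ALL_ACYCLIC:
            for pname, smarts in self.bond_patterns:
                patt = Chem.MolFromSmarts(smarts)
                if patt is None:
                    raise ValueError(f"invalid SMARTS for rule {pname!r}: {smarts}")

    def digest(self) -> str:
        payload = {
            "bonds": (self.bond_patterns if self.bond_patterns is ALL_ACYCLIC
                      else list(map(list, self.bond_patterns))),
            "max_cuts": self.max_cuts,
            "scaffold_filters": [f.__name__ for f in self.scaffold_filters],
            "decoration_filters": [f.__name__ for f in self.decoration_filters],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_smarts_rules(path=None) -> list:
    """Load a "name<TAB>SMARTS" rule file; default is the shipped RECAP set."""
    if path is None:
        ref = importlib.resources.files("scaffdec") / "data" / "recap.smarts"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        rules.append((name, smarts))
    return rules


def acyclic_rules(max_cuts: int = 4, scaffold_ring: bool = True,
                  decoration_ro3: bool = True) -> SlicingRuleSet:
    return SlicingRuleSet(
        bond_patterns=ALL_ACYCLIC, max_cuts=max_cuts,
        scaffold_filters=(has_ring,) if scaffold_ring else (),
        decoration_filters=(rule_of_three,) if decoration_ro3 else (),
        name="acyclic")


def recap_rules(max_cuts: int = 4, scaffold_ring: bool = True,
                decoration_ro3: bool = True, path=None) -> SlicingRuleSet:
    return SlicingRuleSet(
        bond_patterns=tuple(load_smarts_rules(path)), max_cuts=max_cuts,
        scaffold_filters=(has_ring,) if scaffold_ring else (),
        decoration_filters=(rule_of_three,) if decoration_ro3 else (),
        name="recap")


@dataclass(frozen=True)
class ScaffoldDecorationTuple:
    """One scaffold with as many decorations as it has attachment points.

    ``decorations[i]`` belongs to the i-th ``[*]`` by order of appearance in
    ``scaffold.smiles``; joining them all reproduces ``source``.
    """

    scaffold: AttachmentSmiles
    decorations: tuple
    source: str

    def __post_init__(self):
        if len(self.decorations) != self.scaffold.n_attachments:
            raise ValueError(
                f"{len(self.decorations)} decorations for a scaffold with "
                f"{self.scaffold.n_attachments} attachment points")

    @property
    def n_cuts(self) -> int:
        return self.scaffold.n_attachments

    def dedup_key(self):
        return (self.scaffold.smiles,
                tuple(sorted(d.smiles for d in self.decorations)))

    def rejoin(self) -> str:
        return join_all(self.scaffold, self.decorations)


def _bonds_matching_patterns(mol, patterns) -> set:
    matched = set()
    for _, smarts in patterns:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[0], match[1])
            if bond is not None:
                matched.add(bond.GetIdx())
    return matched


def candidate_bonds(mol_or_record, rules: SlicingRuleSet) -> list:
    """Indices of bonds eligible for cutting, deterministically ordered.

    Every candidate is a single, acyclic bond between two heavy atoms; with
    SMARTS rules, it must additionally match at least one pattern.
    """
    if isinstance(mol_or_record, MoleculeRecord):
        mol = mol_from_smiles(mol_or_record.canonical_smiles)
    elif isinstance(mol_or_record, str):
        mol = mol_from_smiles(canonicalize(mol_or_record))
    else:
        mol = mol_or_record
    eligible = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if (bond.GetBeginAtom().GetAtomicNum() == 0
                or bond.GetEndAtom().GetAtomicNum() == 0):
            continue
        eligible.append(bond.GetIdx())
    if rules.bond_patterns is not ALL_ACYCLIC:
        matched = _bonds_matching_patterns(mol, rules.bond_patterns)
        eligible = [b for b in eligible if b in matched]
    return sorted(eligible)


def _attachment_count(mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def classify_fragments(fragments: Sequence[AttachmentSmiles], c: int) -> list:
    """Classify the fragments of a c-bond cut into scaffold/decoration roles.

    Returns a list of ``(scaffold, decorations)`` orientations: empty when the
    combination is discarded (no fragment carries exactly c attachments), one
    entry in the general case, and two for c == 1 where either fragment may
    serve as the scaffold.
    """
    total = sum(f.n_attachments for f in fragments)
    if total != 2 * c:
        raise ValueError(
            f"attachment bookkeeping broken: {total} attachments for {c} cuts")
    if c == 1:
        if len(fragments) != 2:
            raise ValueError("a single cut must produce exactly two fragments")
        a, b = fragments
        return [(a, (b,)), (b, (a,))]
    scaffolds = [f for f in fragments if f.n_attachments == c]
    if len(scaffolds) != 1:
        return []
    scaffold = scaffolds[0]
    rest = [f for f in fragments if f is not scaffold]
    if any(f.n_attachments != 1 for f in rest):
        return []
    return [(scaffold, tuple(rest))]


def _ordered_tuple_from_cut(mol, bond_indices) -> Optional[list]:
    """Cut ``bond_indices`` and return labelled (scaffold, decorations) splits.

    Attachment dummies are isotope-labelled per cut bond so that each scaffold
    attachment can be paired with the decoration severed at the same bond.
    """
    c = len(bond_indices)
    labels = [(i + 1, i + 1) for i in range(c)]
    frag = Chem.FragmentOnBonds(mol, list(bond_indices), addDummies=True,
                                dummyLabels=labels)
    try:
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    except Exception:
        return None
    if len(pieces) != c + 1:
        return None  # a cut failed to disconnect (should not happen acyclic)
    counts = [_attachment_count(p) for p in pieces]
    orientations = []
    if c == 1:
        pairs = [(0, 1), (1, 0)]
    else:
        try:
            scaf_pos = counts.index(c)
        except ValueError:
            return []
        if counts.count(c) != 1 or any(
                n != 1 for i, n in enumerate(counts) if i != scaf_pos):
            return []
        pairs = [(scaf_pos, None)]
    for scaf_pos, other in pairs:
        scaf_mol = pieces[scaf_pos]
        dec_mols = ([pieces[other]] if other is not None
                    else [p for i, p in enumerate(pieces) if i != scaf_pos])
        orientations.append((scaf_mol, dec_mols))
    return orientations


def _canonical_scaffold_and_order(scaf_mol):
    """Canonical unlabelled scaffold SMILES + cut labels in [*] string order."""
    work = Chem.Mol(scaf_mol)
    dummy_labels = {}
    for atom in work.GetAtoms():
        if atom.GetAtomicNum() == 0:
            dummy_labels[atom.GetIdx()] = atom.GetIsotope()
            atom.SetIsotope(0)
    smiles = mol_to_smiles(work)
    order = json.loads(work.GetProp("_smilesAtomOutputOrder"))
    labels_in_order = [dummy_labels[idx] for idx in order if idx in dummy_labels]
    return smiles, labels_in_order


def _canonical_decoration(dec_mol) -> str:
    work = Chem.Mol(dec_mol)
    for atom in work.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    return mol_to_smiles(work)


def exhaustive_slice(record: MoleculeRecord | str,
                     rules: SlicingRuleSet) -> list:
    """All scaffold-decoration tuples obtainable by cutting 1..max_cuts bonds.

    Iterates every subset of candidate bonds up to ``rules.max_cuts``,
    classifies fragments, applies the scaffold and decoration filters, and
    deduplicates on (canonical scaffold, sorted canonical decorations).
    """
    if isinstance(record, str):
        record = MoleculeRecord.from_smiles(record)
    mol = mol_from_smiles(record.canonical_smiles)
    cand = candidate_bonds(mol, rules)
    seen = {}
    for c in range(1, min(rules.max_cuts, len(cand)) + 1):
        for subset in combinations(cand, c):
            orientations = _ordered_tuple_from_cut(mol, subset)
            if not orientations:
                continue
            for scaf_mol, dec_mols in orientations:
                scaf_smiles, label_order = _canonical_scaffold_and_order(scaf_mol)
                scaffold = AttachmentSmiles(scaf_smiles, len(label_order))
                if not all(f(scaffold) for f in rules.scaffold_filters):
                    continue
                by_label = {}
                for dm in dec_mols:
                    label = next(a.GetIsotope() for a in dm.GetAtoms()
                                 if a.GetAtomicNum() == 0)
                    by_label[label] = AttachmentSmiles(_canonical_decoration(dm), 1)
                decorations = tuple(by_label[lbl] for lbl in label_order)
                if not all(f(d) for f in rules.decoration_filters
                           for d in decorations):
                    continue
                tup = ScaffoldDecorationTuple(
                    scaffold=scaffold, decorations=decorations,
                    source=record.canonical_smiles)
                seen.setdefault(tup.dedup_key(), tup)
    return list(seen.values())


def _nth_dummy_atom(mol, n: int) -> int:
    """Atom index of the n-th dummy in SMILES-string appearance order.

    RDKit assigns atom indices in input order when parsing, so the n-th dummy
    by atom index is the n-th ``[*]`` in the string the mol was parsed from.
    """
    count = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            if count == n:
                return atom.GetIdx()
            count += 1
    raise IndexError(f"scaffold has only {count} attachment points, asked for #{n}")


def _attach(rw: Chem.RWMol, scaffold_dummy: int, dec_mol) -> Chem.RWMol:
    dec_dummy_local = _nth_dummy_atom(dec_mol, 0)
    offset = rw.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(rw, dec_mol))
    scaf_nbrs = [a.GetIdx() for a in combo.GetAtomWithIdx(scaffold_dummy).GetNeighbors()]
    dec_dummy = offset + dec_dummy_local
    dec_nbrs = [a.GetIdx() for a in combo.GetAtomWithIdx(dec_dummy).GetNeighbors()]
    if len(scaf_nbrs) != 1 or len(dec_nbrs) != 1:
        raise JoinError("attachment atoms must have exactly one neighbor")
    combo.AddBond(scaf_nbrs[0], dec_nbrs[0], Chem.BondType.SINGLE)
    for idx in sorted((scaffold_dummy, dec_dummy), reverse=True):
        combo.RemoveAtom(idx)
    return combo


def join(scaffold: AttachmentSmiles | str, decoration: AttachmentSmiles | str,
         attachment_index: int = 0) -> AttachmentSmiles:
    """Bond a single-attachment decoration onto one scaffold attachment point.

    ``attachment_index`` counts ``[*]`` tokens by order of appearance in the
    scaffold string. The new bond is a single bond; the result has one fewer
    attachment point.
    """
    scaf_s = scaffold.smiles if isinstance(scaffold, AttachmentSmiles) else scaffold
    dec_s = decoration.smiles if isinstance(decoration, AttachmentSmiles) else decoration
    scaf_mol = mol_from_smiles(scaf_s)
    dec_mol = mol_from_smiles(dec_s)
    if _attachment_count(dec_mol) != 1:
        raise JoinError(f"decoration must have exactly one attachment: {dec_s!r}")
    n_scaf = _attachment_count(scaf_mol)
    if not 0 <= attachment_index < n_scaf:
        raise JoinError(
            f"attachment_index {attachment_index} out of range for {scaf_s!r}")
    dummy = _nth_dummy_atom(scaf_mol, attachment_index)
    combo = _attach(Chem.RWMol(scaf_mol), dummy, dec_mol)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise JoinError(
            f"joining {dec_s!r} onto {scaf_s!r} at point {attachment_index}: {exc}"
        ) from exc
    return AttachmentSmiles(mol_to_smiles(mol), n_scaf - 1)


def join_all(scaffold: AttachmentSmiles | str,
             decorations: Sequence) -> str:
    """Fold :func:`join` over all decorations; returns the canonical SMILES.

    ``decorations[i]`` is attached at the i-th ``[*]`` of the *original*
    scaffold string, regardless of how intermediate joins reorder the string.
    """
    scaf_s = scaffold.smiles if isinstance(scaffold, AttachmentSmiles) else scaffold
    scaf_mol = mol_from_smiles(scaf_s)
    dummies = [a.GetIdx() for a in scaf_mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != len(decorations):
        raise JoinError(
            f"{len(decorations)} decorations for {len(dummies)} attachment points")
    rw = Chem.RWMol(scaf_mol)
    # Tag each dummy with its appearance position so indices survive edits.
    for pos, idx in enumerate(dummies):
        rw.GetAtomWithIdx(idx).SetIsotope(pos + 1)
    for pos, dec in enumerate(decorations):
        dec_s = dec.smiles if isinstance(dec, AttachmentSmiles) else dec
        dec_mol = mol_from_smiles(dec_s)
        if _attachment_count(dec_mol) != 1:
            raise JoinError(f"decoration must have exactly one attachment: {dec_s!r}")
        dummy = next(a.GetIdx() for a in rw.GetAtoms()
                     if a.GetAtomicNum() == 0 and a.GetIsotope() == pos + 1)
        rw = _attach(rw, dummy, dec_mol)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise JoinError(f"rejoined molecule failed sanitization: {exc}") from exc
    return mol_to_smiles(mol)


@dataclass
class TupleDataset:
    """A multiset of scaffold-decoration tuples with provenance and summaries.

    Multiplicity is kept: the same (scaffold, decoration set) arising from two
    different source molecules is two entries, matching the dataset semantics
    used to train decorators.
    """

    tuples: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tuples)

    def __iter__(self):
        return iter(self.tuples)

    def summary(self) -> dict:
        scaffold_sets = {}
        decorations = Counter()
        attachment_hist = Counter()
        for tup in self.tuples:
            scaffold_sets.setdefault(tup.scaffold.smiles, set()).add(
                tuple(sorted(d.smiles for d in tup.decorations)))
            for d in tup.decorations:
                decorations[d.smiles] += 1
            attachment_hist[tup.scaffold.n_attachments] += 1
        n_scaffolds = len(scaffold_sets)
        singletons = sum(1 for sets in scaffold_sets.values() if len(sets) == 1)
        return {
            "n_tuples": len(self.tuples),
            "n_unique_scaffolds": n_scaffolds,
            "n_unique_decorations": len(decorations),
            "attachment_histogram": dict(sorted(attachment_hist.items())),
            "singleton_fraction": (singletons / n_scaffolds) if n_scaffolds else 0.0,
        }

    def unique_decorations(self) -> set:
        return {d.smiles for tup in self.tuples for d in tup.decorations}

    def unique_scaffolds(self) -> set:
        return {tup.scaffold.smiles for tup in self.tuples}

    def save_tsv(self, path, header: bool = False) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write("scaffold\tdecorations\tsource\n")
            for tup in self.tuples:
                decs = "|".join(d.smiles for d in tup.decorations)
                fh.write(f"{tup.scaffold.smiles}\t{decs}\t{tup.source}\n")

    @classmethod
    def load_tsv(cls, path) -> "TupleDataset":
        tuples = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("scaffold\t"):
                    continue
                scaffold_s, decs_s, source = line.split("\t")
                decorations = tuple(
                    AttachmentSmiles.from_smiles(d) for d in decs_s.split("|"))
                tuples.append(ScaffoldDecorationTuple(
                    scaffold=AttachmentSmiles.from_smiles(scaffold_s),
                    decorations=decorations, source=source))
        return cls(tuples=tuples, provenance={"source": str(path)})


def slice_corpus(corpus: Iterable[MoleculeRecord], rules: SlicingRuleSet,
                 on_error: str = "skip") -> TupleDataset:
    """Slice every molecule of a corpus and pool the tuples (multiset).

    Per-molecule failures are skipped (and counted in provenance) rather than
    aborting the run, unless ``on_error='raise'``.
    """
    tuples = []
    n_failed = 0
    n_molecules = 0
    for record in corpus:
        n_molecules += 1
        try:
            tuples.extend(exhaustive_slice(record, rules))
        except Exception:
            if on_error == "raise":
                raise
            n_failed += 1
    return TupleDataset(tuples=tuples, provenance={
        "rule_set": rules.name,
        "rule_digest": rules.digest(),
        "n_molecules": n_molecules,
        "n_failed": n_failed,
    })
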