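"""Molecule I/O, SMILES canonicalization/randomization, tokenization and vocabularies.

SMILES strings here may carry the attachment-point extension: a dummy atom
written ``[*]`` marks an open position of a partially built molecule (a
scaffold), and ``|`` separates multiple decorations in a single sequence.
All heavy lifting on molecular graphs is delegated to RDKit; this module owns
the string-level contracts (token classes, attachment bookkeeping, vocabulary
indexing) that the generative models depend on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

ATTACHMENT_TOKEN = "[*]"
SEPARATOR_TOKEN = "|"
BEGIN_TOKEN = "^"
END_TOKEN = "$"
PAD_TOKEN = "<pad>"

__all__ = [
    "MoleculeRecord",
    "AttachmentSmiles",
    "TokenSequence",
    "Vocabulary",
    "SmilesError",
    "canonicalize",
    "mol_from_smiles",
    "mol_to_smiles",
    "randomize_smiles",
    "count_attachments",
    "tokenize",
    "detokenize",
    "build_vocabulary",
    "read_smiles_file",
    "write_smiles_file",
]


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed or tokenized."""


# Dummy atoms print as bare "*" in RDKit output; the models expect the
# bracketed token, so output is normalized. Isotope-labelled dummies such as
# "[3*]" (internal attachment bookkeeping) are left untouched.
_BARE_STAR = re.compile(r"(?<![\[\d])\*")
_LABELLED_STAR = re.compile(r"\[\d+\*\]")


def _bracket_attachments(smiles: str) -> str:
    return _BARE_STAR.sub("[*]", smiles)


def strip_attachment_labels(smiles: str) -> str:
    """Replace isotope-labelled attachment atoms ([1*], [2*], ...) with plain [*]."""
    return _LABELLED_STAR.sub("[*]", smiles)


def mol_from_smiles(smiles: str):
    """Parse a SMILES (attachment tokens permitted) or raise :class:`SmilesError`."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def mol_to_smiles(mol, canonical: bool = True) -> str:
    return _bracket_attachments(Chem.MolToSmiles(mol, canonical=canonical))


def canonicalize(smiles: str, strip_stereo: bool = True) -> str:
    """Return the unique canonical SMILES of ``smiles``.

    Stereochemistry is stripped by default, matching the corpus ingestion
    convention; set ``strip_stereo=False`` to keep it. Idempotent.
    """
    mol = mol_from_smiles(smiles)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return mol_to_smiles(mol)


def count_attachments(smiles: str) -> int:
    return sum(1 for t in tokenize(smiles).tokens if t == ATTACHMENT_TOKEN)


def substructure_query(smiles: str):
    """Query molecule for substructure matching, with ``[*]`` as a wildcard.

    A decorated molecule "contains its scaffold" when the scaffold matches
    with each attachment dummy standing for any atom.
    """
    mol = mol_from_smiles(smiles)
    params = Chem.AdjustQueryParameters.NoAdjustments()
    params.makeDummiesQueries = True
    return Chem.AdjustQueryProperties(mol, params)


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule pinned to its canonical SMILES identity."""

    source_smiles: str
    canonical_smiles: str
    id: Optional[str] = None

    @classmethod
    def from_smiles(cls, smiles: str, id: Optional[str] = None,
                    strip_stereo: bool = True) -> "MoleculeRecord":
        return cls(source_smiles=smiles,
                   canonical_smiles=canonicalize(smiles, strip_stereo=strip_stereo),
                   id=id)

    def mol(self):
        return mol_from_smiles(self.canonical_smiles)


@dataclass(frozen=True)
class AttachmentSmiles:
    """A (possibly partial) molecule with zero or more ``[*]`` attachment points."""

    smiles: str
    n_attachments: int

    @classmethod
    def from_smiles(cls, smiles: str) -> "AttachmentSmiles":
        mol_from_smiles(smiles)  # validation
        return cls(smiles=smiles, n_attachments=count_attachments(smiles))

    def canonical(self) -> "AttachmentSmiles":
        return AttachmentSmiles(canonicalize(self.smiles), self.n_attachments)


def randomize_smiles(smiles: str, rng, restricted: bool = True) -> str:
    """Return a randomized (non-canonical) SMILES of the same molecular graph.

    ``rng`` is a :class:`numpy.random.Generator` (or anything with a
    ``permutation`` method). The restricted variant permutes the atom order
    and lets RDKit make canonical branching decisions from that root, which
    yields better-behaved training strings than fully random traversals; pass
    ``restricted=False`` for the unrestricted variant.
    """
    mol = mol_from_smiles(smiles)
    if restricted:
        perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        shuffled = Chem.RenumberAtoms(mol, perm)
        return _bracket_attachments(Chem.MolToSmiles(shuffled, canonical=False))
    seed = int(rng.integers(1, 2**31 - 1))
    return _bracket_attachments(Chem.MolToRandomSmilesVect(mol, 1, seed)[0])


# Token classes: bracket atoms ([nH], [*], [N+], ...), two-letter organic
# subset atoms, ring-bond reopenings (%nn), and single characters (atoms,
# bonds, branches, digits, the separator "|").
_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")


@dataclass(frozen=True)
class TokenSequence:
    """Tokenized SMILES; detokenization reproduces the source string exactly."""

    tokens: tuple

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)


def tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into atom/bond/branch tokens.

    Multi-character atoms ("Cl", "Br", bracket atoms), "[*]" and "|" are each
    a single token. Raises :class:`SmilesError` on empty input or an unclosed
    bracket atom.
    """
    if not smiles:
        raise SmilesError("cannot tokenize an empty string")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise SmilesError(f"tokenization does not cover the input: {smiles!r}")
    for tok in tokens:
        if tok == "[" or (tok.startswith("[") and not tok.endswith("]")):
            raise SmilesError(f"dangling '[' in {smiles!r}")
        if tok == "]":
            raise SmilesError(f"unmatched ']' in {smiles!r}")
    return TokenSequence(tokens=tuple(tokens))


def detokenize(sequence: TokenSequence | Sequence[str]) -> str:
    tokens = sequence.tokens if isinstance(sequence, TokenSequence) else sequence
    return "".join(tokens)


class Vocabulary:
    """Bijective token<->index mapping with reserved special tokens.

    Index 0 is the padding token and is never emitted by sampling. Tokens are
    assigned indices deterministically (specials first, then sorted corpus
    tokens) so two corpora with the same token set produce identical
    vocabularies regardless of ordering.
    """

    SPECIALS = (PAD_TOKEN, BEGIN_TOKEN, END_TOKEN, ATTACHMENT_TOKEN, SEPARATOR_TOKEN)

    def __init__(self, tokens: Iterable[str]):
        ordered = list(self.SPECIALS)
        for tok in sorted(set(tokens) - set(self.SPECIALS)):
            ordered.append(tok)
        self._tokens = ordered
        self._index = {tok: i for i, tok in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self._tokens == other._tokens

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def begin_index(self) -> int:
        return self._index[BEGIN_TOKEN]

    @property
    def end_index(self) -> int:
        return self._index[END_TOKEN]

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise SmilesError(f"token {token!r} is not in the vocabulary") from None

    def token(self, index: int) -> str:
        return self._tokens[index]

    def encode(self, smiles_or_tokens, wrap: bool = True) -> list:
        """Indices for a SMILES string (or pre-tokenized sequence).

        ``wrap=True`` adds begin/end markers, the framing the models train on.
        """
        if isinstance(smiles_or_tokens, str):
            tokens = list(tokenize(smiles_or_tokens))
        else:
            tokens = list(smiles_or_tokens)
        if wrap:
            tokens = [BEGIN_TOKEN] + tokens + [END_TOKEN]
        return [self.index(t) for t in tokens]

    def decode(self, indices: Sequence[int]) -> str:
        """String for a list of indices, stopping at the end marker."""
        out = []
        for i in indices:
            tok = self.token(int(i))
            if tok == END_TOKEN:
                break
            if tok in (BEGIN_TOKEN, PAD_TOKEN):
                continue
            out.append(tok)
        return "".join(out)

    def tokens(self) -> list:
        return list(self._tokens)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok in self._tokens:
                fh.write(tok + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        vocab = cls.__new__(cls)
        vocab._tokens = tokens
        vocab._index = {tok: i for i, tok in enumerate(tokens)}
        return vocab


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Vocabulary over every token occurring in ``corpus`` plus the specials."""
    tokens: set = set()
    n = 0
    for line_no, smiles in enumerate(corpus, start=1):
        n += 1
        try:
            tokens.update(tokenize(smiles))
        except SmilesError as exc:
            raise SmilesError(f"line {line_no}: {exc}") from exc
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(tokens)


def read_smiles_file(path, strip_stereo: bool = True,
                     skip_invalid: bool = False) -> list:
    """Read a "SMILES[\\tID]" file into :class:`MoleculeRecord` objects.

    Lines starting with '#' and blank lines are ignored.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else None
            try:
                records.append(MoleculeRecord.from_smiles(
                    smiles, id=mol_id, strip_stereo=strip_stereo))
            except SmilesError:
                if not skip_invalid:
                    raise SmilesError(f"{path}:{line_no}: unparseable SMILES {smiles!r}")
    return records


def write_smiles_file(path, records: Iterable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if isinstance(rec, MoleculeRecord):
                line = rec.canonical_smiles + (f"\t{rec.id}" if rec.id else "")
            elif isinstance(rec, AttachmentSmiles):
                line = rec.smiles
            else:
                line = str(rec)
            fh.write(line + "\n")
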