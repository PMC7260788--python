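"""Exhaustive slicing: candidate bonds, classification, filters, round trips."""

from itertools import combinations

import pytest
from rdkit import Chem

from scaffdec.chemio import AttachmentSmiles, MoleculeRecord, canonicalize
from scaffdec.slicer import (
    JoinError,
    ScaffoldDecorationTuple,
    SlicingRuleSet,
    TupleDataset,
    acyclic_rules,
    candidate_bonds,
    classify_fragments,
    exhaustive_slice,
    has_ring,
    join,
    join_all,
    recap_rules,
    rule_of_three,
    slice_corpus,
)

CINNARIZINE = canonicalize("C(c1ccccc1)(c1ccccc1)N1CCN(CC1)C/C=C/c1ccccc1")


def brute_force_acyclic_bonds(smiles: str):
    """Independent scan: single, non-ring bonds between heavy atoms."""
    mol = Chem.MolFromSmiles(smiles)
    return sorted(
        b.GetIdx() for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 0
        and b.GetEndAtom().GetAtomicNum() > 0)


def naive_tuple_count(smiles: str, max_cuts: int,
                      scaffold_ring=True, decoration_ro3=True) -> int:
    """Brute-force tuple enumeration, independent of the slicer internals.

    Cuts every subset of acyclic single bonds, classifies fragments purely by
    attachment counting, applies the filters, and deduplicates on canonical
    (scaffold, sorted decorations).
    """
    source = canonicalize(smiles)
    mol = Chem.MolFromSmiles(source)
    bonds = brute_force_acyclic_bonds(source)
    seen = set()
    for c in range(1, max_cuts + 1):
        for subset in combinations(bonds, c):
            frag = Chem.FragmentOnBonds(mol, list(subset), addDummies=True,
                                        dummyLabels=[(0, 0)] * c)
            try:
                pieces = Chem.GetMolFrags(frag, asMols=True)
            except Exception:
                continue
            if len(pieces) != c + 1:
                continue
            counts = [sum(1 for a in p.GetAtoms() if a.GetAtomicNum() == 0)
                      for p in pieces]
            if c == 1:
                orientations = [(0, [1]), (1, [0])]
            elif counts.count(c) == 1:
                scaf = counts.index(c)
                if any(n != 1 for i, n in enumerate(counts) if i != scaf):
                    continue
                orientations = [(scaf, [i for i in range(len(pieces))
                                        if i != scaf])]
            else:
                continue
            for scaf_i, dec_is in orientations:
                scaf_smiles = canonicalize(Chem.MolToSmiles(pieces[scaf_i]))
                dec_smiles = tuple(sorted(
                    canonicalize(Chem.MolToSmiles(pieces[i])) for i in dec_is))
                scaf_att = AttachmentSmiles.from_smiles(scaf_smiles)
                if scaffold_ring and not has_ring(scaf_att):
                    continue
                if decoration_ro3 and not all(
                        rule_of_three(AttachmentSmiles.from_smiles(d))
                        for d in dec_smiles):
                    continue
                seen.add((scaf_smiles, dec_smiles))
    return len(seen)


class TestCandidateBonds:
    def test_benzene_has_none(self):
        assert candidate_bonds("c1ccccc1", acyclic_rules()) == []

    def test_toluene_single_bond_matches_brute_force(self):
        got = candidate_bonds("Cc1ccccc1", acyclic_rules())
        assert got == brute_force_acyclic_bonds(canonicalize("Cc1ccccc1"))
        assert len(got) == 1

    def test_recap_selects_amide_not_anilide_ring_bond(self):
        smiles = canonicalize("CC(=O)Nc1ccccc1")
        mol = Chem.MolFromSmiles(smiles)
        got = candidate_bonds(smiles, recap_rules())
        amide, ring_cn = None, None
        for bond in mol.GetBonds():
            syms = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
            if syms == {"C", "N"}:
                carbons = [a for a in (bond.GetBeginAtom(), bond.GetEndAtom())
                           if a.GetSymbol() == "C"]
                if carbons[0].GetIsAromatic():
                    ring_cn = bond.GetIdx()
                else:
                    amide = bond.GetIdx()
        assert amide in got
        assert ring_cn not in got

    def test_recap_subset_of_acyclic(self, toy_corpus60):
        for rec in toy_corpus60.records[:20]:
            acyclic = set(candidate_bonds(rec, acyclic_rules()))
            recap = set(candidate_bonds(rec, recap_rules()))
            assert recap <= acyclic


class TestClassifyFragments:
    @staticmethod
    def _frags(*smiles):
        return [AttachmentSmiles.from_smiles(s) for s in smiles]

    def test_two_cut_unique_scaffold(self):
        frags = self._frags("[*]N1CCN([*])CC1", "[*]CC", "[*]CC")
        result = classify_fragments(frags, c=2)
        assert len(result) == 1
        scaffold, decorations = result[0]
        assert scaffold.n_attachments == 2
        assert len(decorations) == 2

    def test_single_cut_both_orientations(self):
        frags = self._frags("[*]c1ccccc1", "[*]CCO")
        result = classify_fragments(frags, c=1)
        assert len(result) == 2
        assert {r[0].smiles for r in result} == {"[*]c1ccccc1", "[*]CCO"}

    def test_star_molecule_cut_sets(self):
        # central atom with three cut branches: valid {3,1,1,1}
        ok = classify_fragments(
            self._frags("[*]C([*])([*])C", "[*]C", "[*]C", "[*]C"), c=3)
        assert len(ok) == 1
        assert ok[0][0].n_attachments == 3
        # chain cut twice at both ends plus middle: {1,2,2,1} has no
        # 3-attachment fragment -> discard
        bad = classify_fragments(
            self._frags("[*]C", "[*]C[*]", "[*]C[*]", "[*]C"), c=3)
        assert bad == []

    def test_bookkeeping_error(self):
        with pytest.raises(ValueError, match="bookkeeping"):
            classify_fragments(self._frags("[*]C", "[*]C"), c=2)


class TestRuleOfThree:
    def test_methyl_passes(self):
        assert rule_of_three(AttachmentSmiles.from_smiles("[*]C"))

    def test_c22_chain_fails_molecular_weight(self):
        chain = "[*]" + "C" * 22
        frag = AttachmentSmiles.from_smiles(chain)
        # oracle: 22 carbons at 12.011 plus 45 hydrogens exceeds 300 Da
        assert 22 * 12.011 + 45 * 1.008 > 300
        assert not rule_of_three(frag)

    def test_four_donors_fail(self):
        frag = AttachmentSmiles.from_smiles("[*]CC(N)C(N)C(N)N")
        mol = Chem.MolFromSmiles(frag.smiles)
        donors = len(mol.GetSubstructMatches(
            Chem.MolFromSmarts("[$([N;!H0]),$([O;!H0])]")))
        assert donors == 4
        assert not rule_of_three(frag)

    def test_contract_error_on_wrong_attachment_count(self):
        with pytest.raises(ValueError):
            rule_of_three(AttachmentSmiles.from_smiles("[*]C[*]"))


class TestJoin:
    def test_smallest_join_gives_toluene(self):
        assert join("[*]c1ccccc1", "[*]C").smiles == canonicalize("Cc1ccccc1")

    def test_attachment_arithmetic(self):
        out = join("[*]c1ccc([*])cc1", "[*]C", 0)
        assert out.n_attachments == 1

    def test_join_all_by_appearance_order(self):
        molecule = join_all("[*]c1ccc([*])cc1", ["[*]CCO", "[*]N"])
        assert molecule == canonicalize("OCCc1ccc(N)cc1")

    def test_errors(self):
        with pytest.raises(JoinError):
            join("[*]c1ccccc1", "[*]C[*]")  # two attachments
        with pytest.raises(JoinError):
            join("[*]c1ccccc1", "[*]C", attachment_index=1)
        with pytest.raises(JoinError):
            join_all("[*]c1ccccc1", ["[*]C", "[*]C"])


class TestExhaustiveSlice:
    def test_benzene_empty(self):
        assert exhaustive_slice("c1ccccc1", acyclic_rules()) == []

    def test_cinnarizine_piperazine_tuple(self):
        # the emblematic slicing of cinnarizine: piperazine scaffold with
        # benzhydryl + cinnamyl decorations (decoration filters off, since
        # benzhydryl's cLogP exceeds the rule-of-3 cap)
        rules = acyclic_rules(max_cuts=4, decoration_ro3=False)
        tuples = exhaustive_slice(CINNARIZINE, rules)
        piperazine = canonicalize("[*]N1CCN([*])CC1")
        match = [t for t in tuples if t.scaffold.smiles == piperazine]
        assert len(match) == 1
        decs = {d.smiles for d in match[0].decorations}
        assert decs == {canonicalize("[*]C(c1ccccc1)c1ccccc1"),
                        canonicalize("[*]CC=Cc1ccccc1")}

    def test_rule_of_three_filter_drops_benzhydryl_tuple(self):
        tuples = exhaustive_slice(CINNARIZINE, acyclic_rules(max_cuts=4))
        piperazine = canonicalize("[*]N1CCN([*])CC1")
        assert not any(t.scaffold.smiles == piperazine for t in tuples)

    @pytest.mark.parametrize("smiles,max_cuts", [
        ("c1ccccc1CCO", 2),
        ("CC(=O)Nc1ccccc1", 3),
        ("Cc1ccc(CC(C)O)cc1", 3),
    ])
    def test_counts_match_naive_enumeration(self, smiles, max_cuts):
        tuples = exhaustive_slice(smiles, acyclic_rules(max_cuts=max_cuts))
        assert len(tuples) == naive_tuple_count(smiles, max_cuts)

    def test_roundtrip_and_conservation(self, toy_corpus60):
        rules = acyclic_rules(max_cuts=3)
        for rec in toy_corpus60.records[:25]:
            parent = Chem.MolFromSmiles(rec.canonical_smiles)
            n_parent = parent.GetNumHeavyAtoms()
            for tup in exhaustive_slice(rec, rules):
                assert tup.rejoin() == rec.canonical_smiles
                heavy = Chem.MolFromSmiles(tup.scaffold.smiles).GetNumHeavyAtoms()
                heavy += sum(
                    Chem.MolFromSmiles(d.smiles).GetNumHeavyAtoms()
                    for d in tup.decorations)
                # dummies carry atomic number 0 and are not heavy atoms
                assert heavy == n_parent

    def test_recap_tuples_subset_of_acyclic(self, toy_corpus60):
        for rec in toy_corpus60.records[:15]:
            acyclic = {t.dedup_key() for t in
                       exhaustive_slice(rec, acyclic_rules(max_cuts=3))}
            recap = {t.dedup_key() for t in
                     exhaustive_slice(rec, recap_rules(max_cuts=3))}
            assert recap <= acyclic

    def test_filter_soundness(self, toy_corpus60):
        rules = acyclic_rules(max_cuts=3)
        for rec in toy_corpus60.records[:15]:
            for tup in exhaustive_slice(rec, rules):
                assert has_ring(tup.scaffold)
                for d in tup.decorations:
                    assert rule_of_three(d)

    def test_decoration_order_matches_attachment_order(self, toy_corpus60):
        # joining decorations in stored order must reproduce the source;
        # joining a non-symmetric tuple in swapped order must not
        rules = acyclic_rules(max_cuts=2)
        checked = 0
        for rec in toy_corpus60.records:
            for tup in exhaustive_slice(rec, rules):
                if tup.n_cuts != 2:
                    continue
                d0, d1 = tup.decorations
                if d0.smiles == d1.smiles:
                    continue
                assert join_all(tup.scaffold, [d0, d1]) == tup.source
                swapped = join_all(tup.scaffold, [d1, d0])
                if swapped != tup.source:
                    checked += 1
            if checked >= 3:
                return
        assert checked > 0


class TestSliceCorpus:
    def test_benzene_corpus_all_zero(self):
        ds = slice_corpus([MoleculeRecord.from_smiles("c1ccccc1")],
                          acyclic_rules())
        summary = ds.summary()
        assert summary["n_tuples"] == 0
        assert summary["n_unique_scaffolds"] == 0

    def test_doubling_corpus_doubles_multiset(self, toy_corpus60):
        records = toy_corpus60.records[:8]
        rules = acyclic_rules(max_cuts=2)
        once = slice_corpus(records, rules)
        twice = slice_corpus(records + records, rules)
        assert len(twice) == 2 * len(once)
        assert (twice.summary()["n_unique_scaffolds"]
                == once.summary()["n_unique_scaffolds"])

    def test_failures_are_skipped_not_fatal(self):
        good = MoleculeRecord.from_smiles("Cc1ccccc1")
        bad = MoleculeRecord("x", "x", None)  # bypasses parsing on purpose
        ds = slice_corpus([good, bad], acyclic_rules())
        assert ds.provenance["n_failed"] == 1
        assert len(ds) > 0

    def test_tsv_roundtrip(self, toy_corpus60, tmp_path):
        ds = slice_corpus(toy_corpus60.records[:8], acyclic_rules(max_cuts=2))
        path = tmp_path / "tuples.tsv"
        ds.save_tsv(path)
        loaded = TupleDataset.load_tsv(path)
        assert len(loaded) == len(ds)
        assert ({t.dedup_key() for t in loaded}
                == {t.dedup_key() for t in ds})
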