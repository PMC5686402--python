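"""Substructure pattern parsing, matching, and library filtering."""

import itertools
import random

import pytest

from isospace.chemgraph import from_smiles
from isospace.formula import parse_formula
from isospace.generator import enumerate_isomers
from isospace.patterns import (
    Badlist,
    count_embeddings,
    filter_library,
    match,
    parse_pattern,
)
from conftest import random_molecule, relabel_randomly


class TestParsing:
    def test_peroxide_two_atoms(self):
        p = parse_pattern("OO")
        assert p.n_atoms == 2
        assert p.bonds == ((0, 1, 1),)

    def test_carboxyl_like(self):
        p = parse_pattern("C(=O)O")
        assert p.n_atoms == 3
        assert sorted(p.bonds) == [(0, 1, 2), (0, 2, 1)]

    def test_wildcard_and_any_bond(self):
        p = parse_pattern("*~O")
        assert p.atoms[0][0] == "*"
        assert p.bonds[0][2] is None

    def test_min_hydrogen_bracket(self):
        p = parse_pattern("[OH]C")
        assert p.atoms[0] == ("O", 1)

    def test_ring_pattern(self):
        p = parse_pattern("*1~*~*~1")
        assert p.n_atoms == 3 and len(p.bonds) == 3

    @pytest.mark.parametrize("bad", ["[Zn]", "c1ccccc1", "O)O", "[O&H]", "C%"])
    def test_unsupported_tokens_rejected_with_position(self, bad):
        with pytest.raises(ValueError):
            parse_pattern(bad)


class TestMatching:
    def test_peroxide_in_dimethyl_peroxide(self):
        assert match(parse_pattern("OO"), from_smiles("COOC"))

    def test_peroxide_not_in_ethylene_glycol(self):
        assert not match(parse_pattern("OO"), from_smiles("OCCO"))

    def test_hydrogen_requirement(self):
        hydroxyl = parse_pattern("[OH]")
        assert match(hydroxyl, from_smiles("CO"))
        assert not match(hydroxyl, from_smiles("COC"))

    def test_implicit_h_satisfied_flag(self):
        # terminal-methyl pattern: C whose remaining valence is all H
        p = parse_pattern("CC", implicit_h_satisfied=True)
        assert match(p, from_smiles("CC"))
        assert not match(p, from_smiles("C1CC1"))  # ring carbons have 2 heavy neighbors

    def test_match_invariant_under_relabeling(self):
        rng = random.Random(11)
        patterns = [parse_pattern(t) for t in ["C~O", "O~O", "C=C", "[OH]", "*~N"]]
        for _ in range(25):
            mol = random_molecule(rng)
            shuffled = relabel_randomly(mol, rng)
            for p in patterns:
                assert match(p, mol) == match(p, shuffled)

    def test_embedding_counts_against_brute_force(self):
        """Embedding counts for small patterns vs an exhaustive
        injective-mapping enumeration over all C3HxO isomers."""
        patterns = [parse_pattern(t) for t in ["CC", "CO", "C=O", "CCO", "[OH]", "C~C~C"]]
        mols = []
        for h in range(0, 9, 2):
            f = {"C": 3, "O": 1}
            if h:
                f["H"] = h
            from isospace.formula import Formula, is_graphical

            ff = Formula(f)
            if is_graphical(ff):
                mols.extend(enumerate_isomers(ff))
        assert mols
        for p in patterns:
            for mol in mols:
                assert count_embeddings(p, mol) == _brute_embeddings(p, mol)

    def test_rdkit_smarts_agreement_on_plain_molecules(self):
        from rdkit import Chem

        cases = [
            ("OO", "[#8]-[#8]"),
            ("C=O", "[#6]=[#8]"),
            ("OCO", "[#8]-[#6]-[#8]"),
            ("C#N", "[#6]#[#7]"),
        ]
        smiles = ["OCCO", "COOC", "CC=O", "OCO", "C(O)(O)O", "CC#N", "OC1CO1"]
        for pat_text, smarts in cases:
            p = parse_pattern(pat_text)
            q = Chem.MolFromSmarts(smarts)
            for s in smiles:
                ours = match(p, from_smiles(s))
                theirs = Chem.MolFromSmiles(s).HasSubstructMatch(q)
                assert ours == theirs, (pat_text, s)


def _brute_embeddings(p, mol):
    n_p, n_m = p.n_atoms, mol.n_atoms
    adj = mol.adjacency_matrix()
    count = 0
    for perm in itertools.permutations(range(n_m), n_p):
        ok = True
        for k in range(n_p):
            el, min_h = p.atoms[k]
            if el != "*" and mol.atoms[perm[k]] != el:
                ok = False
                break
            if mol.implicit_hydrogens(perm[k]) < min_h:
                ok = False
                break
        if not ok:
            continue
        for a, b, order in p.bonds:
            o = adj[perm[a]][perm[b]]
            if o == 0 or (order is not None and o != order):
                ok = False
                break
        if ok:
            count += 1
    return count


class TestFilterLibrary:
    def test_empty_badlist_is_identity(self):
        mols = list(enumerate_isomers(parse_formula("C2H6O2")))
        out, report = filter_library(mols)
        assert len(out) == len(mols)
        assert report.total_removed_bad == 0

    def test_single_atom_badlist_empties_output(self):
        bad = Badlist("all")
        bad.add("anyC", parse_pattern("C"))
        bad.add("anyO", parse_pattern("O"))
        mols = list(enumerate_isomers(parse_formula("C2H6O")))
        out, report = filter_library(mols, bad)
        assert out == []
        assert report.total_removed_bad == len(mols)

    def test_peroxide_filter_on_c2h6o2(self):
        bad = Badlist("stab")
        bad.add("peroxide", parse_pattern("O~O"))
        mols = list(enumerate_isomers(parse_formula("C2H6O2")))
        out, report = filter_library(mols, bad)
        assert len(mols) == 5
        assert len(out) == 3  # glycol, methoxymethanol, 1,1-ethanediol
        assert report.removed_by["peroxide"] == 2
        for m in out:
            assert not match(parse_pattern("O~O"), m)

    def test_first_match_attribution_sums_to_total(self):
        bad = Badlist("two")
        bad.add("oxygen", parse_pattern("O"))
        bad.add("peroxide", parse_pattern("O~O"))  # never credited: O fires first
        mols = list(enumerate_isomers(parse_formula("C2H6O2")))
        out, report = filter_library(mols, bad)
        assert sum(report.removed_by.values()) == report.total_removed_bad == 5
        assert report.removed_by["peroxide"] == 0

    def test_output_set_independent_of_input_order(self):
        from isospace.chemgraph import canonical_form

        bad = Badlist("stab")
        bad.add("peroxide", parse_pattern("O~O"))
        mols = list(enumerate_isomers(parse_formula("C2H6O2")))
        out1, _ = filter_library(mols, bad)
        out2, _ = filter_library(list(reversed(mols)), bad)
        assert {canonical_form(m) for m in out1} == {canonical_form(m) for m in out2}

    def test_goodlist_requires_all_patterns(self):
        good = [parse_pattern("[OH]"), parse_pattern("O~O")]
        mols = list(enumerate_isomers(parse_formula("C2H6O2")))
        out, report = filter_library(mols, good=good)
        assert len(out) == 1  # only ethyl hydroperoxide has both O-O and O-H
        assert report.total_removed_good == 4
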