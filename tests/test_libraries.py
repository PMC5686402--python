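"""Library builders, substitution symmetry, diffs, persistence."""

import pytest

from isospace.chemgraph import canonical_form, from_smiles
from isospace.formula import FuzzyFormula, parse_formula
from isospace.generator import count_isomers, enumerate_isomers
from isospace.libraries import (
    ALPHA_AMINO_ACID_PATTERN,
    Library,
    NucleosideConstraints,
    build_amino_acid_library,
    build_nucleoside_library,
    coded_amino_acids,
    default_badlist,
    free_functional_groups,
    library_diff,
    substitute_heteroatom,
)
from isospace.patterns import match, parse_pattern


class TestAminoAcidLibrary:
    def test_glycine_is_in_the_smallest_library(self):
        lib = build_amino_acid_library(2, o_range=(2, 2), n_range=(1, 1))
        glycine = canonical_form(from_smiles("NCC(=O)O"))
        assert glycine in lib
        assert len(lib) >= 1

    def test_every_member_matches_the_scaffold(self):
        lib = build_amino_acid_library(3, o_range=(2, 3), n_range=(1, 1))
        scaffold = parse_pattern(ALPHA_AMINO_ACID_PATTERN)
        assert len(lib) > 5
        for mol in lib.iter_molecules():
            assert match(scaffold, mol)

    def test_monotone_in_carbon_count_and_duplicate_free(self):
        sizes = []
        for max_c in (2, 3):
            lib = build_amino_acid_library(max_c, o_range=(2, 3), n_range=(1, 1))
            assert len(set(lib.certificates())) == len(lib)
            sizes.append(len(lib))
        assert sizes[0] < sizes[1]

    def test_badlist_reduces_size(self):
        bad = default_badlist("amino_acid")
        free = build_amino_acid_library(3, o_range=(2, 3), n_range=(1, 1))
        culled = build_amino_acid_library(3, o_range=(2, 3), n_range=(1, 1), bad=bad)
        assert 0 < len(culled) < len(free)

    def test_cl_mode_contains_coded_members(self):
        lib = build_amino_acid_library(
            3, mode="CL", o_range=(2, 2), n_range=(1, 1), cl_sweep_carbons=2
        )
        alanine = canonical_form(from_smiles("CC(N)C(=O)O"))
        assert alanine in lib
        assert lib.provenance["mode"] == "CL"

    def test_max_carbons_below_glycine_rejected(self):
        with pytest.raises(ValueError, match="glycine"):
            build_amino_acid_library(1)

    def test_coded_twenty_all_match_scaffold(self):
        scaffold = parse_pattern(ALPHA_AMINO_ACID_PATTERN)
        lib = coded_amino_acids()
        assert len(lib) == 20
        for mol in lib.iter_molecules():
            assert match(scaffold, mol)


class TestNucleosideLibrary:
    def test_no_heteroatoms_means_no_functional_groups(self):
        lib = build_nucleoside_library("CH3B", NucleosideConstraints(2, None))
        assert len(lib) == 0

    def test_unconstrained_count_equals_raw_enumeration(self):
        f = parse_formula("C2H5OB")
        lib = build_nucleoside_library(f, NucleosideConstraints(0, None))
        assert len(lib) == count_isomers(f)

    def test_functional_group_counting_hand_cases(self):
        from isospace.fixtures import fixture_generator

        for smiles, expected in fixture_generator(0, "toy-nucleosides"):
            assert free_functional_groups(from_smiles(smiles)) == expected

    def test_placeholder_range_must_be_fixed_at_one(self):
        with pytest.raises(ValueError, match="placeholder"):
            build_nucleoside_library(
                FuzzyFormula({"C": (2, 2), "O": (1, 1), "B": (0, 1)})
            )

    def test_every_member_has_one_placeholder_and_enough_groups(self):
        lib = build_nucleoside_library(
            "C3H7O2B", NucleosideConstraints(2, default_badlist("nucleoside"))
        )
        assert len(lib) > 0
        for mol in lib.iter_molecules():
            assert sum(1 for el in mol.atoms if el == "B") == 1
            assert free_functional_groups(mol) >= 2


class TestSubstitution:
    def test_ethanol_gives_one_thiol(self):
        lib = Library("t")
        lib.add(from_smiles("CCO"))
        out = substitute_heteroatom(lib, "O", "S", 1)
        assert out.certificates() == [canonical_form(from_smiles("CCS"))]

    def test_symmetric_glycol_gives_one_monothio_product(self):
        lib = Library("t")
        lib.add(from_smiles("OCCO"))
        out = substitute_heteroatom(lib, "O", "S", 1)
        assert len(out) == 1  # the two O sites are symmetry-equivalent

    def test_library_level_equivalence_with_de_novo_generation(self):
        # O->S over all C2H6O2 isomers == de-novo enumeration of C2H6OS
        src = Library("c2h6o2")
        for mol in enumerate_isomers(parse_formula("C2H6O2")):
            src.add(mol)
        subst = substitute_heteroatom(src, "O", "S", 1)
        de_novo = {canonical_form(m) for m in enumerate_isomers(parse_formula("C2H6OS"))}
        assert set(subst.certificates()) == de_novo

    def test_double_substitution_equivalence(self):
        src = Library("c3h8o2")
        for mol in enumerate_isomers(parse_formula("C3H8O2")):
            src.add(mol)
        subst = substitute_heteroatom(src, "O", "S", 2)
        expected = {canonical_form(m) for m in enumerate_isomers(parse_formula("C3H8OS"))}
        expected |= {canonical_form(m) for m in enumerate_isomers(parse_formula("C3H8S2"))}
        assert set(subst.certificates()) == expected

    def test_valence_mismatch_rejected(self):
        with pytest.raises(ValueError, match="valence"):
            substitute_heteroatom(Library("t"), "O", "N", 1)


class TestDiffAndPersistence:
    def _small_lib(self, formula):
        lib = Library(formula)
        for mol in enumerate_isomers(parse_formula(formula)):
            lib.add(mol)
        return lib

    def test_diff_with_self(self):
        lib = self._small_lib("C2H6O")
        only_a, only_b, shared = library_diff(lib, lib)
        assert only_a == only_b == set()
        assert shared == set(lib.certificates())

    def test_diff_with_empty(self):
        lib = self._small_lib("C2H6O")
        empty = Library("empty")
        only_a, only_b, shared = library_diff(lib, empty)
        assert only_a == set(lib.certificates())
        assert only_b == shared == set()

    def test_diff_sizes_are_a_partition(self):
        a = self._small_lib("C3H6O")
        b = self._small_lib("C3H8O")
        only_a, only_b, shared = library_diff(a, b)
        assert len(only_a) + len(shared) == len(a)
        assert len(only_b) + len(shared) == len(b)

    def test_save_load_round_trip(self, tmp_path):
        lib = self._small_lib("C3H6O")
        lib.provenance = {"note": "round-trip"}
        path = tmp_path / "lib.smi"
        lib.save(path)
        back = Library.load(path)
        assert back.certificates() == lib.certificates()
        assert back.provenance == {"note": "round-trip"}
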