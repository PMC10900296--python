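"""Standardization protocol, file readers, and library overlap."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from chemspacekit import (
    MolStandardizer,
    RemovalVerdict,
    compound_overlap,
    library_from_smiles,
    read_library,
    standardize,
)
from chemspacekit.curation import pairwise_intersections
from tests.conftest import PLANTED_REGIONS


class TestStandardize:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("[Na+].CC(=O)[O-]", "CC(=O)O"),  # salt -> neutral parent acid
            ("CCO", "CCO"),  # identity case
            ("C(F)(F)F.CCCCCCCC", "CCCCCCCC"),  # largest fragment kept
            ("CC([O-])=O", "CC(=O)O"),  # carboxylate neutralized
        ],
    )
    def test_protocol_examples(self, smiles, expected):
        res = standardize(smiles)
        assert isinstance(res, Chem.Mol)
        assert Chem.MolToSmiles(res) == Chem.CanonSmiles(expected)

    @pytest.mark.parametrize("smiles", ["C[As](C)C", "CC[Hg]CC", "[Te](C)C"])
    def test_disallowed_elements_removed(self, smiles):
        res = standardize(smiles)
        assert isinstance(res, RemovalVerdict)
        assert "disallowed element" in res.reason

    def test_valence_error_removed(self):
        res = standardize("C(C)(C)(C)(C)C")  # pentavalent carbon
        assert isinstance(res, RemovalVerdict)
        assert "valence" in res.reason

    def test_unparseable_removed(self):
        assert isinstance(standardize("not-a-smiles(("), RemovalVerdict)

    def test_chirality_stripping(self):
        kept = standardize("C[C@H](N)C(=O)O", keep_chirality=True)
        stripped = standardize("C[C@H](N)C(=O)O", keep_chirality=False)
        assert "@" in Chem.MolToSmiles(kept)
        assert "@" not in Chem.MolToSmiles(stripped)

    @settings(max_examples=30, deadline=None)
    @given(
        st.sampled_from(
            [
                "CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "OC(=O)c1ccccc1O",
                "CN1CCC[C@H]1c1cccnc1", "[NH4+].[Cl-]", "CC(C)=CCO",
                "Oc1ccc2ccccc2c1", "NCC(=O)O", "C1CCOC1", "O=C1NC=CC(=O)N1",
            ]
        )
    )
    def test_idempotence(self, smiles):
        """Standardizing a standardized molecule changes nothing."""
        once = standardize(smiles)
        assert isinstance(once, Chem.Mol)
        twice = standardize(Chem.MolToSmiles(once))
        assert Chem.MolToSmiles(twice) == Chem.MolToSmiles(once)


class TestReaders:
    def test_smiles_list(self, tmp_path):
        path = tmp_path / "lib.smi"
        path.write_text("CCO mol1\nc1ccccc1 mol2\n")
        lib = read_library(path)
        assert len(lib) == 2
        assert set(lib.molecules) == {"mol1", "mol2"}

    def test_csv_with_malformed_row(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text("id,smiles\na,CCO\nb,xxxx((\nc,CCN\n")
        lib = read_library(path, smiles_column="smiles")
        assert len(lib) == 2
        removed = [e for e in lib.curation_log if e[1] == "removed"]
        assert len(removed) == 1 and removed[0][0] == "b"

    def test_csv_requires_smiles_column(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text("id,structure\na,CCO\n")
        with pytest.raises(ValueError, match="smiles_column"):
            read_library(path, format="csv", smiles_column="smiles")

    def test_sdf(self, tmp_path):
        block = (
            "ethanol\n     RDKit          2D\n\n"
            "  3  2  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0\n"
            "    1.0000    0.0000    0.0000 C   0  0\n"
            "    2.0000    0.0000    0.0000 O   0  0\n"
            "  1  2  1  0\n  2  3  1  0\nM  END\n$$$$\n"
        )
        path = tmp_path / "lib.sdf"
        path.write_text(block + block.replace("ethanol", "ethanol2"))
        lib = read_library(path)
        # two records parse; identical structures deduplicate to one
        assert len(lib) == 1
        assert "ethanol" in lib.molecules

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_library(tmp_path / "absent.smi")

    def test_zero_parseable_fatal(self, tmp_path):
        path = tmp_path / "junk.smi"
        path.write_text("((((\n)))(\n")
        with pytest.raises(ValueError, match="no parseable"):
            read_library(path)

    def test_deduplication_keeps_first_seen(self):
        lib = library_from_smiles([("x", "CCO"), ("y", "OCC"), ("z", "CCN")])
        assert set(lib.molecules) == {"x", "z"}
        assert any("duplicate of x" in r for _, _, r in lib.curation_log)

    def test_log_accounts_for_every_record(self):
        lib = library_from_smiles(["CCO", "OCC", "C[As](C)C", "CCN"], name="t")
        assert len(lib.curation_log) == 4
        assert sum(1 for _, a, _ in lib.curation_log if a == "kept") == len(lib)


class TestOverlap:
    def test_constructed_example(self):
        a = library_from_smiles(["CCO", "CCC"], name="A", standardize_input=False)
        b = library_from_smiles(["CCC", "CCN"], name="B", standardize_input=False)
        rep = compound_overlap([a, b])
        assert rep.regions[("A", "B")] == 1
        assert rep.unique("A") == 1 and rep.unique("B") == 1
        assert rep.shared_ids[("A", "B")] == ["CCC"]

    def test_identical_libraries(self):
        a = library_from_smiles(["CCO", "CCC"], name="A", standardize_input=False)
        b = library_from_smiles(["CCO", "CCC"], name="B", standardize_input=False)
        rep = compound_overlap([a, b])
        assert rep.intersection("A", "B") == 2
        assert rep.unique("A") == 0 and rep.unique("B") == 0

    def test_planted_triple_recovered(self, overlap_triple):
        rep = compound_overlap(list(overlap_triple))
        regions = {k: v for k, v in rep.regions.items() if v}
        assert regions == PLANTED_REGIONS
        assert rep.union_size == sum(PLANTED_REGIONS.values())

    def test_symmetry_under_permutation(self, overlap_triple):
        a, b, c = overlap_triple
        fwd = compound_overlap([a, b, c])
        rev = compound_overlap([c, a, b])
        assert fwd.regions == rev.regions

    def test_chirality_stripping_never_decreases_intersections(self):
        a = library_from_smiles(
            ["C[C@H](N)C(=O)O", "CCO"], name="A", keep_chirality=True
        )
        b = library_from_smiles(
            ["C[C@@H](N)C(=O)O", "CCO"], name="B", keep_chirality=True
        )
        with_stereo = compound_overlap([a, b], use_chirality=True)
        without = compound_overlap([a, b], use_chirality=False)
        for pair, count in pairwise_intersections(with_stereo).items():
            assert without.intersection(*pair) >= count
        # the enantiomer pair merges only under stereo-agnostic comparison
        assert without.intersection("A", "B") == 2
        assert with_stereo.intersection("A", "B") == 1
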