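"""Descriptor panel, CSP3, and the unique-subgraph complexity index."""

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem

from chemspacekit import (
    compute_descriptors,
    csp3,
    descriptor_table,
    subgraph_complexity,
    summarize,
)


def brute_force_fragment_count(smiles: str, max_atoms: int = 7) -> int:
    """Independent oracle: distinct connected induced subgraphs of 2..max atoms.

    Enumerates every atom subset with itertools, keeps the connected ones
    (checked by breadth-first search over the bond graph), and canonicalizes
    each fragment for distinctness.
    """
    mol = Chem.MolFromSmiles(smiles)
    adj = {a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()}
    fragments = set()
    for size in range(2, max_atoms + 1):
        for subset in itertools.combinations(range(mol.GetNumAtoms()), size):
            nodes = set(subset)
            seen, stack = {subset[0]}, [subset[0]]
            while stack:
                for nb in adj[stack.pop()] & nodes:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if seen == nodes:
                fragments.add(
                    Chem.MolFragmentToSmiles(
                        mol, atomsToUse=list(subset), canonical=True, isomericSmiles=False
                    )
                )
    return len(fragments)


class TestCsp3:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("CC", 1.0), ("c1ccccc1", 0.0), ("Cc1ccccc1", 1 / 7), ("C1CCCCC1", 1.0)],
    )
    def test_values(self, smiles, expected):
        assert csp3(Chem.MolFromSmiles(smiles)) == pytest.approx(expected)

    def test_zero_carbon_flagged(self):
        with pytest.warns(UserWarning, match="carbon-free"):
            assert csp3(Chem.MolFromSmiles("O=S=O")) == 0.0

    def test_invariant_under_stereo_and_canonicalization(self):
        chiral = Chem.MolFromSmiles("C[C@H](N)C(=O)O")
        flat = Chem.MolFromSmiles("CC(N)C(=O)O")
        assert csp3(chiral) == csp3(flat)


class TestPanel:
    def test_benzene(self):
        d = compute_descriptors(Chem.MolFromSmiles("c1ccccc1"))
        assert (d.hbd, d.hba, d.csp3) == (0, 0, 0.0)
        assert d.aromatic_rings_total == 1
        assert d.carbocyclic_aromatic_rings == 1
        assert d.rotatable_bonds == 0
        assert d.aromatic_atoms == 6

    def test_ethanol(self):
        d = compute_descriptors(Chem.MolFromSmiles("CCO"))
        assert (d.hbd, d.hba, d.heavy_atoms, d.o_count) == (1, 1, 3, 1)

    def test_glucose_open_chain(self):
        # C6H12O6; mass from standard atomic masses: 6*12.011 + 12*1.008 + 6*15.999
        d = compute_descriptors(Chem.MolFromSmiles("OCC(O)C(O)C(O)C(O)C=O"))
        assert d.hbd == 5
        assert d.hba == 6
        assert d.mw == pytest.approx(6 * 12.011 + 12 * 1.008 + 6 * 15.999, abs=0.05)
        assert d.mw == pytest.approx(180.16, abs=0.01)

    def test_ring_profile_classification(self):
        # pyridine: heterocyclic aromatic; decalin: two carbocyclic aliphatic,
        # one fused ring system
        p = compute_descriptors(Chem.MolFromSmiles("c1ccncc1"))
        assert p.heterocyclic_aromatic_rings == 1 and p.aromatic_rings_total == 1
        d = compute_descriptors(Chem.MolFromSmiles("C1CCC2CCCCC2C1"))
        assert d.carbocyclic_aliphatic_rings == 2
        assert d.ring_systems == 1

    def test_acid_base_counts(self):
        acid = compute_descriptors(Chem.MolFromSmiles("CC(=O)O"))
        base = compute_descriptors(Chem.MolFromSmiles("CCN"))
        assert acid.acidic_atoms > 0 and acid.basic_atoms == 0
        assert base.basic_atoms > 0 and base.acidic_atoms == 0

    def test_mw_additivity(self):
        """MW equals the sum of atomic masses including implicit hydrogens."""
        masses = {"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008}
        for smiles in ["CCO", "c1ccccc1", "NCC(=O)O", "CC(C)CC"]:
            mol = Chem.MolFromSmiles(smiles)
            total = sum(
                masses[a.GetSymbol()] + a.GetTotalNumHs() * masses["H"]
                for a in mol.GetAtoms()
            )
            d = compute_descriptors(mol)
            assert d.mw == pytest.approx(total, abs=0.01)


class TestSubgraphComplexity:
    def test_ethane_single_fragment(self):
        assert subgraph_complexity(Chem.MolFromSmiles("CC")) == 0.0

    @pytest.mark.parametrize(
        "smiles", ["CCCC", "CC(C)C", "c1ccccc1", "CCOC(=O)C", "CC(C)CO", "C1CCOC1"]
    )
    def test_matches_exhaustive_oracle(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        f = brute_force_fragment_count(smiles)
        expected = min(1.0, math.log2(f) / mol.GetNumHeavyAtoms()) if f > 1 else 0.0
        assert subgraph_complexity(mol) == pytest.approx(expected)

    def test_branched_at_least_as_many_fragments_as_linear(self):
        assert brute_force_fragment_count("CC(C)C") >= brute_force_fragment_count("CCCC")

    @pytest.mark.parametrize(
        "smiles", ["CCCCCCCCCC", "c1ccc2ccccc2c1", "CC(C)(C)C", "CN1CCC[CH]1c1cccnc1"]
    )
    def test_bounded(self, smiles):
        assert 0.0 <= subgraph_complexity(Chem.MolFromSmiles(smiles)) <= 1.0

    def test_single_heavy_atom_flagged(self):
        with pytest.warns(UserWarning):
            assert subgraph_complexity(Chem.MolFromSmiles("C")) == 0.0


class TestSummarize:
    def test_matches_brute_force_recomputation(self, scaffold_series_532):
        table = descriptor_table(scaffold_series_532, compute_complexity=False)
        summary = summarize(table)
        mw = table.records["mw"].to_numpy(dtype=float)
        assert summary.loc["mw", "mean"] == pytest.approx(np.mean(mw))
        assert summary.loc["mw", "median"] == pytest.approx(np.median(mw))
        assert summary.loc["mw", "sd"] == pytest.approx(np.std(mw, ddof=1))
        assert summary.loc["mw", "q1"] == pytest.approx(np.quantile(mw, 0.25))
        assert summary.loc["mw", "q3"] == pytest.approx(np.quantile(mw, 0.75))

    def test_tag_library_is_lipid_like(self, tag_library):
        """The triacylglycerol benchmark is acyclic, heavy, and sp3-rich."""
        table = descriptor_table(tag_library, compute_complexity=False)
        assert table.records["csp3"].mean() > 0.9
        assert table.records["mw"].mean() > 500
        assert (table.records["aromatic_rings_total"] == 0).all()

    def test_invariants_hold_on_benchmark(self, scaffold_series_532):
        table = descriptor_table(scaffold_series_532, compute_complexity=False)
        rec = table.records
        assert (
            rec["aromatic_rings_total"]
            == rec["carbocyclic_aromatic_rings"] + rec["heterocyclic_aromatic_rings"]
        ).all()
        assert rec["csp3"].between(0, 1).all()
        assert rec["fraction_rotatable"].between(0, 1).all()
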