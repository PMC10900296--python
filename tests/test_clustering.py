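"""Sphere-exclusion clustering against a brute-force oracle, MW filter, MCS."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from chemspacekit import (
    ButinaClustering,
    ClusterParams,
    butina_cluster,
    cluster_mcs,
    fingerprint_library,
    library_from_smiles,
    mw_filter,
)


def sphere_exclusion_oracle(sim, cutoff):
    """Reference implementation: plain-Python sphere exclusion.

    Repeatedly picks the unassigned item with the most unassigned neighbors
    (ties: lowest index), forms a cluster from it and its unassigned
    neighbors; everything left is a singleton.
    """
    n = len(sim)
    threshold = 1 - cutoff
    neighbors = {
        i: {j for j in range(n) if j != i and sim[i][j] >= threshold}
        for i in range(n)
    }
    unassigned = set(range(n))
    clusters = []
    while True:
        best, best_count = None, 0
        for i in sorted(unassigned):
            count = len(neighbors[i] & unassigned)
            if count > best_count:
                best, best_count = i, count
        if best is None:
            break
        members = {best} | (neighbors[best] & unassigned)
        clusters.append((best, sorted(members)))
        unassigned -= members
    return clusters, sorted(unassigned)


def assignment_from_estimator(est):
    clusters = []
    for k, cen in enumerate(est.centroid_indices_):
        clusters.append((cen, sorted(np.flatnonzero(est.labels_ == k).tolist())))
    singles = sorted(
        int(np.flatnonzero(est.labels_ == lab)[0])
        for lab in range(est.n_multi_clusters_, est.labels_.max() + 1)
    )
    return clusters, singles


class TestButina:
    def test_three_identical(self):
        sim = np.ones((3, 3))
        est = ButinaClustering(0.05, metric="precomputed").fit(sim)
        assert est.n_multi_clusters_ == 1
        assert len(set(est.labels_)) == 1

    def test_three_dissimilar_all_singletons(self):
        sim = np.eye(3)
        est = ButinaClustering(0.05, metric="precomputed").fit(sim)
        assert est.n_multi_clusters_ == 0
        assert len(set(est.labels_)) == 3

    def test_eight_item_hand_built_matrix_matches_oracle(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.0, 1.0, size=(8, 8))
        sim = (base + base.T) / 2
        np.fill_diagonal(sim, 1.0)
        cutoff = 0.4
        est = ButinaClustering(cutoff, metric="precomputed").fit(sim)
        assert assignment_from_estimator(est) == sphere_exclusion_oracle(sim, cutoff)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_random_toy_sets_match_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        base = rng.uniform(size=(n, n))
        sim = (base + base.T) / 2
        np.fill_diagonal(sim, 1.0)
        for cutoff in (0.2, 0.5):
            est = ButinaClustering(cutoff, metric="precomputed").fit(sim)
            assert assignment_from_estimator(est) == sphere_exclusion_oracle(sim, cutoff)

    def test_members_within_cutoff_of_centroid(self, tag_library):
        fps = fingerprint_library(tag_library, "circular4-1024")
        from chemspacekit.fingerprints import similarity_matrix

        params = ClusterParams(dissimilarity_cutoff=0.3)
        assignment = butina_cluster(fps, params)
        sim = similarity_matrix(fps)
        pos = {cid: k for k, cid in enumerate(fps.ids)}
        for centroid, members in assignment.clusters:
            for m in members:
                assert sim[pos[centroid], pos[m]] >= 1 - params.dissimilarity_cutoff


class TestMWFilter:
    def test_threshold(self):
        lib = library_from_smiles(
            [("small", "CCO"), ("big", "C" * 80)], name="t", standardize_input=False
        )
        out = mw_filter(lib, cap=1000.0)
        assert set(out.molecules) == {"small"}
        assert any("above cap" in r for _, _, r in out.curation_log)

    def test_infinite_cap_identity(self, tag_library):
        out = mw_filter(tag_library, cap=float("inf"))
        assert set(out.molecules) == set(tag_library.molecules)

    def test_tag_c18_pool_all_above_800(self):
        """Tri-esters of C18 acids all sit above 800 g/mol but below 1000."""
        from chemspacekit.synthetic import gen_triacylglycerols

        lib = gen_triacylglycerols([(18, ()), (18, (9,))], name="c18")
        mws = [Descriptors.MolWt(m) for m in lib.molecules.values()]
        assert all(mw > 800 for mw in mws)
        survivors = mw_filter(lib, cap=1000.0)
        assert len(survivors) == sum(1 for mw in mws if mw <= 1000.0)
        assert len(survivors) == len(lib)  # C18 TAGs are ~885-890 g/mol


class TestMCS:
    def test_propanol_propanamine_three_carbon_chain(self):
        mols = [Chem.MolFromSmiles(s) for s in ("CCCO", "CCCN")]
        res = cluster_mcs(mols)
        assert res.atom_count == 3
        assert res.n_supporting == 2
        patt = Chem.MolFromSmarts(res.substructure)
        assert all(m.HasSubstructMatch(patt) for m in mols)

    def test_identical_molecules_whole_molecule(self):
        mols = [Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")] * 2
        res = cluster_mcs(mols)
        assert res.atom_count == mols[0].GetNumHeavyAtoms()

    def test_below_min_atoms_returns_none(self):
        mols = [Chem.MolFromSmiles("CO"), Chem.MolFromSmiles("CN")]
        assert cluster_mcs(mols, ClusterParams(mcs_min_atoms=3)) is None

    def test_result_is_subgraph_of_every_supporting_member(self, tag_library):
        mols = list(tag_library.molecules.values())[:8]
        res = cluster_mcs(mols)
        patt = Chem.MolFromSmarts(res.substructure)
        assert res.n_supporting == len(mols)
        assert all(m.HasSubstructMatch(patt) for m in mols)

    def test_tag_cluster_recovers_glycerol_triester_core(self, tag_library):
        """Lipid clusters consolidate onto the glycerol tri-ester backbone."""
        mols = list(tag_library.molecules.values())[:10]
        res = cluster_mcs(mols)
        core = Chem.MolFromSmarts("[#6](-[#8]-[#6]=[#8])(-[#6]-[#8]-[#6]=[#8])-[#6]-[#8]-[#6]=[#8]")
        mcs_mol = Chem.MolFromSmarts(res.substructure)
        # the recovered MCS must itself contain the tri-ester core pattern
        from rdkit.Chem import rdFMCS

        probe = rdFMCS.FindMCS(
            [Chem.MolFromSmiles("C(COC(=O)C)(OC(=O)C)COC(=O)C"), mols[0]]
        )
        assert res.atom_count >= 11  # glycerol C3 + 3x (O-C=O) = 12 heavy atoms
        assert all(m.HasSubstructMatch(core) for m in mols)
        assert mcs_mol.GetNumAtoms() >= probe.numAtoms - 1

    def test_sequential_mcs_no_larger_than_any_pairwise(self, tag_library):
        mols = list(tag_library.molecules.values())[:5]
        seq = cluster_mcs(mols)
        from rdkit.Chem import rdFMCS

        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                pair = rdFMCS.FindMCS([mols[i], mols[j]])
                assert seq.atom_count <= pair.numAtoms

    def test_single_molecule_error(self):
        with pytest.raises(ValueError):
            cluster_mcs([Chem.MolFromSmiles("CCO")])
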