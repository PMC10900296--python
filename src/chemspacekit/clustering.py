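"""Sphere-exclusion (Taylor-Butina) clustering and per-cluster MCS.

Clustering operates on fingerprint similarity: two compounds are neighbors
when their Tanimoto/Jaccard similarity is at least ``1 - dissimilarity_cutoff``.
The default cutoff of 0.05 (membership at similarity >= 0.95) produces tight
clusters whose members converge onto a meaningful maximum common substructure
(MCS); compounds above 1000 g/mol are removed beforehand to bound the cost.

The multi-molecule MCS is computed by sequential reduction: the pairwise MCS
of the two largest members, then the MCS of the running pattern with each
further member in descending size order. The sequential result is therefore
at most as large as the pairwise MCS of any two members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFMCS
from sklearn.base import BaseEstimator, ClusterMixin

from .curation import CompoundLibrary
from .fingerprints import FingerprintSet, similarity_matrix


@dataclass
class ClusterParams:
    """Knobs of the clustering/MCS stage."""

    dissimilarity_cutoff: float = 0.05
    mw_cap: float = 1000.0
    representation: str = "circular4-1024"
    mcs_min_atoms: int = 3
    mcs_timeout: int = 10  # seconds per pairwise MCS call

    def __post_init__(self):
        if not 0.0 < self.dissimilarity_cutoff < 1.0:
            raise ValueError("dissimilarity_cutoff must be in (0, 1)")
        if self.mw_cap <= 0:
            raise ValueError("mw_cap must be positive")


@dataclass
class ClusterAssignment:
    """Sphere-exclusion clustering result."""

    clusters: list[tuple[str, list[str]]]  # (centroid ID, member IDs incl. centroid)
    singletons: list[str]
    params: ClusterParams

    @property
    def n_clustered(self) -> int:
        return sum(len(m) for _, m in self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster_id": k, "centroid": cen, "member_id": m}
            for k, (cen, members) in enumerate(self.clusters)
            for m in members
        ]
        rows += [
            {"cluster_id": -1, "centroid": s, "member_id": s} for s in self.singletons
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "centroid", "member_id"])


class ButinaClustering(BaseEstimator, ClusterMixin):
    """Sphere-exclusion clustering over a similarity matrix or fingerprints.

    At each step the unassigned item with the most unassigned neighbors (ties
    broken by ascending index) becomes a centroid and absorbs its unassigned
    neighbors; items left without any cluster are singletons.

    Parameters
    ----------
    dissimilarity_cutoff:
        Neighbor relation: similarity >= 1 - cutoff.
    metric:
        ``"precomputed"`` expects a square similarity matrix in ``fit``;
        anything else expects a :class:`FingerprintSet`.

    Attributes
    ----------
    labels_:
        Cluster label per item; singletons get their own labels after the
        multi-member clusters.
    centroid_indices_:
        Index of the centroid of each multi-member cluster.
    """

    def __init__(self, dissimilarity_cutoff: float = 0.05, metric: str = "fingerprints"):
        self.dissimilarity_cutoff = dissimilarity_cutoff
        self.metric = metric

    def fit(self, X, y=None):
        sim = np.asarray(X, dtype=float) if self.metric == "precomputed" else similarity_matrix(X)
        if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
            raise ValueError("similarity matrix must be square")
        n = sim.shape[0]
        threshold = 1.0 - self.dissimilarity_cutoff
        neighbor = sim >= threshold
        np.fill_diagonal(neighbor, False)

        labels = np.full(n, -1, dtype=int)
        centroids: list[int] = []
        unassigned = np.ones(n, dtype=bool)
        label = 0
        while True:
            counts = (neighbor & unassigned[None, :]).sum(axis=1)
            counts[~unassigned] = -1
            best = int(np.argmax(counts))  # argmax takes the lowest index on ties
            if counts[best] <= 0:
                break
            members = np.flatnonzero(neighbor[best] & unassigned)
            labels[best] = label
            labels[members] = label
            unassigned[best] = False
            unassigned[members] = False
            centroids.append(best)
            label += 1
        # leftovers become singleton clusters in ascending index order
        singleton_start = label
        for idx in np.flatnonzero(unassigned):
            labels[idx] = label
            label += 1
        self.labels_ = labels
        self.centroid_indices_ = centroids
        self.n_multi_clusters_ = singleton_start
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def butina_cluster(fps: FingerprintSet, params: ClusterParams | None = None) -> ClusterAssignment:
    """Cluster a fingerprint set; returns ID-keyed clusters and singletons."""
    params = params or ClusterParams()
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    est = ButinaClustering(dissimilarity_cutoff=params.dissimilarity_cutoff).fit(fps)
    clusters = []
    for k, cen in enumerate(est.centroid_indices_):
        members = [fps.ids[i] for i in np.flatnonzero(est.labels_ == k)]
        clusters.append((fps.ids[cen], members))
    singleton_labels = range(est.n_multi_clusters_, est.labels_.max() + 1)
    singletons = [
        fps.ids[int(np.flatnonzero(est.labels_ == lab)[0])] for lab in singleton_labels
    ]
    return ClusterAssignment(clusters=clusters, singletons=singletons, params=params)


def mw_filter(library: CompoundLibrary, cap: float = 1000.0) -> CompoundLibrary:
    """Retain compounds with molecular weight <= cap; removals are logged."""
    out = CompoundLibrary(
        name=library.name,
        chirality_kept=library.chirality_kept,
        curation_log=list(library.curation_log),
    )
    for cid, mol in library.molecules.items():
        mw = Descriptors.MolWt(mol)
        if mw <= cap:
            out.molecules[cid] = mol
        else:
            out.curation_log.append((cid, "removed", f"MW {mw:.1f} above cap {cap:g}"))
    return out


@dataclass
class MCSResult:
    """Maximum common substructure consolidated over a cluster."""

    cluster_id: int
    substructure: str  # SMARTS
    atom_count: int
    bond_count: int
    n_supporting: int
    timed_out: bool = False


def _pairwise_mcs(a: Chem.Mol, b: Chem.Mol, timeout: int) -> rdFMCS.MCSResult:
    params = rdFMCS.MCSParameters()
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareOrder
    params.Timeout = timeout
    return rdFMCS.FindMCS([a, b], params)


def cluster_mcs(
    molecules: list[Chem.Mol],
    params: ClusterParams | None = None,
    cluster_id: int = 0,
) -> MCSResult | None:
    """Sequential-reduction MCS over a cluster's members.

    Members are processed in descending heavy-atom order; the running pattern
    is re-materialized as a real submolecule of the first member after each
    reduction, so atom/bond chemistry stays concrete. Returns None when the
    common substructure falls below ``mcs_min_atoms``.
    """
    params = params or ClusterParams()
    if len(molecules) < 2:
        raise ValueError("MCS needs at least two molecules")
    ordered = sorted(molecules, key=lambda m: -m.GetNumHeavyAtoms())
    pattern = ordered[0]
    timed_out = False
    for nxt in ordered[1:]:
        res = _pairwise_mcs(pattern, nxt, params.mcs_timeout)
        timed_out = timed_out or res.canceled
        if res.numAtoms < params.mcs_min_atoms or not res.smartsString:
            return None
        query = Chem.MolFromSmarts(res.smartsString)
        match = pattern.GetSubstructMatch(query)
        if not match:
            return None
        bonds = [
            pattern.GetBondBetweenAtoms(match[b.GetBeginAtomIdx()], match[b.GetEndAtomIdx()]).GetIdx()
            for b in query.GetBonds()
        ]
        pattern = Chem.PathToSubmol(pattern, bonds) if bonds else None
        if pattern is None:
            return None
    smarts = Chem.MolToSmarts(pattern)
    query = Chem.MolFromSmarts(smarts)
    n_support = sum(1 for m in molecules if m.HasSubstructMatch(query))
    return MCSResult(
        cluster_id=cluster_id,
        substructure=smarts,
        atom_count=pattern.GetNumAtoms(),
        bond_count=pattern.GetNumBonds(),
        n_supporting=n_support,
        timed_out=timed_out,
    )


def cluster_and_consolidate(
    library: CompoundLibrary,
    fps: FingerprintSet,
    params: ClusterParams | None = None,
) -> tuple[ClusterAssignment, list[MCSResult]]:
    """Butina clustering followed by per-cluster MCS extraction."""
    params = params or ClusterParams()
    assignment = butina_cluster(fps, params)
    results = []
    for k, (_, members) in enumerate(assignment.clusters):
        mols = [library.molecules[m] for m in members if m in library.molecules]
        if len(mols) < 2:
            continue
        res = cluster_mcs(mols, params, cluster_id=k)
        if res is not None:
            results.append(res)
    return assignment, results


def mcs_table(results: list[MCSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "mcs_smarts": r.substructure,
                "atom_count": r.atom_count,
                "bond_count": r.bond_count,
                "n_supporting": r.n_supporting,
            }
            for r in results
        ],
        columns=["cluster_id", "mcs_smarts", "atom_count", "bond_count", "n_supporting"],
    )
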