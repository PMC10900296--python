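"""Physicochemical/constitutional descriptor panel and structural complexity.

Two complexity measures are provided: CSP3 (fraction of sp3-hybridized
carbons, a proxy for three-dimensionality) and a unique-subgraph complexity
index — the number of distinct connected heavy-atom fragments up to a size
cap, log-scaled and normalized by molecular size. The latter is an
operationalized index in the spirit of fragment-count complexity measures;
no bit-level agreement with any desktop package is implied.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

from .curation import CompoundLibrary

_HALOGENS = {9, 17, 35, 53}


def _load_protonation_smarts() -> dict[str, list[Chem.Mol]]:
    raw = json.loads(
        resources.files("chemspacekit.data")
        .joinpath("protonation_smarts.json")
        .read_text()
    )
    return {
        key: [Chem.MolFromSmarts(s) for s in raw[key]] for key in ("acidic", "basic")
    }


_PROTONATION = None


def _protonation_patterns():
    global _PROTONATION
    if _PROTONATION is None:
        _PROTONATION = _load_protonation_smarts()
    return _PROTONATION


@dataclass
class DescriptorRecord:
    """One molecule's descriptor panel."""

    hbd: int
    hba: int
    logp: float
    tpsa: float
    mw: float
    csp3: float
    heavy_atoms: int
    ring_systems: int
    heteroatoms: int
    rotatable_bonds: int
    fraction_rotatable: float
    carbocyclic_aliphatic_rings: int
    heterocyclic_aliphatic_rings: int
    carbocyclic_aromatic_rings: int
    heterocyclic_aromatic_rings: int
    aromatic_rings_total: int
    acidic_atoms: int
    basic_atoms: int
    aromatic_atoms: int
    n_count: int
    o_count: int
    halogen_count: int
    chiral_centers: int
    formal_charge: int
    complexity_index: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


DESCRIPTOR_NAMES = [f.name for f in dc_fields(DescriptorRecord)]


def csp3(mol: Chem.Mol) -> float:
    """Fraction of carbon atoms that are sp3-hybridized.

    Defined as (# sp3 carbons) / (# carbons); a molecule without carbon is
    flagged with a warning and scored 0.
    """
    carbons = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
    if not carbons:
        warnings.warn("csp3 undefined for a carbon-free molecule; reporting 0")
        return 0.0
    n_sp3 = sum(
        1 for a in carbons if a.GetHybridization() == Chem.HybridizationType.SP3
    )
    return n_sp3 / len(carbons)


def _connected_subgraph_atom_sets(mol: Chem.Mol, max_atoms: int) -> set[frozenset]:
    """All connected induced heavy-atom subgraphs with 2..max_atoms atoms."""
    neighbors = {
        a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()
    }
    current: set[frozenset] = {frozenset({i}) for i in neighbors}
    found: set[frozenset] = set()
    for _size in range(2, max_atoms + 1):
        grown: set[frozenset] = set()
        for s in current:
            frontier = set().union(*(neighbors[i] for i in s)) - s
            for nb in frontier:
                grown.add(s | {nb})
        found |= grown
        current = grown
        if not current:
            break
    return found


def subgraph_complexity(mol: Chem.Mol, max_fragment_atoms: int = 7) -> float:
    """Unique-fragment complexity index in [0, 1].

    Enumerates every connected induced subgraph of the heavy-atom graph with
    2..``max_fragment_atoms`` atoms, canonicalizes each fragment (element and
    bond-order labels), counts the distinct fragments F, and returns
    ``min(1, log2(F) / heavy_atoms)``. Symmetric molecules built from few
    distinct fragments (long saturated chains) score low; scaffold-rich
    molecules score high.
    """
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < 2:
        warnings.warn("complexity index undefined below 2 heavy atoms; reporting 0")
        return 0.0
    fragments = set()
    for atom_set in _connected_subgraph_atom_sets(mol, max_fragment_atoms):
        fragments.add(
            Chem.MolFragmentToSmiles(
                mol, atomsToUse=sorted(atom_set), canonical=True, isomericSmiles=False
            )
        )
    n_distinct = max(len(fragments), 1)
    return min(1.0, math.log2(n_distinct) / n_heavy) if n_distinct > 1 else 0.0


def _ring_profile(mol: Chem.Mol) -> tuple[int, int, int, int, int]:
    """(carbo-aliphatic, hetero-aliphatic, carbo-aromatic, hetero-aromatic, n_ring_systems)."""
    ri = mol.GetRingInfo()
    atom_rings = ri.AtomRings()
    bond_rings = ri.BondRings()
    counts = [0, 0, 0, 0]
    for atoms, bonds in zip(atom_rings, bond_rings):
        aromatic = all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bonds)
        carbocyclic = all(mol.GetAtomWithIdx(a).GetAtomicNum() == 6 for a in atoms)
        idx = (2 if aromatic else 0) + (0 if carbocyclic else 1)
        counts[idx] += 1
    # ring systems: connected components of the "rings sharing an atom" graph
    n_sys = 0
    remaining = [set(r) for r in atom_rings]
    while remaining:
        sys_atoms = remaining.pop()
        merged = True
        while merged:
            merged = False
            for other in list(remaining):
                if sys_atoms & other:
                    sys_atoms |= other
                    remaining.remove(other)
                    merged = True
        n_sys += 1
    return counts[0], counts[1], counts[2], counts[3], n_sys


def _count_pattern_atoms(mol: Chem.Mol, patterns: Sequence[Chem.Mol]) -> int:
    matched: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            matched.update(match)
    return len(matched)


def compute_descriptors(
    mol: Chem.Mol, max_fragment_atoms: int = 7, complexity: bool = True
) -> DescriptorRecord:
    """Full descriptor panel for one standardized molecule."""
    patterns = _protonation_patterns()
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy_bonds = sum(
        1
        for b in mol.GetBonds()
        if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
    )
    carbo_ali, hetero_ali, carbo_aro, hetero_aro, n_sys = _ring_profile(mol)
    chiral = len(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )
    return DescriptorRecord(
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        logp=Crippen.MolLogP(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        mw=Descriptors.MolWt(mol),
        csp3=csp3(mol) if any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()) else 0.0,
        heavy_atoms=mol.GetNumHeavyAtoms(),
        ring_systems=n_sys,
        heteroatoms=rdMolDescriptors.CalcNumHeteroatoms(mol),
        rotatable_bonds=rb,
        fraction_rotatable=rb / heavy_bonds if heavy_bonds else 0.0,
        carbocyclic_aliphatic_rings=carbo_ali,
        heterocyclic_aliphatic_rings=hetero_ali,
        carbocyclic_aromatic_rings=carbo_aro,
        heterocyclic_aromatic_rings=hetero_aro,
        aromatic_rings_total=carbo_aro + hetero_aro,
        acidic_atoms=_count_pattern_atoms(mol, patterns["acidic"]),
        basic_atoms=_count_pattern_atoms(mol, patterns["basic"]),
        aromatic_atoms=sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        n_count=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7),
        o_count=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8),
        halogen_count=sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() in _HALOGENS
        ),
        chiral_centers=chiral,
        formal_charge=Chem.GetFormalCharge(mol),
        complexity_index=(
            subgraph_complexity(mol, max_fragment_atoms)
            if complexity and mol.GetNumHeavyAtoms() >= 2
            else 0.0
        ),
    )


class DescriptorCalculator(BaseEstimator, TransformerMixin):
    """Transformer: molecules/SMILES -> descriptor panel DataFrame.

    Parameters
    ----------
    complexity_max_atoms:
        Size cap (heavy atoms) for the unique-subgraph complexity enumeration.
    compute_complexity:
        The complexity index is the only super-linear descriptor; it can be
        switched off for very large molecules or libraries.
    """

    def __init__(self, complexity_max_atoms: int = 7, compute_complexity: bool = True):
        self.complexity_max_atoms = complexity_max_atoms
        self.compute_complexity = compute_complexity

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Sequence[str | Chem.Mol]) -> pd.DataFrame:
        rows, index = [], []
        for i, item in enumerate(X):
            mol = Chem.MolFromSmiles(item) if isinstance(item, str) else item
            if mol is None:
                raise ValueError(f"unparseable SMILES at position {i}: {item!r}")
            rows.append(
                compute_descriptors(
                    mol, self.complexity_max_atoms, self.compute_complexity
                ).as_dict()
            )
            index.append(i)
        return pd.DataFrame(rows, index=index)


@dataclass
class DescriptorTable:
    """Per-compound descriptor records for one library, with summary stats."""

    library_name: str
    records: pd.DataFrame  # index: compound ID, columns: DESCRIPTOR_NAMES

    def summary(self) -> pd.DataFrame:
        return summarize(self)

    def write_csv(self, path) -> None:
        self.records.to_csv(path, index_label="id")

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "library": self.library_name,
                    "n": int(len(self.records)),
                    "summary": self.summary().to_dict(orient="index"),
                },
                fh,
                indent=2,
            )


def descriptor_table(
    library: CompoundLibrary,
    complexity_max_atoms: int = 7,
    compute_complexity: bool = True,
) -> DescriptorTable:
    """Descriptor panel for every compound in a curated library."""
    if len(library) == 0:
        raise ValueError("empty library")
    calc = DescriptorCalculator(complexity_max_atoms, compute_complexity)
    frame = calc.transform(list(library.molecules.values()))
    frame.index = list(library.molecules.keys())
    return DescriptorTable(library_name=library.name, records=frame)


def summarize(table: DescriptorTable) -> pd.DataFrame:
    """Mean, median, sample SD, and quartiles per descriptor.

    A single-record table reports SD 0 (flagged by n=1 in the output).
    """
    rec = table.records
    if len(rec) == 0:
        raise ValueError("empty descriptor table")
    num = rec.astype(float)
    out = pd.DataFrame(
        {
            "mean": num.mean(),
            "median": num.median(),
            "sd": num.std(ddof=1).fillna(0.0) if len(num) > 1 else 0.0,
            "q1": num.quantile(0.25),
            "q3": num.quantile(0.75),
        }
    )
    out["n"] = len(num)
    return out
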