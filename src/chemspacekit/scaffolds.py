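"""Bemis-Murcko scaffold extraction and scaffold-diversity metrics.

A scaffold is the union of a molecule's ring systems and the linkers that
connect them, with all acyclic side chains removed. Diversity over scaffolds
is quantified two ways: the cyclic system retrieval (CSR) curve — cumulative
fraction of cyclic compounds recovered as scaffolds are consumed in
descending frequency order — and the scaled Shannon entropy (SSE) of the
most populated scaffolds, normalized to [0, 1].

Acyclic compounds form their own bucket and are excluded from CSR and SSE;
an "empty scaffold" bucket would otherwise swamp the curve for lipid-rich
libraries. The acyclic fraction is reported separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import CompoundLibrary, OverlapReport, _overlap_of_sets

#: Marker returned for molecules without any ring.
ACYCLIC = "<acyclic>"


def bemis_murcko(mol: Chem.Mol | str, use_chirality: bool = False) -> str:
    """Canonical Bemis-Murcko scaffold SMILES, or the acyclic marker.

    Scaffolds are compared without stereochemistry by default, consistent
    with cross-library overlap handling.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("unparseable SMILES")
    if mol.GetRingInfo().NumRings() == 0:
        return ACYCLIC
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC
    return Chem.MolToSmiles(scaffold, isomericSmiles=use_chirality)


@dataclass
class ScaffoldIndex:
    """Partition of a library into scaffold buckets plus an acyclic bucket."""

    library_name: str
    scaffold_to_ids: dict[str, list[str]] = field(default_factory=dict)
    acyclic_ids: list[str] = field(default_factory=list)

    @property
    def ordering(self) -> list[str]:
        """Scaffolds by descending member count; ties broken lexicographically."""
        return sorted(self.scaffold_to_ids, key=lambda s: (-len(self.scaffold_to_ids[s]), s))

    @property
    def counts(self) -> list[int]:
        return [len(self.scaffold_to_ids[s]) for s in self.ordering]

    @property
    def n_compounds(self) -> int:
        return sum(len(v) for v in self.scaffold_to_ids.values()) + len(self.acyclic_ids)

    @property
    def n_cyclic(self) -> int:
        return self.n_compounds - len(self.acyclic_ids)

    @property
    def acyclic_fraction(self) -> float:
        return len(self.acyclic_ids) / self.n_compounds if self.n_compounds else 0.0

    def to_frame(self) -> pd.DataFrame:
        total = self.n_compounds
        rows = [
            {
                "scaffold_smiles": s,
                "count": len(self.scaffold_to_ids[s]),
                "fraction": len(self.scaffold_to_ids[s]) / total,
            }
            for s in self.ordering
        ]
        return pd.DataFrame(rows, columns=["scaffold_smiles", "count", "fraction"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def scaffold_index(library: CompoundLibrary) -> ScaffoldIndex:
    """Classify every library compound under its Bemis-Murcko scaffold."""
    if len(library) == 0:
        raise ValueError("empty library")
    index = ScaffoldIndex(library_name=library.name)
    for cid, mol in library.molecules.items():
        scaf = bemis_murcko(mol)
        if scaf == ACYCLIC:
            index.acyclic_ids.append(cid)
        else:
            index.scaffold_to_ids.setdefault(scaf, []).append(cid)
    return index


@dataclass
class CSRCurve:
    """Cyclic system retrieval curve: scaffold fraction vs compound fraction."""

    points: list[tuple[float, float]]
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["fraction_of_scaffolds", "fraction_of_compounds"]
        )


def csr_curve(index: ScaffoldIndex) -> CSRCurve:
    """CSR curve over the cyclic members of a scaffold index.

    Scaffolds are consumed in descending frequency; point k is
    (k/S, cumulative members / total cyclic compounds). Acyclic compounds are
    excluded from both axes. The AUC is computed by the trapezoid rule with
    the origin (0, 0) prepended; it ranges from 0.5 (every compound its own
    scaffold) toward 1 as frequencies skew. A single-scaffold library is the
    maximally non-diverse degenerate case and reports AUC 1 by convention
    (the curve hugs the top of the unit square in the skew limit).
    """
    counts = index.counts
    if not counts:
        raise ValueError(
            "CSR curve undefined for an acyclic-only library (no scaffolds)"
        )
    if len(counts) == 1:
        return CSRCurve(points=[(1.0, 1.0)], auc=1.0)
    n_scaffolds = len(counts)
    total = sum(counts)
    points, cum = [], 0
    for k, c in enumerate(counts, start=1):
        cum += c
        points.append((k / n_scaffolds, cum / total))
    xs = [0.0] + [p[0] for p in points]
    ys = [0.0] + [p[1] for p in points]
    auc = sum(
        (xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2 for i in range(len(xs) - 1)
    )
    return CSRCurve(points=points, auc=auc)


@dataclass
class EntropyResult:
    """Scaled Shannon entropy over the top-N scaffold counts."""

    top_n: int
    sse: float
    counts_used: list[int]


def scaled_shannon_entropy(
    index: ScaffoldIndex | Sequence[int], top_n: int = 15
) -> EntropyResult:
    """Shannon entropy of the top-N scaffold frequencies, scaled to [0, 1].

    With counts c_i over the N most frequent scaffolds and p_i = c_i / sum c,
    SSE = -sum p_i log2 p_i / log2 N. SSE is 0 when one scaffold holds all
    mass and 1 when the top-N counts are all equal. If fewer than ``top_n``
    scaffolds exist, all are used and the effective N is recorded.
    """
    counts = sorted(
        index.counts if isinstance(index, ScaffoldIndex) else list(index), reverse=True
    )
    if len(counts) < 2:
        raise ValueError("scaled Shannon entropy needs at least 2 scaffolds")
    used = counts[:top_n]
    n_eff = len(used)
    total = sum(used)
    entropy = -sum((c / total) * math.log2(c / total) for c in used if c > 0)
    return EntropyResult(top_n=n_eff, sse=entropy / math.log2(n_eff), counts_used=used)


def scaffold_overlap(indices: Sequence[ScaffoldIndex]) -> OverlapReport:
    """Venn regions over canonical scaffolds (acyclic buckets excluded)."""
    if len(indices) < 2:
        raise ValueError("need at least two scaffold indices")
    names = [ix.library_name for ix in indices]
    if len(set(names)) != len(names):
        raise ValueError("library names must be unique")
    return _overlap_of_sets(
        {ix.library_name: set(ix.scaffold_to_ids) for ix in indices}
    )


def write_entropy_json(result: EntropyResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"top_n": result.top_n, "sse": result.sse, "counts_used": result.counts_used},
            fh,
            indent=2,
        )


def plot_csr_curves(curves: dict[str, CSRCurve], path=None):
    """Overlay CSR curves of several libraries on one axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        xs = [0.0] + [p[0] for p in curve.points]
        ys = [0.0] + [p[1] for p in curve.points]
        ax.plot(xs, ys, label=f"{name} (AUC {curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("fraction of cyclic systems")
    ax.set_ylabel("fraction of compounds")
    ax.legend()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
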