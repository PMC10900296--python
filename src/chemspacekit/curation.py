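"""Library loading, standardization, and inter-library overlap.

The curation protocol mirrors common practice for comparing heterogeneous
compound collections: disallowed-element filter, valence check, largest
organic fragment, neutralization/reionization, canonical tautomer, optional
stereochemistry stripping, and canonical-SMILES deduplication.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from sklearn.base import BaseEstimator, TransformerMixin

RDLogger.DisableLog("rdApp.*")

#: Atomic numbers allowed in a curated library (H, B, C, N, O, F, Si, P, S,
#: Cl, Se, Br, I). Anything else triggers a removal verdict.
ALLOWED_ELEMENTS = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53})


@dataclass
class RemovalVerdict:
    """Outcome for a structure the protocol rejects."""

    source_id: str
    reason: str

    def __bool__(self) -> bool:  # a verdict is falsy: "no molecule survived"
        return False


@dataclass
class CompoundLibrary:
    """Named, ID-keyed set of standardized molecules with curation provenance.

    ``molecules`` maps a stable source ID to an RDKit molecule whose canonical
    SMILES is unique within the library after deduplication. ``curation_log``
    records one ``(source_id, action, reason)`` entry per input record.
    """

    name: str
    molecules: dict[str, Chem.Mol] = field(default_factory=dict)
    chirality_kept: bool = True
    curation_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules.items())

    def smiles(self) -> dict[str, str]:
        """ID -> canonical SMILES for every member."""
        return {i: Chem.MolToSmiles(m) for i, m in self.molecules.items()}

    def canonical_set(self, use_chirality: bool | None = None) -> set[str]:
        """Set of canonical SMILES, optionally with stereo stripped."""
        if use_chirality is None:
            use_chirality = self.chirality_kept
        out = set()
        for mol in self.molecules.values():
            out.add(Chem.MolToSmiles(mol, isomericSmiles=use_chirality))
        return out

    def write_csv(self, path: str | Path) -> None:
        """Curated library as CSV: id, canonical_smiles plus a log of actions."""
        logged = {sid: (action, reason) for sid, action, reason in self.curation_log}
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "canonical_smiles", "action"])
            for sid, mol in self.molecules.items():
                action = logged.get(sid, ("kept", ""))[0]
                writer.writerow([sid, Chem.MolToSmiles(mol), action])

    def write_curation_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "library": self.name,
                    "size": len(self),
                    "chirality_kept": self.chirality_kept,
                    "log": [
                        {"source_id": s, "action": a, "reason": r}
                        for s, a, r in self.curation_log
                    ],
                },
                fh,
                indent=2,
            )


class MolStandardizer(BaseEstimator, TransformerMixin):
    """Deterministic structure standardizer.

    Pipeline order: element filter -> valence check -> largest-fragment
    selection -> uncharge/reionize -> canonical tautomer -> optional stereo
    stripping -> canonicalization. Same input always yields the same output,
    and the map is idempotent.

    Parameters
    ----------
    keep_chirality:
        If False, stereocenters and double-bond stereo are erased before
        canonicalization. Libraries compared for overlap must agree on this.
    canonical_tautomer:
        Apply score-based canonical tautomer selection (ties resolved inside
        the toolkit deterministically). Disable only for speed on huge inputs.
    """

    def __init__(self, keep_chirality: bool = True, canonical_tautomer: bool = True):
        self.keep_chirality = keep_chirality
        self.canonical_tautomer = canonical_tautomer

    # lazily built RDKit helpers, keyed by stereo handling (not fitted state)
    _helpers: dict = {}

    def _get_helpers(self):
        key = bool(self.keep_chirality)
        if key not in MolStandardizer._helpers:
            tautomer = rdMolStandardize.TautomerEnumerator()
            if key:  # keep stereo through tautomer canonicalization
                tautomer.SetRemoveSp3Stereo(False)
                tautomer.SetRemoveBondStereo(False)
            MolStandardizer._helpers[key] = {
                "fragment": rdMolStandardize.LargestFragmentChooser(preferOrganic=True),
                "uncharger": rdMolStandardize.Uncharger(),
                "reionizer": rdMolStandardize.Reionizer(),
                "tautomer": tautomer,
            }
        return MolStandardizer._helpers[key]

    def fit(self, X=None, y=None):  # stateless transformer
        return self

    def transform(self, X: Sequence[str | Chem.Mol]) -> list[str | None]:
        """Standardize a sequence of SMILES/mols; None marks removed records."""
        out = []
        for item in X:
            res = self.standardize(item)
            out.append(Chem.MolToSmiles(res) if isinstance(res, Chem.Mol) else None)
        return out

    def standardize(
        self, mol: str | Chem.Mol, source_id: str = ""
    ) -> Chem.Mol | RemovalVerdict:
        """Apply the full protocol to one structure.

        Returns the standardized molecule, or a :class:`RemovalVerdict`
        carrying the reason when the structure fails the protocol.
        """
        if isinstance(mol, str):
            mol = Chem.MolFromSmiles(mol, sanitize=False)
        if mol is None:
            return RemovalVerdict(source_id, "unparseable structure")

        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # valence or aromaticity failure
            return RemovalVerdict(source_id, f"valence error: {exc}")

        helpers = self._get_helpers()
        try:
            mol = helpers["fragment"].choose(mol)
        except Exception as exc:
            return RemovalVerdict(source_id, f"standardization failure: {exc}")

        # element filter applies to the retained component, so simple
        # counterions (Na+, Cl-) never disqualify an organic parent
        bad = sorted(
            {
                a.GetSymbol()
                for a in mol.GetAtoms()
                if a.GetAtomicNum() not in ALLOWED_ELEMENTS
            }
        )
        if bad:
            return RemovalVerdict(source_id, f"disallowed element: {', '.join(bad)}")

        try:
            mol = helpers["uncharger"].uncharge(mol)
            mol = helpers["reionizer"].reionize(mol)
            if self.canonical_tautomer:
                mol = helpers["tautomer"].Canonicalize(mol)
        except Exception as exc:
            return RemovalVerdict(source_id, f"standardization failure: {exc}")

        if not self.keep_chirality:
            Chem.RemoveStereochemistry(mol)

        # round-trip through canonical SMILES so the output is in canonical form
        out = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
        if out is None:
            return RemovalVerdict(source_id, "canonicalization failure")
        return out


def standardize(
    mol: str | Chem.Mol, keep_chirality: bool = True
) -> Chem.Mol | RemovalVerdict:
    """Standardize a single structure (functional wrapper)."""
    return MolStandardizer(keep_chirality=keep_chirality).standardize(mol)


# ---------------------------------------------------------------------------
# readers


def _iter_records(
    path: Path, fmt: str, smiles_column: str | None
) -> Iterable[tuple[str, Chem.Mol | None]]:
    if fmt == "smiles-list":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                sid = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{i}"
                yield sid, Chem.MolFromSmiles(parts[0], sanitize=False)
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if smiles_column is None or smiles_column not in (reader.fieldnames or []):
                raise ValueError(
                    f"csv format requires smiles_column present in header; "
                    f"got {smiles_column!r}, header {reader.fieldnames}"
                )
            id_col = next(
                (c for c in (reader.fieldnames or []) if c.lower() in ("id", "name")),
                None,
            )
            for i, row in enumerate(reader):
                sid = row[id_col] if id_col else f"{path.stem}_{i}"
                yield sid, Chem.MolFromSmiles(row[smiles_column], sanitize=False)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                yield f"{path.stem}_{i}", None
                continue
            sid = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
                else f"{path.stem}_{i}"
            )
            yield sid, mol
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_library(
    path: str | Path,
    format: str | None = None,
    smiles_column: str | None = None,
    name: str | None = None,
    keep_chirality: bool = True,
    standardizer: MolStandardizer | None = None,
) -> CompoundLibrary:
    """Load and curate a compound library from disk.

    ``format`` is one of ``smiles-list``, ``csv``, ``sdf``; if omitted it is
    guessed from the extension. Unparseable records are logged and skipped;
    a file with zero parseable records is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smiles-list", ".txt": "smiles-list", ".csv": "csv", ".sdf": "sdf"}.get(
            path.suffix.lower(), "smiles-list"
        )
    if standardizer is None:
        standardizer = MolStandardizer(keep_chirality=keep_chirality)

    lib = CompoundLibrary(
        name=name or path.stem, chirality_kept=standardizer.keep_chirality
    )
    seen: dict[str, str] = {}  # canonical smiles -> first-seen id
    n_records = 0
    for sid, raw in _iter_records(path, format, smiles_column):
        n_records += 1
        if raw is None:
            lib.curation_log.append((sid, "removed", "unparseable record"))
            continue
        res = standardizer.standardize(raw, source_id=sid)
        if isinstance(res, RemovalVerdict):
            lib.curation_log.append((sid, "removed", res.reason))
            continue
        smi = Chem.MolToSmiles(res)
        if smi in seen:
            lib.curation_log.append((sid, "removed", f"duplicate of {seen[smi]}"))
            continue
        seen[smi] = sid
        lib.molecules[sid] = res
        lib.curation_log.append((sid, "kept", ""))
    if n_records == 0 or not any(a == "kept" for _, a, _ in lib.curation_log):
        raise ValueError(f"no parseable records in {path}")
    return lib


def library_from_smiles(
    smiles: Iterable[str | tuple[str, str]],
    name: str = "library",
    keep_chirality: bool = True,
    standardize_input: bool = True,
) -> CompoundLibrary:
    """Build a curated library directly from SMILES strings.

    Accepts plain SMILES or ``(id, smiles)`` pairs. Deduplication keeps the
    first-seen ID, matching the file readers.
    """
    standardizer = MolStandardizer(keep_chirality=keep_chirality)
    lib = CompoundLibrary(name=name, chirality_kept=keep_chirality)
    seen: dict[str, str] = {}
    for i, item in enumerate(smiles):
        sid, smi = item if isinstance(item, tuple) else (f"{name}_{i}", item)
        if standardize_input:
            res = standardizer.standardize(smi, source_id=sid)
        else:
            res = Chem.MolFromSmiles(smi)
            if res is None:
                res = RemovalVerdict(sid, "unparseable structure")
        if isinstance(res, RemovalVerdict):
            lib.curation_log.append((sid, "removed", res.reason))
            continue
        can = Chem.MolToSmiles(res)
        if can in seen:
            lib.curation_log.append((sid, "removed", f"duplicate of {seen[can]}"))
            continue
        seen[can] = sid
        lib.molecules[sid] = res
        lib.curation_log.append((sid, "kept", ""))
    return lib


# ---------------------------------------------------------------------------
# overlap


@dataclass
class OverlapReport:
    """Venn-style decomposition of several libraries over canonical forms.

    ``regions`` maps the exact subset of library names (a sorted tuple) to the
    number of canonical forms found in precisely those libraries; every form
    lands in exactly one region, so region counts sum to the union size.
    """

    library_names: list[str]
    regions: dict[tuple[str, ...], int]
    shared_ids: dict[tuple[str, ...], list[str]]

    def intersection(self, *names: str) -> int:
        """Total count of forms present in all of ``names`` (any region containing them)."""
        want = set(names)
        return sum(
            c for region, c in self.regions.items() if want.issubset(region)
        )

    def unique(self, name: str) -> int:
        return self.regions.get((name,), 0)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def _overlap_of_sets(sets: dict[str, set[str]]) -> OverlapReport:
    names = sorted(sets)
    membership: dict[str, tuple[str, ...]] = {}
    for form in set().union(*sets.values()) if sets else set():
        region = tuple(n for n in names if form in sets[n])
        membership[form] = region
    regions: dict[tuple[str, ...], int] = {}
    shared: dict[tuple[str, ...], list[str]] = {}
    for form, region in membership.items():
        regions[region] = regions.get(region, 0) + 1
        shared.setdefault(region, []).append(form)
    for v in shared.values():
        v.sort()
    return OverlapReport(library_names=names, regions=regions, shared_ids=shared)


def compound_overlap(
    libraries: Sequence[CompoundLibrary], use_chirality: bool = False
) -> OverlapReport:
    """Venn-region counts over canonical SMILES of two or more libraries.

    With ``use_chirality=False`` (the default, matching standard practice for
    cross-database comparison) stereo tags are stripped before comparison.
    """
    if len(libraries) < 2:
        raise ValueError("need at least two libraries")
    if use_chirality and not all(lib.chirality_kept for lib in libraries):
        raise ValueError(
            "use_chirality=True requires all libraries standardized with chirality kept"
        )
    names = [lib.name for lib in libraries]
    if len(set(names)) != len(names):
        raise ValueError("library names must be unique")
    sets = {lib.name: lib.canonical_set(use_chirality) for lib in libraries}
    return _overlap_of_sets(sets)


def pairwise_intersections(report: OverlapReport) -> dict[tuple[str, str], int]:
    """Convenience: all pairwise intersection totals from a report."""
    return {
        pair: report.intersection(*pair)
        for pair in combinations(report.library_names, 2)
    }


def mw_of(mol: Chem.Mol) -> float:
    """Average molecular weight including implicit hydrogens (g/mol)."""
    return Descriptors.MolWt(mol)
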