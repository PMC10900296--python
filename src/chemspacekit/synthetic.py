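"""Synthetic compound libraries with planted, exactly-known structure.

Every pipeline stage is testable without downloads because the generators
plant the quantity the stage measures:

* :func:`gen_triacylglycerols` — exhaustive glycerol tri-esters over a fatty
  acid pool: an acyclic, high-CSP3, high-MW, scaffold-poor library emulating
  a lipid-dominated food-chemical collection;
* :func:`gen_scaffold_series` — libraries whose Bemis-Murcko scaffold
  frequency vector is exact by construction;
* :func:`gen_npl_corpora` — a natural-product-like corpus (decorated
  oxygenated saturated ring systems) and a synthetic-like corpus
  (halogenated flat aromatics) whose distinguishing atom environments are
  disjoint by construction;
* :func:`gen_overlap_triple` — three libraries reproducing a planted Venn
  region plan over canonical forms.

All generators are deterministic given their plan (parameters + seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from rdkit import Chem

from .curation import CompoundLibrary, MolStandardizer, library_from_smiles
from .scaffolds import bemis_murcko

#: Fatty-acid pool used for the benchmark lipid library: even-chain saturated
#: acids C8-C18 plus oleic-type 18:1 (double bond after carbon 9).
DEFAULT_ACID_POOL: list[tuple[int, tuple[int, ...]]] = [
    (8, ()),
    (10, ()),
    (12, ()),
    (14, ()),
    (16, ()),
    (18, ()),
    (18, (9,)),
]


@dataclass
class GeneratorPlan:
    """Fully determines one synthetic library (same plan -> same library)."""

    kind: str  # tag | scaffold_series | npl_corpora | overlap_triple
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"kind": self.kind, "parameters": self.parameters, "seed": self.seed},
                fh,
                indent=2,
                default=list,
            )


def _acyl_fragment(chain_length: int, double_bonds: Sequence[int]) -> str:
    """SMILES of the acyl substituent R in an ester O-C(=O)-R.

    ``chain_length`` counts carbons including the carbonyl carbon; a double
    bond at position k sits between chain carbons k and k+1 (2 <= k < length,
    keeping the carbonyl out of conjugation and the geometry unspecified).
    """
    if chain_length < 2:
        raise ValueError("chain length must be at least 2")
    for k in double_bonds:
        if not 2 <= k < chain_length:
            raise ValueError(
                f"invalid double-bond position {k} for chain length {chain_length}"
            )
    db = set(double_bonds)
    out = []
    for c in range(2, chain_length + 1):
        out.append("C")
        if c in db:
            out.append("=")
    return "".join(out).rstrip("=")


def gen_triacylglycerols(
    acid_pool: Sequence[tuple[int, Sequence[int]]] | None = None,
    distinct_only: bool = True,
    seed: int = 0,
    name: str = "tag",
) -> CompoundLibrary:
    """All glycerol tri-esters over a fatty-acid pool.

    With ``distinct_only`` the sn-1/sn-3 mirror duplicates collapse under
    canonical-form deduplication, leaving |pool| * C(|pool|+1, 2) unique
    esters. Every member is acyclic and, for long saturated pools, nearly
    fully sp3.
    """
    pool = list(acid_pool) if acid_pool is not None else list(DEFAULT_ACID_POOL)
    if not pool:
        raise ValueError("empty acid pool")
    acyls = [_acyl_fragment(length, tuple(dbs)) for length, dbs in pool]
    records = []
    for i, (r1, r2, r3) in enumerate(product(acyls, repeat=3)):
        smi = f"C(OC(=O){r2})(COC(=O){r1})COC(=O){r3}"
        records.append((f"{name}_{i:04d}", smi))
    if not distinct_only:
        lib = CompoundLibrary(name=name)
        std = MolStandardizer()
        for sid, smi in records:
            mol = std.standardize(smi, source_id=sid)
            lib.molecules[sid] = mol
            lib.curation_log.append((sid, "kept", ""))
        return lib
    return library_from_smiles(records, name=name)


# ---------------------------------------------------------------------------
# scaffold series

#: Acyclic side chains used to decorate scaffolds (must never add a ring).
DEFAULT_DECORATIONS = (
    "C", "CC", "CCC", "CCCC", "O", "OC", "CO", "CCO", "N", "CN", "CC(C)C", "C(=O)O",
)


def _attach(mol: Chem.Mol, atom_idx: int, decoration: str) -> Chem.Mol | None:
    """Bond the first atom of an acyclic decoration fragment to ``atom_idx``."""
    frag = Chem.MolFromSmiles(decoration)
    if frag is None:
        raise ValueError(f"unparseable decoration {decoration!r}")
    if frag.GetRingInfo().NumRings() > 0:
        raise ValueError(f"decoration {decoration!r} introduces a new ring")
    if mol.GetAtomWithIdx(atom_idx).GetTotalNumHs() == 0:
        return None
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _decorated_variants(scaffold: Chem.Mol, decorations: Sequence[str]):
    """Yield decorated molecules: bare, single- then double-substituted."""
    yield Chem.Mol(scaffold)
    sites = [
        a.GetIdx() for a in scaffold.GetAtoms() if a.GetTotalNumHs() > 0
    ]
    singles = []
    for idx in sites:
        for dec in decorations:
            m = _attach(scaffold, idx, dec)
            if m is not None:
                singles.append(m)
                yield m
    for base in singles:
        for idx in [a.GetIdx() for a in base.GetAtoms() if a.GetTotalNumHs() > 0]:
            for dec in decorations:
                m = _attach(base, idx, dec)
                if m is not None:
                    yield m


def gen_scaffold_series(
    scaffolds: Sequence[str],
    frequencies: Sequence[int],
    decoration: Sequence[str] | None = None,
    seed: int = 0,
    name: str = "series",
) -> CompoundLibrary:
    """Library whose scaffold frequency vector equals ``frequencies`` exactly.

    Each scaffold receives the requested number of distinct members built by
    attaching acyclic side chains (which a Bemis-Murcko reduction removes
    again). Every candidate is standardized before acceptance, so the planted
    counts survive curation unchanged.
    """
    if len(scaffolds) != len(frequencies):
        raise ValueError("scaffolds and frequencies must have equal length")
    decorations = tuple(decoration) if decoration is not None else DEFAULT_DECORATIONS
    std = MolStandardizer()
    lib = CompoundLibrary(name=name)
    seen: set[str] = set()
    counter = 0
    for scaf_smiles, freq in zip(scaffolds, frequencies):
        scaf_mol = Chem.MolFromSmiles(scaf_smiles)
        if scaf_mol is None:
            raise ValueError(f"unparseable scaffold {scaf_smiles!r}")
        target_scaffold = bemis_murcko(scaf_mol)
        collected = 0
        for candidate in _decorated_variants(scaf_mol, decorations):
            if collected >= freq:
                break
            res = std.standardize(candidate)
            if not isinstance(res, Chem.Mol):
                continue
            can = Chem.MolToSmiles(res)
            if can in seen or bemis_murcko(res) != target_scaffold:
                continue
            seen.add(can)
            sid = f"{name}_{counter:04d}"
            lib.molecules[sid] = res
            lib.curation_log.append((sid, "kept", ""))
            collected += 1
            counter += 1
        if collected < freq:
            raise ValueError(
                f"could not build {freq} distinct members for scaffold "
                f"{scaf_smiles!r}; extend the decoration pool"
            )
    return lib


# ---------------------------------------------------------------------------
# NPL corpora

_NP_SCAFFOLDS = ("C1CCOC1", "C1CCOCC1", "C1CCCCC1", "C1CCCCCC1", "C1CCC2CCCCC2C1")
_NP_DECORATIONS = ("O", "OC", "CO", "CCO", "OCC", "C(O)CO", "CC(O)C", "OCCO")
_SYN_SCAFFOLDS = ("c1ccccc1", "c1ccc(-c2ccccc2)cc1", "c1ccncc1")
_SYN_DECORATIONS = ("Cl", "F", "Br", "C(F)(F)F", "Cl", "CCl", "C", "CC")


def _fill_corpus(
    scaffold_pool: Sequence[str],
    decorations: Sequence[str],
    n: int,
    rng: np.random.Generator,
    name: str,
    require: str | None = None,
) -> CompoundLibrary:
    std = MolStandardizer()
    lib = CompoundLibrary(name=name)
    seen: set[str] = set()
    counter = 0
    scaffold_mols = [Chem.MolFromSmiles(s) for s in scaffold_pool]
    attempts = 0
    while counter < n and attempts < 200 * n:
        attempts += 1
        scaf = scaffold_mols[int(rng.integers(len(scaffold_mols)))]
        mol = Chem.Mol(scaf)
        for _ in range(int(rng.integers(1, 4))):  # 1-3 substituents
            sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
            if not sites:
                break
            dec = decorations[int(rng.integers(len(decorations)))]
            new = _attach(mol, int(sites[int(rng.integers(len(sites)))]), dec)
            if new is not None:
                mol = new
        res = std.standardize(mol)
        if not isinstance(res, Chem.Mol):
            continue
        if require == "halogen" and not any(
            a.GetAtomicNum() in (9, 17, 35) for a in res.GetAtoms()
        ):
            continue
        if require == "oxygen" and not any(
            a.GetAtomicNum() == 8 for a in res.GetAtoms()
        ):
            continue
        can = Chem.MolToSmiles(res)
        if can in seen:
            continue
        seen.add(can)
        sid = f"{name}_{counter:04d}"
        lib.molecules[sid] = res
        lib.curation_log.append((sid, "kept", ""))
        counter += 1
    if counter < n:
        raise RuntimeError(f"could not generate {n} distinct molecules for {name}")
    return lib


def gen_npl_corpora(
    n_np: int = 100, n_syn: int = 100, seed: int = 0
) -> tuple[CompoundLibrary, CompoundLibrary]:
    """Natural-product-like and synthetic-like training corpora.

    The NP-like corpus holds oxygen-decorated saturated (fused) ring systems
    with no halogens; the synthetic-like corpus holds halogenated small
    aromatics with no oxygen. Their class-distinguishing atom environments
    are therefore disjoint by construction.
    """
    if n_np < 10 or n_syn < 10:
        raise ValueError("corpus sizes must be at least 10")
    rng_np = np.random.default_rng(seed)
    rng_syn = np.random.default_rng(seed + 1)
    np_lib = _fill_corpus(
        _NP_SCAFFOLDS, _NP_DECORATIONS, n_np, rng_np, "np_like", require="oxygen"
    )
    syn_lib = _fill_corpus(
        _SYN_SCAFFOLDS, _SYN_DECORATIONS, n_syn, rng_syn, "syn_like", require="halogen"
    )
    return np_lib, syn_lib


# ---------------------------------------------------------------------------
# overlap triples

_HOMOLOG_FAMILIES = ("{c}", "OC{c}", "NC{c}", "SC{c}", "OC(=O)C{c}", "N#CC{c}")


def _distinct_molecule_stream():
    """Endless deterministic stream of distinct, standardization-stable SMILES."""
    k = 2
    std = MolStandardizer()
    seen: set[str] = set()
    while True:
        k += 1
        for fam in _HOMOLOG_FAMILIES:
            smi = fam.format(c="C" * k)
            res = std.standardize(smi)
            if not isinstance(res, Chem.Mol):
                continue
            can = Chem.MolToSmiles(res)
            if can not in seen:
                seen.add(can)
                yield can


def gen_overlap_triple(
    sizes: tuple[int, int, int],
    planted: dict[tuple[str, ...], int],
    seed: int = 0,
    names: tuple[str, str, str] = ("A", "B", "C"),
) -> tuple[CompoundLibrary, CompoundLibrary, CompoundLibrary]:
    """Three libraries reproducing a planted Venn-region plan exactly.

    ``planted`` maps each exclusive region (tuple of library names, e.g.
    ``("A", "B")`` for the A-and-B-only region) to its compound count.
    Region counts must be consistent with ``sizes``.
    """
    planted = {tuple(sorted(k)): v for k, v in planted.items()}
    for region in planted:
        if not set(region) <= set(names):
            raise ValueError(f"region {region} references unknown library names")
    implied = {
        name: sum(c for region, c in planted.items() if name in region)
        for name in names
    }
    if tuple(implied[n] for n in names) != tuple(sizes):
        raise ValueError(
            f"planted regions imply sizes {implied}, inconsistent with {sizes}"
        )
    stream = _distinct_molecule_stream()
    libs = {n: CompoundLibrary(name=n) for n in names}
    counter = {n: 0 for n in names}
    for region in sorted(planted):  # deterministic region order
        for _ in range(planted[region]):
            can = next(stream)
            for lib_name in region:
                sid = f"{lib_name}_{counter[lib_name]:04d}"
                libs[lib_name].molecules[sid] = Chem.MolFromSmiles(can)
                libs[lib_name].curation_log.append((sid, "kept", ""))
                counter[lib_name] += 1
    return tuple(libs[n] for n in names)  # type: ignore[return-value]


def generate(plan: GeneratorPlan):
    """Dispatch a generator plan to the matching generator."""
    kinds = {
        "tag": gen_triacylglycerols,
        "scaffold_series": gen_scaffold_series,
        "npl_corpora": gen_npl_corpora,
        "overlap_triple": gen_overlap_triple,
    }
    if plan.kind not in kinds:
        raise ValueError(f"unknown plan kind {plan.kind!r}")
    return kinds[plan.kind](**plan.parameters, seed=plan.seed)
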