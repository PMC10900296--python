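"""Molecular representations and similarity functions.

Four representations are supported:

* ``keys166`` — the 166 structural keys (presence/absence of a fixed SMARTS
  dictionary);
* ``circular4-1024`` / ``circular6-1024`` — extended-connectivity circular
  fingerprints of diameter 4 and 6, folded to 1024 bits;
* ``map4-2048`` — a MinHashed atom-pair fingerprint: shingles pair the
  circular environments of two atoms (radius 1..2, i.e. up to a diameter of
  four bonds) with their topological distance, and the shingle set is
  compressed into a 2048-component MinHash signature.

Bit fingerprints are compared with the Tanimoto coefficient; MinHash
signatures estimate the Jaccard similarity of the underlying shingle sets by
the fraction of equal components.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .curation import CompoundLibrary

REPRESENTATIONS = ("keys166", "circular4-1024", "circular6-1024", "map4-2048")

#: Mersenne prime for the universal hash family; products of two values
#: below it stay inside int64 arithmetic.
_MERSENNE = np.int64(2**31 - 1)


@dataclass(frozen=True)
class BitFingerprint:
    """Sparse bit fingerprint under a named representation."""

    representation: str
    bits: frozenset
    length: int

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.length:
            raise ValueError("bit position exceeds fingerprint length")


@dataclass(frozen=True)
class MinHashSignature:
    """MinHash signature of an atom-pair shingle set."""

    representation: str
    components: tuple
    hash_seed: int

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class FingerprintSet:
    """One fingerprint per compound of a library, uniform representation.

    Bit representations are stored as a boolean matrix (n x length); MinHash
    signatures as an int64 matrix (n x n_components).
    """

    library_name: str
    representation: str
    ids: list[str]
    matrix: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_minhash(self) -> bool:
        return self.representation.startswith("map4")

    def subset(self, positions: Sequence[int]) -> "FingerprintSet":
        return FingerprintSet(
            library_name=self.library_name,
            representation=self.representation,
            ids=[self.ids[i] for i in positions],
            matrix=self.matrix[list(positions)],
            seed=self.seed,
        )

    def write_json(self, path, compress: bool = True) -> None:
        payload = {
            "library": self.library_name,
            "representation": self.representation,
            "seed": self.seed,
            "length": int(self.matrix.shape[1]),
            "fingerprints": {
                cid: (
                    [int(v) for v in row]
                    if self.is_minhash
                    else [int(i) for i in np.flatnonzero(row)]
                )
                for cid, row in zip(self.ids, self.matrix)
            },
        }
        data = json.dumps(payload).encode()
        if compress:
            with gzip.open(path, "wb") as fh:
                fh.write(data)
        else:
            with open(path, "wb") as fh:
                fh.write(data)


def _as_mol(mol: str | Chem.Mol) -> Chem.Mol:
    if isinstance(mol, str):
        out = Chem.MolFromSmiles(mol)
        if out is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        return out
    return mol


def _strip_stereo(mol: Chem.Mol) -> Chem.Mol:
    """Fingerprints use nonchiral structures by default."""
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return flat


# ---------------------------------------------------------------------------
# structural keys and circular fingerprints


def keys_fingerprint(mol: str | Chem.Mol) -> BitFingerprint:
    """166 structural keys (the toolkit's key 0 is unused and dropped)."""
    bv = MACCSkeys.GenMACCSKeys(_strip_stereo(_as_mol(mol)))
    bits = frozenset(b - 1 for b in bv.GetOnBits() if b >= 1)
    return BitFingerprint(representation="keys166", bits=bits, length=166)


def circular_fingerprint(
    mol: str | Chem.Mol, diameter: int = 4, n_bits: int = 1024
) -> BitFingerprint:
    """Extended-connectivity fingerprint of the given bond diameter, folded."""
    if diameter not in (4, 6):
        raise ValueError("diameter must be 4 or 6")
    gen = _morgan_generator(diameter // 2, n_bits)
    bv = gen.GetFingerprint(_strip_stereo(_as_mol(mol)))
    return BitFingerprint(
        representation=f"circular{diameter}-{n_bits}",
        bits=frozenset(bv.GetOnBits()),
        length=n_bits,
    )


_GENERATORS: dict = {}


def _morgan_generator(radius: int, n_bits: int | None):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        if n_bits is None:
            _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
        else:
            _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
                radius=radius, fpSize=n_bits
            )
    return _GENERATORS[key]


def circular_identifiers(mol: str | Chem.Mol, diameter: int = 4) -> set[int]:
    """Unfolded circular-environment identifiers (all radii up to diameter/2)."""
    gen = _morgan_generator(diameter // 2, None)
    fp = gen.GetSparseCountFingerprint(_strip_stereo(_as_mol(mol)))
    return set(fp.GetNonzeroElements())


# ---------------------------------------------------------------------------
# MinHashed atom-pair fingerprint


def atom_environment_smiles(mol: Chem.Mol, atom_idx: int, radius: int) -> str:
    """Canonical SMILES of the bond environment of ``radius`` around an atom.

    Falls back to shorter radii (finally the bare atom) when the molecule is
    smaller than the requested environment.
    """
    for r in range(radius, 0, -1):
        env = Chem.FindAtomEnvironmentOfRadiusN(mol, r, atom_idx)
        if env:
            amap: dict[int, int] = {}
            sub = Chem.PathToSubmol(mol, env, atomMap=amap)
            return Chem.MolToSmiles(
                sub, rootedAtAtom=amap[atom_idx], canonical=True, isomericSmiles=False
            )
    return Chem.MolToSmiles(
        Chem.MolFromSmiles(f"[{mol.GetAtomWithIdx(atom_idx).GetSymbol()}]")
    )


def atom_pair_shingles(mol: str | Chem.Mol, radius_max: int = 2) -> set[str]:
    """Atom-pair shingle set: ``envA|distance|envB`` for every heavy-atom pair.

    For each unordered pair (i, j) and each radius r in 1..radius_max, the two
    circular environments are rendered as canonical SMILES, ordered
    lexicographically, and joined with the topological (bond-count) distance.
    """
    mol = _strip_stereo(_as_mol(mol))
    n = mol.GetNumAtoms()
    if n < 2:
        raise ValueError("atom-pair shingles need at least 2 heavy atoms")
    dist = Chem.GetDistanceMatrix(mol)
    envs = {
        (i, r): atom_environment_smiles(mol, i, r)
        for i in range(n)
        for r in range(1, radius_max + 1)
    }
    shingles = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dist[i, j])
            if d <= 0 or d > 1e6:  # disconnected pair (multi-fragment input)
                continue
            for r in range(1, radius_max + 1):
                a, b = sorted((envs[(i, r)], envs[(j, r)]))
                shingles.add(f"{a}|{d}|{b}")
    return shingles


def _hash_params(n_components: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    p = int(_MERSENNE)
    a = rng.integers(1, p, size=n_components, dtype=np.int64)
    b = rng.integers(0, p, size=n_components, dtype=np.int64)
    return a, b


def _shingle_values(shingles: set[str]) -> np.ndarray:
    vals = np.fromiter(
        (
            int.from_bytes(hashlib.blake2b(s.encode(), digest_size=8).digest(), "big")
            % int(_MERSENNE)
            for s in sorted(shingles)
        ),
        dtype=np.int64,
        count=len(shingles),
    )
    return vals


def minhash_signature(
    shingles: set[str], n_components: int = 2048, seed: int = 42
) -> np.ndarray:
    """MinHash signature of a string shingle set via a universal hash family."""
    if not shingles:
        raise ValueError("empty shingle set")
    a, b = _hash_params(n_components, seed)
    xs = _shingle_values(shingles)
    p = _MERSENNE
    sig = np.full(n_components, np.iinfo(np.int64).max, dtype=np.int64)
    for start in range(0, len(xs), 512):  # chunked to bound the temporary
        chunk = xs[start : start + 512, None]
        sig = np.minimum(sig, ((a[None, :] * chunk + b[None, :]) % p).min(axis=0))
    return sig


def map4_signature(
    mol: str | Chem.Mol,
    n_components: int = 2048,
    radius_max: int = 2,
    seed: int = 42,
) -> MinHashSignature:
    """MinHashed atom-pair fingerprint (diameter up to 2*radius_max bonds)."""
    sig = minhash_signature(
        atom_pair_shingles(mol, radius_max), n_components=n_components, seed=seed
    )
    return MinHashSignature(
        representation=f"map4-{n_components}",
        components=tuple(int(v) for v in sig),
        hash_seed=seed,
    )


# ---------------------------------------------------------------------------
# similarity


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |A n B| / |A u B| of two bit fingerprints."""
    if a.representation != b.representation or a.length != b.length:
        raise ValueError("representation mismatch")
    union = len(a.bits | b.bits)
    if union == 0:
        import warnings

        warnings.warn("both fingerprints empty; Tanimoto defined as 1.0")
        return 1.0
    return len(a.bits & b.bits) / union


def minhash_similarity(a: MinHashSignature, b: MinHashSignature) -> float:
    """Jaccard estimate: fraction of equal signature components."""
    if (
        a.representation != b.representation
        or a.n_components != b.n_components
        or a.hash_seed != b.hash_seed
    ):
        raise ValueError("signature size/seed mismatch")
    eq = sum(1 for x, y in zip(a.components, b.components) if x == y)
    return eq / a.n_components


def similarity_matrix(fps: FingerprintSet) -> np.ndarray:
    """Full pairwise similarity matrix of a fingerprint set."""
    X = fps.matrix
    if fps.is_minhash:
        n = len(X)
        out = np.ones((n, n))
        for i in range(n):
            out[i, i + 1 :] = (X[i + 1 :] == X[i]).mean(axis=1)
            out[i + 1 :, i] = out[i, i + 1 :]
        return out
    Xf = X.astype(np.float32)
    inter = Xf @ Xf.T
    pop = Xf.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def pairwise_similarities(fps: FingerprintSet) -> np.ndarray:
    """Condensed upper-triangle pairwise similarities."""
    sim = similarity_matrix(fps)
    iu = np.triu_indices(len(sim), k=1)
    return sim[iu]


# ---------------------------------------------------------------------------
# estimator classes and library-level driver


class _BaseFingerprinter(BaseEstimator, TransformerMixin):
    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Sequence[str | Chem.Mol]) -> np.ndarray:
        return np.vstack([self._row(x) for x in X])


class MACCSFingerprinter(_BaseFingerprinter):
    """Transformer: molecules -> 166-key boolean matrix."""

    representation = "keys166"

    def _row(self, mol) -> np.ndarray:
        row = np.zeros(166, dtype=bool)
        row[list(keys_fingerprint(mol).bits)] = True
        return row


class CircularFingerprinter(_BaseFingerprinter):
    """Transformer: molecules -> folded circular-fingerprint boolean matrix."""

    def __init__(self, diameter: int = 4, n_bits: int = 1024):
        self.diameter = diameter
        self.n_bits = n_bits

    @property
    def representation(self) -> str:
        return f"circular{self.diameter}-{self.n_bits}"

    def _row(self, mol) -> np.ndarray:
        row = np.zeros(self.n_bits, dtype=bool)
        row[list(circular_fingerprint(mol, self.diameter, self.n_bits).bits)] = True
        return row


class MAP4Fingerprinter(_BaseFingerprinter):
    """Transformer: molecules -> MinHash signature matrix (int64)."""

    def __init__(self, n_components: int = 2048, radius_max: int = 2, seed: int = 42):
        self.n_components = n_components
        self.radius_max = radius_max
        self.seed = seed

    @property
    def representation(self) -> str:
        return f"map4-{self.n_components}"

    def _row(self, mol) -> np.ndarray:
        return minhash_signature(
            atom_pair_shingles(mol, self.radius_max),
            n_components=self.n_components,
            seed=self.seed,
        )


def make_fingerprinter(representation: str, seed: int = 42) -> _BaseFingerprinter:
    if representation == "keys166":
        return MACCSFingerprinter()
    if representation.startswith("circular"):
        diameter_part, bits_part = representation.removeprefix("circular").split("-")
        return CircularFingerprinter(diameter=int(diameter_part), n_bits=int(bits_part))
    if representation.startswith("map4"):
        n = int(representation.split("-")[1]) if "-" in representation else 2048
        return MAP4Fingerprinter(n_components=n, seed=seed)
    raise ValueError(f"unknown representation {representation!r}")


def fingerprint_library(
    library: CompoundLibrary, representation: str, seed: int = 42
) -> FingerprintSet:
    """Compute one fingerprint per library compound."""
    fper = make_fingerprinter(representation, seed=seed)
    ids = list(library.molecules)
    matrix = fper.transform([library.molecules[i] for i in ids])
    return FingerprintSet(
        library_name=library.name,
        representation=fper.representation,
        ids=ids,
        matrix=matrix,
        seed=seed if representation.startswith("map4") else None,
    )
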