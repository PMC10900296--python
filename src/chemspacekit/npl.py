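"""Trainable natural-product-likeness (NPL) scoring.

The score measures how close a molecule sits to the structural space of a
natural-product corpus relative to a synthetic corpus. Each circular atom
environment (radius 0..R) receives a smoothed log10 frequency-ratio
contribution between the two training corpora; a molecule's raw score is the
per-heavy-atom average of its environments' contributions, with a decadic-log
tail compression beyond |raw| > 4 and clamping so the final score is bounded
in [-5, 5]. Positive values mean natural-product-like.

The model is trainable from any two corpora; it is a reimplementation
convention, so numerical agreement with any previously published scorer's
values is not expected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator

from .curation import CompoundLibrary


def fragment_occurrences(mol: Chem.Mol, radius: int = 2) -> dict[int, int]:
    """Multiset of circular atom-environment identifiers up to ``radius``.

    Each heavy atom contributes its environment identifier at every radius
    0..``radius``; environments covering an identical bond set are collapsed
    by the underlying circular algorithm.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    return {
        ident: len(occurrences)
        for ident, occurrences in ao.GetBitInfoMap().items()
    }


@dataclass
class NPLScore:
    """Bounded NPL score for one molecule."""

    value: float
    raw: float
    n_fragments: int


def _compress(raw: float) -> float:
    """Tail compression: identity within [-4, 4], decadic-log beyond, clamped."""
    if abs(raw) <= 4.0:
        return raw
    compressed = math.copysign(4.0 + math.log10(abs(raw) - 3.0), raw)
    return max(-5.0, min(5.0, compressed))


class NPLScorer(BaseEstimator):
    """Fragment log-ratio NPL model in sklearn estimator form.

    ``fit(X, y)`` takes molecules/SMILES with binary labels (1 = natural
    product corpus, 0 = synthetic corpus). ``score_samples`` returns the
    bounded scores.

    Parameters
    ----------
    radius:
        Circular-environment radius for fragment generation.
    smoothing:
        Additive pseudo-count applied to every fragment frequency, so that
        corpus-exclusive fragments get finite contributions.

    Attributes
    ----------
    contributions_:
        Fragment identifier -> log10 frequency-ratio contribution.
    n_np_, n_syn_:
        Training corpus sizes.
    """

    def __init__(self, radius: int = 2, smoothing: float = 1.0):
        self.radius = radius
        self.smoothing = smoothing

    def fit(self, X: Sequence[str | Chem.Mol], y: Sequence[int]):
        y = np.asarray(list(y))
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if not (np.any(y == 1) and np.any(y == 0)):
            raise ValueError("need both a natural (1) and a synthetic (0) corpus")
        counts = [dict(), dict()]  # index by label
        for item, label in zip(X, y):
            mol = Chem.MolFromSmiles(item) if isinstance(item, str) else item
            if mol is None:
                raise ValueError(f"unparseable SMILES: {item!r}")
            for frag, occ in fragment_occurrences(mol, self.radius).items():
                counts[label][frag] = counts[label].get(frag, 0) + occ
        vocab = set(counts[0]) | set(counts[1])
        t_np = sum(counts[1].values())
        t_syn = sum(counts[0].values())
        s, v = self.smoothing, len(vocab)
        self.contributions_ = {
            frag: math.log10(
                ((counts[1].get(frag, 0) + s) / (t_np + s * v))
                / ((counts[0].get(frag, 0) + s) / (t_syn + s * v))
            )
            for frag in vocab
        }
        self.n_np_ = int(np.sum(y == 1))
        self.n_syn_ = int(np.sum(y == 0))
        return self

    def score_one(self, mol: str | Chem.Mol) -> NPLScore:
        if isinstance(mol, str):
            mol = Chem.MolFromSmiles(mol)
            if mol is None:
                raise ValueError("unparseable SMILES")
        heavy = mol.GetNumHeavyAtoms()
        occurrences = fragment_occurrences(mol, self.radius)
        raw = (
            sum(
                self.contributions_.get(frag, 0.0) * occ
                for frag, occ in occurrences.items()
            )
            / heavy
            if heavy
            else 0.0
        )
        return NPLScore(
            value=_compress(raw),
            raw=raw,
            n_fragments=sum(occurrences.values()),
        )

    def score_samples(self, X: Sequence[str | Chem.Mol]) -> np.ndarray:
        return np.array([self.score_one(m).value for m in X])

    # ---------------------------------------------------------------- persistence

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "radius": self.radius,
                    "smoothing": self.smoothing,
                    "n_np": self.n_np_,
                    "n_syn": self.n_syn_,
                    "contributions": {
                        str(k): v for k, v in self.contributions_.items()
                    },
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "NPLScorer":
        with open(path) as fh:
            blob = json.load(fh)
        model = cls(radius=blob["radius"], smoothing=blob["smoothing"])
        model.contributions_ = {int(k): v for k, v in blob["contributions"].items()}
        model.n_np_ = blob["n_np"]
        model.n_syn_ = blob["n_syn"]
        return model


def train_npl(
    np_corpus: CompoundLibrary, syn_corpus: CompoundLibrary, radius: int = 2
) -> NPLScorer:
    """Train an NPL model from a natural-product and a synthetic library."""
    if len(np_corpus) == 0 or len(syn_corpus) == 0:
        raise ValueError("both corpora must be non-empty")
    mols = list(np_corpus.molecules.values()) + list(syn_corpus.molecules.values())
    labels = [1] * len(np_corpus) + [0] * len(syn_corpus)
    return NPLScorer(radius=radius).fit(mols, labels)


def npl_score(mol: str | Chem.Mol, model: NPLScorer) -> NPLScore:
    """Score one molecule under a trained NPL model."""
    return model.score_one(mol)
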