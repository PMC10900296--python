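"""Chemical multiverse: per-representation 2-D projections of pooled libraries.

A chemical multiverse is the collection of alternative chemical-space views
of the same compounds, one per molecular representation. Each view embeds the
pooled libraries with t-SNE on the precomputed Tanimoto/Jaccard dissimilarity
matrix of that representation; the embedding is deterministic given the seed.

Purchasability-style catalog queries are answered locally by canonical-form
intersection against a catalog library (with or without stereochemistry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import TSNE

from .curation import CompoundLibrary, OverlapReport, _overlap_of_sets
from .fingerprints import FingerprintSet, fingerprint_library, similarity_matrix


@dataclass
class EmbeddingConfig:
    """t-SNE contract parameters; the embedding is property-checked, never
    coordinate-exact."""

    perplexity: float = 30.0
    seed: int = 0
    representation: str = "circular4-1024"
    n_iter: int = 500
    method: str = "t-SNE"


class MultiverseEmbedder(BaseEstimator, TransformerMixin):
    """Transformer: fingerprint set -> deterministic 2-D coordinates."""

    def __init__(self, perplexity: float = 30.0, seed: int = 0, n_iter: int = 500):
        self.perplexity = perplexity
        self.seed = seed
        self.n_iter = n_iter

    def fit_transform(self, X: FingerprintSet, y=None) -> np.ndarray:
        n = len(X)
        if n < 3 * self.perplexity:
            raise ValueError(
                f"{n} points is too few for perplexity {self.perplexity}; "
                f"lower the perplexity below {n / 3:.0f} or pool more compounds"
            )
        dissim = 1.0 - similarity_matrix(X)
        np.fill_diagonal(dissim, 0.0)
        dissim = np.clip(dissim, 0.0, None)
        tsne = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            random_state=self.seed,
            perplexity=self.perplexity,
            max_iter=self.n_iter,
        )
        return tsne.fit_transform(dissim.astype(np.float64))

    def transform(self, X):
        return self.fit_transform(X)


def embed(fps: FingerprintSet, config: EmbeddingConfig) -> dict[str, tuple[float, float]]:
    """Embed a pooled fingerprint set; returns ID -> (x, y)."""
    coords = MultiverseEmbedder(
        perplexity=config.perplexity, seed=config.seed, n_iter=config.n_iter
    ).fit_transform(fps)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("non-finite embedding coordinates")
    return {cid: (float(x), float(y)) for cid, (x, y) in zip(fps.ids, coords)}


@dataclass
class MultiverseView:
    """Coordinates per representation plus library labels, consistent IDs."""

    coordinates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    configs: dict[str, EmbeddingConfig] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep, coords in self.coordinates.items():
            for cid, (x, y) in coords.items():
                rows.append(
                    {
                        "id": cid,
                        "library": self.labels[cid],
                        "representation": rep,
                        "x": x,
                        "y": y,
                    }
                )
        return pd.DataFrame(rows, columns=["id", "library", "representation", "x", "y"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pool_libraries(
    libraries: list[CompoundLibrary], representation: str, seed: int = 42
) -> tuple[FingerprintSet, dict[str, str]]:
    """Fingerprint the union of libraries with namespaced IDs and labels."""
    ids: list[str] = []
    labels: dict[str, str] = {}
    matrices = []
    for lib in libraries:
        fps = fingerprint_library(lib, representation, seed=seed)
        for cid in fps.ids:
            key = f"{lib.name}:{cid}"
            ids.append(key)
            labels[key] = lib.name
        matrices.append(fps.matrix)
    pooled = FingerprintSet(
        library_name="+".join(lib.name for lib in libraries),
        representation=representation if "-" in representation else representation,
        ids=ids,
        matrix=np.vstack(matrices),
        seed=seed if representation.startswith("map4") else None,
    )
    return pooled, labels


def build_multiverse(
    libraries: list[CompoundLibrary],
    representations: list[str],
    config: EmbeddingConfig | None = None,
) -> MultiverseView:
    """One embedding per representation over the pooled libraries."""
    if len(representations) < 2:
        raise ValueError("a multiverse needs at least two representations")
    config = config or EmbeddingConfig()
    view = MultiverseView()
    for rep in representations:
        pooled, labels = pool_libraries(libraries, rep, seed=config.seed or 42)
        rep_config = EmbeddingConfig(
            perplexity=config.perplexity,
            seed=config.seed,
            representation=pooled.representation,
            n_iter=config.n_iter,
        )
        view.coordinates[pooled.representation] = embed(pooled, rep_config)
        view.configs[pooled.representation] = rep_config
        view.labels = labels
    key_sets = {frozenset(c) for c in view.coordinates.values()}
    if len(key_sets) != 1:
        raise RuntimeError("inconsistent ID sets across representations")
    return view


def catalog_intersection(
    library: CompoundLibrary, catalog: CompoundLibrary, use_chirality: bool = False
) -> OverlapReport:
    """Members of ``library`` whose canonical form occurs in ``catalog``.

    Stands in for a purchasability query against a vendor catalog: the
    intersection region of the report counts the catalog-available *members*
    of the query library (so a stereo-agnostic query can only match more
    members than a stereo-aware one, never fewer).
    """
    if use_chirality and not (library.chirality_kept and catalog.chirality_kept):
        raise ValueError(
            "use_chirality=True requires both libraries standardized with chirality kept"
        )
    from rdkit import Chem

    catalog_forms = catalog.canonical_set(use_chirality)
    matched_ids, matched_forms = [], set()
    for cid, mol in library.molecules.items():
        form = Chem.MolToSmiles(mol, isomericSmiles=use_chirality)
        if form in catalog_forms:
            matched_ids.append(cid)
            matched_forms.add(form)
    pair = tuple(sorted([library.name, catalog.name]))
    regions = {
        pair: len(matched_ids),
        (library.name,): len(library) - len(matched_ids),
        (catalog.name,): len(catalog_forms - matched_forms),
    }
    return OverlapReport(
        library_names=list(pair),
        regions={k: v for k, v in regions.items() if v or len(k) == 2},
        shared_ids={pair: sorted(matched_forms)},
    )


def plot_multiverse(view: MultiverseView, path=None):
    """One scatter panel per representation, one color per library."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reps = list(view.coordinates)
    fig, axes = plt.subplots(1, len(reps), figsize=(4.5 * len(reps), 4), squeeze=False)
    lib_names = sorted(set(view.labels.values()))
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(lib_names), 2)))
    for ax, rep in zip(axes[0], reps):
        coords = view.coordinates[rep]
        for color, lib in zip(colors, lib_names):
            pts = np.array(
                [xy for cid, xy in coords.items() if view.labels[cid] == lib]
            )
            if len(pts):
                ax.scatter(pts[:, 0], pts[:, 1], s=6, color=color, label=lib)
        ax.set_title(rep)
        ax.set_xticks([])
        ax.set_yticks([])
    axes[0][0].legend(markerscale=2, fontsize=8)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
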