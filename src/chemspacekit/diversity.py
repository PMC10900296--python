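"""Pairwise fingerprint-diversity analysis with random-sample pooling.

Large libraries are profiled by drawing several independent random samples
(default: five samples of 1000 compounds) and pooling all within-sample
pairwise similarities before computing summary statistics — repeated
1000-compound sampling is an accepted estimator of whole-database pairwise
diversity. Libraries at or below the sample size are run in a single full
pairwise pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprints import FingerprintSet, pairwise_similarities


@dataclass
class SimilarityDistribution:
    """Pooled pairwise similarity values for one library/representation."""

    library_name: str
    representation: str
    values: np.ndarray
    n_samples: int
    sample_size: int
    seeds: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def quartiles(self) -> tuple[float, float]:
        return (
            float(np.quantile(self.values, 0.25)),
            float(np.quantile(self.values, 0.75)),
        )

    def summary(self) -> dict:
        q1, q3 = self.quartiles
        return {
            "library": self.library_name,
            "representation": self.representation,
            "n_values": int(len(self.values)),
            "n_samples": self.n_samples,
            "sample_size": self.sample_size,
            "seeds": self.seeds,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "q1": q1,
            "q3": q3,
        }

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def write_values_csv(self, path) -> None:
        pd.DataFrame({"similarity": self.values}).to_csv(path, index=False)


def pairwise_distribution(
    fps: FingerprintSet,
    sample_size: int = 1000,
    n_samples: int = 5,
    seed: int = 0,
) -> SimilarityDistribution:
    """Pooled pairwise-similarity distribution under the sampling protocol.

    If the library holds at most ``sample_size`` compounds a single full
    pairwise pass is used (recorded as one sample). Otherwise ``n_samples``
    independent uniform samples without replacement are drawn; the seed of
    sample k is derived from the master seed by a fixed offset and recorded.
    """
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    if sample_size < 2:
        raise ValueError("sample_size must be at least 2")

    if len(fps) <= sample_size:
        values = pairwise_similarities(fps)
        return SimilarityDistribution(
            library_name=fps.library_name,
            representation=fps.representation,
            values=values,
            n_samples=1,
            sample_size=len(fps),
            seeds=[seed],
        )

    pooled, seeds = [], []
    for k in range(n_samples):
        sample_seed = seed + 1000 * k
        seeds.append(sample_seed)
        rng = np.random.default_rng(sample_seed)
        idx = rng.choice(len(fps), size=sample_size, replace=False)
        pooled.append(pairwise_similarities(fps.subset(idx)))
    return SimilarityDistribution(
        library_name=fps.library_name,
        representation=fps.representation,
        values=np.concatenate(pooled),
        n_samples=n_samples,
        sample_size=sample_size,
        seeds=seeds,
    )


@dataclass
class CDF:
    """Empirical cumulative distribution on an even similarity grid."""

    thresholds: np.ndarray
    fractions: np.ndarray

    def at(self, x: float) -> float:
        return float(np.interp(x, self.thresholds, self.fractions))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"similarity": self.thresholds, "cumulative_fraction": self.fractions}
        )


def cdf(dist: SimilarityDistribution, n_points: int = 200) -> CDF:
    """Empirical CDF of the similarity values on an even grid over [0, 1]."""
    if len(dist.values) == 0:
        raise ValueError("empty distribution")
    grid = np.linspace(0.0, 1.0, n_points + 1)
    sorted_vals = np.sort(dist.values)
    fractions = np.searchsorted(sorted_vals, grid, side="right") / len(sorted_vals)
    return CDF(thresholds=grid, fractions=fractions)


def compare_libraries(dists: list[SimilarityDistribution]) -> pd.DataFrame:
    """Rank libraries by mean pairwise similarity (higher = less diverse).

    All inputs must share a representation. The returned frame is ordered
    from least diverse (highest mean similarity) to most diverse.
    """
    if not dists:
        raise ValueError("no distributions given")
    reps = {d.representation for d in dists}
    if len(reps) != 1:
        raise ValueError(f"mixed representations: {sorted(reps)}")
    rows = []
    for d in sorted(dists, key=lambda d: -d.mean):
        q1, q3 = d.quartiles
        rows.append(
            {
                "library": d.library_name,
                "representation": d.representation,
                "mean": d.mean,
                "median": d.median,
                "sd": d.sd,
                "q1": q1,
                "q3": q3,
                "n_values": len(d.values),
            }
        )
    frame = pd.DataFrame(rows)
    frame.index = pd.RangeIndex(1, len(frame) + 1, name="diversity_rank_from_least")
    return frame


def plot_cdfs(dists: list[SimilarityDistribution], path=None, n_points: int = 200):
    """Overlay CDF curves of several libraries for one representation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for d in dists:
        curve = cdf(d, n_points=n_points)
        ax.plot(curve.thresholds, curve.fractions, label=d.library_name)
    ax.set_xlabel(f"pairwise similarity ({dists[0].representation})")
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
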