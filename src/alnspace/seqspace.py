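"""Sequence-space embedding.

Projects an alignment's sequences into 2-D or 3-D with UMAP, using the
pairwise Hamming-distance matrix as a precomputed metric.  Runs are made
reproducible by seeding UMAP's random state: the same distances, config
and seed yield identical coordinates.

A small neighbor-preservation diagnostic quantifies how well the embedding
retains each sequence's nearest Hamming neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seq_metrics import PairwiseMatrix


@dataclass
class EmbeddingConfig:
    """UMAP hyperparameters.

    Defaults are the library's published defaults (``n_neighbors=15``,
    ``min_dist=0.1``); the seed is fixed so command-line runs reproduce.
    """

    n_components: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.1
    n_epochs: int | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be at least 2")
        if not 0.0 < self.min_dist <= 1.0:
            raise ValueError("min_dist must lie in (0, 1]")


@dataclass
class Embedding:
    """N x d coordinates with the config that produced them."""

    coords: np.ndarray
    config: EmbeddingConfig
    order: list[int] = field(default_factory=list)


def embed_sequences(dist: PairwiseMatrix, config: EmbeddingConfig | None = None) -> Embedding:
    """UMAP embedding of a precomputed (Hamming) distance matrix.

    Deterministic under a fixed seed.  Requires more sequences than
    ``n_neighbors`` and a symmetric zero-diagonal matrix.
    """
    import umap  # deferred: numba compilation makes this import expensive

    config = config or EmbeddingConfig()
    values = np.asarray(dist.values, dtype=np.float64)
    n = values.shape[0]
    if n <= config.n_neighbors:
        raise ValueError(
            f"n_neighbors={config.n_neighbors} must be smaller than the "
            f"number of sequences ({n}); lower n_neighbors")
    if not np.array_equal(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(values) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about precomputed + seed
        reducer = umap.UMAP(
            n_components=config.n_components,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            n_epochs=config.n_epochs,
            metric="precomputed",
            random_state=config.seed,
        )
        coords = reducer.fit_transform(values)
    coords = np.asarray(coords, dtype=np.float64)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    return Embedding(coords=coords, config=config, order=list(dist.order))


def neighbor_distance_preservation(dist: PairwiseMatrix, emb: Embedding,
                                   k: int) -> float:
    """Mean fraction of each point's k nearest input neighbors kept in the embedding.

    1.0 means every sequence's k nearest Hamming neighbors are also its k
    nearest embedding neighbors; chance level is about ``k / (N - 1)``.
    Ties are broken by index, consistently for both spaces.
    """
    values = np.asarray(dist.values, dtype=np.float64)
    n = values.shape[0]
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < N")
    coords = emb.coords
    d_emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    overlap = 0.0
    for i in range(n):
        orig = np.argsort(values[i], kind="stable")
        near = np.argsort(d_emb[i], kind="stable")
        orig_k = set(orig[orig != i][:k].tolist())
        near_k = set(near[near != i][:k].tolist())
        overlap += len(orig_k & near_k) / k
    return overlap / n
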