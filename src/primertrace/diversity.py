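"""Community diversity computations.

Seeded rarefaction (without-replacement subsampling to a common depth),
observed-ASV richness, Bray–Curtis dissimilarity and classical PCoA.
Rarefaction draws from the multivariate hypergeometric distribution, so
every rarefied sample sums exactly to the requested depth and rare taxa can
drop out — the same finite-depth mechanism invoked to explain "unique" ASVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 10_000


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample × sample distance matrix with zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class Ordination:
    """PCoA result: sample coordinates and per-axis explained variance.

    ``explained`` is the fraction of positive-eigenvalue variance per axis,
    non-increasing, each in [0, 1].
    """

    coordinates: pd.DataFrame
    explained: np.ndarray

    def __post_init__(self) -> None:
        e = self.explained
        if np.any((e < 0) | (e > 1)) or np.any(np.diff(e) > 1e-12) or e.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must be non-increasing values in [0,1]")


def rarefy(table: CountTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int = 0) -> CountTable:
    """Subsample every sample, without replacement, to exactly ``depth`` reads.

    Raises if any sample is below ``depth`` (no silent dropping) — the
    offending sample is named.  Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_depths()
    low = totals[totals < depth]
    if len(low):
        raise ValueError(
            f"sample {low.index[0]!r} has {int(low.iloc[0])} reads, below depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CountTable(rarefied, table.metadata)


def observed_asvs(sample: np.ndarray | pd.Series) -> int:
    """Observed-ASV richness: the number of taxa with at least one read."""
    v = np.asarray(sample)
    if np.any(v < 0):
        raise ValueError("counts must be non-negative")
    return int((v > 0).sum())


def richness(table: CountTable) -> pd.Series:
    """Observed-ASV richness per sample."""
    return table.counts.gt(0).sum(axis=1).rename("observed_asvs")


def bray_curtis(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series) -> float:
    """Bray–Curtis dissimilarity: Σ|a_i − b_i| / Σ(a_i + b_i), in [0, 1]."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(av < 0) or np.any(bv < 0):
        raise ValueError("counts must be non-negative")
    total = (av + bv).sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(av - bv).sum() / total)


def bray_curtis_matrix(table: CountTable) -> DistanceMatrix:
    """All-pairs Bray–Curtis distances between the table's samples."""
    x = table.counts.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(x[i], x[j])
    return DistanceMatrix(tuple(table.sample_ids), d)


def pcoa(dm: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical principal coordinates analysis (metric MDS).

    Squares the distances, double-centers, eigendecomposes; axes are ordered
    by descending eigenvalue and only positive eigenvalues enter the
    explained-variance denominator.  Negative eigenvalues (possible for
    non-Euclidean input such as Bray–Curtis) are logged, never silently
    hidden.  The sign of each axis is fixed so its largest-magnitude loading
    is positive.
    """
    n = len(dm.sample_ids)
    if not (0 < k < n):
        raise ValueError(f"k must satisfy 0 < k < n samples ({n})")
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    negative = eigvals[eigvals < -1e-10]
    if negative.size:
        logger.warning(
            "PCoA: %d negative eigenvalue(s), most negative %.3g (non-Euclidean input)",
            negative.size,
            float(negative.min()),
        )
    positive = np.clip(eigvals, 0.0, None)
    denom = positive.sum()
    if denom == 0:
        raise ValueError("all eigenvalues non-positive; distances carry no variance")
    coords = eigvecs[:, :k] * np.sqrt(positive[:k])
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    explained = positive[:k] / denom
    frame = pd.DataFrame(
        coords, index=list(dm.sample_ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return Ordination(frame, explained)
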