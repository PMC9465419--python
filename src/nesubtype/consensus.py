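"""Consensus clustering of samples and discordant-label filtering.

Training labels for tumor subtypes come from pathology and are imperfect.
Before signature discovery, samples whose transcriptional pattern contradicts
their pathological label are removed: samples are consensus-clustered
(repeated subsampled hierarchical clustering, Pearson-correlation distance,
Ward linkage, on the most variable genes), each cluster is named after the
majority pathological side among its members, and samples sitting in a
cluster of the opposite side are flagged as discordant.

The number of clusters k is chosen by the PAC criterion (proportion of
ambiguous clustering): the k whose consensus values are most concentrated
near 0 and 1 — i.e. the smallest fraction of sample pairs with ambiguous
co-clustering rates — wins, with ties going to the smaller k.  The area
under each k's consensus CDF is reported alongside for diagnostics.  For
binary label-cleaning steps the clustering is run directly at k = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import (
    ExpressionMatrix,
    LabelTable,
    NesubtypeError,
    ValidationError,
)

__all__ = [
    "ClusteringConfig",
    "ConsensusResult",
    "AmbiguousMappingError",
    "top_variable_genes",
    "consensus_cluster",
    "flag_discordant",
    "filter_discordant",
]


class AmbiguousMappingError(NesubtypeError):
    """A cluster's pathological sides are split exactly 50/50."""


@dataclass(frozen=True)
class ClusteringConfig:
    """Parameters of the resampled clustering.

    Defaults (80% sample subsampling, 1000 resamples, top 1000 variable
    genes, k from 2 to 10) follow the conventional consensus-clustering
    setup; all are configurable.
    """

    k_range: tuple[int, int] = (2, 10)
    n_resamples: int = 1000
    sample_fraction: float = 0.8
    n_top_genes: int = 1000
    pac_band: tuple[float, float] = (0.1, 0.9)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValidationError(f"invalid k_range {self.k_range}")
        if not 0 < self.sample_fraction <= 1:
            raise ValidationError("sample_fraction must be in (0, 1]")
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")


@dataclass(frozen=True)
class ConsensusResult:
    """Per-k consensus matrices plus the chosen k and its hard assignment."""

    consensus: dict  # k -> sample × sample DataFrame of co-clustering rates
    cdf_areas: dict  # k -> area under the consensus-value CDF
    pac: dict  # k -> proportion of ambiguous consensus values
    chosen_k: int
    assignment: dict  # sample id -> cluster index (1-based) at chosen_k


def top_variable_genes(matrix: ExpressionMatrix, n: int) -> list[str]:
    """The ``n`` genes with the largest variance across samples.

    Ties are broken by gene-id order; ``n`` larger than the gene count raises.
    """
    if n > matrix.shape[0]:
        raise ValidationError(
            f"requested {n} genes but matrix has only {matrix.shape[0]}"
        )
    var = matrix.data.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    order = sorted(matrix.gene_ids, key=lambda g: (-var[g], g))
    return order[:n]


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 − Pearson r between sample columns of a genes × samples array."""
    r = np.corrcoef(x.T)
    # constant columns yield NaN correlation; treat as maximally distant
    r = np.nan_to_num(r, nan=-1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values over [0, 1]."""
    xs = np.sort(values)
    grid = np.concatenate(([0.0], xs, [1.0]))
    cdf = np.searchsorted(xs, grid, side="right") / xs.size
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def consensus_cluster(
    matrix: ExpressionMatrix, config: ClusteringConfig = ClusteringConfig()
) -> ConsensusResult:
    """Resampled hierarchical clustering with co-clustering bookkeeping.

    For each resample, ``sample_fraction`` of the samples are drawn without
    replacement and Ward-clustered on Pearson-correlation distance over the
    top variable genes; the tree is cut at every k in ``k_range``.
    ``consensus(i, j)`` is the fraction of co-draws in which i and j landed in
    the same cluster.  The final assignment Ward-cuts ``1 − consensus`` at the
    chosen k.  Fixed seed ⇒ identical result.
    """
    sample_ids = matrix.sample_ids
    n = len(sample_ids)
    k_lo, k_hi = config.k_range
    k_hi = min(k_hi, n - 1)
    if k_hi < k_lo:
        raise ValidationError(f"k_range {config.k_range} infeasible for {n} samples")
    if n < 2 * k_hi:
        raise ValidationError(
            f"need at least {2 * k_hi} samples for k up to {k_hi}, got {n}"
        )
    genes = top_variable_genes(matrix, min(config.n_top_genes, matrix.shape[0]))
    x = matrix.subset_genes(genes).data.to_numpy()
    # complete-data requirement for correlation: impute per-gene mean
    if np.isnan(x).any():
        row_mean = np.nanmean(x, axis=1, keepdims=True)
        x = np.where(np.isnan(x), row_mean, x)

    rng = np.random.default_rng(config.rng_seed)
    m = max(2, int(round(config.sample_fraction * n)))
    ks = list(range(k_lo, k_hi + 1))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))
    for _ in range(config.n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        dist = _pearson_distance(x[:, idx])
        z = linkage(squareform(dist, checks=False), method="ward")
        grid = np.ix_(idx, idx)
        co_sampled[grid] += 1
        for k in ks:
            lab = fcluster(z, t=k, criterion="maxclust")
            co_cluster[k][grid] += lab[:, None] == lab[None, :]

    off_diag = ~np.eye(n, dtype=bool)
    if np.any(co_sampled[off_diag] == 0):
        raise NesubtypeError(
            "some sample pairs were never co-sampled; increase n_resamples "
            "or sample_fraction"
        )
    np.fill_diagonal(co_sampled, 1.0)
    lo_band, hi_band = config.pac_band
    consensus: dict[int, pd.DataFrame] = {}
    areas: dict[int, float] = {}
    pac: dict[int, float] = {}
    for k in ks:
        mat = co_cluster[k] / co_sampled
        np.fill_diagonal(mat, 1.0)
        mat = (mat + mat.T) / 2.0
        consensus[k] = pd.DataFrame(mat, index=sample_ids, columns=sample_ids)
        upper = mat[np.triu_indices(n, k=1)]
        areas[k] = _cdf_area(upper)
        pac[k] = float(np.mean((upper > lo_band) & (upper < hi_band)))

    # smallest ambiguity wins; ties go to the smaller k
    chosen_k = min(ks, key=lambda k: (pac[k], k))

    final_dist = 1.0 - consensus[chosen_k].to_numpy()
    np.fill_diagonal(final_dist, 0.0)
    z = linkage(squareform(np.clip(final_dist, 0, None), checks=False), method="ward")
    labels = fcluster(z, t=chosen_k, criterion="maxclust")
    assignment = {s: int(c) for s, c in zip(sample_ids, labels)}
    return ConsensusResult(
        consensus=consensus,
        cdf_areas=areas,
        pac=pac,
        chosen_k=chosen_k,
        assignment=assignment,
    )


def flag_discordant(
    assignment: Mapping[str, int],
    labels: LabelTable,
    grouping: Mapping[str, str],
) -> list[str]:
    """Samples whose cluster's majority pathological side is not their own.

    ``grouping`` maps each pathological label to its expected side (e.g.
    ``{"SCLC": "NE", "ADC": "non-NE", ...}``).  Each cluster is named by the
    majority side among its members; an exact 50/50 split raises
    :class:`AmbiguousMappingError` rather than choosing silently.
    """
    labels.require_samples(assignment)
    side_of = {}
    for s in assignment:
        lab = labels[s]
        if lab not in grouping:
            raise ValidationError(f"label {lab!r} has no declared side")
        side_of[s] = grouping[lab]
    cluster_side: dict[int, str] = {}
    for cluster in sorted(set(assignment.values())):
        members = [s for s in assignment if assignment[s] == cluster]
        counts: dict[str, int] = {}
        for s in members:
            counts[side_of[s]] = counts.get(side_of[s], 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(best) > 1 and best[0][1] == best[1][1]:
            raise AmbiguousMappingError(
                f"cluster {cluster}: sides split exactly {best[0][1]}/{best[1][1]}"
            )
        cluster_side[cluster] = best[0][0]
    return [s for s in assignment if side_of[s] != cluster_side[assignment[s]]]


def filter_discordant(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    grouping: Mapping[str, str],
    config: ClusteringConfig | None = None,
) -> list[str]:
    """Run the k = 2 consensus pipeline and return the discordant sample ids.

    Convenience wrapper used before each binary discovery step: clusters the
    samples at k = 2 (the binary step's natural resolution) and applies
    :func:`flag_discordant` with the supplied label → side grouping.
    """
    base = config or ClusteringConfig()
    cfg = ClusteringConfig(
        k_range=(2, 2),
        n_resamples=base.n_resamples,
        sample_fraction=base.sample_fraction,
        n_top_genes=base.n_top_genes,
        pac_band=base.pac_band,
        rng_seed=base.rng_seed,
    )
    result = consensus_cluster(matrix, cfg)
    return flag_discordant(result.assignment, labels, grouping)
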