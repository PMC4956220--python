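"""kNN change detection: change vectors, neighbours, modified z-scores, RMS ranks.

The method asks, gene by gene, whether the between-screen change of a gene's
profile is an outlier relative to the changes of the genes that look like it
in the wild type.  Because localization changes are rare, a gene's k nearest
wild-type neighbours are mostly static, so their change vectors capture the
local "global effect" (imaging conditions, morphology shifts) for that region
of feature space.  Feature-wise modified z-scores of the query's change vector
against the neighbours' change vectors are therefore corrected for global
effects; the root mean square of the z-scores over the 50 localization
features is the ranking statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .profiles import ProfileMatrix, localization_mask

logger = logging.getLogger(__name__)

#: Consistency constant relating the MAD to the standard deviation of a normal
#: distribution (1/1.4826); scales the modified z-score so it is comparable to
#: an ordinary z-score under normality.
MAD_CONSISTENCY = 0.6745
#: Analogous constant for the mean absolute deviation (sqrt(pi/2)), used when
#: the MAD degenerates to zero (Iglewicz-Hoaglin fallback).
MEANAD_CONSISTENCY = 1.2533

DEFAULT_K = 50


@dataclass
class ChangeMatrix:
    """Per-gene change vectors: wild-type profile minus perturbation profile."""

    gene_ids: list[str]
    values: np.ndarray  # (n_genes, n_features)
    feature_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.feature_labels)):
            raise ValueError("values shape does not match gene_ids x feature_labels")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.feature_labels)


@dataclass
class NeighborSet:
    """The k nearest wild-type neighbours of one gene, ascending by distance."""

    query_gene: str
    k: int
    neighbor_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.neighbor_ids) != self.k or len(self.distances) != self.k:
            raise ValueError("neighbour list length must equal k")
        if self.query_gene in self.neighbor_ids:
            raise ValueError("query gene must not be its own neighbour")
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be non-decreasing")


@dataclass
class ZScoreResult:
    """Modified z-score vector, RMS score and rank for one gene."""

    gene_id: str
    M: np.ndarray  # (n_features,)
    rms: float
    rank: int


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two profile vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("profile vectors must be finite")
    return float(np.linalg.norm(a - b))


def change_matrix(wt: ProfileMatrix, pert: ProfileMatrix) -> ChangeMatrix:
    """Wild-type minus perturbation profiles over the genes present in both.

    Genes absent from either screen are dropped (logged); the row order is
    lexicographic over the shared gene set.
    """
    if wt.feature_labels != pert.feature_labels:
        raise ValueError("feature label order differs between screens")
    shared = sorted(set(wt.gene_ids) & set(pert.gene_ids))
    if not shared:
        raise ValueError("no genes shared between the two screens")
    dropped = (len(wt.gene_ids) - len(shared)) + (len(pert.gene_ids) - len(shared))
    if dropped:
        logger.warning("dropping %d gene rows not present in both screens", dropped)
    wt_idx = {g: i for i, g in enumerate(wt.gene_ids)}
    pert_idx = {g: i for i, g in enumerate(pert.gene_ids)}
    values = np.array(
        [wt.values[wt_idx[g]] - pert.values[pert_idx[g]] for g in shared]
    )
    return ChangeMatrix(gene_ids=shared, values=values, feature_labels=list(wt.feature_labels))


def _lex_rank(gene_ids: list[str]) -> np.ndarray:
    """Rank of each gene in lexicographic order (deterministic tie-break key)."""
    order = np.argsort(np.asarray(gene_ids, dtype=object))
    rank = np.empty(len(gene_ids), dtype=int)
    rank[order] = np.arange(len(gene_ids))
    return rank


def _neighbor_indices(values: np.ndarray, gene_ids: list[str], k: int) -> np.ndarray:
    """(n, k) nearest-neighbour index matrix from the exact pairwise distances.

    Self is excluded; ties in distance are broken by lexicographic gene id.
    """
    n = len(gene_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    dist = cdist(values, values)
    lex = _lex_rank(gene_ids)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((lex, dist[i]))
        order = order[order != i]
        neighbors[i] = order[:k]
    return neighbors


def find_neighbors(wt: ProfileMatrix, query_gene: str, k: int = DEFAULT_K) -> NeighborSet:
    """The k genes nearest to ``query_gene`` in wild-type profile space."""
    if query_gene not in wt.gene_ids:
        raise KeyError(f"gene {query_gene!r} not in profile matrix")
    n = len(wt.gene_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    i = wt.gene_ids.index(query_gene)
    dist = cdist(wt.values[i : i + 1], wt.values)[0]
    lex = _lex_rank(wt.gene_ids)
    order = np.lexsort((lex, dist))
    order = order[order != i][:k]
    return NeighborSet(
        query_gene=query_gene,
        k=k,
        neighbor_ids=[wt.gene_ids[j] for j in order],
        distances=dist[order],
    )


def modified_zscores(
    query_change: np.ndarray,
    neighbor_changes: np.ndarray,
    z_cap: float = 10.0,
) -> np.ndarray:
    """Feature-wise modified z-scores of a change vector against its neighbours.

    For feature i, M_i = 0.6745 (x_i - med_i) / MAD_i where med_i and MAD_i are
    the median and median absolute deviation of the neighbours' change values.
    When MAD_i is zero the Iglewicz-Hoaglin fallback divides by 1.2533 times
    the mean absolute deviation about the median; when that is also zero, M_i
    is 0 for a query exactly at the (degenerate) median and +/- ``z_cap``
    otherwise, so a single constant feature cannot contribute an infinity.
    """
    x = np.asarray(query_change, dtype=float)
    nc = np.asarray(neighbor_changes, dtype=float)
    if nc.ndim != 2 or nc.shape[1] != x.shape[0]:
        raise ValueError("neighbor_changes must be (k, n_features) matching the query")
    if nc.shape[0] < 2:
        raise ValueError("need at least 2 neighbours")
    if not (np.isfinite(x).all() and np.isfinite(nc).all()):
        raise ValueError("inputs must be finite")
    med = np.median(nc, axis=0)
    absdev = np.abs(nc - med)
    mad = np.median(absdev, axis=0)
    dev = x - med
    M = np.zeros_like(dev)
    ok = mad > 0
    M[ok] = MAD_CONSISTENCY * dev[ok] / mad[ok]
    if not ok.all():
        meanad = absdev.mean(axis=0)
        fb = ~ok & (meanad > 0)
        M[fb] = dev[fb] / (MEANAD_CONSISTENCY * meanad[fb])
        deg = ~ok & (meanad <= 0) & (dev != 0)
        M[deg] = np.sign(dev[deg]) * z_cap
    return M


def rms_score(M: np.ndarray, localization_mask: np.ndarray) -> float:
    """Root mean square of the modified z-scores over the masked features."""
    M = np.asarray(M, dtype=float)
    mask = np.asarray(localization_mask, dtype=bool)
    if mask.shape != M.shape:
        raise ValueError("mask shape must match M")
    if not mask.any():
        raise ValueError("localization mask selects no features")
    sel = M[mask]
    return float(np.sqrt(np.mean(sel**2)))


def _batch_zscores(
    change_values: np.ndarray, neighbor_idx: np.ndarray, z_cap: float
) -> np.ndarray:
    """Modified z-scores for every gene at once (vectorized over genes)."""
    nc = change_values[neighbor_idx]  # (n, k, f)
    med = np.median(nc, axis=1)
    absdev = np.abs(nc - med[:, None, :])
    mad = np.median(absdev, axis=1)
    dev = change_values - med
    M = np.zeros_like(dev)
    ok = mad > 0
    M[ok] = MAD_CONSISTENCY * dev[ok] / mad[ok]
    if not ok.all():
        meanad = absdev.mean(axis=1)
        fb = ~ok & (meanad > 0)
        M[fb] = dev[fb] / (MEANAD_CONSISTENCY * meanad[fb])
        deg = ~ok & (meanad <= 0) & (dev != 0)
        M[deg] = np.sign(dev[deg]) * z_cap
    return M


def rank_genes(
    wt: ProfileMatrix,
    pert: ProfileMatrix,
    k: int = DEFAULT_K,
    z_cap: float = 10.0,
) -> list[ZScoreResult]:
    """Rank genes by descending RMS modified z-score (rank 1 = strongest hit).

    Both screens must contain the same genes (shared filtering) with the same
    feature-label order.  RMS ties are broken by lexicographic gene id.
    """
    if wt.feature_labels != pert.feature_labels:
        raise ValueError("feature label order differs between screens")
    if set(wt.gene_ids) != set(pert.gene_ids):
        diff = sorted(set(wt.gene_ids) ^ set(pert.gene_ids))
        raise ValueError(f"gene sets differ between screens; symmetric difference: {diff}")
    change = change_matrix(wt, pert)
    # align wild-type profile rows to the change-matrix gene order
    wt_idx = {g: i for i, g in enumerate(wt.gene_ids)}
    wt_values = wt.values[[wt_idx[g] for g in change.gene_ids]]
    neighbor_idx = _neighbor_indices(wt_values, change.gene_ids, k)
    M = _batch_zscores(change.values, neighbor_idx, z_cap)
    mask = localization_mask(change.feature_labels)
    rms = np.sqrt(np.mean(M[:, mask] ** 2, axis=1))
    lex = _lex_rank(change.gene_ids)
    order = np.lexsort((lex, -rms))  # descending rms, ties by gene id
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    results = [
        ZScoreResult(gene_id=g, M=M[i], rms=float(rms[i]), rank=int(ranks[i]))
        for i, g in enumerate(change.gene_ids)
    ]
    results.sort(key=lambda r: r.rank)
    return results


def ranking_frame(results: list[ZScoreResult], feature_labels: list[str]) -> pd.DataFrame:
    """Tabular view of a ranking: gene_id, rank, rms, then one M column per feature."""
    rows = {
        "gene_id": [r.gene_id for r in results],
        "rank": [r.rank for r in results],
        "rms": [r.rms for r in results],
    }
    Mmat = np.array([r.M for r in results])
    for j, lbl in enumerate(feature_labels):
        rows[f"M_{lbl}"] = Mmat[:, j]
    return pd.DataFrame(rows)
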