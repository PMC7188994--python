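"""Distance-matrix clustering of conformational ensembles.

Frames are compared through their internal Cα–Cα distance matrices, which
makes the dissimilarity invariant under per-frame rigid-body motion (no
prior superposition is needed).  The frame-to-frame dissimilarity is

    D(i, j) = sqrt( (1/N₂) Σ_{m<n} (d^i_{mn} − d^j_{mn})² )

with N₂ the number of unordered residue pairs; the root scale makes the Å
cutoff dimensionally meaningful.  Clusters are obtained by average-linkage
agglomerative clustering cut at the cutoff (a deterministic single-pass
"leader" alternative is available), and each cluster is summarised by its
medoid and its population.

Ensembles beyond ``max_exact_frames`` are clustered on an evenly strided
subsample; remaining frames join the cluster of the nearest medoid, which
preserves populations within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import SelectionError
from .structures import AtomSelector, CA_SELECTOR, Ensemble, Structure

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "ca_distance_matrix",
    "ensemble_dissimilarity",
    "pairwise_frame_dissimilarity",
    "cluster_ensemble",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Cα–Cα distance matrix of one conformer."""

    values: np.ndarray
    residue_ids: tuple

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def condensed(self) -> np.ndarray:
        """Upper-triangle (m<n) entries in scipy condensed order."""
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    n_clusters: int
    populations: np.ndarray
    medoid_frames: np.ndarray
    cutoff: float

    def frames_of(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


def _ca_coords(structure: Structure, selector: AtomSelector) -> tuple[np.ndarray, tuple]:
    sub = structure.select(selector)
    if sub is None or len(sub) < 2:
        raise SelectionError("need at least 2 Cα atoms for a distance matrix")
    ids = tuple(
        zip(sub.chain_id.tolist(), sub.residue_number.tolist(), sub.icode.tolist())
    )
    return sub.coords, ids


def ca_distance_matrix(
    structure: Structure, selector: AtomSelector = CA_SELECTOR
) -> DistanceMatrix:
    """Pairwise Euclidean Cα–Cα distances of the selected residues."""
    coords, ids = _ca_coords(structure, selector)
    return DistanceMatrix(values=squareform(pdist(coords)), residue_ids=ids)


def ensemble_dissimilarity(dm_i: DistanceMatrix, dm_j: DistanceMatrix) -> float:
    """Root-mean-square difference of two distance matrices over residue pairs, Å."""
    if dm_i.values.shape != dm_j.values.shape:
        raise ValueError("distance matrices must have equal dimensions")
    if dm_i.residue_ids != dm_j.residue_ids:
        raise ValueError("distance matrices must share the residue ordering")
    di, dj = dm_i.condensed, dm_j.condensed
    n2 = di.size
    return float(np.sqrt(np.sum((di - dj) ** 2) / n2))


def _frame_features(ensemble: Ensemble, selector: AtomSelector) -> np.ndarray:
    """(n_frames, N₂) condensed distance-matrix rows, consistent ordering."""
    coords0, ids0 = _ca_coords(ensemble[0], selector)
    rows = [pdist(coords0)]
    for frame in ensemble.frames[1:]:
        coords, ids = _ca_coords(frame, selector)
        if ids != ids0:
            raise SelectionError("selector resolves differently across frames")
        rows.append(pdist(coords))
    return np.asarray(rows)


def pairwise_frame_dissimilarity(
    ensemble: Ensemble, selector: AtomSelector = CA_SELECTOR
) -> np.ndarray:
    """Condensed frame-to-frame D(i,j) matrix (scipy pdist layout)."""
    feats = _frame_features(ensemble, selector)
    n2 = feats.shape[1]
    return pdist(feats) / np.sqrt(n2)


def _leader_cluster(dmat: np.ndarray, cutoff: float) -> np.ndarray:
    """Single-pass leader clustering: join the first leader within cutoff."""
    n = dmat.shape[0]
    labels = -np.ones(n, dtype=int)
    leaders: list[int] = []
    for i in range(n):
        for c, lead in enumerate(leaders):
            if dmat[i, lead] < cutoff:
                labels[i] = c
                break
        else:
            leaders.append(i)
            labels[i] = len(leaders) - 1
    return labels


def _medoid(dmat: np.ndarray, members: np.ndarray) -> int:
    sub = dmat[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=0))])


def cluster_ensemble(
    ensemble: Ensemble,
    selector: AtomSelector = CA_SELECTOR,
    cutoff: float = 1.5,
    *,
    method: str = "average",
    max_exact_frames: int = 5000,
) -> ClusterResult:
    """Cluster ensemble frames at a dissimilarity *cutoff* (Å).

    ``method="average"`` (default) cuts an average-linkage dendrogram at the
    cutoff; ``method="leader"`` is the single-pass alternative.  Cluster
    indices are ordered by descending population (ties by first frame).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(ensemble)
    stride = max(1, int(np.ceil(n / max_exact_frames)))
    core = np.arange(0, n, stride)

    feats = _frame_features(ensemble, selector)
    n2 = feats.shape[1]
    core_cond = pdist(feats[core]) / np.sqrt(n2)
    core_sq = squareform(core_cond, checks=False)

    if core.size == 1:
        core_labels = np.zeros(1, dtype=int)
    elif method == "average":
        z = linkage(core_cond, method="average")
        core_labels = fcluster(z, t=cutoff, criterion="distance") - 1
    elif method == "leader":
        core_labels = _leader_cluster(core_sq, cutoff)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    cluster_ids = np.unique(core_labels)
    medoids_core = np.array(
        [_medoid(core_sq, np.nonzero(core_labels == c)[0]) for c in cluster_ids]
    )
    medoid_frames = core[medoids_core]

    labels = np.empty(n, dtype=int)
    labels[core] = np.searchsorted(cluster_ids, core_labels)
    rest = np.setdiff1d(np.arange(n), core)
    if rest.size:
        # assign leftover frames to the nearest medoid's cluster
        d = cdist(feats[rest], feats[medoid_frames]) / np.sqrt(n2)
        labels[rest] = np.argmin(d, axis=1)

    # deterministic relabelling: descending population, ties by first frame
    sizes = np.bincount(labels, minlength=cluster_ids.size)
    first = np.array(
        [np.nonzero(labels == c)[0][0] for c in range(cluster_ids.size)]
    )
    order = np.lexsort((first, -sizes))
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    labels = remap[labels]
    medoid_frames = medoid_frames[order]
    populations = np.bincount(labels, minlength=order.size) / n

    return ClusterResult(
        labels=labels,
        n_clusters=int(order.size),
        populations=populations,
        medoid_frames=medoid_frames,
        cutoff=float(cutoff),
    )
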