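"""Connectivity-based parcellation of white-matter ROIs and reliability stats.

The parcellation pipeline mirrors the clustering workflow used to localize
tract bodies: track from every voxel of a coronal white-matter ROI to the
whole brain, correlate the connectivity rows into a similarity matrix,
k-means the similarity profiles, and map clusters to tracts.  Cluster maps
across subjects become probability maps from which equal-sized, disjoint
seed and waypoint masks are drawn.

Reliability statistics (Dice against a permutation null, the hierarchy
index between consecutive cluster counts, correspondence percentage, and
cluster-transition flows) quantify how stable and nested the solutions are.

The similarity measure is the Pearson correlation of connectivity rows and
the hierarchy index is the parent-containment fraction; both are standard
reconstructions where the source workflow leaves the formula open, and are
documented as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .tracking import OrientationField, TrackingParams, track_connectivity

__all__ = [
    "RoiSpec",
    "ClusterSolution",
    "TractMaskSet",
    "roi_voxels",
    "roi_connectivity_matrix",
    "similarity_matrix",
    "cluster",
    "assign_clusters_to_tracts",
    "probability_maps",
    "derive_masks",
    "dice",
    "dice_permutation_null",
    "hierarchy_index",
    "hierarchy_permutation_null",
    "correspondence_percentage",
    "cluster_transition",
]


@dataclass
class RoiSpec:
    """A slab ROI: consecutive slices along one axis, restricted to a mask."""

    axis_position: int
    n_slices: int = 3
    include_mask: np.ndarray | None = None
    exclude_masks: list = dc_field(default_factory=list)
    axis: int = 1  # the phantom's longitudinal axis plays the coronal role

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass
class ClusterSolution:
    voxels: np.ndarray           # (m, 3) ROI voxel coordinates
    labels: np.ndarray           # per-voxel cluster id in 1..k
    k: int
    subject_id: object = None

    def mask(self, cluster_id: int, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        sel = self.voxels[self.labels == cluster_id]
        out[tuple(sel.T)] = True
        return out


@dataclass
class TractMaskSet:
    """Equal-sized, pairwise-disjoint seed/waypoint masks per tract."""

    masks: dict                  # tract -> {position -> bool volume}
    n_voxels_per_mask: int

    def positions(self) -> list:
        first = next(iter(self.masks.values()))
        return list(first.keys())


# --------------------------------------------------------------------------
# ROI tracking and clustering
# --------------------------------------------------------------------------

def roi_voxels(roi: RoiSpec, shape) -> np.ndarray:
    """Integer voxel coordinates of the ROI, in C order."""
    lo = roi.axis_position - roi.n_slices // 2
    sel = np.zeros(shape, dtype=bool)
    index = [slice(None)] * 3
    index[roi.axis] = slice(max(lo, 0), max(lo + roi.n_slices, 0))
    sel[tuple(index)] = True
    if roi.include_mask is not None:
        sel &= np.asarray(roi.include_mask, bool)
    for m in roi.exclude_masks:
        sel &= ~np.asarray(m, bool)
    voxels = np.argwhere(sel)
    if len(voxels) == 0:
        raise ValueError("ROI is empty")
    return voxels


def roi_connectivity_matrix(roi: RoiSpec, field: OrientationField,
                            params: TrackingParams, *,
                            termination: np.ndarray | None = None):
    """ROI-voxel x brain-voxel connectivity from unconstrained tracking.

    Row ``v`` counts, per brain voxel, the streamlines seeded at ROI voxel
    ``v`` that visited it (binary per streamline).  No waypoints or
    exclusions apply; streamlines terminate at gray matter.
    Returns ``(matrix, voxels)`` with a dense float matrix.
    """
    voxels = roi_voxels(roi, field.shape)
    conn = track_connectivity(field, voxels, params, termination=termination)
    return np.asarray(conn.todense(), dtype=np.float64), voxels


def similarity_matrix(conn: np.ndarray) -> np.ndarray:
    """Pearson correlation between connectivity rows.

    Rows with zero variance get similarity 0 to all others (diagonal stays
    1); the result is exactly symmetric with a unit diagonal.
    """
    conn = np.asarray(conn, dtype=np.float64)
    if conn.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    centered = conn - conn.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    sim = np.zeros((conn.shape[0], conn.shape[0]))
    if ok.any():
        unit = centered[ok] / norms[ok, None]
        block = unit @ unit.T
        sim[np.ix_(ok, ok)] = np.clip(block, -1.0, 1.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return sim


def _canonical_labels(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel 1..k by descending cluster size, ties by lowest voxel index."""
    order = sorted(
        range(k),
        key=lambda c: (-int((labels == c).sum()),
                       int(np.flatnonzero(labels == c)[0])),
    )
    lut = np.empty(k, dtype=np.int64)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return lut[labels]


def cluster(similarity: np.ndarray, k: int, seed: int, *,
            voxels: np.ndarray | None = None,
            subject_id=None, n_init: int = 50) -> ClusterSolution:
    """k-means on the rows of the similarity matrix (similarity profiles)."""
    similarity = np.asarray(similarity, dtype=np.float64)
    n = similarity.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} ROI voxels")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed))
    raw = km.fit_predict(similarity)
    labels = _canonical_labels(raw, k)
    if voxels is None:
        voxels = np.arange(n)[:, None]
    return ClusterSolution(voxels=np.asarray(voxels), labels=labels, k=k,
                           subject_id=subject_id)


def assign_clusters_to_tracts(solution: ClusterSolution,
                              reference: np.ndarray) -> dict:
    """Optimal one-to-one cluster-to-tract assignment by reference overlap.

    The reference is a ground-truth label volume (the phantom stand-in for
    anatomical knowledge).  Overlap is maximized with the Hungarian method;
    ties break toward the lowest tract id and clusters with zero overlap to
    every label map to ``None`` (unassigned).
    """
    reference = np.asarray(reference)
    ref_ids = sorted(int(r) for r in np.unique(reference) if r > 0)
    k = solution.k
    if k > len(ref_ids) + 1:
        raise ValueError(
            f"{k} clusters cannot map to {len(ref_ids)} reference labels "
            "plus one unassigned slot")
    ref_at = reference[tuple(solution.voxels.T)]
    overlap = np.zeros((k, len(ref_ids)))
    for ci in range(k):
        at = ref_at[solution.labels == ci + 1]
        for rj, rid in enumerate(ref_ids):
            overlap[ci, rj] = int((at == rid).sum())
    # maximize overlap; nudge ties toward the lowest tract id
    cost = -(overlap - 1e-9 * np.arange(len(ref_ids))[None, :])
    rows, cols = linear_sum_assignment(cost[:, :])
    mapping = {ci + 1: None for ci in range(k)}
    for ci, rj in zip(rows, cols):
        if overlap[ci, rj] > 0:
            mapping[ci + 1] = ref_ids[rj]
    return mapping


def probability_maps(solutions, mappings, shape) -> dict:
    """Fraction of subjects whose assigned cluster contains each voxel.

    ``solutions`` and ``mappings`` are parallel per-subject lists; the
    result maps each tract id to a probability volume with values in
    {0, 1/n, ..., 1}.
    """
    if len(solutions) == 0:
        raise ValueError("need at least one subject")
    tracts = sorted({t for m in mappings for t in m.values() if t is not None})
    acc = {t: np.zeros(shape, dtype=np.float64) for t in tracts}
    for sol, mapping in zip(solutions, mappings):
        for cid, tract in mapping.items():
            if tract is None:
                continue
            acc[tract][sol.mask(cid, shape)] += 1.0
    n = float(len(solutions))
    return {t: v / n for t, v in acc.items()}


def derive_masks(prob_maps: dict, n_voxels: int) -> TractMaskSet:
    """Top-probability voxel masks per tract and position, conflict-resolved.

    Each tract claims its ``n_voxels`` highest-probability voxels at each
    position; a voxel claimed by several tracts goes to the tract with the
    higher probability there (ties to the lowest tract id) and losers move
    to their next-best voxel.  The result has equal-sized masks that are
    pairwise disjoint across tracts.
    """
    tracts = sorted(prob_maps.keys(), key=str)
    positions = list(next(iter(prob_maps.values())).keys())
    masks = {t: {} for t in tracts}
    for pos in positions:
        ranked = {}
        for t in tracts:
            vol = np.asarray(prob_maps[t][pos], dtype=np.float64).ravel()
            order = np.lexsort((np.arange(vol.size), -vol))
            ranked[t] = (vol, order[vol[order] > 0])
        lost = {t: set() for t in tracts}
        while True:
            claims = {}
            for t in tracts:
                vol, order = ranked[t]
                chosen = [v for v in order if v not in lost[t]][:n_voxels]
                if len(chosen) < n_voxels:
                    raise ValueError(
                        f"tract '{t}' position '{pos}': fewer than "
                        f"{n_voxels} available voxels")
                claims[t] = chosen
            conflict = False
            claimed_by = {}
            for t in tracts:
                for v in claims[t]:
                    claimed_by.setdefault(v, []).append(t)
            for v, owners in claimed_by.items():
                if len(owners) > 1:
                    conflict = True
                    winner = max(
                        owners,
                        key=lambda t: (ranked[t][0][v], -tracts.index(t)))
                    for t in owners:
                        if t != winner:
                            lost[t].add(v)
            if not conflict:
                break
        shape = np.asarray(prob_maps[tracts[0]][pos]).shape
        for t in tracts:
            m = np.zeros(int(np.prod(shape)), dtype=bool)
            m[np.asarray(claims[t], dtype=np.int64)] = True
            masks[t][pos] = m.reshape(shape)
    return TractMaskSet(masks=masks, n_voxels_per_mask=n_voxels)


# --------------------------------------------------------------------------
# reliability statistics
# --------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) between binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / denom


def _per_cluster_dice(labels_a, labels_b, ids):
    return {c: (2.0 * int(((labels_a == c) & (labels_b == c)).sum())
                / max(int((labels_a == c).sum()) + int((labels_b == c).sum()), 1))
            for c in ids}


def dice_permutation_null(sol_a: ClusterSolution, sol_b: ClusterSolution,
                          n_perm: int, seed: int):
    """Observed per-cluster Dice plus the (min, max) of a permutation null.

    The null permutes the voxel-to-cluster labels of one solution ``n_perm``
    times and recomputes every per-cluster Dice.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(sol_a.labels) != len(sol_b.labels):
        raise ValueError("solutions cover different ROIs")
    ids = sorted(set(sol_a.labels) | set(sol_b.labels))
    observed = _per_cluster_dice(sol_a.labels, sol_b.labels, ids)
    rng = np.random.default_rng(int(seed))
    null = np.empty((n_perm, len(ids)))
    for p in range(n_perm):
        perm = rng.permutation(sol_b.labels)
        vals = _per_cluster_dice(sol_a.labels, perm, ids)
        null[p] = [vals[c] for c in ids]
    return observed, (float(null.min()), float(null.max()))


def hierarchy_index(sol_k: ClusterSolution, sol_k1: ClusterSolution) -> float:
    """Fraction of ROI voxels nested when the cluster count grows by one.

    Each (k+1)-cluster is assigned the k-cluster parent with maximal
    overlap; the index is the fraction of voxels contained in their
    cluster's parent.  1.0 for a perfect refinement; invariant under
    relabeling of either solution.
    """
    if len(sol_k.labels) != len(sol_k1.labels):
        raise ValueError("solutions cover different ROIs")
    if sol_k1.k != sol_k.k + 1:
        raise ValueError("expected a (k, k+1) pair of solutions")
    return _containment_fraction(sol_k.labels, sol_k1.labels)


def _containment_fraction(parent_labels: np.ndarray,
                          child_labels: np.ndarray) -> float:
    n = len(parent_labels)
    contained = 0
    for c in np.unique(child_labels):
        in_child = child_labels == c
        parents, counts = np.unique(parent_labels[in_child], return_counts=True)
        contained += int(counts.max())
    return contained / n


def hierarchy_permutation_null(sol_k: ClusterSolution, sol_k1: ClusterSolution,
                               n_perm: int = 1000, seed: int = 0):
    """(observed, null array) of the hierarchy index; the null permutes the
    (k+1)-solution's voxel-to-cluster labels."""
    observed = hierarchy_index(sol_k, sol_k1)
    rng = np.random.default_rng(int(seed))
    null = np.array([
        _containment_fraction(sol_k.labels, rng.permutation(sol_k1.labels))
        for _ in range(n_perm)])
    return observed, null


def correspondence_percentage(parent_cluster: np.ndarray,
                              child_union: np.ndarray) -> float:
    """Percentage overlap 100 |A n B| / |A u B| (symmetric)."""
    a = np.asarray(parent_cluster, dtype=bool)
    b = np.asarray(child_union, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("both sets are empty")
    return 100.0 * int((a & b).sum()) / union


def cluster_transition(sol_k: ClusterSolution,
                       sol_k1: ClusterSolution) -> pd.DataFrame:
    """Flow table: percentage of each parent cluster's voxels per child.

    Rows are parent clusters, columns child clusters; each row sums to 100.
    """
    if len(sol_k.labels) != len(sol_k1.labels):
        raise ValueError("solutions cover different ROIs")
    parents = sorted(np.unique(sol_k.labels))
    children = sorted(np.unique(sol_k1.labels))
    table = np.zeros((len(parents), len(children)))
    for i, p in enumerate(parents):
        in_p = sol_k.labels == p
        total = int(in_p.sum())
        for j, c in enumerate(children):
            table[i, j] = 100.0 * int((in_p & (sol_k1.labels == c)).sum()) / total
    return pd.DataFrame(table, index=parents, columns=children)
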