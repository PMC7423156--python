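"""Connectivity blueprints: vertex x tract matrices of connection likelihood.

A blueprint is the product of a vertexwise connectivity matrix (how well
each gray/white-border vertex reaches each brain voxel) with a tract matrix
(how well each brain voxel is reached by each named tract).  Its rows,
normalized to sum one, are the connectivity fingerprints compared across
brains by KL divergence; because the same tracts are reconstructed in both
brains, the columns define a common space.

Row normalization to unit sum is asserted here because the divergence
comparison requires probability distributions; vertices whose raw fingerprint
is identically zero keep a zero row and carry an explicit "undefined" flag
that the divergence module consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .phantom import SurfaceMesh
from .tracking import (OrientationField, TrackingParams, log_normalize,
                       track_connectivity)

__all__ = [
    "VertexConnectivity",
    "Blueprint",
    "vertex_connectivity",
    "build_blueprint",
    "surface_projection",
    "smooth_surface_map",
    "mask_blueprint",
    "tract_territory",
]

_FWHM_TO_SD = 2.3548200450309493  # 2 sqrt(2 ln 2)


@dataclass
class VertexConnectivity:
    """Vertices x brain-voxels visitation matrix from surface-seeded tracking."""

    matrix: sparse.csr_matrix
    surface: SurfaceMesh
    params: TrackingParams
    seed_voxel: np.ndarray  # per-vertex launch voxel index triple (-1: none)


@dataclass
class Blueprint:
    """Vertex x tract matrix; rows are fingerprints normalized to sum 1."""

    matrix: np.ndarray              # normalized rows (or all-zero)
    raw: np.ndarray                 # pre-normalization product
    tract_names: list
    surface: SurfaceMesh | None = None
    vertex_ids: np.ndarray | None = None
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.vertex_ids is None:
            self.vertex_ids = np.arange(self.matrix.shape[0])
        if self.defined is None:
            self.defined = self.matrix.sum(axis=1) > 0
        sums = self.matrix.sum(axis=1)
        bad = self.defined & ~np.isclose(sums, 1.0, atol=1e-9)
        if bad.any():
            raise ValueError("defined blueprint rows must sum to 1")

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]

    def fingerprint(self, vertex: int) -> np.ndarray:
        return self.matrix[vertex]

    def column(self, tract: str) -> int:
        if tract not in self.tract_names:
            raise KeyError(f"unknown tract '{tract}'")
        return self.tract_names.index(tract)


def vertex_connectivity(surface: SurfaceMesh, field: OrientationField,
                        params: TrackingParams, *, wm_mask: np.ndarray,
                        termination: np.ndarray | None = None,
                        max_seed_distance_vox: float = 2.0) -> VertexConnectivity:
    """Whole-surface vertexwise connectivity by unconstrained tracking.

    Each vertex launches ``params.n_samples`` streamlines from its nearest
    white-matter voxel, terminating at gray matter.  Vertices with no white
    matter within ``max_seed_distance_vox`` keep a zero row (with a
    warning).
    """
    wm_vox = np.argwhere(np.asarray(wm_mask, bool))
    if len(wm_vox) == 0:
        raise ValueError("white-matter mask is empty")
    vs = field.voxel_size
    tree = cKDTree((wm_vox + 0.5) * vs)
    dist, idx = tree.query(surface.vertices)
    ok = dist <= max_seed_distance_vox * vs
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} vertices have no adjacent white matter; "
            "their connectivity rows are zero")
    seed_voxel = np.full((surface.n_vertices, 3), -1, dtype=np.int64)
    seed_voxel[ok] = wm_vox[idx[ok]]

    conn = track_connectivity(
        field, seed_voxel[ok], params, termination=termination,
        group=np.flatnonzero(ok))
    n_vox = int(np.prod(field.shape))
    # track_connectivity sized rows by the group index (vertex id); pad to
    # the full vertex count if trailing vertices had no white matter
    if conn.shape[0] < surface.n_vertices:
        conn.resize((surface.n_vertices, n_vox))
    return VertexConnectivity(matrix=conn.tocsr(), surface=surface,
                              params=params, seed_voxel=seed_voxel)


def build_blueprint(vc, tract_matrix: np.ndarray, tract_names: list, *,
                    surface: SurfaceMesh | None = None) -> Blueprint:
    """Multiply vertex connectivity with the voxel x tract matrix.

    ``vc`` may be a :class:`VertexConnectivity` or a (sparse or dense)
    vertices x voxels matrix.  The raw product is row-normalized to sum 1;
    all-zero rows stay zero and are flagged undefined.
    """
    if isinstance(vc, VertexConnectivity):
        if surface is None:
            surface = vc.surface
        vc = vc.matrix
    tract_matrix = np.asarray(tract_matrix, dtype=float)
    if vc.shape[1] != tract_matrix.shape[0]:
        raise ValueError(
            f"inner dimensions mismatch: {vc.shape[1]} voxels vs "
            f"{tract_matrix.shape[0]} rows of the tract matrix")
    if tract_matrix.shape[1] != len(tract_names):
        raise ValueError("one tract name per tract column is required")
    raw = np.asarray(vc @ tract_matrix, dtype=float)
    sums = raw.sum(axis=1)
    defined = sums > 0
    matrix = np.zeros_like(raw)
    matrix[defined] = raw[defined] / sums[defined, None]
    return Blueprint(matrix=matrix, raw=raw, tract_names=list(tract_names),
                     surface=surface, defined=defined)


def surface_projection(bp: Blueprint, tract: str) -> np.ndarray:
    """Per-vertex scalar map of one tract: the raw (pre-normalization) column."""
    return bp.raw[:, bp.column(tract)].copy()


def smooth_surface_map(surface: SurfaceMesh, values: np.ndarray,
                       fwhm_mm: float) -> np.ndarray:
    """Gaussian-equivalent smoothing by iterated neighbor diffusion.

    Runs the symmetric graph-diffusion step
    ``x_i += lam/d_max * sum_j (x_j - x_i)`` for as many iterations as
    needed for the accumulated variance to match a Gaussian of
    sd = fwhm / 2.3548.  The operator preserves constants exactly and
    conserves the total sum; isolated vertices are untouched.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    values = np.asarray(values, dtype=float).copy()
    if fwhm_mm == 0:
        return values
    edges = surface.edges()
    if len(edges) == 0:
        return values
    n = surface.n_vertices
    deg = np.bincount(edges.ravel(), minlength=n)
    d_max = int(deg.max())
    lengths2 = np.sum(
        (surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]]) ** 2,
        axis=1)
    lam = 0.5
    # variance gained per iteration ~ lam * (mean per-vertex sum of squared
    # edge lengths) / d_max  (random-walk step variance)
    per_vertex = np.zeros(n)
    np.add.at(per_vertex, edges[:, 0], lengths2)
    np.add.at(per_vertex, edges[:, 1], lengths2)
    var_per_iter = lam * per_vertex[deg > 0].mean() / d_max
    sd = fwhm_mm / _FWHM_TO_SD
    n_iter = max(1, int(round(sd * sd / var_per_iter)))
    w = lam / d_max
    for _ in range(n_iter):
        flux = w * (values[edges[:, 0]] - values[edges[:, 1]])
        np.subtract.at(values, edges[:, 0], flux)
        np.add.at(values, edges[:, 1], flux)
    return values


def mask_blueprint(bp: Blueprint, vertex_mask: np.ndarray) -> Blueprint:
    """Restrict a blueprint to the masked vertices (rows dropped, ids kept)."""
    vertex_mask = np.asarray(vertex_mask, dtype=bool)
    if len(vertex_mask) != bp.n_vertices:
        raise ValueError("mask length must equal the vertex count")
    if not vertex_mask.any():
        raise ValueError("vertex mask is empty")
    return Blueprint(
        matrix=bp.matrix[vertex_mask], raw=bp.raw[vertex_mask],
        tract_names=list(bp.tract_names), surface=bp.surface,
        vertex_ids=bp.vertex_ids[vertex_mask], defined=bp.defined[vertex_mask])


def tract_territory(bp: Blueprint, tract: str, *, fwhm_mm: float = 2.0,
                    threshold: float = 0.7) -> np.ndarray:
    """Vertices belonging to a tract's surface territory.

    Follows the figure convention: smooth the tract's surface projection,
    log-transform and normalize it, and keep vertices at or above the
    display threshold.
    """
    if bp.surface is None:
        raise ValueError("blueprint carries no surface")
    proj = surface_projection(bp, tract)
    smoothed = smooth_surface_map(bp.surface, proj, fwhm_mm)
    display = log_normalize(np.maximum(smoothed, 0.0))
    return display >= threshold
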