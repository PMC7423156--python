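"""Synthetic "species" brains: fiber-orientation phantoms with ground truth.

Each phantom is a cuboid brain: a gray-matter shell of configurable
thickness lines the grid boundary and everything inside it is white matter.
White-matter bundles are tubes around user-specified centerlines; their end
caps reach the gray/white border, so the surface vertices over a cap carry
that bundle's ground-truth label.  Bundle voxels store the local centerline
tangent perturbed by angular noise (a stand-in for a crossing-fiber
posterior); non-bundle white matter is flagged isotropic, which makes
off-tract tracking diffuse rather than forbidden.

Because the white-matter mask depends only on the grid and the gray-matter
thickness - never on the bundles - phantoms built on the same grid share an
identical gray/white surface.  Vertex homology across phantoms is therefore
the identity on vertex indices, which is the ground truth the cross-brain
matching analyses rely on.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .tracking import OrientationField, _rotate_by_dispersion, canonical_sign

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "SurfaceMesh",
    "SpeciesPhantom",
    "VertexCorrespondence",
    "generate_phantom",
    "generate_cohort",
    "matched_pair",
]

_CENTERLINE_STEP = 0.25  # voxels; dense resampling step along centerlines
_TRUTH_RADIUS = 1.5      # voxels; vertex-to-bundle labelling distance


@dataclass
class BundleSpec:
    """A tube bundle: centerline control points (voxel coords) and radius.

    ``split_into`` models a bundle that dissociates into two subcomponents
    (e.g. a lateral / medial pair): a pair of ``(label, offset)`` entries
    where each child centerline is the parent's displaced by ``offset``
    (voxels).  ``curved`` marks bundles whose centerline bends (an
    arcuate-like dorsal tract); it is descriptive, the geometry comes from
    the control points.
    """

    label: str
    centerline: list
    radius_vox: float = 2.0
    split_into: tuple | None = None
    curved: bool = False

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError(f"bundle '{self.label}': centerline needs >= 2 points")
        if self.radius_vox < 1:
            raise ValueError(f"bundle '{self.label}': radius_vox must be >= 1")
        if self.split_into is not None and len(self.split_into) != 2:
            raise ValueError(f"bundle '{self.label}': split_into must be a pair")


@dataclass
class PhantomSpec:
    grid_shape: tuple = (36, 36, 36)
    voxel_size: float = 1.0
    bundles: list = dc_field(default_factory=list)
    gm_thickness: int = 2
    dispersion_deg: float = 10.0
    subject_jitter_vox: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be a 3-vector with all entries >= 16")
        if self.dispersion_deg < 0:
            raise ValueError("dispersion_deg must be >= 0")
        if not self.bundles:
            raise ValueError("bundles must be non-empty")
        labels = [b.label for b in self.bundles]
        for b in self.bundles:
            if b.split_into is not None:
                labels.extend(child for child, _ in b.split_into)
        if len(labels) != len(set(labels)):
            raise ValueError("bundle labels must be unique")
        if self.gm_thickness < 1:
            raise ValueError("gm_thickness must be >= 1")


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices in mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces index invalid vertices")
        self._neighbors = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def neighbors(self) -> list:
        """Adjacency list derived from the faces (cached)."""
        if self._neighbors is None:
            adj = [set() for _ in range(self.n_vertices)]
            for a, b, c in self.faces:
                adj[a].update((b, c))
                adj[b].update((a, c))
                adj[c].update((a, b))
            self._neighbors = [np.fromiter(s, dtype=np.int64) for s in adj]
        return self._neighbors

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) array."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass
class SpeciesPhantom:
    spec: PhantomSpec
    orientation_field: OrientationField
    wm_mask: np.ndarray
    gm_mask: np.ndarray
    bundle_labels: np.ndarray
    label_names: list                 # label id i+1 -> label_names[i]
    surface: SurfaceMesh
    vertex_truth: np.ndarray          # per-vertex label id (0 = none)
    homology_id: np.ndarray           # per-vertex id shared across matched phantoms

    def label_id(self, name: str) -> int:
        return self.label_names.index(name) + 1

    def bundle_mask(self, name: str) -> np.ndarray:
        return self.bundle_labels == self.label_id(name)

    def truth_names(self) -> np.ndarray:
        """Per-vertex truth as label names ('' where unlabeled)."""
        names = np.array([""] + list(self.label_names), dtype=object)
        return names[self.vertex_truth]


@dataclass
class VertexCorrespondence:
    """Homology-based vertex correspondence between two matched phantoms."""

    a_labeled: np.ndarray        # vertex indices labeled in phantom A
    b_labeled: np.ndarray
    label_map: dict              # A label name -> tuple of B label names
    a_has_counterpart: np.ndarray  # per A-labeled vertex
    b_has_counterpart: np.ndarray

    def is_identity(self) -> bool:
        return (len(self.a_labeled) == len(self.b_labeled)
                and np.array_equal(self.a_labeled, self.b_labeled))


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _resample_centerline(points: np.ndarray,
                         step: float = _CENTERLINE_STEP):
    """Dense arc-length resampling; returns (samples, unit tangents)."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate centerline (zero length)")
    s = np.linspace(0.0, total, max(2, int(np.ceil(total / step)) + 1))
    samples = np.column_stack([np.interp(s, cum, pts[:, i]) for i in range(3)])
    tangents = np.gradient(samples, s, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return samples, tangents


def _rasterize_tube(samples: np.ndarray, radius: float, shape):
    """Voxels whose center lies within ``radius`` of the sampled centerline.

    Returns (voxel index array, nearest-sample index per voxel).  Raises if
    the tube extends beyond the grid.
    """
    shape = np.asarray(shape)
    # the tube leaves the grid iff a voxel *center* outside the grid
    # (nearest at distance 0.5 beyond the boundary) could fall inside it
    if ((samples - radius < -0.5).any()
            or (samples + radius > shape + 0.5).any()):
        raise ValueError("bundle tube leaves the grid")
    lo = np.maximum(np.floor(samples.min(axis=0) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(samples.max(axis=0) + radius).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    cand = np.column_stack([g.ravel() for g in grids])
    centers = cand + 0.5
    tree = cKDTree(samples)
    dist, nearest = tree.query(centers)
    inside = dist <= radius
    return cand[inside], nearest[inside]


def _effective_bundles(spec: PhantomSpec, offsets: dict | None):
    """Expand split bundles into children and apply per-subject offsets."""
    out = []
    for b in spec.bundles:
        base = np.asarray(b.centerline, dtype=float)
        shift = np.zeros(3) if offsets is None else offsets.get(b.label, np.zeros(3))
        if b.split_into is None:
            out.append((b.label, base + shift, b.radius_vox))
        else:
            for child, child_offset in b.split_into:
                out.append((child,
                            base + shift + np.asarray(child_offset, dtype=float),
                            b.radius_vox))
    return out


def _brain_masks(spec: PhantomSpec):
    """Gray-matter shell along the grid boundary; white matter inside."""
    nx, ny, nz = spec.grid_shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    border = np.minimum.reduce([
        ix, nx - 1 - ix, iy, ny - 1 - iy, iz, nz - 1 - iz])
    gm = border < spec.gm_thickness
    return ~gm, gm


def _extract_surface(wm: np.ndarray, voxel_size: float) -> SurfaceMesh:
    verts, faces, _, _ = marching_cubes(
        wm.astype(np.float32), level=0.5,
        spacing=(voxel_size,) * 3)
    # marching_cubes places samples at voxel *centers* indexed by integers;
    # shift into the corner-based mm convention of the tracker.
    verts = verts + 0.5 * voxel_size
    return SurfaceMesh(vertices=verts, faces=faces)


def _vertex_truth(surface: SurfaceMesh, labels: np.ndarray,
                  voxel_size: float) -> np.ndarray:
    truth = np.zeros(surface.n_vertices, dtype=np.int64)
    labeled = np.argwhere(labels > 0)
    if len(labeled) == 0:
        return truth
    centers = (labeled + 0.5) * voxel_size
    tree = cKDTree(centers)
    dist, idx = tree.query(surface.vertices)
    close = dist <= _TRUTH_RADIUS * voxel_size
    truth[close] = labels[tuple(labeled[idx[close]].T)]
    return truth


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec,
                     _bundle_offsets: dict | None = None) -> SpeciesPhantom:
    """Build one phantom: orientation field, masks, labels, surface, truth.

    Distinctly labeled tubes must not overlap (error naming the colliding
    labels); tubes must stay inside the grid.  Identical spec and seed yield
    a bitwise-identical phantom.
    """
    wm, gm = _brain_masks(spec)
    shape = spec.grid_shape
    labels = np.zeros(shape, dtype=np.int16)
    bundles = _effective_bundles(spec, _bundle_offsets)
    label_names = [name for name, _, _ in bundles]

    tangent_of = {}
    for bid, (name, centerline, radius) in enumerate(bundles, start=1):
        try:
            samples, tangents = _resample_centerline(centerline)
            voxels, nearest = _rasterize_tube(samples, radius, shape)
        except ValueError as err:
            raise ValueError(f"bundle '{name}': {err}") from err
        keep = wm[tuple(voxels.T)]          # caps are clipped at the gm border
        voxels, nearest = voxels[keep], nearest[keep]
        prior = labels[tuple(voxels.T)]
        if (prior > 0).any():
            other = label_names[int(prior[prior > 0][0]) - 1]
            raise ValueError(
                f"bundle tubes overlap: '{name}' collides with '{other}'")
        labels[tuple(voxels.T)] = bid
        tangent_of[bid] = (voxels, tangents[nearest])

    orientations = np.zeros(shape + (1, 3), dtype=float)
    weights = np.zeros(shape + (1,), dtype=float)
    rng = np.random.default_rng([spec.seed, 1])
    sigma = np.radians(spec.dispersion_deg)
    for bid, (voxels, tangents) in tangent_of.items():
        u = rng.random((len(voxels), 2))
        perturbed = tangents
        if sigma > 0:
            perturbed = _rotate_by_dispersion(tangents, sigma, u[:, 0], u[:, 1])
        orientations[voxels[:, 0], voxels[:, 1], voxels[:, 2], 0] = (
            canonical_sign(perturbed))
        weights[voxels[:, 0], voxels[:, 1], voxels[:, 2], 0] = 1.0

    isotropic = wm & (labels == 0)
    field = OrientationField(
        orientations=orientations, weights=weights, isotropic=isotropic,
        dispersion_deg=spec.dispersion_deg, voxel_size=spec.voxel_size)

    surface = _extract_surface(wm, spec.voxel_size)
    truth = _vertex_truth(surface, labels, spec.voxel_size)
    return SpeciesPhantom(
        spec=spec, orientation_field=field, wm_mask=wm, gm_mask=gm,
        bundle_labels=labels, label_names=label_names, surface=surface,
        vertex_truth=truth, homology_id=np.arange(surface.n_vertices))


def _subject_offsets(spec: PhantomSpec, subject: int, attempt: int = 0) -> dict:
    """Rigid per-bundle centerline displacement, perpendicular to the chord.

    The longitudinal component is projected out so the bundle caps stay on
    the gray/white border and keep their surface territory; components are
    truncated at +-2 scales.
    """
    rng = np.random.default_rng([spec.seed + subject, 2, attempt])
    scale = spec.subject_jitter_vox
    offsets = {}
    for b in spec.bundles:
        raw = np.clip(scale * rng.normal(size=3), -2 * scale, 2 * scale)
        chord = (np.asarray(b.centerline[-1], float)
                 - np.asarray(b.centerline[0], float))
        chord /= np.linalg.norm(chord)
        offsets[b.label] = raw - np.dot(raw, chord) * chord
    return offsets


_MAX_JITTER_ATTEMPTS = 25


def generate_cohort(spec: PhantomSpec, n_subjects: int) -> list:
    """Per-subject phantoms: subject ``i`` uses seed ``spec.seed + i`` and a
    jittered copy of every centerline.  All subjects share the homology
    assignment (identical surfaces by construction).

    Jitter is drawn conditional on anatomical validity: draws that would
    interpenetrate two tubes or push one off the grid are rejected and
    redrawn (deterministically), mirroring the fact that real tract
    anatomies deform without overlapping.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cohort = []
    for i in range(n_subjects):
        sub_spec = replace(spec, seed=spec.seed + i)
        last_err = None
        for attempt in range(_MAX_JITTER_ATTEMPTS):
            try:
                cohort.append(generate_phantom(
                    sub_spec, _subject_offsets(spec, i, attempt)))
                break
            except ValueError as err:
                message = str(err)
                if ("overlap" not in message
                        and "leaves the grid" not in message):
                    raise
                last_err = err
        else:
            raise ValueError(
                f"subject {i}: no valid jitter draw in "
                f"{_MAX_JITTER_ATTEMPTS} attempts ({last_err})")
    return cohort


def matched_pair(spec_a: PhantomSpec, spec_b: PhantomSpec,
                 label_map: dict | None = None):
    """Generate two phantoms plus their ground-truth vertex correspondence.

    ``label_map`` maps each A bundle label to a B label or tuple of B labels
    (a bundle that splits into a pair in the other brain).  Labels of either
    phantom that appear on no side of the mapping yield vertices without a
    counterpart (e.g. an arcuate-like bundle present in one brain only).
    """
    if tuple(spec_a.grid_shape) != tuple(spec_b.grid_shape):
        raise ValueError("matched specs must share grid_shape")
    pa = generate_phantom(spec_a)
    pb = generate_phantom(spec_b)
    if pa.surface.n_vertices != pb.surface.n_vertices or not np.allclose(
            pa.surface.vertices, pb.surface.vertices):
        raise ValueError("matched phantoms must share the gray/white surface")

    if label_map is None:
        label_map = {name: name for name in pa.label_names
                     if name in pb.label_names}
    norm_map = {}
    missing = []
    for a_name, targets in label_map.items():
        targets = (targets,) if isinstance(targets, str) else tuple(targets)
        if a_name not in pa.label_names:
            missing.append(a_name)
        for t in targets:
            if t not in pb.label_names:
                missing.append(t)
        norm_map[a_name] = targets
    if missing:
        raise ValueError(f"unmappable bundle labels: {sorted(set(missing))}")

    a_labeled = np.flatnonzero(pa.vertex_truth > 0)
    b_labeled = np.flatnonzero(pb.vertex_truth > 0)
    a_names = pa.truth_names()
    b_names = pb.truth_names()
    mapped_b = {t for targets in norm_map.values() for t in targets}
    a_has = np.array([a_names[v] in norm_map for v in a_labeled])
    b_has = np.array([b_names[v] in mapped_b for v in b_labeled])
    corr = VertexCorrespondence(
        a_labeled=a_labeled, b_labeled=b_labeled, label_map=norm_map,
        a_has_counterpart=a_has, b_has_counterpart=b_has)
    return pa, pb, corr
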