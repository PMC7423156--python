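"""Probabilistic streamline tractography over discrete fiber-orientation fields.

The tracker emulates FSL-style probabilistic tractography at phantom scale:
streamlines are launched from every seed voxel, follow per-voxel orientation
samples (re-perturbed by the field's angular dispersion), and are gated by the
seed / waypoint / exclusion / termination protocol:

* a streamline is *retained* only if it crosses at least one waypoint mask
  (OR semantics across waypoints);
* touching any exclusion-mask voxel (including the first) *deletes* it;
* entering the termination mask *stops* it without deletion.

Visitation is counted at most once per streamline per voxel, so the
normalized tractogram value at a voxel is the probability that a retained
streamline visits it.

Randomness
----------
Every streamline ``s`` under root seed ``S`` owns the generator
``np.random.default_rng([S, s])`` and consumes a fixed schedule: 3 uniforms
for the jitter of the start position inside the seed voxel, then exactly 4
uniforms per propagation step ``(u_choice, u_axis, u_magnitude, u_z)``:

* weighted voxel: ``u_choice`` picks a stored orientation
  weight-proportionally, the orientation is rotated by a half-normal angle
  ``sigma * ndtri((1 + u_magnitude) / 2)`` about the in-plane perpendicular
  axis at angle ``2 pi u_axis`` (``u_z`` unused);
* isotropic voxel: a uniform sphere direction from
  ``z = 2 u_z - 1``, ``phi = 2 pi u_axis`` (``u_choice, u_magnitude`` unused).

Deterministic mode consumes no randomness: streamlines start at voxel
centers and follow the highest-weight orientation unperturbed.  This
counter-based design makes batch propagation bitwise-identical to
single-streamline propagation and allows an independent oracle to replay the
exact stream.

Mask tests and orientation lookups use the *containing* voxel
(``floor(position / voxel_size)``); no trilinear interpolation is performed,
which keeps the semantics exact on coarse phantom grids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import sparse
from scipy.special import ndtri

__all__ = [
    "OrientationField",
    "TrackingParams",
    "TractProtocol",
    "Tractogram",
    "Streamline",
    "sample_orientation",
    "propagate_streamline",
    "run_tractography",
    "track_connectivity",
    "average_tractograms",
    "downsample_volume",
    "log_normalize",
    "threshold_map",
    "overlap_fraction",
]

_UNIFORMS_PER_STEP = 4
_JITTER_UNIFORMS = 3


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class OrientationField:
    """Per-voxel set of undirected unit orientations with weights.

    ``orientations`` has shape ``(nx, ny, nz, k, 3)`` and stores unit vectors
    in the canonical axial sign convention (first nonzero component
    positive).  ``weights`` has shape ``(nx, ny, nz, k)``; a voxel whose
    weights sum to zero carries no orientation.  ``isotropic`` flags voxels
    where a fresh uniform random orientation is drawn per sample (diffuse
    background white matter).  ``dispersion_deg`` is the angular standard
    deviation used both when the phantom was generated and when the tracker
    re-perturbs sampled orientations.
    """

    orientations: np.ndarray
    weights: np.ndarray
    isotropic: np.ndarray
    dispersion_deg: float
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.isotropic = np.asarray(self.isotropic, dtype=bool)
        if self.orientations.ndim != 5 or self.orientations.shape[-1] != 3:
            raise ValueError("orientations must have shape (nx, ny, nz, k, 3)")
        if self.weights.shape != self.orientations.shape[:4]:
            raise ValueError("weights shape must match orientations")
        if self.isotropic.shape != self.orientations.shape[:3]:
            raise ValueError("isotropic shape must match the grid")
        if self.dispersion_deg < 0:
            raise ValueError("dispersion_deg must be >= 0")
        norms = np.linalg.norm(self.orientations, axis=-1)
        active = self.weights > 0
        if active.any() and not np.allclose(norms[active], 1.0, atol=1e-9):
            raise ValueError("stored orientations must be unit vectors")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.orientations.shape[:3]

    @property
    def n_orientations(self) -> int:
        return self.orientations.shape[3]


@dataclass
class TrackingParams:
    """Streamline propagation settings.

    Defaults follow the reference acquisition-scale protocol (10,000 samples
    per seed voxel, 2,000 steps, curvature threshold 0.2 expressed as the
    minimum cosine between successive step directions, 0.5 mm steps);
    phantom-scale analyses override ``n_samples`` and ``max_steps``.
    """

    n_samples: int = 10_000
    max_steps: int = 2_000
    step_length: float = 0.5
    curvature_threshold: float = 0.2
    mode: str = "probabilistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if not 0.0 <= self.curvature_threshold <= 1.0:
            raise ValueError("curvature_threshold must be in [0, 1]")
        if self.mode not in ("probabilistic", "deterministic"):
            raise ValueError("mode must be 'probabilistic' or 'deterministic'")


@dataclass
class TractProtocol:
    """Seed, waypoint, exclusion and termination masks for one tract."""

    name: str
    seed_mask: np.ndarray
    waypoint_masks: list = dc_field(default_factory=list)
    exclusion_masks: list = dc_field(default_factory=list)
    termination_mask: np.ndarray | None = None
    params: TrackingParams = dc_field(default_factory=TrackingParams)

    def __post_init__(self) -> None:
        self.seed_mask = np.asarray(self.seed_mask, dtype=bool)
        self.waypoint_masks = [np.asarray(m, dtype=bool) for m in self.waypoint_masks]
        self.exclusion_masks = [np.asarray(m, dtype=bool) for m in self.exclusion_masks]
        if self.termination_mask is not None:
            self.termination_mask = np.asarray(self.termination_mask, dtype=bool)
        if not self.seed_mask.any():
            raise ValueError(f"protocol '{self.name}': seed mask is empty")
        for m in self.exclusion_masks:
            if (self.seed_mask & m).any():
                raise ValueError(
                    f"protocol '{self.name}': seed mask overlaps an exclusion mask"
                )


@dataclass
class Tractogram:
    """Streamline visitation-count volume for one protocol."""

    counts: np.ndarray
    n_generated: int
    n_retained: int
    normalized: np.ndarray
    protocol_name: str
    voxel_size: float = 1.0


@dataclass
class Streamline:
    """A single propagated streamline with its protocol status."""

    points: np.ndarray               # (n_points, 3) positions in mm
    visited_voxels: np.ndarray       # (n_visited, 3) integer voxels, in order
    hit_waypoints: set
    excluded: bool
    terminated: bool


# --------------------------------------------------------------------------
# geometric helpers
# --------------------------------------------------------------------------

def canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip undirected orientations so the first nonzero component is positive."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float)).copy()
    tiny = 1e-12
    lead = np.where(
        np.abs(v[:, 0]) > tiny,
        v[:, 0],
        np.where(np.abs(v[:, 1]) > tiny, v[:, 1], v[:, 2]),
    )
    v[lead < 0] *= -1
    return v.reshape(np.shape(vectors))


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the plane perpendicular to each row of ``d``."""
    helper = np.zeros_like(d)
    use_y = np.abs(d[:, 0]) > 0.9
    helper[use_y, 1] = 1.0
    helper[~use_y, 0] = 1.0
    p1 = np.cross(d, helper)
    p1 /= np.linalg.norm(p1, axis=1, keepdims=True)
    p2 = np.cross(d, p1)
    return p1, p2


def _rotate_by_dispersion(d: np.ndarray, sigma_rad: float,
                          u_axis: np.ndarray, u_mag: np.ndarray) -> np.ndarray:
    """Rotate each direction by a half-normal angle about a random in-plane axis."""
    theta = sigma_rad * ndtri(0.5 + 0.5 * u_mag)
    phi = 2.0 * np.pi * u_axis
    p1, p2 = _perp_basis(d)
    ct = np.cos(theta)[:, None]
    st = np.sin(theta)[:, None]
    return ct * d + st * (np.cos(phi)[:, None] * p1 + np.sin(phi)[:, None] * p2)


def _uniform_sphere(u_phi: np.ndarray, u_z: np.ndarray) -> np.ndarray:
    z = 2.0 * u_z - 1.0
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = 2.0 * np.pi * u_phi
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _waypoint_bits(waypoint_masks, shape) -> np.ndarray | None:
    """Encode the waypoint masks as a per-voxel uint64 bit field."""
    if not waypoint_masks:
        return None
    if len(waypoint_masks) > 62:
        raise ValueError("at most 62 waypoint masks are supported")
    bits = np.zeros(shape, dtype=np.uint64)
    for w, mask in enumerate(waypoint_masks):
        bits[np.asarray(mask, bool)] |= np.uint64(1) << np.uint64(w)
    return bits


def _union_mask(masks, shape) -> np.ndarray | None:
    if not masks:
        return None
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        out |= np.asarray(m, bool)
    return out


def draw_streamline_uniforms(seed: int, ids, max_steps: int):
    """Draw the fixed per-streamline uniform schedule.

    Returns ``(jitter, steps)`` with shapes ``(n, 3)`` and
    ``(n, max_steps, 4)``.  This function *defines* the replayable RNG
    contract of the tracker.
    """
    ids = np.asarray(ids)
    n = len(ids)
    total = _JITTER_UNIFORMS + _UNIFORMS_PER_STEP * max_steps
    out = np.empty((n, total))
    for i, sid in enumerate(ids):
        out[i] = np.random.default_rng([int(seed), int(sid)]).random(total)
    return out[:, :3], out[:, 3:].reshape(n, max_steps, _UNIFORMS_PER_STEP)


# --------------------------------------------------------------------------
# propagation engine
# --------------------------------------------------------------------------

@dataclass
class _BatchResult:
    visited: np.ndarray       # (n, max_steps + 1) flat voxel ids, -1 padded
    excluded: np.ndarray      # (n,) bool
    waypoint_bits: np.ndarray  # (n,) uint64
    terminated: np.ndarray    # (n,) bool
    paths: np.ndarray | None
    n_points: np.ndarray | None


def _propagate_batch(field: OrientationField, starts: np.ndarray, signs: np.ndarray,
                     params: TrackingParams, uniforms: np.ndarray | None, *,
                     exclusion: np.ndarray | None = None,
                     termination: np.ndarray | None = None,
                     waypoint_bits: np.ndarray | None = None,
                     record_paths: bool = False) -> _BatchResult:
    """Euler-step a batch of streamlines through the orientation field.

    One iteration per step: resolve the containing voxel, apply the
    exclusion / visitation / waypoint / termination checks at that voxel,
    sample a direction (consuming this step's 4 uniforms), sign-align it
    with the previous direction, test the curvature threshold, and move.
    """
    nx, ny, nz = field.shape
    k_max = field.n_orientations
    vs = float(field.voxel_size)
    orients = field.orientations.reshape(-1, k_max, 3)
    weights = field.weights.reshape(-1, k_max)
    iso = field.isotropic.reshape(-1)
    excl = None if exclusion is None else np.asarray(exclusion, bool).reshape(-1)
    term = None if termination is None else np.asarray(termination, bool).reshape(-1)
    wpb = None if waypoint_bits is None else waypoint_bits.reshape(-1)

    probabilistic = params.mode == "probabilistic"
    if probabilistic and uniforms is None:
        raise ValueError("probabilistic propagation requires the uniform schedule")
    sigma = math.radians(field.dispersion_deg)
    step = float(params.step_length)
    cthr = float(params.curvature_threshold)
    n_steps = int(params.max_steps)

    n = starts.shape[0]
    pos = np.array(starts, dtype=float)
    prev = np.zeros((n, 3))
    launched = np.zeros(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    excluded = np.zeros(n, dtype=bool)
    terminated = np.zeros(n, dtype=bool)
    wp_hits = np.zeros(n, dtype=np.uint64)
    visited = np.full((n, n_steps + 1), -1, dtype=np.int64)
    paths = n_points = None
    if record_paths:
        paths = np.full((n, n_steps + 1, 3), np.nan)
        paths[:, 0] = pos
        n_points = np.ones(n, dtype=np.int64)

    for t in range(n_steps + 1):
        act = np.flatnonzero(alive)
        if act.size == 0:
            break
        vox = np.floor(pos[act] / vs).astype(np.int64)
        inb = ((vox[:, 0] >= 0) & (vox[:, 0] < nx)
               & (vox[:, 1] >= 0) & (vox[:, 1] < ny)
               & (vox[:, 2] >= 0) & (vox[:, 2] < nz))
        alive[act[~inb]] = False
        act, vox = act[inb], vox[inb]
        if act.size == 0:
            continue
        flat = (vox[:, 0] * ny + vox[:, 1]) * nz + vox[:, 2]

        if excl is not None:
            bad = excl[flat]
            if bad.any():
                excluded[act[bad]] = True
                alive[act[bad]] = False
                act, flat = act[~bad], flat[~bad]
                if act.size == 0:
                    continue
        visited[act, t] = flat
        if wpb is not None:
            wp_hits[act] |= wpb[flat]
        if term is not None:
            stop = term[flat]
            if stop.any():
                terminated[act[stop]] = True
                alive[act[stop]] = False
                act, flat = act[~stop], flat[~stop]
        if t == n_steps:
            break
        if act.size == 0:
            continue

        w = weights[flat]
        total = w.sum(axis=1)
        iso_here = iso[flat]
        dead = (total <= 0) & ~iso_here
        if not probabilistic:
            dead = dead | iso_here  # no orientation preference to follow
        if dead.any():
            alive[act[dead]] = False
            act, flat, w, total, iso_here = (
                act[~dead], flat[~dead], w[~dead], total[~dead],
                iso_here[~dead])
            if act.size == 0:
                continue
        if probabilistic:
            u = uniforms[act, t, :]
            d = np.zeros((act.size, 3))
            stored = ~iso_here
            if stored.any():
                choice = np.minimum(
                    (np.cumsum(w[stored], axis=1)
                     < (u[stored, 0] * total[stored])[:, None]).sum(axis=1),
                    k_max - 1,
                )
                base = orients[flat[stored], choice]
                if sigma > 0.0:
                    base = _rotate_by_dispersion(
                        base, sigma, u[stored, 1], u[stored, 2])
                d[stored] = base
            if iso_here.any():
                d[iso_here] = _uniform_sphere(u[iso_here, 1], u[iso_here, 3])
        else:
            d = orients[flat, np.argmax(w, axis=1)].copy()

        fresh = ~launched[act]
        if fresh.any():
            d[fresh] *= signs[act[fresh], None]
        old = np.flatnonzero(~fresh)
        if old.size:
            cosine = np.einsum("ij,ij->i", prev[act[old]], d[old])
            neg = cosine < 0
            if neg.any():
                d[old[neg]] = -d[old[neg]]
                cosine = np.abs(cosine)
            bend = cosine < cthr
            if bend.any():
                alive[act[old[bend]]] = False
                keep = np.ones(act.size, dtype=bool)
                keep[old[bend]] = False
                act, d = act[keep], d[keep]
                if act.size == 0:
                    continue

        pos[act] += step * d
        prev[act] = d
        launched[act] = True
        if record_paths:
            paths[act, n_points[act]] = pos[act]
            n_points[act] += 1

    return _BatchResult(visited, excluded, wp_hits, terminated, paths, n_points)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def sample_orientation(field: OrientationField, position, previous_dir=None, *,
                       mode: str = "probabilistic", rng=None) -> np.ndarray:
    """Draw one propagation direction at ``position`` (mm).

    Probabilistic mode draws a stored orientation weight-proportionally and
    re-perturbs it by the field's dispersion (consuming 4 uniforms from
    ``rng``); deterministic mode returns the highest-weight orientation
    unperturbed.  The sign is flipped so ``dot(previous_dir, result) >= 0``.
    """
    position = np.asarray(position, dtype=float)
    vox = np.floor(position / field.voxel_size).astype(int)
    if np.any(vox < 0) or np.any(vox >= np.array(field.shape)):
        raise ValueError(f"position {position} is outside the grid")
    w = field.weights[tuple(vox)]
    total = w.sum()
    isotropic = bool(field.isotropic[tuple(vox)])
    if total <= 0 and not isotropic:
        raise ValueError(f"voxel {tuple(vox)} carries no orientation")
    if mode == "deterministic":
        if isotropic and total <= 0:
            raise ValueError("deterministic mode undefined at isotropic voxel")
        d = field.orientations[tuple(vox)][int(np.argmax(w))].copy()
    else:
        if rng is None:
            rng = np.random.default_rng()
        u = rng.random(_UNIFORMS_PER_STEP)
        if total > 0 and not isotropic:
            choice = min(int((np.cumsum(w) < u[0] * total).sum()), len(w) - 1)
            d = field.orientations[tuple(vox)][choice][None, :]
            sigma = math.radians(field.dispersion_deg)
            if sigma > 0:
                d = _rotate_by_dispersion(d, sigma, u[1:2], u[2:3])
            d = d[0]
        else:
            d = _uniform_sphere(u[1:2], u[3:4])[0]
    if previous_dir is not None and float(np.dot(previous_dir, d)) < 0:
        d = -d
    return d


def propagate_streamline(field: OrientationField, start, protocol: TractProtocol, *,
                         launch_sign: int = 1, rng=None,
                         uniforms: np.ndarray | None = None) -> Streamline:
    """Propagate one streamline from ``start`` (mm) under a protocol.

    ``uniforms`` may supply the per-step schedule explicitly (shape
    ``(max_steps, 4)`` or flat); otherwise it is drawn from ``rng``.
    """
    params = protocol.params
    u = None
    if params.mode == "probabilistic":
        if uniforms is None:
            if rng is None:
                rng = np.random.default_rng()
            uniforms = rng.random(params.max_steps * _UNIFORMS_PER_STEP)
        u = np.asarray(uniforms, dtype=float).reshape(
            1, params.max_steps, _UNIFORMS_PER_STEP)
    shape = field.shape
    res = _propagate_batch(
        field,
        np.asarray(start, dtype=float)[None, :],
        np.array([float(launch_sign)]),
        params,
        u,
        exclusion=_union_mask(protocol.exclusion_masks, shape),
        termination=protocol.termination_mask,
        waypoint_bits=_waypoint_bits(protocol.waypoint_masks, shape),
        record_paths=True,
    )
    row = res.visited[0]
    flat = row[row >= 0]
    ny, nz = shape[1], shape[2]
    voxels = np.column_stack([flat // (ny * nz), (flat // nz) % ny, flat % nz])
    bits = int(res.waypoint_bits[0])
    hit = {w for w in range(len(protocol.waypoint_masks)) if bits >> w & 1}
    return Streamline(
        points=res.paths[0, : res.n_points[0]],
        visited_voxels=voxels,
        hit_waypoints=hit,
        excluded=bool(res.excluded[0]),
        terminated=bool(res.terminated[0]),
    )


def _first_occurrences(visited: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row unique flat voxel ids of a visited matrix (binary visitation).

    Returns ``(row_index, flat_voxel)`` pairs with each voxel counted once
    per row.
    """
    sv = np.sort(visited, axis=1)
    keep = sv >= 0
    keep[:, 1:] &= sv[:, 1:] != sv[:, :-1]
    rows = np.broadcast_to(np.arange(sv.shape[0])[:, None], sv.shape)[keep]
    return rows, sv[keep]


def _seed_starts(seed_voxels: np.ndarray, sample_idx: np.ndarray,
                 jitter: np.ndarray | None, voxel_size: float,
                 mode: str) -> np.ndarray:
    if mode == "probabilistic":
        return (seed_voxels + jitter) * voxel_size
    return (seed_voxels + 0.5) * voxel_size


def run_tractography(protocol: TractProtocol, field: OrientationField, *,
                     chunk_size: int = 8192) -> Tractogram:
    """Generate ``n_samples`` streamlines per seed voxel and count visitation.

    Half of each voxel's samples launch with each initial orientation sign
    (the seed sits in the tract body with waypoints on both sides).  A
    streamline is retained if it is not excluded and crossed at least one
    waypoint; with no waypoint masks every non-excluded streamline is
    retained.  Each retained streamline increments a voxel at most once and
    the map is normalized by the retained count.
    """
    params = protocol.params
    shape = field.shape
    seed_voxels = np.argwhere(protocol.seed_mask)
    n_per = params.n_samples
    n_total = len(seed_voxels) * n_per
    half = (n_per + 1) // 2
    exclusion = _union_mask(protocol.exclusion_masks, shape)
    wp_bits = _waypoint_bits(protocol.waypoint_masks, shape)
    has_waypoints = wp_bits is not None

    counts = np.zeros(int(np.prod(shape)), dtype=np.int64)
    n_retained = 0
    for lo in range(0, n_total, chunk_size):
        ids = np.arange(lo, min(lo + chunk_size, n_total))
        voxels = seed_voxels[ids // n_per]
        m = ids % n_per
        signs = np.where(m < half, 1.0, -1.0)
        jitter = uniforms = None
        if params.mode == "probabilistic":
            jitter, uniforms = draw_streamline_uniforms(
                params.seed, ids, params.max_steps)
        starts = _seed_starts(voxels, m, jitter, field.voxel_size, params.mode)
        res = _propagate_batch(
            field, starts, signs, params, uniforms,
            exclusion=exclusion, termination=protocol.termination_mask,
            waypoint_bits=wp_bits)
        retained = ~res.excluded
        if has_waypoints:
            retained &= res.waypoint_bits != 0
        n_retained += int(retained.sum())
        _, flat = _first_occurrences(res.visited[retained])
        np.add.at(counts, flat, 1)

    counts = counts.reshape(shape)
    if n_retained > 0:
        normalized = counts / float(n_retained)
    else:
        warnings.warn(
            f"protocol '{protocol.name}': no streamlines retained; "
            "normalized map is all zero")
        normalized = np.zeros(shape, dtype=float)
    return Tractogram(
        counts=counts, n_generated=n_total, n_retained=n_retained,
        normalized=normalized, protocol_name=protocol.name,
        voxel_size=field.voxel_size)


def track_connectivity(field: OrientationField, start_voxels: np.ndarray,
                       params: TrackingParams, *, termination=None,
                       exclusion=None, group: np.ndarray | None = None,
                       chunk_size: int = 8192) -> sparse.csr_matrix:
    """Unconstrained tracking from given voxels, rows grouped by ``group``.

    Returns a sparse ``(n_groups, n_voxels)`` matrix whose entry ``(g, v)``
    counts the streamlines of group ``g`` that visited voxel ``v`` (at most
    once per streamline).  This is the common substrate of the ROI
    connectivity matrix and the vertexwise connectivity matrix.
    """
    start_voxels = np.asarray(start_voxels)
    if group is None:
        group = np.arange(len(start_voxels))
    group = np.asarray(group)
    n_groups = int(group.max()) + 1 if len(group) else 0
    shape = field.shape
    n_vox = int(np.prod(shape))
    n_per = params.n_samples
    n_total = len(start_voxels) * n_per
    half = (n_per + 1) // 2

    rows_acc, cols_acc = [], []
    for lo in range(0, n_total, chunk_size):
        ids = np.arange(lo, min(lo + chunk_size, n_total))
        which = ids // n_per
        voxels = start_voxels[which]
        m = ids % n_per
        signs = np.where(m < half, 1.0, -1.0)
        jitter = uniforms = None
        if params.mode == "probabilistic":
            jitter, uniforms = draw_streamline_uniforms(
                params.seed, ids, params.max_steps)
        starts = _seed_starts(voxels, m, jitter, field.voxel_size, params.mode)
        res = _propagate_batch(
            field, starts, signs, params, uniforms,
            exclusion=exclusion, termination=termination)
        retained = ~res.excluded
        sub_rows, flat = _first_occurrences(res.visited[retained])
        rows_acc.append(group[which[retained][sub_rows]])
        cols_acc.append(flat)

    if rows_acc:
        rows = np.concatenate(rows_acc)
        cols = np.concatenate(cols_acc)
    else:
        rows = cols = np.array([], dtype=np.int64)
    mat = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.float64), (rows, cols)),
        shape=(n_groups, n_vox))
    return mat.tocsr()


# --------------------------------------------------------------------------
# tractogram post-processing
# --------------------------------------------------------------------------

def _as_map(t) -> np.ndarray:
    return t.normalized if isinstance(t, Tractogram) else np.asarray(t, dtype=float)


def average_tractograms(tractograms) -> np.ndarray:
    """Voxelwise arithmetic mean of normalized maps (cross-subject average)."""
    if len(tractograms) == 0:
        raise ValueError("need at least one tractogram")
    maps = [_as_map(t) for t in tractograms]
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError("tractograms are on different grids")
    return np.mean(maps, axis=0)


def downsample_volume(volume: np.ndarray, factor: int,
                      voxel_size: float | None = None):
    """Block-mean pooling over ``factor**3`` blocks."""
    volume = np.asarray(volume, dtype=float)
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if any(s % factor for s in volume.shape):
        raise ValueError(
            f"shape {volume.shape} is not divisible by factor {factor}")
    nx, ny, nz = (s // factor for s in volume.shape)
    out = volume.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
    if voxel_size is not None:
        return out, voxel_size * factor
    return out


def log_normalize(volume: np.ndarray) -> np.ndarray:
    """Display transform: ``v -> log(1 + v)`` scaled to a maximum of 1."""
    volume = np.asarray(volume, dtype=float)
    if (volume < 0).any():
        raise ValueError("volume must be non-negative")
    out = np.log1p(volume)
    peak = out.max()
    if peak <= 0:
        warnings.warn("log_normalize: all-zero volume returned unchanged")
        return volume.copy()
    return out / peak


def threshold_map(volume: np.ndarray, t: float) -> np.ndarray:
    """Binary mask of voxels with value >= ``t``."""
    return np.asarray(volume) >= t


def overlap_fraction(tract_a: np.ndarray, tract_b: np.ndarray) -> float:
    """|A intersect B| / |A| for binary tract masks."""
    a = np.asarray(tract_a, dtype=bool)
    b = np.asarray(tract_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("tract_a is empty")
    return float((a & b).sum()) / n_a


def with_seed(params: TrackingParams, seed: int) -> TrackingParams:
    """Copy of ``params`` with a different RNG seed."""
    return replace(params, seed=int(seed))
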