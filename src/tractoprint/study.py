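"""Canonical study conditions: phantom geometries, protocols, pipelines.

Two synthetic "species" are compared throughout the analyses:

* the **three-bundle brain** (macaque-like): three straight longitudinal
  tubes - a dorsal MdLF, a ventromedial IFOF and a ventral ILF running
  directly alongside the IFOF (one-voxel gap, mirroring their adjacent
  anatomical course);
* the **split brain** (human-like): the same MdLF and IFOF, the ILF split
  into a medial subcomponent (congruent with the other brain's ILF, still
  next to the IFOF) and a lateral subcomponent displaced away from every
  other tract, plus an arcuate-like curved dorsal bundle (AF) absent from
  the first brain.

Geometry is fixed in voxels on a 36-voxel grid for the blueprint/divergence
analyses and on a 40-voxel grid (wider spacing, radius 2.5) for the
parcellation analyses.  All tube end caps reach the gray/white border so
their surface territory is labeled.

The functions here assemble complete study runs (cohorts, protocol-
constrained tract reconstruction, blueprints, divergence comparisons) from
the building blocks of the other modules; the analysis scripts, the test
suite and the acceptance script all call them with the same defaults, which
*are* the study conditions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from . import blueprint as bp_mod
from . import divergence as div_mod
from .phantom import BundleSpec, PhantomSpec, SpeciesPhantom, generate_cohort, \
    generate_phantom
from .tracking import (TrackingParams, TractProtocol, average_tractograms,
                       run_tractography)

__all__ = [
    "three_bundle_spec",
    "split_bundle_spec",
    "parcellation_spec",
    "protocol_slabs",
    "tract_protocols",
    "reconstruct_tracts",
    "BlueprintStudy",
    "run_blueprint_study",
    "run_identity_study",
    "derive_seed",
]

BLUEPRINT_GRID = 36
PARCELLATION_GRID = 40

# tube axis positions (x, z) on the 36-voxel blueprint grid, radius 2
_BP_LAYOUT = {
    "MdLF": (18.0, 22.0),
    "IFOF": (13.0, 12.0),
    "ILF": (18.0, 12.0),      # one-voxel gap to the IFOF tube
}
_BP_RADIUS = 2.0
_ILF_LAT_OFFSET = (8.0, 0.0, 0.0)   # lateral child displacement (voxels)

# arcuate-like curved bundle: dorsal run bending ventrally at the back
# (one-voxel longitudinal margin so subject jitter keeps the tube in-grid)
_AF_CONTROL = [
    (24.0, 3.0, 26.0),
    (24.0, 10.0, 29.0),
    (24.0, 20.0, 29.0),
    (24.0, 28.0, 25.0),
    (24.0, 33.0, 18.0),
]

# wider layout for the parcellation phantom (40-voxel grid, radius 2.5)
_PARC_LAYOUT = {
    "MdLF": (20.0, 28.0),
    "IFOF": (11.0, 13.0),
    "ILF": (25.0, 13.0),
}
_PARC_RADIUS = 2.5
_PARC_LAT_OFFSET = (8.0, 0.0, 0.0)


def derive_seed(root: int, *parts) -> int:
    """Stable sub-seed below 2**31 derived from a root seed and labels."""
    digest = hashlib.sha256(
        ("|".join([str(int(root))] + [str(p) for p in parts])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _straight(label: str, x: float, z: float, grid: int, g: int,
              radius: float) -> BundleSpec:
    return BundleSpec(
        label=label,
        centerline=[(x, float(g), z), (x, float(grid - g), z)],
        radius_vox=radius)


def three_bundle_spec(seed: int = 0, *, dispersion_deg: float = 10.0,
                      jitter: float = 0.75) -> PhantomSpec:
    """Macaque-like brain: MdLF, IFOF and a single ILF beside the IFOF."""
    g, grid = 2, BLUEPRINT_GRID
    bundles = [_straight(n, x, z, grid, g, _BP_RADIUS)
               for n, (x, z) in _BP_LAYOUT.items()]
    return PhantomSpec(grid_shape=(grid,) * 3, bundles=bundles,
                       gm_thickness=g, dispersion_deg=dispersion_deg,
                       subject_jitter_vox=jitter, seed=seed)


def split_bundle_spec(seed: int = 0, *, dispersion_deg: float = 10.0,
                      jitter: float = 0.75,
                      with_arcuate: bool = True) -> PhantomSpec:
    """Human-like brain: ILF split into medial + lateral, optional arcuate."""
    g, grid = 2, BLUEPRINT_GRID
    bundles = []
    for n, (x, z) in _BP_LAYOUT.items():
        b = _straight(n, x, z, grid, g, _BP_RADIUS)
        if n == "ILF":
            b = replace(b, split_into=(("ILFmed", (0.0, 0.0, 0.0)),
                                       ("ILFlat", _ILF_LAT_OFFSET)))
        bundles.append(b)
    if with_arcuate:
        bundles.append(BundleSpec(label="AF", centerline=list(_AF_CONTROL),
                                  radius_vox=_BP_RADIUS, curved=True))
    return PhantomSpec(grid_shape=(grid,) * 3, bundles=bundles,
                       gm_thickness=g, dispersion_deg=dispersion_deg,
                       subject_jitter_vox=jitter, seed=seed)


def parcellation_spec(seed: int = 0, *, split: bool = False,
                      dispersion_deg: float = 10.0,
                      jitter: float = 1.0) -> PhantomSpec:
    """Well-separated straight bundles for the ROI clustering analyses."""
    g, grid = 2, PARCELLATION_GRID
    bundles = []
    for n, (x, z) in _PARC_LAYOUT.items():
        b = _straight(n, x, z, grid, g, _PARC_RADIUS)
        if split and n == "ILF":
            b = replace(b, split_into=(("ILFmed", (0.0, 0.0, 0.0)),
                                       ("ILFlat", _PARC_LAT_OFFSET)))
        bundles.append(b)
    return PhantomSpec(grid_shape=(grid,) * 3, bundles=bundles,
                       gm_thickness=g, dispersion_deg=dispersion_deg,
                       subject_jitter_vox=jitter, seed=seed)


# --------------------------------------------------------------------------
# protocols and tract reconstruction
# --------------------------------------------------------------------------

def protocol_slabs(grid: int, gm: int):
    """(anterior, middle, posterior) slab slices along the longitudinal axis."""
    mid = grid // 2
    return (slice(gm + 2, gm + 5),
            slice(mid - 1, mid + 2),
            slice(grid - gm - 5, grid - gm - 2))


def _slab_mask(tube: np.ndarray, sl: slice) -> np.ndarray:
    out = np.zeros_like(tube)
    out[:, sl, :] = tube[:, sl, :]
    return out


def tract_protocols(template: SpeciesPhantom, params: TrackingParams, *,
                    extra_tubes: dict | None = None,
                    no_mutual_exclusion: tuple = ("ILFlat", "ILFmed")) -> dict:
    """Seed/waypoint/exclusion protocols from a template phantom's tubes.

    Seeds come from the middle slab of each tube, waypoints from the
    anterior and posterior slabs; every other tract's seed and waypoints act
    as exclusion masks (the two ILF subcomponents exempt each other);
    streamlines terminate at gray matter.  ``extra_tubes`` supplies tube
    masks for protocols a phantom lacks (the arcuate protocol applied to the
    brain without an arcuate bundle, mirroring a shared-space protocol).
    """
    grid = template.spec.grid_shape[1]
    gm = template.spec.gm_thickness
    ant, mid, post = protocol_slabs(grid, gm)
    tubes = {name: template.bundle_mask(name) for name in template.label_names}
    if extra_tubes:
        tubes.update(extra_tubes)

    parts = {}
    for name, tube in tubes.items():
        parts[name] = {
            "seed": _slab_mask(tube, mid),
            "anterior": _slab_mask(tube, ant),
            "posterior": _slab_mask(tube, post),
        }
        for role, mask in parts[name].items():
            if not mask.any():
                raise ValueError(f"tract '{name}': empty {role} mask")

    protocols = {}
    for name in tubes:
        own = parts[name]
        exclusion = np.zeros(template.spec.grid_shape, dtype=bool)
        for other in tubes:
            if other == name:
                continue
            if name in no_mutual_exclusion and other in no_mutual_exclusion:
                continue
            for mask in parts[other].values():
                exclusion |= mask
        exclusion &= ~(own["seed"] | own["anterior"] | own["posterior"])
        protocols[name] = TractProtocol(
            name=name,
            seed_mask=own["seed"],
            waypoint_masks=[own["anterior"], own["posterior"]],
            exclusion_masks=[exclusion] if exclusion.any() else [],
            termination_mask=template.gm_mask,
            params=params)
    return protocols


def reconstruct_tracts(cohort, protocols: dict, base_seed: int) -> dict:
    """Per-tract cross-subject average of normalized tractograms."""
    averaged = {}
    for t_idx, (name, protocol) in enumerate(sorted(protocols.items())):
        maps = []
        for s_idx, subject in enumerate(cohort):
            p = replace(protocol,
                        params=replace(protocol.params,
                                       seed=derive_seed(base_seed, name, s_idx)))
            maps.append(run_tractography(p, subject.orientation_field))
        averaged[name] = average_tractograms(maps)
    return averaged


# --------------------------------------------------------------------------
# blueprint / divergence studies
# --------------------------------------------------------------------------

@dataclass
class SpeciesData:
    """One species' processed data: phantoms, tract maps, vertex matrix."""

    template: SpeciesPhantom
    cohort: list
    tract_maps: dict          # tract name -> averaged normalized volume
    vertex_conn: object       # averaged sparse vertices x voxels matrix

    def blueprint(self, column_groups: dict) -> bp_mod.Blueprint:
        """Assemble a blueprint whose columns are means of named tract maps."""
        names = list(column_groups.keys())
        n_vox = int(np.prod(self.template.spec.grid_shape))
        cols = np.column_stack([
            np.mean([self.tract_maps[m] for m in members], axis=0).ravel()
            for members in column_groups.values()])
        assert cols.shape == (n_vox, len(names))
        return bp_mod.build_blueprint(self.vertex_conn, cols, names,
                                      surface=self.template.surface)


def _build_species(spec: PhantomSpec, protocols_template: SpeciesPhantom,
                   n_subjects: int, tract_params: TrackingParams,
                   vertex_params: TrackingParams, base_seed: int,
                   extra_tubes: dict | None = None) -> SpeciesData:
    template = generate_phantom(spec)
    cohort = generate_cohort(spec, n_subjects)
    protocols = tract_protocols(protocols_template, tract_params,
                                extra_tubes=extra_tubes)
    tract_maps = reconstruct_tracts(cohort, protocols,
                                    derive_seed(base_seed, "tracts"))
    mats = []
    for s_idx, subject in enumerate(cohort):
        vp = replace(vertex_params,
                     seed=derive_seed(base_seed, "vertex", s_idx))
        vc = bp_mod.vertex_connectivity(
            subject.surface, subject.orientation_field, vp,
            wm_mask=subject.wm_mask, termination=subject.gm_mask)
        mats.append(vc.matrix)
    avg = sum(mats[1:], start=mats[0]) / len(mats)
    return SpeciesData(template=template, cohort=cohort,
                       tract_maps=tract_maps, vertex_conn=avg)


# blueprint column spaces (common across species)
LONGITUDINAL_COLUMNS = {"MdLF": ("MdLF",), "IFOF": ("IFOF",), "ILF": ("ILF",)}


@dataclass
class BlueprintStudy:
    """Both species' data plus the blueprints the comparisons use."""

    species_a: SpeciesData           # three-bundle brain
    species_b: SpeciesData           # split brain with arcuate
    bp_a: bp_mod.Blueprint           # A, columns MdLF/IFOF/ILF/AF
    bp_b: bp_mod.Blueprint           # B, same columns (ILF = lat+med combined)
    bp_a_no_af: bp_mod.Blueprint
    bp_b_no_af: bp_mod.Blueprint
    bp_b_lat: bp_mod.Blueprint       # ILF column = lateral subcomponent only
    bp_b_med: bp_mod.Blueprint       # ILF column = medial subcomponent only


def run_blueprint_study(seed: int, *, n_subjects: int = 3,
                        n_samples_tract: int = 200,
                        n_samples_vertex: int = 96,
                        max_steps: int = 150,
                        dispersion_deg: float = 10.0) -> BlueprintStudy:
    """Full two-species blueprint comparison at phantom scale."""
    tract_params = TrackingParams(n_samples=n_samples_tract,
                                  max_steps=max_steps)
    vertex_params = TrackingParams(n_samples=n_samples_vertex,
                                   max_steps=max_steps)
    spec_a = three_bundle_spec(seed=derive_seed(seed, "phantom_a"),
                               dispersion_deg=dispersion_deg)
    spec_b = split_bundle_spec(seed=derive_seed(seed, "phantom_b"),
                               dispersion_deg=dispersion_deg)
    template_b = generate_phantom(spec_b)
    af_tube = {"AF": template_b.bundle_mask("AF")}

    a = _build_species(spec_a, generate_phantom(spec_a), n_subjects,
                       tract_params, vertex_params,
                       derive_seed(seed, "species_a"), extra_tubes=af_tube)
    b = _build_species(spec_b, template_b, n_subjects,
                       tract_params, vertex_params,
                       derive_seed(seed, "species_b"))

    cols_a = dict(LONGITUDINAL_COLUMNS, AF=("AF",))
    cols_b = {"MdLF": ("MdLF",), "IFOF": ("IFOF",),
              "ILF": ("ILFlat", "ILFmed"), "AF": ("AF",)}
    cols_b_lat = dict(cols_b, ILF=("ILFlat",))
    cols_b_med = dict(cols_b, ILF=("ILFmed",))

    def drop_af(cols):
        return {k: v for k, v in cols.items() if k != "AF"}

    return BlueprintStudy(
        species_a=a, species_b=b,
        bp_a=a.blueprint(cols_a),
        bp_b=b.blueprint(cols_b),
        bp_a_no_af=a.blueprint(drop_af(cols_a)),
        bp_b_no_af=b.blueprint(drop_af(cols_b)),
        bp_b_lat=b.blueprint(cols_b_lat),
        bp_b_med=b.blueprint(cols_b_med))


@dataclass
class ParcellationStudy:
    """Per-subject ROI clustering of a straight-bundle cohort."""

    cohort: list
    solutions: list           # per-subject ClusterSolution (middle ROI)
    roi_truths: list          # per-subject ground-truth label id per ROI voxel
    k: int


def run_parcellation_study(seed: int, *, split: bool = False,
                           n_subjects: int = 4, n_samples: int = 500,
                           max_steps: int = 180,
                           k: int | None = None) -> ParcellationStudy:
    """Middle-ROI connectivity-based clustering on the parcellation phantom.

    The ROI is the middle three-slab of tract-bearing white matter; every
    ROI voxel seeds ``n_samples`` unconstrained streamlines terminating at
    gray matter, rows are correlated into a similarity matrix and k-means'd
    with one cluster per bundle.
    """
    from . import parcellation as pc

    spec = parcellation_spec(seed=derive_seed(seed, "parc", split),
                             split=split)
    if k is None:
        k = 4 if split else 3
    cohort = generate_cohort(spec, n_subjects)
    grid, gm = spec.grid_shape[1], spec.gm_thickness
    _, mid, _ = protocol_slabs(grid, gm)
    solutions, truths = [], []
    for s_idx, subject in enumerate(cohort):
        roi = pc.RoiSpec(axis_position=grid // 2, n_slices=3,
                         include_mask=subject.bundle_labels > 0)
        params = TrackingParams(
            n_samples=n_samples, max_steps=max_steps,
            seed=derive_seed(seed, "roi", split, s_idx))
        conn, voxels = pc.roi_connectivity_matrix(
            roi, subject.orientation_field, params,
            termination=subject.gm_mask)
        sim = pc.similarity_matrix(conn)
        sol = pc.cluster(sim, k, derive_seed(seed, "kmeans", split, s_idx),
                         voxels=voxels, subject_id=s_idx)
        solutions.append(sol)
        truths.append(subject.bundle_labels[tuple(voxels.T)])
    return ParcellationStudy(cohort=cohort, solutions=solutions,
                             roi_truths=truths, k=k)


def run_identity_study(seed: int, *, n_subjects: int = 2,
                       n_samples_tract: int = 200,
                       n_samples_vertex: int = 96,
                       max_steps: int = 150) -> div_mod.DivergenceMap:
    """Min-KL map between two independent analyses of identical phantoms.

    Both "species" share the same phantom spec and seed; only the tracking
    randomness differs, so the divergence observed is pure estimation noise.
    """
    tract_params = TrackingParams(n_samples=n_samples_tract,
                                  max_steps=max_steps)
    vertex_params = TrackingParams(n_samples=n_samples_vertex,
                                   max_steps=max_steps)
    spec = three_bundle_spec(seed=derive_seed(seed, "phantom_id"))
    template = generate_phantom(spec)
    runs = []
    for tag in ("first", "second"):
        runs.append(_build_species(
            spec, template, n_subjects, tract_params, vertex_params,
            derive_seed(seed, "identity", tag)))
    bp1 = runs[0].blueprint(LONGITUDINAL_COLUMNS)
    bp2 = runs[1].blueprint(LONGITUDINAL_COLUMNS)
    return div_mod.min_kl_map(bp1, bp2)
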