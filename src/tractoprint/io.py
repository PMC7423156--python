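"""File I/O and pipeline orchestration.

Volumes travel as NIfTI (nibabel), surfaces and per-vertex scalars as GIFTI,
sparse matrices as MatrixMarket, tables as TSV, configuration as YAML and
run metadata as JSON.  ``run_pipeline`` ties phantom generation, tract
reconstruction, blueprint construction and the divergence comparison into
one reproducible run that emits a manifest with SHA-256 checksums of every
artifact: identical configurations produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from . import divergence as div_mod
from . import study
from .phantom import SurfaceMesh
from .tracking import OrientationField

__all__ = [
    "save_volume", "load_volume",
    "save_surface", "load_surface",
    "save_vertex_scalars", "load_vertex_scalars",
    "save_orientation_field", "load_orientation_field",
    "save_sparse_matrix", "load_sparse_matrix",
    "save_table", "load_table",
    "save_yaml", "load_yaml",
    "save_json", "load_json",
    "file_sha256",
    "run_pipeline",
    "default_pipeline_config",
]


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_volume(path, data: np.ndarray, voxel_size: float = 1.0,
                dtype=None) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if dtype is None:
        dtype = np.int16 if arr.dtype == bool else arr.dtype
    img = nib.Nifti1Image(arr.astype(dtype), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_volume(path):
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), float(img.header.get_zooms()[0])


# --------------------------------------------------------------------------
# surfaces and per-vertex scalars
# --------------------------------------------------------------------------

def save_surface(path, surface: SurfaceMesh) -> Path:
    path = Path(path)
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(surface.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(surface.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))
    return path


def load_surface(path) -> SurfaceMesh:
    img = nib.load(str(path))
    verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(vertices=np.asarray(verts, float),
                       faces=np.asarray(faces, np.int64))


def save_vertex_scalars(path, values: np.ndarray) -> Path:
    path = Path(path)
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(np.asarray(values, np.float32),
                                 intent="NIFTI_INTENT_SHAPE")])
    nib.save(img, str(path))
    return path


def load_vertex_scalars(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, float)


# --------------------------------------------------------------------------
# orientation fields
# --------------------------------------------------------------------------

def save_orientation_field(stem, field: OrientationField) -> dict:
    """Write a field as NIfTI volumes plus a JSON sidecar; returns the paths."""
    stem = Path(stem)
    k = field.n_orientations
    shape = field.shape
    paths = {
        "orientations": save_volume(
            stem.with_suffix(".orient.nii.gz"),
            field.orientations.reshape(shape + (3 * k,)).astype(np.float32),
            field.voxel_size, dtype=np.float32),
        "weights": save_volume(
            stem.with_suffix(".weights.nii.gz"),
            field.weights.astype(np.float32), field.voxel_size,
            dtype=np.float32),
        "isotropic": save_volume(
            stem.with_suffix(".iso.nii.gz"), field.isotropic,
            field.voxel_size),
    }
    sidecar = stem.with_suffix(".field.json")
    save_json(sidecar, {"n_orientations": k,
                        "dispersion_deg": field.dispersion_deg,
                        "voxel_size": field.voxel_size})
    paths["sidecar"] = sidecar
    return paths


def load_orientation_field(stem) -> OrientationField:
    stem = Path(stem)
    meta = load_json(stem.with_suffix(".field.json"))
    k = int(meta["n_orientations"])
    orients, vs = load_volume(stem.with_suffix(".orient.nii.gz"))
    weights, _ = load_volume(stem.with_suffix(".weights.nii.gz"))
    iso, _ = load_volume(stem.with_suffix(".iso.nii.gz"))
    shape = orients.shape[:3]
    return OrientationField(
        orientations=np.asarray(orients, float).reshape(shape + (k, 3)),
        weights=np.asarray(weights, float).reshape(shape + (k,)),
        isotropic=np.asarray(iso, bool),
        dispersion_deg=float(meta["dispersion_deg"]),
        voxel_size=float(meta["voxel_size"]))


# --------------------------------------------------------------------------
# matrices, tables, config
# --------------------------------------------------------------------------

def save_sparse_matrix(path, matrix) -> Path:
    path = Path(path)
    scipy_io.mmwrite(str(path), sparse.coo_matrix(matrix))
    return path


def load_sparse_matrix(path):
    return sparse.csr_matrix(scipy_io.mmread(str(path)))


def save_table(path, frame: pd.DataFrame, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=index)
    return path


def load_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def save_yaml(path, obj) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_json(path, obj) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def default_pipeline_config(seed: int = 0, out_dir: str = "results/pipeline") -> dict:
    """Small two-species demonstration configuration."""
    return {
        "seed": int(seed),
        "out_dir": str(out_dir),
        "n_subjects": 2,
        "dispersion_deg": 10.0,
        "tracking": {
            "n_samples_tract": 60,
            "n_samples_vertex": 24,
            "max_steps": 150,
        },
    }


def run_pipeline(config: dict | str | Path) -> dict:
    """Run phantoms -> tracts -> blueprints -> divergence and write a manifest.

    ``config`` is a dict or a YAML path following
    :func:`default_pipeline_config`.  Every stage artifact is written under
    ``out_dir`` and hashed into the returned (and saved) manifest.
    """
    if not isinstance(config, dict):
        config = load_yaml(config)
    cfg = default_pipeline_config()
    cfg.update({k: v for k, v in config.items() if k != "tracking"})
    cfg["tracking"] = {**default_pipeline_config()["tracking"],
                       **config.get("tracking", {})}
    if "seed" not in config:
        raise ValueError("pipeline config must set a seed")

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    res = study.run_blueprint_study(
        cfg["seed"], n_subjects=cfg["n_subjects"],
        n_samples_tract=cfg["tracking"]["n_samples_tract"],
        n_samples_vertex=cfg["tracking"]["n_samples_vertex"],
        max_steps=cfg["tracking"]["max_steps"],
        dispersion_deg=cfg["dispersion_deg"])

    for tag, species in (("a", res.species_a), ("b", res.species_b)):
        phantom = species.template
        vs = phantom.spec.voxel_size
        artifacts[f"labels_{tag}"] = save_volume(
            out / f"species_{tag}_labels.nii.gz", phantom.bundle_labels, vs)
        artifacts[f"surface_{tag}"] = save_surface(
            out / f"species_{tag}.surf.gii", phantom.surface)
        artifacts[f"truth_{tag}"] = save_vertex_scalars(
            out / f"species_{tag}_truth.func.gii", phantom.vertex_truth)
        for tract, volume in sorted(species.tract_maps.items()):
            artifacts[f"tract_{tag}_{tract}"] = save_volume(
                out / f"species_{tag}_{tract}.nii.gz", volume, vs,
                dtype=np.float32)

    for tag, bp in (("a", res.bp_a), ("b", res.bp_b)):
        frame = pd.DataFrame(bp.matrix, columns=bp.tract_names)
        frame.insert(0, "vertex", bp.vertex_ids)
        artifacts[f"blueprint_{tag}"] = save_table(
            out / f"blueprint_{tag}.tsv", frame)

    div_ab = div_mod.min_kl_map(res.bp_a, res.bp_b)
    div_ba = div_mod.min_kl_map(res.bp_b, res.bp_a)
    for tag, dmap in (("a_to_b", div_ab), ("b_to_a", div_ba)):
        frame = pd.DataFrame({
            "vertex": np.arange(len(dmap.min_kl)),
            "min_kl": dmap.min_kl,
            "best_match": dmap.best_match,
        })
        artifacts[f"divergence_{tag}"] = save_table(
            out / f"divergence_{tag}.tsv", frame)

    with_af = div_mod.kl_distribution(div_ba)
    without_af = div_mod.kl_distribution(
        div_mod.min_kl_map(res.bp_b_no_af, res.bp_a_no_af))
    d_stat, p_value = div_mod.ks_compare(with_af, without_af)
    artifacts["ks_arcuate"] = save_json(out / "ks_arcuate.json", {
        "D": d_stat, "p": p_value,
        "n_with_af": int(len(with_af)), "n_without_af": int(len(without_af))})

    manifest = {
        "config": cfg,
        "artifacts": {k: {"path": str(p.relative_to(out)),
                          "sha256": file_sha256(p)}
                      for k, p in sorted(artifacts.items())},
    }
    save_json(out / "manifest.json", manifest)
    return manifest
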