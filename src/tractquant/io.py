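"""File-format boundary: NIfTI volumes, FSL bval/bvec tables, manifests.

World coordinates (affines) live only here; the analysis core works in
0-based voxel indices on unit grids.  Masks are written as uint8.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import AcquisitionScheme

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_bvalbvec",
    "write_bvalbvec",
    "write_mask",
    "save_orientation_samples",
    "load_orientation_samples",
    "file_sha256",
    "write_manifest",
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Load a NIfTI file; returns (data, affine, header dict).

    Malformed or truncated files raise a ValueError naming the file instead
    of returning silent garbage.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several exception types
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    hdr = {"dim": img.shape, "voxel_size": tuple(img.header.get_zooms())}
    return data, img.affine, hdr


def write_nifti(volume: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    """Write a volume as NIfTI (gzip chosen by the .gz extension)."""
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(volume), affine)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_mask(mask: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    return write_nifti(np.asarray(mask, np.uint8), path, affine)


def read_bvalbvec(bval_path, bvec_path) -> AcquisitionScheme:
    """Read FSL-style gradient tables (one row of b-values; three rows of
    direction components).  Directions are renormalized to unit length with a
    warning when they deviate by more than 1e-3; b=0 rows keep (0,0,0)."""
    bvals = np.loadtxt(bval_path, ndmin=1)
    if bvals.ndim != 1:
        raise ValueError(f"{bval_path}: expected a single row of b-values")
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"{bvec_path}: expected three rows of components")
    if bvecs.shape[1] != len(bvals):
        raise ValueError(
            f"gradient table length mismatch: {len(bvals)} b-values vs "
            f"{bvecs.shape[1]} direction columns"
        )
    vecs = bvecs.T.astype(float)
    nz = bvals > 0
    norms = np.linalg.norm(vecs[nz], axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length direction for a non-zero b-value")
    if np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn("renormalizing gradient directions deviating from unit length")
    vecs[nz] /= np.linalg.norm(vecs[nz], axis=1, keepdims=True)
    vecs[~nz] = 0.0
    return AcquisitionScheme(bvals, vecs)


def write_bvalbvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    Path(bval_path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10f")


def save_orientation_samples(samples, path) -> Path:
    """Store orientation samples as .npz with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        voxels=samples.voxels,
        voxel_index=samples.voxel_index,
        directions=samples.directions,
        fractions=samples.fractions,
        point_directions=samples.point_directions,
        point_fractions=samples.point_fractions,
        support=samples.support,
        fallback=samples.fallback,
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "grid_shape": list(samples.grid_shape),
                "n_voxels": int(len(samples.voxels)),
                "n_samples": int(samples.n_samples),
                "n_fibers": int(samples.n_fibers),
                "rng_seed": int(samples.rng_seed),
            },
            indent=2,
        )
    )
    return path


def load_orientation_samples(path):
    from .tensors import OrientationSamples

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        return OrientationSamples(
            grid_shape=tuple(meta["grid_shape"]),
            voxels=z["voxels"],
            voxel_index=z["voxel_index"],
            directions=z["directions"],
            fractions=z["fractions"],
            point_directions=z["point_directions"],
            point_fractions=z["point_fractions"],
            support=z["support"],
            fallback=z["fallback"],
            rng_seed=meta["rng_seed"],
        )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: list[Path], out_path, extra: dict | None = None) -> Path:
    """JSON manifest of written artifacts with checksums."""
    out_path = Path(out_path)
    entry = {
        "files": [
            {"path": str(p), "sha256": file_sha256(p)} for p in sorted(map(Path, paths))
        ]
    }
    if extra:
        entry.update(extra)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(entry, indent=2))
    return out_path
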