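"""NIfTI / bval / bvec / YAML reading and writing."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
    "check_same_grid",
    "load_yaml",
    "save_yaml",
]

log = logging.getLogger("t1aniso")


def save_nifti(path, data, affine=None):
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return Path(path)


def load_nifti(path):
    """Returns ``(data, affine)`` as float64 / (4, 4)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, dtype=float)


def write_bvals_bvecs(bvals, bvecs, bvals_path, bvecs_path):
    """FSL dialect: one row of b-values, three rows of vector components."""
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape[0] != 3:
        bvecs = bvecs.T
    np.savetxt(bvals_path, bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, bvecs, fmt="%.8f")


def read_bvals_bvecs(bvals_path, bvecs_path, n_volumes=None):
    """Read FSL-style tables; transposed (N, 3) bvec files are auto-detected
    and logged; directions are re-normalised with a warning when their norm
    deviates from 1 by more than 1e-3."""
    bvals = np.atleast_1d(np.loadtxt(bvals_path, dtype=float).ravel())
    bvecs = np.atleast_2d(np.loadtxt(bvecs_path, dtype=float))
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        log.info("bvecs file %s is N x 3; transposing to the 3 x N dialect", bvecs_path)
        bvecs = bvecs.T
    if bvecs.shape != (3, bvals.size):
        raise ValueError(
            f"bvecs shape {bvecs.shape} incompatible with {bvals.size} b-values"
        )
    if n_volumes is not None and bvals.size != n_volumes:
        raise ValueError(
            f"{n_volumes} volumes in the image but {bvals.size} b-values"
        )
    dw = bvals > 50.0
    norms = np.linalg.norm(bvecs[:, dw], axis=0)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn("non-unit gradient directions found; re-normalising")
        bvecs = bvecs.copy()
        bvecs[:, dw] /= np.where(norms > 0, norms, 1.0)
    return bvals, bvecs


def check_same_grid(*pairs, atol: float = 1e-6):
    """Each argument is ``(data, affine)``; raises on any grid or affine
    mismatch (no silent resampling)."""
    if not pairs:
        return
    shape0 = np.asarray(pairs[0][0]).shape[:3]
    aff0 = np.asarray(pairs[0][1])
    for data, aff in pairs[1:]:
        if np.asarray(data).shape[:3] != shape0:
            raise ValueError("input volumes are on different voxel grids")
        if not np.allclose(np.asarray(aff), aff0, atol=atol):
            raise ValueError("input volumes have mismatched affines")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path):
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        if isinstance(x, np.ndarray):
            return clean(x.tolist())
        return x

    with open(path, "w") as fh:
        yaml.safe_dump(clean(obj), fh, sort_keys=False)
    return Path(path)
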