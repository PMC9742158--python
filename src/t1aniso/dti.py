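"""Weighted-least-squares diffusion tensor fitting and derived indices.

The estimator mirrors the classic log-linear tensor fit: an ordinary
least-squares pass on ``ln S`` initialises a single weighted pass whose
weights are the squared *predicted* signals.  Scalar indices (FA, MD) and
the sorted eigensystem are derived per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DWIDataset

__all__ = ["TensorField", "design_matrix", "fit_tensor_wls", "fa", "md"]

B0_THRESHOLD = 50.0
# lower-triangular order of the 6 unique tensor elements
_TENSOR_ELEMENTS = ["Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz"]


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with eigensystem and scalar maps.

    Arrays share the grid shape of the input data.  ``evals`` is sorted
    descending; voxels outside ``mask`` are NaN.  ``negative_evals`` flags
    voxels whose eigenvalues were clamped to zero; ``unreliable`` flags
    near-oblate voxels (lambda1 ~ lambda2) whose V1 orientation is not
    trustworthy.
    """

    tensor: np.ndarray        # (..., 3, 3)
    evals: np.ndarray         # (..., 3)
    evecs: np.ndarray         # (..., 3, 3) columns V1, V2, V3
    fa: np.ndarray
    md: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    negative_evals: np.ndarray
    unreliable: np.ndarray
    log_clipped: np.ndarray

    @property
    def v1(self) -> np.ndarray:
        return self.evecs[..., 0]


def design_matrix(bvals, bvecs) -> np.ndarray:
    """(N, 7) design matrix for ``ln S = X beta`` with
    ``beta = (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    if g.shape[0] != 3:
        g = g.T
    gx, gy, gz = g
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx,
        -b * gy * gy,
        -b * gz * gz,
        -2.0 * b * gx * gy,
        -2.0 * b * gx * gz,
        -2.0 * b * gy * gz,
    ])


def _tensor_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """(..., 6) -> (..., 3, 3) symmetric tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(coeffs, -1, 0)
    out = np.empty(coeffs.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


def fa(evals) -> np.ndarray:
    """Fractional anisotropy from eigenvalues (any leading shape).

    ``FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||``, clipped to [0, 1];
    all-zero eigenvalues give NaN.
    """
    lam = np.asarray(evals, dtype=float)
    if np.any(lam[np.isfinite(lam)] < -1e-12):
        raise ValueError("eigenvalues must be >= 0")
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5) * num / den
    out = np.where(den > 0, out, np.nan)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def md(evals) -> np.ndarray:
    lam = np.asarray(evals, dtype=float)
    out = lam.mean(axis=-1)
    if out.ndim == 0:
        return float(out)
    return out


def _select_volumes(dwi: DWIDataset, shell_policy) -> np.ndarray:
    """Boolean volume selector: all b0s plus the requested shell(s)."""
    b = dwi.bvals
    is_b0 = b <= B0_THRESHOLD
    if shell_policy == "all":
        return np.ones_like(is_b0, dtype=bool)
    if shell_policy == "lowest":
        shells = dwi.shells(B0_THRESHOLD)
        if shells.size == 0:
            raise ValueError("no diffusion-weighted shells present")
        target = shells[0]
    else:
        target = float(shell_policy)
    keep = is_b0 | (np.abs(b - target) <= B0_THRESHOLD)
    if not np.any(np.abs(b - target) <= B0_THRESHOLD):
        raise ValueError(f"no volumes found for shell b={target}")
    return keep


def fit_tensor_wls(dwi: DWIDataset, shell_policy="lowest", n_wls_passes: int = 1) -> TensorField:
    """Fit the diffusion tensor by OLS followed by one WLS pass.

    ``shell_policy`` selects which volumes enter the fit: ``"lowest"``
    (all b = 0 plus the lowest shell — the rule used throughout), ``"all"``,
    or an explicit shell b-value.  Weights for the WLS pass are the squared
    *predicted* signals from the previous pass; ``n_wls_passes=0`` gives the
    plain OLS estimate.  Non-positive signals are replaced by the smallest
    positive observed signal in that voxel before taking the log (flagged in
    ``log_clipped``); all-zero voxels are masked out.
    """
    keep = _select_volumes(dwi, shell_policy)
    if int(keep.sum()) < 7:
        raise ValueError("need at least 7 usable volumes for a tensor fit")

    grid = dwi.grid_shape
    data = dwi.data[..., keep].reshape(-1, int(keep.sum()))
    X = design_matrix(dwi.bvals[keep], dwi.bvecs[:, keep])

    vox = dwi.mask.reshape(-1).copy()
    vox &= np.any(data > 0, axis=1)

    S = data[vox]
    log_clipped = np.zeros(S.shape[0], dtype=bool)
    bad = S <= 0
    if np.any(bad):
        log_clipped = np.any(bad, axis=1)
        floor = np.where(S > 0, S, np.inf).min(axis=1)
        S = np.where(bad, floor[:, None], S)

    y = np.log(S)
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T                       # (V, 7) OLS
    for _ in range(n_wls_passes):
        pred = beta @ X.T
        w = np.exp(2.0 * pred)              # squared predicted signals
        A = np.einsum("ni,vn,nj->vij", X, w, X)
        rhs = np.einsum("ni,vn,vn->vi", X, w, y)
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]

    tensors = _tensor_from_coeffs(beta[:, 1:])
    evals, evecs = np.linalg.eigh(tensors)
    order = np.argsort(evals, axis=-1)[..., ::-1]
    evals = np.take_along_axis(evals, order, axis=-1)
    evecs = np.take_along_axis(evecs, order[:, None, :], axis=-1)

    negative = np.any(evals < 0, axis=-1)
    evals = np.clip(evals, 0.0, None)
    rel_gap = np.where(evals[:, 0] > 0, (evals[:, 0] - evals[:, 1]) / np.where(evals[:, 0] > 0, evals[:, 0], 1.0), 0.0)
    unreliable = rel_gap < 1e-6

    def full(values, fill=np.nan):
        shape = (int(np.prod(grid)),) + values.shape[1:]
        out = np.full(shape, fill, dtype=values.dtype if values.dtype != bool else bool)
        out[vox] = values
        return out.reshape(grid + values.shape[1:])

    fa_v = fa(evals)
    return TensorField(
        tensor=full(tensors),
        evals=full(evals),
        evecs=full(evecs),
        fa=full(fa_v),
        md=full(md(evals)),
        s0=full(np.exp(beta[:, 0])),
        mask=vox.reshape(grid),
        negative_evals=full(negative, fill=False),
        unreliable=full(unreliable, fill=False),
        log_clipped=full(log_clipped, fill=False),
    )
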