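"""Shared in-memory data containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DWIDataset"]


@dataclass
class DWIDataset:
    """A 4D diffusion-weighted dataset with its gradient table.

    ``data`` has shape (nx, ny, nz, nvol); ``bvals`` (nvol,) in s/mm^2;
    ``bvecs`` (3, nvol) unit columns (zero columns for b = 0 volumes);
    ``mask`` marks voxels eligible for fitting.
    """

    data: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, volume)")
        if self.bvecs.shape == (self.bvals.size, 3) and self.bvecs.shape[0] != 3:
            self.bvecs = self.bvecs.T
        if self.bvecs.shape != (3, self.bvals.size):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match {self.bvals.size} b-values"
            )
        if self.data.shape[-1] != self.bvals.size:
            raise ValueError(
                f"{self.data.shape[-1]} volumes but {self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be >= 0")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[:, dw], axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("diffusion gradient directions must have unit norm")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape does not match data grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def shells(self, b0_threshold: float = 50.0) -> np.ndarray:
        """Sorted unique nonzero shell b-values."""
        b = self.bvals[self.bvals > b0_threshold]
        return np.unique(np.round(b))
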