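"""Shared primitives: acquisition schemes, grid helpers, small mask utilities.

All core code works in 0-based voxel index coordinates on axis-aligned,
isotropic unit-voxel grids; world coordinates (NIfTI affines) appear only at
the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "default_scheme",
    "fibonacci_directions",
    "dice",
    "ball_mask",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when a requested geometry does not fit the voxel grid."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """Single-shell diffusion acquisition table.

    Attributes
    ----------
    bvals : (n,) array of b-values in s/mm^2; must include at least one zero.
    bvecs : (n, 3) array of gradient directions; unit norm for b > 0 rows,
        (0, 0, 0) allowed for b = 0 rows.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"length mismatch: {len(bvals)} b-values vs {len(bvecs)} directions"
            )
        if not np.any(bvals == 0):
            raise ValueError("scheme must contain at least one b=0 volume")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("non-zero-b gradient directions must be unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


def fibonacci_directions(n: int) -> np.ndarray:
    """`n` roughly uniformly spread unit vectors on the hemisphere.

    Deterministic spherical Fibonacci lattice, folded onto one hemisphere
    (diffusion gradients are antipodally symmetric).
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - i / n  # upper hemisphere-ish band
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    v = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def default_scheme(n_dirs: int = 32, n_b0: int = 4, bval: float = 1000.0) -> AcquisitionScheme:
    """Desk-scale analogue of a 64-direction single-shell acquisition.

    b = 1000 s/mm^2 with `n_dirs` non-collinear directions plus `n_b0`
    unweighted volumes (defaults scaled down from 64 + 4 for speed).
    """
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), fibonacci_directions(n_dirs)])
    return AcquisitionScheme(bvals, bvecs)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * np.logical_and(a, b).sum() / denom


def ball_mask(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    """Binary ball of `radius` voxels around `center` (voxel coordinates)."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2
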