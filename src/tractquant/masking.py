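"""Tract-center sampling masks: FA ridge skeleton plus CSF/GM exclusion.

The skeleton marks voxels that are local FA maxima along the perpendicular-
to-tract direction, estimated from the Hessian of the (smoothed) cohort mean
FA map — a thin sheet/curve set through the centers of large tracts, used
purely as a mask.  Three sampling configurations mirror the analysis:
no masking, skeleton masking, and skeleton + CSF + GM masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .templates import TractTemplate
from .tensors import ScalarMap

__all__ = ["SamplingMask", "skeletonize", "make_sampling_mask", "MASK_CONFIGS"]

MASK_CONFIGS = ("none", "skeleton", "skeleton+gm+csf")


@dataclass
class SamplingMask:
    """Binary sampling region for one tract under one masking configuration."""

    mask: np.ndarray
    config_label: str
    tract_id: str

    def __post_init__(self) -> None:
        if self.config_label not in MASK_CONFIGS:
            raise ValueError(f"unknown masking config {self.config_label!r}")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def _sample_along(fa: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA linearly interpolated one voxel forward/backward along field d."""
    shape = fa.shape
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"), axis=0
    )
    fwd = ndimage.map_coordinates(fa, idx + np.moveaxis(d, -1, 0), order=1, mode="nearest")
    bwd = ndimage.map_coordinates(fa, idx - np.moveaxis(d, -1, 0), order=1, mode="nearest")
    return fwd, bwd


def skeletonize(mean_fa: ScalarMap | np.ndarray, fa_floor: float = 0.2, smooth_sigma: float = 1.0) -> np.ndarray:
    """Ridge skeleton of a mean FA map.

    A voxel joins the skeleton when its FA is at least `fa_floor` and is a
    local maximum along the direction(s) of strongest negative curvature of
    the smoothed FA field (Hessian eigenvectors) — the perpendicular-to-tract
    search of skeleton-based masking, as non-maximum suppression.  Returns an
    empty mask with a warning if no voxel clears the floor.
    """
    fa = mean_fa.values if isinstance(mean_fa, ScalarMap) else np.asarray(mean_fa, float)
    above = fa >= fa_floor
    if not above.any():
        warnings.warn("no voxels at or above fa_floor; skeleton is empty")
        return np.zeros(fa.shape, bool)

    sm = ndimage.gaussian_filter(fa, smooth_sigma)
    grads = np.gradient(sm)
    gvec = np.stack(grads, axis=-1)
    gnorm = np.linalg.norm(gvec, axis=-1)
    H = np.empty(fa.shape + (3, 3))
    for i in range(3):
        gi = np.gradient(grads[i])
        for j in range(3):
            H[..., i, j] = gi[j]
    H = 0.5 * (H + np.swapaxes(H, -1, -2))
    w, v = np.linalg.eigh(H)  # ascending: w[...,0] most negative

    # flank voxels (strong FA gradient): non-maximum suppression along the
    # gradient direction — FA rises toward the ridge, so these drop out
    gdir = gvec / np.maximum(gnorm, 1e-12)[..., None]
    fwd_g, bwd_g = _sample_along(sm, gdir)
    cond_grad = (sm + 1e-12 >= fwd_g) & (sm + 1e-12 >= bwd_g)

    # on-ridge voxels (vanishing gradient): local maximum along the most
    # negative Hessian curvature direction(s)
    cond_hess = w[..., 0] < 0
    fwd, bwd = _sample_along(sm, v[..., :, 0])
    cond_hess &= (sm + 1e-12 >= fwd) & (sm + 1e-12 >= bwd)
    # tube-like regions: second curvature also strongly negative -> require a
    # maximum along that direction too, thinning the sheet to a curve
    tube = w[..., 1] < 0.5 * w[..., 0]
    if tube.any():
        fwd2, bwd2 = _sample_along(sm, v[..., :, 1])
        ok2 = (sm + 1e-12 >= fwd2) & (sm + 1e-12 >= bwd2)
        cond_hess &= ~tube | ok2

    strong = gnorm > 0.02
    return above & np.where(strong, cond_grad & cond_hess, cond_hess)


def make_sampling_mask(
    template: TractTemplate,
    skeleton: np.ndarray | None,
    csf: np.ndarray | None,
    gm: np.ndarray | None,
    config_label: str,
) -> SamplingMask:
    """Combine template, skeleton and tissue masks into a sampling region.

    ``none`` -> template; ``skeleton`` -> template ∩ skeleton;
    ``skeleton+gm+csf`` -> template ∩ skeleton minus (csf ∪ gm).
    An empty result is an error: the tract cannot be sampled.
    """
    if config_label not in MASK_CONFIGS:
        raise ValueError(f"unknown masking config {config_label!r}")
    mask = template.mask.copy()
    if config_label in ("skeleton", "skeleton+gm+csf"):
        if skeleton is None:
            raise ValueError("skeleton mask required for this configuration")
        if skeleton.shape != mask.shape:
            raise ValueError("skeleton is not on the template grid")
        mask &= np.asarray(skeleton, bool)
    if config_label == "skeleton+gm+csf":
        if csf is None or gm is None:
            raise ValueError("csf and gm masks required for this configuration")
        mask &= ~(np.asarray(csf, bool) | np.asarray(gm, bool))
    if not mask.any():
        raise ValueError(
            f"sampling mask for tract {template.tract_id!r} is empty under "
            f"config {config_label!r}"
        )
    return SamplingMask(mask=mask, config_label=config_label, tract_id=template.tract_id)
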