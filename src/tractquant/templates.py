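"""Mean tract templates and volume-matched individual binarization.

Templates are built by averaging normalized connectivity maps from controls
in the common grid, thresholding the mean at a percentile of its nonzero
distribution, and binarizing.  Individual maps are compared through
volume-matched binarization: keep exactly as many top-connectivity voxels as
the template contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GeometryError
from .tracking import ConnectivityMap

__all__ = [
    "TractTemplate",
    "resample_to_common",
    "build_template",
    "volume_matched_binarize",
]


@dataclass
class TractTemplate:
    """Binary tract mask in the common grid, with provenance."""

    mask: np.ndarray
    tract_id: str
    n_subjects: int
    percentile: float
    threshold: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")
        if not np.any(self.mask):
            raise ValueError(f"template mask for {self.tract_id!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def resample_to_common(cmap: ConnectivityMap, displacement: np.ndarray) -> ConnectivityMap:
    """Nearest-neighbor pull of a connectivity map into the common grid.

    ``out[x] = in[round(x + displacement[x])]`` — no new values are created,
    matching nearest-neighbor interpolation of connectivity values.  In
    phantom mode the displacement is the (approximate) inverse of the
    subject's jitter field.
    """
    from .phantom import nn_warp  # local import; phantom depends on tracking

    if displacement.shape[:3] != cmap.counts.shape:
        raise GeometryError("displacement grid does not match connectivity grid")
    counts = nn_warp(cmap.counts, displacement)
    return ConnectivityMap(
        counts=counts,
        total_streamlines=cmap.total_streamlines,
        n_reached=cmap.n_reached,
        normalized=counts / max(cmap.total_streamlines, 1),
        tract_id=cmap.tract_id,
        config=cmap.config,
    )


def build_template(
    maps: list[ConnectivityMap] | list[np.ndarray],
    percentile: float = 95.0,
    tract_id: str = "tract",
    include_zeros: bool = False,
    provenance: tuple[str, ...] = (),
) -> TractTemplate:
    """Average normalized connectivity maps, threshold, binarize.

    The threshold is the given percentile (linear interpolation between order
    statistics) of the mean map's values over its nonzero support — or over
    all voxels with ``include_zeros=True``.  Voxels strictly exceeding the
    threshold are retained.
    """
    arrays = [m.normalized if isinstance(m, ConnectivityMap) else np.asarray(m, float) for m in maps]
    if len(arrays) < 2:
        raise ValueError("need at least 2 maps to build a template")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("connectivity maps are not on a common grid")

    mean = np.mean(arrays, axis=0)
    support = mean > 0
    if not support.any():
        raise ValueError("mean connectivity map has empty nonzero support")
    pool = mean.ravel() if include_zeros else mean[support]
    threshold = float(np.percentile(pool, percentile))
    mask = mean > threshold
    return TractTemplate(
        mask=mask,
        tract_id=tract_id,
        n_subjects=len(arrays),
        percentile=float(percentile),
        threshold=threshold,
        provenance=tuple(provenance),
    )


def volume_matched_binarize(
    cmap: ConnectivityMap | np.ndarray, template: TractTemplate
) -> tuple[np.ndarray, bool]:
    """Binarize an individual map to exactly the template's voxel count.

    Returns ``(mask, shortfall)``: the V highest-connectivity voxels, where V
    is the template volume; ties at the cut broken deterministically by
    (value descending, linear voxel index ascending).  If the map has fewer
    than V nonzero voxels, all of them are returned with ``shortfall=True``.
    """
    values = cmap.normalized if isinstance(cmap, ConnectivityMap) else np.asarray(cmap, float)
    if values.shape != template.mask.shape:
        raise GeometryError("map and template are not on the same grid")
    flat = values.ravel()
    nz = np.flatnonzero(flat > 0)
    if len(nz) == 0:
        raise ValueError("connectivity map is empty (no nonzero voxels)")
    V = template.n_voxels
    out = np.zeros(flat.shape, bool)
    if len(nz) <= V:
        out[nz] = True
        return out.reshape(values.shape), len(nz) < V
    order = np.lexsort((nz, -flat[nz]))  # value desc, then index asc
    out[nz[order[:V]]] = True
    return out.reshape(values.shape), False
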