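"""Probabilistic streamline tractography on orientation-sample fields.

Each streamline repeatedly draws a direction sample from the current voxel's
orientation PDF, enforces a curvature threshold (minimum cosine with the
previous step, sign flip allowed), and advances by a fixed step.  Streamlines
are propagated from every seed voxel in both directions; a streamline counts
toward the connectivity map only if it reaches the target, and is discarded
entirely if either half enters the exclusion mask.  Visit counts are
normalized by the total number of generated streamlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensors import OrientationSamples

__all__ = ["ROISet", "TrackingConfig", "ConnectivityMap", "track", "tract_success_rate"]


@dataclass
class ROISet:
    """Seed/target/exclusion and tissue masks for one tract, common grid."""

    seed: np.ndarray
    targets: dict[str, np.ndarray]
    exclusion: np.ndarray
    csf: np.ndarray
    gm: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.seed & self.exclusion):
            raise ValueError("seed and exclusion masks overlap")


@dataclass(frozen=True)
class TrackingConfig:
    """Streamline propagation parameters.

    `curvature_threshold` is the minimum cosine between consecutive steps
    (0.2 by convention); `step_size` is in voxel units.
    """

    n_samples_per_seed_voxel: int = 500
    curvature_threshold: float = 0.2
    step_size: float = 0.5
    max_steps: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.curvature_threshold <= 1.0:
            raise ValueError("curvature_threshold must lie in [-1, 1]")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.n_samples_per_seed_voxel < 1 or self.max_steps < 1:
            raise ValueError("n_samples_per_seed_voxel and max_steps must be >= 1")


@dataclass
class ConnectivityMap:
    """Visit counts of target-reaching streamlines for one seed->target tract."""

    counts: np.ndarray  # (X, Y, Z) int, one count per streamline per voxel
    total_streamlines: int
    n_reached: int
    normalized: np.ndarray  # counts / total_streamlines
    tract_id: str
    config: TrackingConfig | None = None


def tract_success_rate(cmap: ConnectivityMap) -> float:
    """Fraction of generated streamlines that reached the target."""
    if cmap.total_streamlines == 0:
        return 0.0
    return cmap.n_reached / cmap.total_streamlines


def _half_walk(
    samples: OrientationSamples,
    start_vox: np.ndarray,
    init_dir: np.ndarray,
    sign: float,
    target: np.ndarray,
    exclusion: np.ndarray,
    config: TrackingConfig,
    rng: np.random.Generator,
):
    """Propagate M walkers from seed voxel centers along sign*init_dir.

    Returns (reached, excluded, visit_pairs) where visit_pairs is an
    (n_visits, 2) array of [walker_id, linear_voxel] rows, consecutive-
    deduplicated per walker.
    """
    shape = np.asarray(samples.grid_shape)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    idx_vol = samples.voxel_index
    dirs = samples.directions  # (nf, N, S, 3)
    support = samples.support
    nf, _, S, _ = dirs.shape

    M = len(start_vox)
    pos = start_vox.astype(float)
    prev = sign * init_dir
    active = np.ones(M, bool)
    reached = np.zeros(M, bool)
    excluded = np.zeros(M, bool)
    last_vox = np.full(M, -1, np.int64)
    wid = np.arange(M)
    pairs: list[np.ndarray] = []

    tgt = np.asarray(target, bool)
    excl = np.asarray(exclusion, bool)

    for _ in range(config.max_steps):
        if not active.any():
            break
        a = np.where(active)[0]
        vox = np.rint(pos[a]).astype(np.int64)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        if not inside.all():
            active[a[~inside]] = False
            a = a[inside]
            vox = vox[inside]
            if len(a) == 0:
                continue
        vi, vj, vk = vox.T
        lin = vox @ strides

        # record entry into a new voxel
        newv = lin != last_vox[a]
        if newv.any():
            pairs.append(np.column_stack([wid[a[newv]], lin[newv]]))
            last_vox[a[newv]] = lin[newv]

        hit_t = tgt[vi, vj, vk]
        hit_e = excl[vi, vj, vk]
        if hit_t.any():
            reached[a[hit_t]] = True
            active[a[hit_t]] = False
        if hit_e.any():
            excluded[a[hit_e]] = True
            active[a[hit_e]] = False
        keep = ~(hit_t | hit_e)
        a = a[keep]
        if len(a) == 0:
            continue
        row = idx_vol[vi[keep], vj[keep], vk[keep]]
        nodata = row < 0
        # voxels whose dominant fiber fraction fell below the support
        # threshold stop propagation (anisotropy-constraint analogue)
        nodata |= ~support[0, np.maximum(row, 0)]
        if nodata.any():
            active[a[nodata]] = False
            a = a[~nodata]
            row = row[~nodata]
            if len(a) == 0:
                continue

        k = rng.integers(0, S, size=len(a))
        cand = dirs[0, row, k].astype(float)  # (m, 3)
        cos = np.einsum("mc,mc->m", cand, prev[a])
        if nf == 2:
            sup2 = support[1, row]
            cand2 = dirs[1, row, k].astype(float)
            cos2 = np.einsum("mc,mc->m", cand2, prev[a])
            use2 = sup2 & (np.abs(cos2) > np.abs(cos))
            cand = np.where(use2[:, None], cand2, cand)
            cos = np.where(use2, cos2, cos)

        flip = cos < 0
        cand[flip] *= -1.0
        cos = np.abs(cos)
        ok = cos > config.curvature_threshold
        active[a[~ok]] = False
        a = a[ok]
        if len(a) == 0:
            continue
        step_dir = cand[ok]
        pos[a] += config.step_size * step_dir
        prev[a] = step_dir

    if pairs:
        visit = np.concatenate(pairs, axis=0)
    else:
        visit = np.empty((0, 2), np.int64)
    return reached, excluded, visit


def track(
    samples: OrientationSamples,
    rois: ROISet,
    target_name: str,
    config: TrackingConfig,
    tract_id: str | None = None,
) -> ConnectivityMap:
    """Run probabilistic tractography from seed to the named target.

    `config.n_samples_per_seed_voxel` streamlines start at the center of each
    seed voxel; each is propagated in both directions from its first drawn
    orientation sample.  Streamlines touching the exclusion mask are dropped;
    those reaching the target contribute one count per visited voxel.
    """
    seed = np.asarray(rois.seed, bool)
    if not seed.any():
        raise ValueError("empty seed mask")
    if target_name not in rois.targets:
        raise KeyError(f"unknown target {target_name!r}")
    target = np.asarray(rois.targets[target_name], bool)
    if np.any(seed & target):
        raise ValueError("target overlaps seed")

    seed_vox = np.argwhere(seed)
    nspv = config.n_samples_per_seed_voxel
    M = len(seed_vox) * nspv
    start = np.repeat(seed_vox, nspv, axis=0)

    rng = np.random.default_rng(config.rng_seed)

    # initial direction: a fiber-1 sample at the seed voxel
    row0 = samples.voxel_index[tuple(start.T)]
    has = (row0 >= 0) & samples.support[0, np.maximum(row0, 0)]
    k0 = rng.integers(0, samples.n_samples, size=M)
    init = np.zeros((M, 3))
    init[has] = samples.directions[0, row0[has], k0[has]].astype(float)

    res_f = _half_walk(
        samples, start[has], init[has], +1.0, target, rois.exclusion, config, rng
    )
    res_b = _half_walk(
        samples, start[has], init[has], -1.0, target, rois.exclusion, config, rng
    )

    reached = np.zeros(M, bool)
    excluded = np.zeros(M, bool)
    hid = np.where(has)[0]
    reached[hid] = res_f[0] | res_b[0]
    excluded[hid] = res_f[1] | res_b[1]
    good = reached & ~excluded

    shape = samples.grid_shape
    counts = np.zeros(shape, np.int64)
    visit = np.concatenate(
        [np.column_stack([hid[v[:, 0]], v[:, 1]]) for v in (res_f[2], res_b[2])]
    )
    if len(visit):
        keep = good[visit[:, 0]]
        visit = visit[keep]
        if len(visit):
            key = np.unique(visit[:, 0] * np.prod(shape) + visit[:, 1])
            voxlin = key % np.prod(shape)
            np.add.at(counts.ravel(), voxlin, 1)

    return ConnectivityMap(
        counts=counts,
        total_streamlines=M,
        n_reached=int(good.sum()),
        normalized=counts / M,
        tract_id=tract_id or target_name,
        config=config,
    )
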