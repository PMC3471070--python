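"""Synthetic diffusion-MRI phantom cohorts.

Generates multi-subject 4D DWI volumes containing curved anisotropic tract
bundles (ball-and-stick voxels) embedded in an isotropic background, with
Rician noise, smooth per-subject spatial jitter standing in for residual
registration error, and graded injury (reduced stick fraction, elevated
diffusivity) in known locations.  Every downstream stage of the analysis is
testable against the ground truth emitted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree

from .core import AcquisitionScheme, GeometryError, ball_mask, default_scheme
from .tensors import DWIVolume
from .tracking import ROISet

__all__ = [
    "FiberField",
    "PhantomTruth",
    "CohortSpec",
    "TractSpec",
    "Subject",
    "Cohort",
    "sample_curve",
    "make_tract_field",
    "inject_damage",
    "simulate_dwi",
    "dti_truth",
    "smooth_displacement",
    "nn_warp",
    "default_geometry",
    "make_cohort",
]

# Damaged voxels: diffusivity is multiplied by (1 + s_eff) and each stick
# volume fraction by (1 - s_eff)**DAMAGE_FRACTION_EXPONENT.  The quadratic
# fraction loss makes fiber-orientation contrast degrade gradually through
# the trackability floor as severity grows (a linear loss keeps orientations
# recoverable until s_eff ~ 0.9 at workable SNR, making tractography failure
# a step function instead of graded).  Severity 1 leaves a purely isotropic
# compartment with doubled diffusivity (FA -> 0, MD up).
DAMAGE_DIFFUSIVITY_FACTOR = 1.0
DAMAGE_FRACTION_EXPONENT = 2


@dataclass
class FiberField:
    """Ground-truth ball-and-stick parameter field on a voxel grid.

    ``fractions[..., k]`` and ``directions[..., k, :]`` describe fiber
    population ``k``; the isotropic "ball" takes up the remaining
    ``1 - sum(fractions)`` of each voxel.  ``d`` is the shared diffusivity
    (mm^2/s) and ``S0`` the unweighted signal.
    """

    S0: np.ndarray  # (X, Y, Z)
    d: np.ndarray  # (X, Y, Z) mm^2/s
    fractions: np.ndarray  # (X, Y, Z, K)
    directions: np.ndarray  # (X, Y, Z, K, 3), unit where fraction > 0

    def __post_init__(self) -> None:
        if np.any(self.d <= 0):
            raise ValueError("isotropic diffusivity must be positive everywhere")
        fsum = self.fractions.sum(axis=-1)
        if np.any(fsum > 1 + 1e-9):
            raise ValueError("per-voxel volume fractions must sum to <= 1")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.S0.shape

    def copy(self) -> "FiberField":
        return FiberField(
            self.S0.copy(), self.d.copy(), self.fractions.copy(), self.directions.copy()
        )


@dataclass
class PhantomTruth:
    """Ground truth for one phantom subject."""

    tract_masks: dict[str, np.ndarray]
    true_fa: np.ndarray
    true_md: np.ndarray
    damage_mask: np.ndarray
    damage_severity: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_controls: int
    n_patients: int
    jitter_voxels: float = 1.25
    noise_sigma: float = 5.0
    damage_severities: tuple[float, ...] = ()
    rng_seed: int = 0
    n_heldout: int = 0
    damage_mode: str = "focal"  # "focal" mid-tract block or "diffuse" whole tract
    # residual misregistration: jitter that the analysis-time warp does NOT
    # recover (the stand-in for imperfect nonlinear registration)
    misreg_voxels: float = 0.6

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")
        if self.jitter_voxels < 0 or self.noise_sigma < 0 or self.misreg_voxels < 0:
            raise ValueError("jitter_voxels, noise_sigma, misreg_voxels must be >= 0")
        if len(self.damage_severities) != self.n_patients:
            raise ValueError("need exactly one damage severity per patient")
        if any(not 0 <= s <= 1 for s in self.damage_severities):
            raise ValueError("severities must lie in [0, 1]")
        if self.damage_mode not in ("focal", "diffuse"):
            raise ValueError(f"unknown damage_mode {self.damage_mode!r}")


@dataclass(frozen=True)
class TractSpec:
    """A curved bundle: spline control points (voxel coords) + tube radius."""

    tract_id: str
    control_points: np.ndarray
    radius: float


@dataclass
class Subject:
    subject_id: str
    role: str  # control | patient | heldout
    severity: float
    dwi: DWIVolume
    truth: PhantomTruth
    rois: dict[str, ROISet]
    to_common_disp: np.ndarray  # displacement field mapping common -> subject lookup


@dataclass
class Cohort:
    spec: CohortSpec
    scheme: AcquisitionScheme
    subjects: list[Subject]
    base_truth: PhantomTruth
    base_rois: dict[str, ROISet]
    damage_region: np.ndarray
    damage_weight: np.ndarray | None = None

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.role == "control"]

    @property
    def patients(self) -> list[Subject]:
        return [s for s in self.subjects if s.role == "patient"]

    @property
    def heldout(self) -> list[Subject]:
        return [s for s in self.subjects if s.role == "heldout"]


# ---------------------------------------------------------------------------
# geometry


def sample_curve(control_points: np.ndarray, n: int = 400):
    """Densely sample a spline through `control_points`.

    Returns (points (n,3), unit tangents (n,3)).  Degree is min(3, npts-1),
    so two control points give the straight segment between them.
    """
    cp = np.asarray(control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 2:
        raise ValueError("control_points must be (>=2, 3)")
    k = min(3, len(cp) - 1)
    t = np.linspace(0.0, 1.0, len(cp))
    spl = make_interp_spline(t, cp, k=k)
    ts = np.linspace(0.0, 1.0, n)
    pts = spl(ts)
    tang = spl.derivative()(ts)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.where(norms > 0, norms, 1.0)
    return pts, tang


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points `p` to segments `a`-`b` (row-wise)."""
    ab = b - a
    denom = np.einsum("...c,...c->...", ab, ab)
    t = np.einsum("...c,...c->...", p - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(p - proj, axis=-1)


def make_tract_field(
    control_points: np.ndarray,
    radius: float,
    grid_shape: tuple[int, int, int],
    fiber_fraction: float = 0.7,
    d: float = 1.7e-3,
    S0: float = 100.0,
    background_d: float = 0.9e-3,
    field: FiberField | None = None,
    population: int = 0,
):
    """Embed a tube of tangent-aligned stick voxels in an isotropic field.

    Voxels whose center lies within `radius` of the spline carry one fiber
    population tangent to the curve; everything else stays isotropic.  Pass
    an existing `field` to add further bundles.  Returns (field, tract_mask).
    """
    if radius < 1:
        raise GeometryError("tube radius must be at least 1 voxel")
    pts, tang = sample_curve(np.asarray(control_points, float))
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if np.any(lo - radius < -0.5) or np.any(hi + radius > np.asarray(grid_shape) - 0.5):
        raise GeometryError(
            f"curve (extent {lo}..{hi}, radius {radius}) exits grid {grid_shape}"
        )

    if field is None:
        K = max(population + 1, 1)
        field = FiberField(
            S0=np.full(grid_shape, float(S0)),
            d=np.full(grid_shape, float(background_d)),
            fractions=np.zeros(grid_shape + (K,)),
            directions=np.zeros(grid_shape + (K, 3)),
        )
    elif population >= field.fractions.shape[-1]:
        raise ValueError("population index exceeds field capacity")

    centers = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    _, idx = cKDTree(pts).query(centers, k=1)
    # refine to the exact distance to the two polyline segments adjacent to
    # the nearest sample, so boundary voxels are classified correctly
    dist = np.minimum(
        _segment_distance(centers, pts[np.maximum(idx - 1, 0)], pts[idx]),
        _segment_distance(centers, pts[idx], pts[np.minimum(idx + 1, len(pts) - 1)]),
    )
    mask = (dist <= radius + 1e-9).reshape(grid_shape)
    nearest_tangent = tang[idx].reshape(grid_shape + (3,))

    field.fractions[mask, population] = fiber_fraction
    field.directions[mask, population, :] = nearest_tangent[mask]
    field.d[mask] = d
    return field, mask


# ---------------------------------------------------------------------------
# forward model and truth


def simulate_dwi(
    field: FiberField,
    scheme: AcquisitionScheme,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DWIVolume:
    """Ball-and-stick forward simulation with optional Rician noise.

    Noiseless signal per voxel and volume:
    ``S = S0 * [(1 - sum_j f_j) exp(-b d) + sum_j f_j exp(-b d (g.v_j)^2)]``.
    Rician noise is the magnitude of a complex Gaussian perturbation with
    standard deviation `noise_sigma` (in S0 units) per channel.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    b = scheme.bvals  # (n,)
    g = scheme.bvecs  # (n, 3)
    f = field.fractions  # (..., K)
    v = field.directions  # (..., K, 3)
    d = field.d[..., None]  # (..., 1)

    ball = (1.0 - f.sum(axis=-1))[..., None] * np.exp(-b * d)  # (..., n)
    # cos^2 between each gradient and each population direction
    c2 = np.einsum("...kc,nc->...kn", v, g) ** 2  # (..., K, n)
    stick = np.einsum("...k,...kn->...n", f, np.exp(-b * d[..., None] * c2))
    signal = field.S0[..., None] * (ball + stick)

    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        n2 = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    return DWIVolume(signal=signal, scheme=scheme, voxel_size=voxel_size)


def _adc_tensor_maps(adc: np.ndarray, scheme: AcquisitionScheme):
    """Solve the apparent tensor from per-direction ADCs by normal equations."""
    g = scheme.bvecs[scheme.dwi_mask]
    B = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    dvec = np.linalg.solve(B.T @ B, B.T @ adc.reshape(-1, B.shape[0]).T).T
    D = np.empty(adc.shape[:-1] + (3, 3))
    flat = dvec.reshape(-1, 6)
    D = D.reshape(-1, 3, 3)
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = flat[:, 0], flat[:, 1], flat[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = flat[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = flat[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = flat[:, 5]
    return D.reshape(adc.shape[:-1] + (3, 3))


def dti_truth(field: FiberField, scheme: AcquisitionScheme):
    """Closed-form FA/MD ground truth at the acquisition b-value.

    The ball-and-stick mixture is not Gaussian, so "true" FA/MD are defined
    as the apparent diffusion tensor a log-linear DTI fit sees on noiseless
    data: per-direction ADC evaluated analytically from the mixture signal,
    projected onto a tensor by exact normal equations.  For purely isotropic
    (f = 0) and single-stick (f = 1) voxels this reduces to the textbook
    closed forms d*I and d*vv^T.  Returns (true_fa, true_md).
    """
    b = scheme.bvals[scheme.dwi_mask]
    g = scheme.bvecs[scheme.dwi_mask]
    f = field.fractions
    v = field.directions
    d = field.d[..., None]
    ball = (1.0 - f.sum(axis=-1))[..., None] * np.exp(-b * d)
    c2 = np.einsum("...kc,nc->...kn", v, g) ** 2
    stick = np.einsum("...k,...kn->...n", f, np.exp(-b * d[..., None] * c2))
    frac = ball + stick  # S / S0, strictly positive
    adc = -np.log(frac) / b

    D = _adc_tensor_maps(adc, scheme)
    lam = np.linalg.eigvalsh(D)[..., ::-1]
    md = lam.mean(axis=-1)
    num = ((lam - md[..., None]) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md


# ---------------------------------------------------------------------------
# damage


def inject_damage(
    field: FiberField,
    truth: PhantomTruth,
    severity: float,
    region: np.ndarray,
    scheme: AcquisitionScheme | None = None,
    weight: np.ndarray | None = None,
):
    """Scale down fiber fractions and scale up diffusivity inside `region`.

    The per-voxel effective severity is ``severity * weight`` (weight
    defaults to 1 inside `region`, giving a uniform lesion); each stick
    volume fraction is multiplied by ``(1 - s_eff)`` and the diffusivity by
    ``(1 + s_eff)``, so true FA falls and true MD rises monotonically with
    severity.  A graded `weight` (e.g. strongest at the tract core) yields
    spatially graded damage.  Returns the modified (field, truth) — both new
    objects.
    """
    if not 0 <= severity <= 1:
        raise ValueError("severity must lie in [0, 1]")
    region = np.asarray(region, bool)
    if region.shape != field.grid_shape:
        raise GeometryError(
            f"damage region shape {region.shape} does not match grid {field.grid_shape}"
        )
    if weight is None:
        w = region.astype(float)
    else:
        w = np.clip(np.asarray(weight, float), 0.0, 1.0) * region
    s_eff = severity * w
    out = field.copy()
    out.fractions *= ((1.0 - s_eff) ** DAMAGE_FRACTION_EXPONENT)[..., None]
    out.d *= 1.0 + DAMAGE_DIFFUSIVITY_FACTOR * s_eff

    scheme = scheme if scheme is not None else default_scheme()
    fa, md = dti_truth(out, scheme)
    new_truth = PhantomTruth(
        tract_masks={k: m.copy() for k, m in truth.tract_masks.items()},
        true_fa=fa,
        true_md=md,
        damage_mask=region.copy(),
        damage_severity=float(severity),
    )
    return out, new_truth


# ---------------------------------------------------------------------------
# jitter / warping


def smooth_displacement(
    grid_shape: tuple[int, int, int],
    max_voxels: float,
    rng: np.random.Generator,
    coarse: int = 5,
) -> np.ndarray:
    """Band-limited random displacement field bounded in max-norm.

    Gaussian noise on a coarse lattice, spline-upsampled to the grid and
    rescaled so the largest displacement component equals `max_voxels`.
    """
    if max_voxels == 0:
        return np.zeros(grid_shape + (3,))
    comps = []
    for _ in range(3):
        c = rng.normal(size=(coarse, coarse, coarse))
        z = ndimage.zoom(c, [s / coarse for s in grid_shape], order=3)
        comps.append(z[: grid_shape[0], : grid_shape[1], : grid_shape[2]])
    u = np.stack(comps, axis=-1)
    peak = np.abs(u).max()
    if peak > 0:
        u *= max_voxels / peak
    return u


def nn_warp(volume: np.ndarray, disp: np.ndarray, fill=0) -> np.ndarray:
    """Pull-warp by nearest neighbor: ``out[x] = volume[round(x + disp[x])]``.

    Out-of-grid lookups yield `fill`.  Works on 3D volumes and on fields with
    trailing component axes (shape (X,Y,Z,...)).
    """
    shape = disp.shape[:3]
    if volume.shape[:3] != shape:
        raise GeometryError("displacement grid does not match volume grid")
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    src = np.rint(idx + disp).astype(np.int64)
    inside = np.all((src >= 0) & (src < np.asarray(shape)), axis=-1)
    src_c = np.clip(src, 0, np.asarray(shape) - 1)
    out = volume[src_c[..., 0], src_c[..., 1], src_c[..., 2]]
    out = np.where(
        inside.reshape(shape + (1,) * (out.ndim - 3)), out, np.asarray(fill, out.dtype)
    )
    return out


def _warp_field(field: FiberField, disp: np.ndarray) -> FiberField:
    return FiberField(
        S0=nn_warp(field.S0, disp, fill=field.S0.ravel()[0]),
        d=nn_warp(field.d, disp, fill=field.d.ravel()[0]),
        fractions=nn_warp(field.fractions, disp),
        directions=nn_warp(field.directions, disp),
    )


def _warp_rois(rois: ROISet, disp: np.ndarray) -> ROISet:
    return ROISet(
        seed=nn_warp(rois.seed, disp, fill=False),
        targets={k: nn_warp(v, disp, fill=False) for k, v in rois.targets.items()},
        exclusion=nn_warp(rois.exclusion, disp, fill=False),
        csf=nn_warp(rois.csf, disp, fill=False),
        gm=nn_warp(rois.gm, disp, fill=False),
    )


# ---------------------------------------------------------------------------
# cohort assembly


def default_geometry(grid: int = 40) -> list[TractSpec]:
    """Two mirrored curved bundles (left/right analogues) in a `grid`^3 box."""
    s = grid / 40.0
    left = np.array([[6, 12, 18], [20, 12, 27], [34, 12, 18]]) * s
    right = np.array([[6, 27, 18], [20, 27, 27], [34, 27, 18]]) * s
    return [
        TractSpec("left", left, 2.5 * s),
        TractSpec("right", right, 2.5 * s),
    ]


def _build_base(
    tracts: list[TractSpec],
    grid_shape: tuple[int, int, int],
    fiber_fraction: float,
    tract_d: float,
    S0: float,
    csf_d: float = 3.0e-3,
):
    field = None
    masks: dict[str, np.ndarray] = {}
    for ts in tracts:
        field, mask = make_tract_field(
            ts.control_points,
            ts.radius,
            grid_shape,
            fiber_fraction=fiber_fraction,
            d=tract_d,
            S0=S0,
            field=field,
        )
        masks[ts.tract_id] = mask
    all_tracts = np.any(list(masks.values()), axis=0)
    # CSF shell directly hugging the bundles: the partial-volume hazard that
    # makes unmasked edge sampling unstable under registration jitter
    rim = ndimage.binary_dilation(all_tracts, iterations=1) & ~all_tracts
    field.d[rim] = csf_d

    ymid = grid_shape[1] // 2
    exclusion = np.zeros(grid_shape, bool)
    exclusion[:, ymid - 1 : ymid + 1, :] = True

    rois = {}
    gm_all = np.zeros(grid_shape, bool)
    for ts in tracts:
        pts, _ = sample_curve(ts.control_points)
        start, end = pts[0], pts[-1]
        # seed slightly interior to the bundle so walkers start on well-fit voxels
        seed = ball_mask(grid_shape, start, max(ts.radius - 1.0, 1.0)) & masks[ts.tract_id]
        target = ball_mask(grid_shape, end, ts.radius + 0.8)
        caps = (
            ball_mask(grid_shape, start, ts.radius + 1.5)
            | ball_mask(grid_shape, end, ts.radius + 1.5)
        ) & ~all_tracts
        gm_all |= caps
        rois[ts.tract_id] = ROISet(
            seed=seed,
            targets={"cortex": target},
            exclusion=exclusion,
            csf=rim,
            gm=caps,
        )
    for r in rois.values():
        r.gm = gm_all.copy()
    return field, masks, rim, rois


def _damage_region(
    tracts: list[TractSpec],
    tract_masks: dict[str, np.ndarray],
    mode: str,
    grid_shape,
):
    """Damage region plus a radial severity weight (strongest at tract cores).

    The graded weight makes injury heaviest along the bundle axis, so the
    tract center (where skeleton sampling concentrates) is most abnormal and
    streamlines are deflected toward the milder periphery.
    """
    all_tracts = np.any(list(tract_masks.values()), axis=0)
    xs = np.where(all_tracts.any(axis=(1, 2)))[0]
    xc = 0.5 * (xs[0] + xs[-1])
    if mode == "diffuse":
        region = all_tracts.copy()
    else:
        half = 0.45 * (xs[-1] - xs[0])
        region = np.zeros(grid_shape, bool)
        region[int(xc - half) : int(xc + half) + 1] = True
        region &= all_tracts

    centers = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    rdist = np.full(int(np.prod(grid_shape)), np.inf)
    max_radius = 1.0
    for ts in tracts:
        pts, _ = sample_curve(ts.control_points)
        d, _ = cKDTree(pts).query(centers, k=1)
        rdist = np.minimum(rdist, d)
        max_radius = max(max_radius, ts.radius)
    rdist = rdist.reshape(grid_shape)
    # radial taper: heaviest on the bundle axis, milder toward the surface
    radial = np.clip(1.0 - 0.8 * (rdist / max_radius) ** 2, 0.08, 1.0)
    if mode == "diffuse":
        weight = radial
    else:
        # flat-top severe core (disrupts tracking at high severity) plus
        # heavy Cauchy tails along the tract so the Z>3 boundary sweeps
        # outward as severity grows instead of saturating
        x = np.arange(grid_shape[0], dtype=float)[:, None, None]
        core = np.exp(-(((x - xc) / 5.0) ** 6))
        tails = 1.0 / (1.0 + np.abs(x - xc) / 0.8)
        weight = radial * np.maximum(core, tails)
    return region, weight * region


def make_cohort(
    spec: CohortSpec,
    tracts: list[TractSpec] | None = None,
    grid_shape: tuple[int, int, int] = (40, 40, 40),
    scheme: AcquisitionScheme | None = None,
    fiber_fraction: float = 0.7,
    tract_d: float = 1.7e-3,
    S0: float = 100.0,
) -> Cohort:
    """Generate a full synthetic cohort: controls, patients, held-out controls.

    Each subject is the base geometry pulled through a smooth random
    displacement bounded by ``spec.jitter_voxels``; patients additionally get
    :func:`inject_damage` at their listed severity inside the (warped) damage
    region.  Fully reproducible from ``spec.rng_seed``.
    """
    tracts = tracts if tracts is not None else default_geometry(grid_shape[0])
    scheme = scheme if scheme is not None else default_scheme()

    base_field, tract_masks, rim, base_rois = _build_base(
        tracts, grid_shape, fiber_fraction, tract_d, S0
    )
    fa0, md0 = dti_truth(base_field, scheme)
    region, dmg_weight = _damage_region(tracts, tract_masks, spec.damage_mode, grid_shape)
    base_truth = PhantomTruth(
        tract_masks=tract_masks,
        true_fa=fa0,
        true_md=md0,
        damage_mask=np.zeros(grid_shape, bool),
    )

    roles = (
        [("control", 0.0)] * spec.n_controls
        + [("patient", s) for s in spec.damage_severities]
        + [("heldout", 0.0)] * spec.n_heldout
    )
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(len(roles))

    subjects = []
    for i, ((role, severity), ss) in enumerate(zip(roles, seeds)):
        rng = np.random.default_rng(ss)
        # recoverable jitter (inverted at analysis) + residual misregistration
        u_reg = smooth_displacement(grid_shape, spec.jitter_voxels, rng)
        u_res = smooth_displacement(grid_shape, spec.misreg_voxels, rng)
        u = u_reg + u_res
        sfield = _warp_field(base_field, u)
        srois = {tid: _warp_rois(r, u) for tid, r in base_rois.items()}
        smasks = {tid: nn_warp(m, u, fill=False) for tid, m in tract_masks.items()}
        struth = PhantomTruth(
            tract_masks=smasks,
            true_fa=nn_warp(fa0, u),
            true_md=nn_warp(md0, u),
            damage_mask=np.zeros(grid_shape, bool),
        )
        if role == "patient" and severity > 0:
            sregion = nn_warp(region, u, fill=False)
            sweight = nn_warp(dmg_weight, u)
            sfield, struth = inject_damage(
                sfield, struth, severity, sregion, scheme, weight=sweight
            )
        noise_seed = int(rng.integers(2**31 - 1))
        dwi = simulate_dwi(sfield, scheme, spec.noise_sigma, rng_seed=noise_seed)
        subjects.append(
            Subject(
                subject_id=f"{role[:3]}{i:02d}",
                role=role,
                severity=float(severity),
                dwi=dwi,
                truth=struth,
                rois=srois,
                to_common_disp=-u_reg,
            )
        )
    return Cohort(
        spec=spec,
        scheme=scheme,
        subjects=subjects,
        base_truth=base_truth,
        base_rois=base_rois,
        damage_region=region,
        damage_weight=dmg_weight,
    )
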