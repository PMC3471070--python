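"""Diffusion model fitting: tensor (FA/MD) and two-fiber ball-and-stick.

The ball-and-stick fit returns per-voxel *orientation samples* obtained by
residual bootstrap around a nonlinear least-squares point estimate — the
sampling PDF that probabilistic tracking draws from — plus a per-voxel
dispersion statistic (1 minus the principal eigenvalue of the mean dyadic
tensor of the direction samples, range [0, 2/3]).

All fits are vectorized over voxels; the nonlinear refits are driven by a
small batched Levenberg-Marquardt loop rather than per-voxel scipy calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionScheme

__all__ = [
    "DWIVolume",
    "TensorField",
    "ScalarMap",
    "OrientationSamples",
    "fit_tensor",
    "fa_md",
    "fit_ball_and_stick",
    "dispersion_map",
]

SIGNAL_FLOOR_FRACTION = 1e-6  # S clamped at this fraction of S0 before log
FIBER_SUPPORT_FRACTION = 0.05  # population used for tracking only if fitted fraction >= this


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal plus its acquisition table."""

    signal: np.ndarray  # (X, Y, Z, n_volumes), non-negative
    scheme: AcquisitionScheme
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got shape {self.signal.shape}")
        if self.signal.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but scheme has "
                f"{self.scheme.n_volumes}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel diffusion tensor eigensystem (descending eigenvalues)."""

    evals: np.ndarray  # (X, Y, Z, 3), lambda1 >= lambda2 >= lambda3
    evecs: np.ndarray  # (X, Y, Z, 3, 3); evecs[..., :, i] pairs with evals[..., i]
    mask: np.ndarray  # fitted voxels
    neg_clamped: np.ndarray  # voxels where eigenvalues were clamped to 0
    s0: np.ndarray  # estimated unweighted signal


@dataclass
class ScalarMap:
    """3D scalar map with an explicit validity mask (never silent zeros)."""

    values: np.ndarray
    kind: str  # "FA" | "MD" | "dispersion"
    valid: np.ndarray

    def masked(self, mask: np.ndarray) -> np.ndarray:
        """Values within `mask` & valid, as a flat array."""
        return self.values[np.asarray(mask, bool) & self.valid]


def _design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Log-linear least-squares diffusion tensor fit within `mask`.

    S0 is the mean of the b=0 volumes; signals are clamped at
    ``SIGNAL_FLOOR_FRACTION * S0`` before the log.  Negative eigenvalues are
    clamped to zero and flagged.
    """
    scheme = dwi.scheme
    shape = dwi.grid_shape
    mask = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    if scheme.dwi_mask.sum() < 6:
        raise ValueError("tensor fit needs at least 6 non-zero-b directions")
    X = _design_matrix(scheme)[scheme.dwi_mask]
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError(
            "rank-deficient design matrix: gradient directions are not "
            "sufficiently non-collinear for a tensor fit"
        )

    sig = dwi.signal[mask]  # (M, n)
    s0 = sig[:, scheme.b0_mask].mean(axis=1)
    s0 = np.maximum(s0, np.finfo(float).tiny)
    floor = SIGNAL_FLOOR_FRACTION * s0[:, None]
    s = np.maximum(sig[:, scheme.dwi_mask], floor)
    y = -np.log(s / s0[:, None])  # (M, n_dwi)

    dvec, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    dvec = dvec.T  # (M, 6)
    D = np.zeros((len(dvec), 3, 3))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = dvec[:, 0], dvec[:, 1], dvec[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = dvec[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = dvec[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = dvec[:, 5]

    w, v = np.linalg.eigh(D)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    clamped = np.any(w < 0, axis=1)
    w = np.maximum(w, 0.0)

    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    s0_map = np.zeros(shape)
    neg = np.zeros(shape, bool)
    evals[mask] = w
    evecs[mask] = v
    s0_map[mask] = s0
    neg[mask] = clamped
    return TensorField(evals=evals, evecs=evecs, mask=mask, neg_clamped=neg, s0=s0_map)


def fa_md(tensors: TensorField) -> tuple[ScalarMap, ScalarMap]:
    """FA and MD maps from a fitted tensor field.

    ``FA = sqrt(3/2) * sqrt(sum (l_i - mean)^2) / sqrt(sum l_i^2)``;
    ``MD = mean(l_i)``.  FA is flagged undefined where all eigenvalues are 0.
    """
    lam = tensors.evals
    md = lam.mean(axis=-1)
    num = ((lam - md[..., None]) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    defined = tensors.mask & (den > 0)
    fa = np.zeros_like(md)
    fa[defined] = np.sqrt(1.5 * num[defined] / den[defined])
    fa = np.clip(fa, 0.0, 1.0)
    return (
        ScalarMap(values=fa, kind="FA", valid=defined),
        ScalarMap(values=md, kind="MD", valid=tensors.mask.copy()),
    )


# ---------------------------------------------------------------------------
# ball-and-stick


@dataclass
class OrientationSamples:
    """Per-voxel fiber orientation samples from the residual bootstrap.

    Arrays are stored sparsely over the fitted voxels; ``voxel_index`` maps a
    grid location to its row (or -1 outside the fit mask).
    """

    grid_shape: tuple[int, int, int]
    voxels: np.ndarray  # (N, 3) int voxel coordinates
    voxel_index: np.ndarray  # (X, Y, Z) int32, -1 where unfitted
    directions: np.ndarray  # (n_fibers, N, S, 3) unit vectors
    fractions: np.ndarray  # (n_fibers, N, S)
    point_directions: np.ndarray  # (n_fibers, N, 3)
    point_fractions: np.ndarray  # (n_fibers, N)
    support: np.ndarray  # (n_fibers, N) bool — population usable for tracking
    fallback: np.ndarray  # (N,) bool — voxels where NLLS failed
    rng_seed: int

    @property
    def n_samples(self) -> int:
        return self.directions.shape[2]

    @property
    def n_fibers(self) -> int:
        return self.directions.shape[0]


def _angles_to_dirs(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def _dirs_to_angles(v: np.ndarray):
    v = v / np.maximum(np.linalg.norm(v, axis=-1, keepdims=True), 1e-30)
    return np.arccos(np.clip(v[..., 2], -1, 1)), np.arctan2(v[..., 1], v[..., 0])


def _bs_forward(
    x: np.ndarray, b: np.ndarray, g: np.ndarray, nf: int, jac: bool = False
):
    """Ball-and-stick signal (and optionally analytic Jacobian) for a batch.

    x columns: [s0, d, (f_j, theta_j, phi_j) for each fiber j].
    """
    B = len(x)
    n = len(b)
    s0 = x[:, 0]
    d = np.clip(x[:, 1], 1e-7, None)
    bd = d[:, None] * b  # (B, n)
    e0 = np.exp(-bd)
    fsum = np.zeros(B)
    stick = np.zeros((B, n))
    per_fiber = []
    for j in range(nf):
        f = x[:, 2 + 3 * j]
        th, phv = x[:, 3 + 3 * j], x[:, 4 + 3 * j]
        st, ct = np.sin(th), np.cos(th)
        sp, cp = np.sin(phv), np.cos(phv)
        v = np.stack([st * cp, st * sp, ct], axis=-1)
        c = v @ g.T  # (B, n)
        ej = np.exp(-bd * c**2)
        stick += f[:, None] * ej
        fsum += f
        per_fiber.append((f, ct, st, sp, cp, c, ej))
    mix = (1.0 - fsum)[:, None] * e0 + stick
    S = s0[:, None] * mix
    if not jac:
        return S

    P = 2 + 3 * nf
    J = np.empty((B, n, P))
    J[:, :, 0] = mix
    dd = -(1.0 - fsum)[:, None] * b * e0
    for f, ct, st, sp, cp, c, ej in per_fiber:
        dd -= f[:, None] * b * c**2 * ej
    J[:, :, 1] = s0[:, None] * dd
    for j, (f, ct, st, sp, cp, c, ej) in enumerate(per_fiber):
        J[:, :, 2 + 3 * j] = s0[:, None] * (ej - e0)
        # dv/dtheta = (ct*cp, ct*sp, -st); dv/dphi = (-st*sp, st*cp, 0)
        dcdth = (
            (ct * cp)[:, None] * g[:, 0]
            + (ct * sp)[:, None] * g[:, 1]
            - st[:, None] * g[:, 2]
        )
        dcdph = (-(st * sp))[:, None] * g[:, 0] + (st * cp)[:, None] * g[:, 1]
        common = s0[:, None] * f[:, None] * ej * (-2.0 * bd * c)
        J[:, :, 3 + 3 * j] = common * dcdth
        J[:, :, 4 + 3 * j] = common * dcdph
    return S, J


def _clip_params(x: np.ndarray, nf: int) -> np.ndarray:
    x[:, 0] = np.clip(x[:, 0], 1e-9, None)
    x[:, 1] = np.clip(x[:, 1], 1e-6, 2e-2)
    fcols = [2 + 3 * j for j in range(nf)]
    x[:, fcols] = np.clip(x[:, fcols], 0.0, 1.0)
    fsum = x[:, fcols].sum(axis=1)
    over = fsum > 1.0
    if np.any(over):
        x[np.ix_(over, fcols)] /= fsum[over, None]
    return x


def _lm_fit(
    y: np.ndarray,
    b: np.ndarray,
    g: np.ndarray,
    nf: int,
    x0: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-6,
) -> np.ndarray:
    """Batched Levenberg-Marquardt on the ball-and-stick model.

    Analytic Jacobian; per-element damping; bounds enforced by clipping.
    Small problem (P <= 8, n <= ~70) so dense linear algebra per element is
    cheap.
    """
    B, P = x0.shape
    x = x0.copy()
    lam = np.full(B, 1e-2)
    r = _bs_forward(x, b, g, nf) - y
    cost = (r**2).sum(axis=1)
    eye = np.eye(P)
    act = np.arange(B)  # still-converging elements
    for _ in range(max_iter):
        if len(act) == 0:
            break
        xa, ya, ra = x[act], y[act], r[act]
        _, J = _bs_forward(xa, b, g, nf, jac=True)
        A = np.einsum("bnp,bnq->bpq", J, J)
        grad = np.einsum("bnp,bn->bp", J, ra)
        diag = np.einsum("bpp->bp", A)
        la = lam[act]
        M = A + la[:, None, None] * (diag[:, :, None] * eye) + 1e-12 * eye
        try:
            delta = np.linalg.solve(M, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(
                M.reshape(-1, P), grad.reshape(-1, 1), rcond=None
            )[0].reshape(len(act), P)
        xn = _clip_params(xa - delta, nf)
        rn = _bs_forward(xn, b, g, nf) - ya
        cn = (rn**2).sum(axis=1)
        ca = cost[act]
        better = cn <= ca
        improved = np.where(better, ca - cn, np.inf)
        idx = act[better]
        x[idx] = xn[better]
        r[idx] = rn[better]
        cost[idx] = cn[better]
        lam[act] = np.where(better, la * 0.3, la * 4.0)
        lam[act] = np.clip(lam[act], 1e-9, 1e9)
        # freeze elements whose accepted step barely improved the fit
        done = better & (improved <= tol * (cn + 1e-30))
        done |= lam[act] >= 1e8
        act = act[~done]
    return x


def _gn_refine(
    y: np.ndarray,
    b: np.ndarray,
    g: np.ndarray,
    nf: int,
    x0: np.ndarray,
    iters: int = 3,
    damping: float = 1e-3,
) -> np.ndarray:
    """Damped Gauss-Newton refinement for warm-started (bootstrap) refits.

    No accept/reject trial step — cheap and adequate when starting at the
    point estimate with small resampled perturbations.
    """
    P = x0.shape[1]
    x = x0.copy()
    eye = np.eye(P)
    for _ in range(iters):
        S, J = _bs_forward(x, b, g, nf, jac=True)
        r = S - y
        A = np.einsum("bnp,bnq->bpq", J, J)
        grad = np.einsum("bnp,bn->bp", J, r)
        diag = np.einsum("bpp->bp", A)
        M = A + damping * (diag[:, :, None] * eye) + 1e-12 * eye
        delta = np.linalg.solve(M, grad[..., None])[..., 0]
        x = _clip_params(x - delta, nf)
    bad = ~np.all(np.isfinite(x), axis=1)
    if np.any(bad):
        x[bad] = x0[bad]
    return x


def _tensor_init(dwi: DWIVolume, mask: np.ndarray, nf: int) -> np.ndarray:
    tf = fit_tensor(dwi, mask)
    fa, _ = fa_md(tf)
    lam1 = tf.evals[mask][:, 0]
    e1 = tf.evecs[mask][:, :, 0]
    e2 = tf.evecs[mask][:, :, 1]
    s0 = tf.s0[mask]
    favals = fa.values[mask]
    d0 = np.clip(lam1, 3e-4, 1e-2)
    x0 = np.empty((mask.sum(), 2 + 3 * nf))
    x0[:, 0] = np.maximum(s0, 1e-3)
    x0[:, 1] = d0
    th1, ph1 = _dirs_to_angles(e1)
    x0[:, 2] = np.clip(favals, 0.1, 0.9)
    x0[:, 3], x0[:, 4] = th1, ph1
    if nf == 2:
        th2, ph2 = _dirs_to_angles(e2)
        x0[:, 5] = 0.10
        x0[:, 6], x0[:, 7] = th2, ph2
        x0[:, 2] *= 0.85
    return x0


def fit_ball_and_stick(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    n_fibers: int = 2,
    n_samples: int = 50,
    rng_seed: int = 0,
    chunk: int = 1000,
    bootstrap_iters: int = 3,
) -> OrientationSamples:
    """Fit the ball-and-stick model and bootstrap orientation uncertainty.

    Per voxel: nonlinear least-squares point estimate (initialized from the
    tensor fit), then `n_samples` refits on residual-bootstrap resampled
    signals, warm-started from the point estimate.  The second fiber is
    marked supported only where its point-estimate fraction is at least
    ``FIBER_SUPPORT_FRACTION``.  Deterministic given `rng_seed`.
    """
    if n_fibers not in (1, 2):
        raise ValueError("n_fibers must be 1 or 2")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    shape = dwi.grid_shape
    mask = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    voxels = np.argwhere(mask)
    N = len(voxels)
    if N == 0:
        raise ValueError("empty fit mask")

    scheme = dwi.scheme
    b, g = scheme.bvals, scheme.bvecs
    y_all = dwi.signal[mask].astype(float)
    x0_all = _tensor_init(dwi, mask, n_fibers)
    P = x0_all.shape[1]
    rng = np.random.default_rng(rng_seed)

    point = np.empty((N, P))
    samples = np.empty((N, n_samples, P))
    fallback = np.zeros(N, bool)

    for lo in range(0, N, chunk):
        hi = min(lo + chunk, N)
        y = y_all[lo:hi]
        xh = _lm_fit(y, b, g, n_fibers, x0_all[lo:hi])
        bad = ~np.all(np.isfinite(xh), axis=1)
        if np.any(bad):
            xh[bad] = x0_all[lo:hi][bad]
            fallback[lo:hi][bad] = True
        point[lo:hi] = xh

        fit = _bs_forward(xh, b, g, n_fibers)
        resid = y - fit
        M = hi - lo
        idx = rng.integers(0, len(b), size=(M, n_samples, len(b)))
        yb = fit[:, None, :] + np.take_along_axis(resid[:, None, :], idx, axis=2)
        yb = np.maximum(yb, 0.0).reshape(M * n_samples, len(b))
        xb0 = np.repeat(xh, n_samples, axis=0)
        xb = _gn_refine(yb, b, g, n_fibers, xb0, iters=bootstrap_iters)
        samples[lo:hi] = xb.reshape(M, n_samples, P)

    vol_index = np.full(shape, -1, np.int32)
    vol_index[tuple(voxels.T)] = np.arange(N, dtype=np.int32)

    dirs = np.empty((n_fibers, N, n_samples, 3), np.float32)
    fracs = np.empty((n_fibers, N, n_samples), np.float32)
    pdirs = np.empty((n_fibers, N, 3))
    pfracs = np.empty((n_fibers, N))
    for j in range(n_fibers):
        dirs[j] = _angles_to_dirs(samples[..., 3 + 3 * j], samples[..., 4 + 3 * j])
        fracs[j] = samples[..., 2 + 3 * j]
        pdirs[j] = _angles_to_dirs(point[:, 3 + 3 * j], point[:, 4 + 3 * j])
        pfracs[j] = point[:, 2 + 3 * j]

    support = pfracs >= FIBER_SUPPORT_FRACTION

    return OrientationSamples(
        grid_shape=shape,
        voxels=voxels,
        voxel_index=vol_index,
        directions=dirs,
        fractions=fracs,
        point_directions=pdirs,
        point_fractions=pfracs,
        support=support,
        fallback=fallback,
        rng_seed=rng_seed,
    )


def dispersion_map(samples: OrientationSamples, fiber_index: int = 0) -> ScalarMap:
    """Orientation dispersion: 1 - principal eigenvalue of the mean dyadic.

    0 when all samples coincide; -> 2/3 for directions uniform on the sphere.
    Undefined (flagged) where the requested fiber population is unsupported.
    """
    if fiber_index >= samples.n_fibers:
        raise ValueError(f"no fiber population {fiber_index}")
    v = samples.directions[fiber_index].astype(float)  # (N, S, 3)
    dyad = np.einsum("nsa,nsb->nab", v, v) / samples.n_samples
    mu1 = np.linalg.eigvalsh(dyad)[:, -1]
    disp = np.clip(1.0 - mu1, 0.0, 2.0 / 3.0)

    values = np.zeros(samples.grid_shape)
    valid = np.zeros(samples.grid_shape, bool)
    sup = samples.support[fiber_index]
    coords = tuple(samples.voxels[sup].T)
    values[coords] = disp[sup]
    valid[coords] = True
    return ScalarMap(values=values, kind="dispersion", valid=valid)
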