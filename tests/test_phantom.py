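import numpy as np
import pytest

from tractquant.core import GeometryError, default_scheme
from tractquant.phantom import (
    CohortSpec,
    FiberField,
    PhantomTruth,
    dti_truth,
    inject_damage,
    make_cohort,
    make_tract_field,
    nn_warp,
    sample_curve,
    simulate_dwi,
    smooth_displacement,
)

GRID = (40, 40, 40)


def _segment_distance(points, a, b):
    """Brute-force distance from each point to segment a-b."""
    ab = b - a
    t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


class TestMakeTractField:
    def test_straight_line_tangents(self):
        field, mask = make_tract_field(
            np.array([[5, 20, 20], [35, 20, 20]]), 2.0, GRID
        )
        dirs = field.directions[mask, 0]
        assert np.allclose(np.abs(dirs @ [1, 0, 0]), 1.0, atol=1e-12)

    def test_quarter_circle_end_tangent_perpendicular(self):
        # quarter arc in the x-y plane, radius 12 around (20, 20, 20);
        # the spline interpolant reproduces circle tangents to ~h^3
        theta = np.linspace(0, np.pi / 2, 33)
        cp = np.stack(
            [20 + 12 * np.cos(theta), 20 + 12 * np.sin(theta), np.full(33, 20.0)],
            axis=1,
        )
        _, tang = sample_curve(cp)
        assert abs(tang[0] @ tang[-1]) < 1e-4
        # tangent at the arc midpoint sits at 45 degrees to both ends
        # (sampled tangents sit on a 400-point grid, so allow the off-by-
        # half-sample angular slack)
        mid = tang[len(tang) // 2]
        assert mid @ tang[0] == pytest.approx(np.cos(np.pi / 4), abs=5e-3)

    def test_mask_matches_bruteforce_segment_distance(self):
        a, b = np.array([5.0, 20, 20]), np.array([35.0, 20, 20])
        _, mask = make_tract_field(np.stack([a, b]), 2.0, GRID)
        centers = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in GRID], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        expected = (_segment_distance(centers, a, b) <= 2.0).reshape(GRID)
        assert np.array_equal(mask, expected)

    def test_curve_exiting_grid_rejected(self):
        with pytest.raises(GeometryError, match="exits grid"):
            make_tract_field(np.array([[2, 20, 20], [45, 20, 20]]), 2.0, GRID)

    def test_small_radius_rejected(self):
        with pytest.raises(GeometryError, match="radius"):
            make_tract_field(np.array([[5, 20, 20], [35, 20, 20]]), 0.5, GRID)


class TestInjectDamage:
    @pytest.fixture()
    def tube(self):
        field, mask = make_tract_field(
            np.array([[5, 20, 20], [35, 20, 20]]), 2.0, GRID
        )
        scheme = default_scheme()
        fa, md = dti_truth(field, scheme)
        truth = PhantomTruth(
            tract_masks={"t": mask}, true_fa=fa, true_md=md,
            damage_mask=np.zeros(GRID, bool),
        )
        region = np.zeros(GRID, bool)
        region[15:25] = mask[15:25]
        return field, truth, region, scheme

    def test_zero_severity_identity(self, tube):
        field, truth, region, scheme = tube
        out, t2 = inject_damage(field, truth, 0.0, region, scheme)
        assert np.array_equal(out.fractions, field.fractions)
        assert np.array_equal(out.d, field.d)
        assert np.allclose(t2.true_fa, truth.true_fa)
        assert np.array_equal(t2.damage_mask, region)

    def test_full_severity_isotropic(self, tube):
        field, truth, region, scheme = tube
        out, t2 = inject_damage(field, truth, 1.0, region, scheme)
        assert np.all(out.fractions[region] == 0)
        assert np.allclose(t2.true_fa[region], 0.0, atol=1e-12)
        assert t2.damage_severity == 1.0

    def test_severity_monotonicity(self, tube):
        # oracle: closed-form apparent tensor of the mixed compartments
        field, truth, region, scheme = tube
        fas, mds = [], []
        for s in (0.2, 0.5, 0.8):
            _, t2 = inject_damage(field, truth, s, region, scheme)
            fas.append(t2.true_fa[region].mean())
            mds.append(t2.true_md[region].mean())
        assert fas[0] > fas[1] > fas[2]
        assert mds[0] < mds[1] < mds[2]

    def test_voxelwise_monotonicity(self, tube):
        field, truth, region, scheme = tube
        prev_fa = truth.true_fa
        prev_md = truth.true_md
        for s in (0.3, 0.6, 0.9):
            _, t2 = inject_damage(field, truth, s, region, scheme)
            assert np.all(t2.true_fa[region] <= prev_fa[region] + 1e-12)
            assert np.all(t2.true_md[region] >= prev_md[region] - 1e-12)
            prev_fa, prev_md = t2.true_fa, t2.true_md

    def test_graded_weight(self, tube):
        from tractquant.phantom import DAMAGE_FRACTION_EXPONENT

        field, truth, region, scheme = tube
        w = region * 0.5
        out, _ = inject_damage(field, truth, 1.0, region, scheme, weight=w)
        factor = 0.5**DAMAGE_FRACTION_EXPONENT
        assert np.allclose(out.fractions[region, 0], field.fractions[region, 0] * factor)

    def test_region_shape_mismatch(self, tube):
        field, truth, _, scheme = tube
        with pytest.raises(GeometryError):
            inject_damage(field, truth, 0.5, np.zeros((10, 10, 10), bool), scheme)

    def test_bad_severity(self, tube):
        field, truth, region, scheme = tube
        with pytest.raises(ValueError):
            inject_damage(field, truth, 1.5, region, scheme)


class TestSimulateDwi:
    def test_b0_returns_s0(self, straight_tube, scheme):
        field, _ = straight_tube
        dwi = simulate_dwi(field, scheme, 0.0)
        for i in np.where(scheme.b0_mask)[0]:
            assert np.allclose(dwi.signal[..., i], field.S0)

    def test_perpendicular_stick_no_attenuation(self):
        # single fiber f=1 along z, gradient along x: S = S0 exactly
        field = FiberField(
            S0=np.full((1, 1, 1), 100.0),
            d=np.full((1, 1, 1), 1.7e-3),
            fractions=np.ones((1, 1, 1, 1)),
            directions=np.zeros((1, 1, 1, 1, 3)),
        )
        field.directions[0, 0, 0, 0] = [0, 0, 1]
        scheme = default_scheme(n_dirs=1, n_b0=1)
        object.__setattr__(scheme, "bvecs", np.array([[0, 0, 0], [1.0, 0, 0]]))
        dwi = simulate_dwi(field, scheme, 0.0)
        assert dwi.signal[0, 0, 0, 1] == pytest.approx(100.0)

    def test_isotropic_closed_form(self, scheme):
        field = FiberField(
            S0=np.full((2, 2, 2), 100.0),
            d=np.full((2, 2, 2), 0.7e-3),
            fractions=np.zeros((2, 2, 2, 1)),
            directions=np.zeros((2, 2, 2, 1, 3)),
        )
        dwi = simulate_dwi(field, scheme, 0.0)
        expected = 100.0 * np.exp(-0.7)
        assert np.allclose(dwi.signal[..., scheme.dwi_mask], expected)

    def test_noise_deterministic(self, straight_tube, scheme):
        field, _ = straight_tube
        a = simulate_dwi(field, scheme, 5.0, rng_seed=3)
        b = simulate_dwi(field, scheme, 5.0, rng_seed=3)
        assert np.array_equal(a.signal, b.signal)

    def test_noise_converges_to_closed_form(self, straight_tube, scheme):
        field, _ = straight_tube
        clean = simulate_dwi(field, scheme, 0.0).signal
        prev = np.inf
        for sigma in (1.0, 0.1, 0.001):
            noisy = simulate_dwi(field, scheme, sigma, rng_seed=5).signal
            dev = np.abs(noisy - clean).max()
            assert dev < prev
            prev = dev
        assert prev < 0.01

    def test_negative_sigma_rejected(self, straight_tube, scheme):
        field, _ = straight_tube
        with pytest.raises(ValueError):
            simulate_dwi(field, scheme, -1.0)


class TestDisplacement:
    def test_max_norm_bound(self):
        rng = np.random.default_rng(0)
        u = smooth_displacement((20, 20, 20), 1.5, rng)
        assert np.abs(u).max() == pytest.approx(1.5)

    def test_zero_jitter(self):
        rng = np.random.default_rng(0)
        u = smooth_displacement((10, 10, 10), 0.0, rng)
        assert np.all(u == 0)

    def test_nn_warp_identity(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(8, 8, 8))
        out = nn_warp(vol, np.zeros((8, 8, 8, 3)))
        assert np.array_equal(out, vol)

    def test_nn_warp_integer_shift(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(8, 8, 8))
        disp = np.zeros((8, 8, 8, 3))
        disp[..., 0] = 1.0  # out[x] = in[x+1]
        out = nn_warp(vol, disp)
        assert np.array_equal(out[:-1], vol[1:])
        assert np.all(out[-1] == 0)


class TestCohortSpec:
    def test_requires_two_controls(self):
        with pytest.raises(ValueError, match="2 controls"):
            CohortSpec(n_controls=1, n_patients=0, damage_severities=())

    def test_severity_count(self):
        with pytest.raises(ValueError, match="one damage severity"):
            CohortSpec(n_controls=2, n_patients=2, damage_severities=(0.5,))

    def test_severity_range(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            CohortSpec(n_controls=2, n_patients=1, damage_severities=(1.5,))


@pytest.mark.slow
class TestMakeCohort:
    def test_determinism_and_jitterless_identity(self):
        spec = CohortSpec(
            n_controls=2, n_patients=0, damage_severities=(),
            jitter_voxels=0.0, noise_sigma=0.0, rng_seed=7,
        )
        c1 = make_cohort(spec)
        c2 = make_cohort(spec)
        # identical spec+seed -> byte-identical volumes
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert np.array_equal(s1.dwi.signal, s2.dwi.signal)
        # jitter 0, noise 0 -> all controls identical
        assert np.array_equal(
            c1.subjects[0].dwi.signal, c1.subjects[1].dwi.signal
        )

    def test_patient_severity_ordering(self):
        spec = CohortSpec(
            n_controls=2, n_patients=2, damage_severities=(0.1, 0.6),
            jitter_voxels=0.0, noise_sigma=0.0, rng_seed=3,
        )
        c = make_cohort(spec)
        p1, p2 = c.patients
        region = c.damage_region
        assert p2.truth.true_fa[region].mean() < p1.truth.true_fa[region].mean()
        assert p2.truth.true_md[region].mean() > p1.truth.true_md[region].mean()

    def test_rois_well_formed(self):
        spec = CohortSpec(n_controls=2, n_patients=0, damage_severities=(), rng_seed=0)
        c = make_cohort(spec)
        for s in c.subjects:
            for rois in s.rois.values():
                assert rois.seed.any()
                assert not np.any(rois.seed & rois.exclusion)
                for t in rois.targets.values():
                    assert t.any()
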