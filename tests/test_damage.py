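import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tractquant.damage import (
    DamageReport,
    assess_cohort,
    compare_methods,
    control_stats,
    holm_adjust,
    percent_abnormal,
    spearman,
    wilcoxon_rank_sum,
)
from tractquant.masking import SamplingMask
from tractquant.tensors import ScalarMap

GRID = (6, 6, 6)


def _map(values, kind="MD"):
    values = np.asarray(values, float)
    return ScalarMap(values=values, kind=kind, valid=np.ones(values.shape, bool))


def _mask(mask=None, tract="left", config="skeleton+gm+csf"):
    if mask is None:
        mask = np.ones(GRID, bool)
    return SamplingMask(mask=mask, config_label=config, tract_id=tract)


class TestControlStats:
    def test_two_point_formula(self):
        a = _map(np.full(GRID, 1.0))
        b = _map(np.full(GRID, 3.0))
        cs = control_stats([a, b], _mask())
        assert np.allclose(cs.mean, 2.0)
        assert np.allclose(cs.sd, np.sqrt(2.0))

    def test_identical_controls_flagged(self):
        a = _map(np.full(GRID, 1.0))
        cs = control_stats([a, _map(np.full(GRID, 1.0))], _mask())
        assert cs.sd_zero.all()

    def test_gaussian_sampling_property(self):
        rng = np.random.default_rng(0)
        shape = (20, 20, 20)
        maps = [
            ScalarMap(rng.normal(size=shape), "MD", np.ones(shape, bool))
            for _ in range(10)
        ]
        sm = SamplingMask(np.ones(shape, bool), "none", "t")
        cs = control_stats(maps, sm)
        frac = (np.abs(cs.mean) <= 0.1 + 1e-12).mean()
        # sd of the mean is 1/sqrt(10) ~ 0.316; P(|mean| <= 0.1) ~ 0.248...
        # loose check that the voxelwise mean is centered, not the 95% claim
        assert np.abs(cs.mean.mean()) < 0.01
        assert 0.15 < frac < 0.35

    def test_requires_two(self):
        with pytest.raises(ValueError):
            control_stats([_map(np.zeros(GRID))], _mask())


class TestPercentAbnormal:
    def _stats(self, mean=0.8e-3, sd=0.05e-3):
        cs = control_stats(
            [_map(np.full(GRID, mean - sd / 2)), _map(np.full(GRID, mean + sd / 2))],
            _mask(),
        )
        # two controls give sd = |diff|/sqrt(2); rescale to the target sd
        cs.sd[:] = sd
        cs.mean[:] = mean
        return cs

    def test_patient_equal_to_mean_is_zero(self):
        cs = self._stats()
        rep = percent_abnormal(_map(np.full(GRID, 0.8e-3)), cs, "MD")
        assert rep.pct_abnormal == 0.0

    def test_z_of_four_abnormal_for_md(self):
        cs = self._stats()
        rep = percent_abnormal(_map(np.full(GRID, 1.0e-3)), cs, "MD")
        assert rep.pct_abnormal == 100.0

    def test_counting(self):
        cs = self._stats()
        vals = np.full(GRID, 0.8e-3)
        flat = vals.reshape(-1)
        flat[:2] = 1.0e-3
        mask = np.zeros(GRID, bool)
        mask.reshape(-1)[:10] = True
        cs.mask = _mask(mask)
        rep = percent_abnormal(_map(vals), cs, "MD")
        assert rep.pct_abnormal == pytest.approx(20.0)
        assert rep.n_voxels == 10

    def test_fa_directionality(self):
        cs = self._stats(mean=0.5, sd=0.05)
        low = percent_abnormal(_map(np.full(GRID, 0.2), "FA"), cs, "FA")
        high = percent_abnormal(_map(np.full(GRID, 0.8), "FA"), cs, "FA")
        assert low.pct_abnormal == 100.0
        assert high.pct_abnormal == 0.0  # elevated FA not flagged one-sided
        both = percent_abnormal(_map(np.full(GRID, 0.8), "FA"), cs, "FA", two_sided=True)
        assert both.pct_abnormal == 100.0

    def test_no_valid_voxels_errors(self):
        cs = self._stats()
        cs.sd_zero[:] = True
        with pytest.raises(ValueError, match="no valid voxels"):
            percent_abnormal(_map(np.zeros(GRID)), cs, "MD")

    def test_false_positive_calibration(self):
        # one-sided Z>3 on Gaussian controls: expected rate 0.00135
        rng = np.random.default_rng(7)
        shape = (40, 40, 25)  # 40k voxels
        controls = [
            ScalarMap(rng.normal(size=shape), "MD", np.ones(shape, bool))
            for _ in range(400)
        ]
        cs = control_stats(controls, SamplingMask(np.ones(shape, bool), "none", "t"))
        patient = ScalarMap(rng.normal(size=shape), "MD", np.ones(shape, bool))
        rep = percent_abnormal(patient, cs, "MD")
        p = sps.norm.sf(3.0)
        se = np.sqrt(p * (1 - p) / np.prod(shape))
        assert abs(rep.pct_abnormal / 100.0 - p) < 3 * se


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2, 3, 4, 5]
        assert spearman(x, [2.0, 4, 6, 8, 10], n_permutations=200).rho == 1.0
        assert spearman(x, [5.0, 4, 3, 2, 1], n_permutations=200).rho == -1.0

    def test_hand_computed_example(self):
        # ranks d^2 sum = 2 -> rho = 1 - 6*2/(4*15) = 0.8
        r = spearman([1, 2, 3, 4], [1, 3, 2, 4], n_permutations=2000, rng_seed=0)
        assert r.rho == pytest.approx(0.8)

    def test_constant_input_flagged(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not r.defined and np.isnan(r.rho)

    def test_matches_scipy_rho(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            ours = spearman(x, y, n_permutations=100).rho
            assert ours == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_permutation_p_reasonable(self):
        rng = np.random.default_rng(4)
        x = np.arange(10.0)
        y = x + rng.normal(0, 0.5, 10)
        r = spearman(x, y, n_permutations=5000, rng_seed=1)
        assert r.p_value < 0.01

    def test_length_checks(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


def _brute_force_ranksum_p(a, b, alternative):
    """Independent enumeration oracle over all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    sums = [
        ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)
    ]
    sums = np.asarray(sums)
    p_less = np.mean(sums <= w_obs + 1e-9)
    p_greater = np.mean(sums >= w_obs - 1e-9)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


class TestWilcoxonRankSum:
    def test_exact_one_in_twenty(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert r.method == "exact"
        assert r.p_value == pytest.approx(1 / 20)

    def test_identical_multisets_p_one(self):
        r = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=8)
        other = rng.normal(size=8)
        pvals = [
            wilcoxon_rank_sum(base, other + shift, alternative="less").p_value
            for shift in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(p2 <= p1 for p1, p2 in zip(pvals, pvals[1:]))

    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=2, max_size=6),
        st.lists(st.integers(min_value=0, max_value=8), min_size=2, max_size=6),
        st.sampled_from(["two-sided", "less", "greater"]),
    )
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_bruteforce_enumeration(self, a, b, alternative):
        r = wilcoxon_rank_sum(a, b, alternative=alternative)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(
            _brute_force_ranksum_p(np.array(a, float), np.array(b, float), alternative)
        )

    def test_normal_approximation_branch(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=30)
        b = rng.normal(1.0, 1.0, size=30)
        r = wilcoxon_rank_sum(a, b, alternative="less")
        assert r.method == "normal"
        scipy_p = sps.mannwhitneyu(a, b, alternative="less").pvalue
        assert r.p_value == pytest.approx(scipy_p, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def test_holm_adjust():
    p = [0.01, 0.04, 0.03, 0.005]
    adj = holm_adjust(p)
    # step-down: sorted (0.005, 0.01, 0.03, 0.04) * (4, 3, 2, 1), cummax
    assert adj[3] == pytest.approx(0.02)
    assert adj[0] == pytest.approx(0.03)
    assert adj[2] == pytest.approx(0.06)
    assert adj[1] == pytest.approx(0.06)
    assert np.all(adj <= 1.0)


def _report(sid, tract, method, pct, metric="MD"):
    return DamageReport(
        subject_id=sid, tract_id=tract, method=method, metric=metric,
        pct_abnormal=pct, n_voxels=10, mean_value=1.0,
    )


class TestCompareMethods:
    def test_identical_methods_flagged(self):
        reports = []
        for sid in "abcd":
            reports.append(_report(sid, "t", "template", 5.0))
            reports.append(_report(sid, "t", "individual", 5.0))
        comp = compare_methods(reports)
        assert np.allclose(comp.discrepancies, 0.0)
        assert comp.spearman_rho_vs_discrepancy is None
        assert comp.paired_p == 1.0

    def test_unpaired_entries_error(self):
        reports = [
            _report("a", "t", "template", 5.0),
            _report("a", "t", "individual", 5.0),
            _report("b", "t", "template", 6.0),
        ]
        with pytest.raises(ValueError, match="unpaired"):
            compare_methods(reports)

    def test_too_few_pairs_skips_correlation(self):
        reports = []
        for sid, t, i in (("a", 10.0, 5.0), ("b", 20.0, 10.0)):
            reports.append(_report(sid, "t", "template", t))
            reports.append(_report(sid, "t", "individual", i))
        comp = compare_methods(reports)
        assert comp.spearman_rho_vs_discrepancy is None
        assert np.allclose(comp.discrepancies, [5.0, 10.0])

    def test_underestimation_pattern_detected(self):
        rng = np.random.default_rng(8)
        reports = []
        for i in range(12):
            t = 5.0 + 4 * i + rng.normal(0, 0.5)
            d = 0.5 * i + rng.normal(0, 0.3)
            reports.append(_report(f"s{i}", "t", "template", t))
            reports.append(_report(f"s{i}", "t", "individual", t - d))
        comp = compare_methods(reports, n_permutations=2000)
        sp = comp.spearman_rho_vs_discrepancy
        assert sp.rho > 0.5 and sp.p_value < 0.05
        assert comp.paired_p < 0.05


class TestAssessCohort:
    def test_absent_individual_flagged_not_skipped(self):
        rng = np.random.default_rng(9)
        controls = [
            ScalarMap(rng.normal(1.0, 0.1, GRID), "MD", np.ones(GRID, bool))
            for _ in range(4)
        ]
        cs = control_stats(controls, _mask())
        patient_maps = {"p1": {"MD": _map(np.full(GRID, 1.0))}}
        reports = assess_cohort(
            patient_maps, {"left": {"MD": cs}}, {"p1": {"left": None}}
        )
        assert len(reports) == 2
        indiv = [r for r in reports if r.method == "individual"][0]
        assert indiv.absent and indiv.pct_abnormal == 0.0
        tmpl = [r for r in reports if r.method == "template"][0]
        assert not tmpl.absent
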