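"""Voxelwise Z-score damage quantification and method-comparison statistics.

Patient FA/MD maps are compared voxelwise against a control cohort's mean
and SD inside a sampling mask; voxels beyond 3 control SDs (elevated MD,
reduced FA — directional by default) count as abnormal.  The same
calculation runs on the subject's own tractography-derived tract, allowing
the template-vs-individual comparison.  The statistical kernels (Spearman
with permutation p, Wilcoxon rank-sum with exact enumeration) are
implemented here and cross-checked against brute force in the tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .masking import SamplingMask
from .tensors import ScalarMap

__all__ = [
    "CohortStats",
    "DamageReport",
    "MethodComparison",
    "SpearmanResult",
    "RankSumResult",
    "control_stats",
    "percent_abnormal",
    "assess_cohort",
    "spearman",
    "wilcoxon_rank_sum",
    "compare_methods",
    "holm_adjust",
]


@dataclass
class CohortStats:
    """Voxelwise control mean/SD for one metric within a sampling mask."""

    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    mask: SamplingMask
    metric: str
    sd_zero: np.ndarray  # voxels with zero control SD (Z undefined there)


@dataclass
class DamageReport:
    """Abnormal-voxel percentages for one subject x tract x method."""

    subject_id: str
    tract_id: str
    method: str  # "template" | "individual"
    metric: str  # "FA" | "MD"
    pct_abnormal: float
    n_voxels: int
    mean_value: float
    absent: bool = False

    def __post_init__(self) -> None:
        if not self.absent and not 0.0 <= self.pct_abnormal <= 100.0:
            raise ValueError("percentage out of [0, 100]")


@dataclass
class SpearmanResult:
    rho: float
    p_value: float  # permutation p (primary)
    p_asymptotic: float
    n: int
    defined: bool = True


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first sample
    p_value: float
    method: str  # "exact" | "normal"
    alternative: str


@dataclass
class MethodComparison:
    """Pooled template-vs-individual comparison across subject x tract pairs."""

    discrepancies: np.ndarray  # template % - individual %
    template_pct: np.ndarray
    individual_pct: np.ndarray
    pair_labels: list[tuple[str, str]]
    spearman_rho_vs_discrepancy: SpearmanResult | None
    paired_stat: float
    paired_p: float


def control_stats(
    control_maps: list[ScalarMap], mask: SamplingMask, metric: str | None = None
) -> CohortStats:
    """Voxelwise mean and SD (ddof=1) of control maps within the mask."""
    if len(control_maps) < 2:
        raise ValueError("need at least 2 controls")
    shape = control_maps[0].values.shape
    if any(m.values.shape != shape for m in control_maps):
        raise ValueError("control maps are not on a common grid")
    stack = np.stack([m.values for m in control_maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    sd_zero = (sd == 0) & mask.mask
    return CohortStats(
        mean=mean,
        sd=sd,
        n_controls=len(control_maps),
        mask=mask,
        metric=metric or control_maps[0].kind,
        sd_zero=sd_zero,
    )


def percent_abnormal(
    patient: ScalarMap,
    cstats: CohortStats,
    metric: str | None = None,
    z_threshold: float = 3.0,
    two_sided: bool = False,
    sample_mask: np.ndarray | None = None,
    subject_id: str = "",
    method: str = "template",
    min_voxels: int = 1,
) -> DamageReport:
    """Percentage of sampled voxels abnormal by the 3-SD rule.

    ``Z = (patient - control mean) / control SD`` per voxel.  Directional by
    default: MD abnormal iff Z > +threshold, FA abnormal iff Z < -threshold
    (injury raises MD and lowers FA); ``two_sided=True`` uses |Z| instead.
    `sample_mask` restricts sampling further (e.g. the subject's own tract);
    it is intersected with the cohort mask.  A region smaller than
    `min_voxels` is refused — a percentage over a handful of voxels is
    meaningless and marks a failed sampling region.
    """
    metric = metric or cstats.metric
    if metric not in ("FA", "MD"):
        raise ValueError("metric must be 'FA' or 'MD'")
    region = cstats.mask.mask & ~cstats.sd_zero & patient.valid
    if sample_mask is not None:
        region = region & np.asarray(sample_mask, bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("no valid voxels to sample")
    if n < min_voxels:
        raise ValueError(
            f"only {n} valid voxels to sample (minimum {min_voxels})"
        )
    z = (patient.values[region] - cstats.mean[region]) / cstats.sd[region]
    if two_sided:
        abnormal = np.abs(z) > z_threshold
    elif metric == "MD":
        abnormal = z > z_threshold
    else:
        abnormal = z < -z_threshold
    return DamageReport(
        subject_id=subject_id,
        tract_id=cstats.mask.tract_id,
        method=method,
        metric=metric,
        pct_abnormal=100.0 * abnormal.sum() / n,
        n_voxels=n,
        mean_value=float(patient.values[region].mean()),
    )


def assess_cohort(
    patient_maps: dict[str, dict[str, ScalarMap]],
    cstats_by_tract: dict[str, dict[str, CohortStats]],
    individual_tracts: dict[str, dict[str, np.ndarray | None]],
    z_threshold: float = 3.0,
    two_sided: bool = False,
    min_voxels: int = 12,
) -> list[DamageReport]:
    """One DamageReport per subject x tract x method x metric.

    `patient_maps[subject][metric]`, `cstats_by_tract[tract][metric]`, and
    `individual_tracts[subject][tract]` (a binary volume, or None when the
    subject's tractography produced nothing — reported as absent with 0%,
    the limiting case of a completely failed individual tract).  Sampling
    regions below `min_voxels` are likewise reported absent with 0%.
    """
    reports: list[DamageReport] = []
    for sid, maps in patient_maps.items():
        for tract_id, by_metric in cstats_by_tract.items():
            indiv = individual_tracts.get(sid, {}).get(tract_id)
            for metric, cstats in by_metric.items():
                reports.append(
                    percent_abnormal(
                        maps[metric], cstats, metric, z_threshold, two_sided,
                        subject_id=sid, method="template", min_voxels=min_voxels,
                    )
                )
                if indiv is None:
                    reports.append(
                        DamageReport(
                            subject_id=sid, tract_id=tract_id, method="individual",
                            metric=metric, pct_abnormal=0.0, n_voxels=0,
                            mean_value=float("nan"), absent=True,
                        )
                    )
                    continue
                try:
                    reports.append(
                        percent_abnormal(
                            maps[metric], cstats, metric, z_threshold, two_sided,
                            sample_mask=indiv, subject_id=sid, method="individual",
                            min_voxels=min_voxels,
                        )
                    )
                except ValueError:
                    reports.append(
                        DamageReport(
                            subject_id=sid, tract_id=tract_id, method="individual",
                            metric=metric, pct_abnormal=0.0, n_voxels=0,
                            mean_value=float("nan"), absent=True,
                        )
                    )
    return reports


# ---------------------------------------------------------------------------
# statistical kernels


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(
    x, y, n_permutations: int = 10_000, rng_seed: int = 0
) -> SpearmanResult:
    """Spearman rank correlation with a seeded permutation p-value.

    Average ranks for ties; two-sided p by permuting y (the asymptotic
    t-approximation p is reported alongside).  Constant input yields an
    undefined (flagged) result.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), float("nan"), len(x), False)

    rx, ry = _rank(x), _rank(y)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_permutations):
        count += abs(_rho(rx, rng.permutation(ry))) >= abs(rho) - 1e-12
    p_perm = (count + 1) / (n_permutations + 1)
    p_asym = float(sps.spearmanr(x, y).pvalue)
    return SpearmanResult(rho, p_perm, p_asym, len(x))


def _ranksum_exact(ranks: np.ndarray, n1: int, w_obs: float, alternative: str) -> float:
    """Exact null distribution of the group-1 rank sum by full enumeration."""
    n = len(ranks)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    sums = ranks[combos].sum(axis=1)
    eps = 1e-9
    p_less = np.mean(sums <= w_obs + eps)
    p_greater = np.mean(sums >= w_obs - eps)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum test on two samples (statistic: rank sum of `a`).

    Average ranks for ties.  Exact p by full enumeration of C(n1+n2, n1)
    rank assignments when both groups have at most 10 observations;
    otherwise a normal approximation with tie correction.  `alternative`
    refers to the location of `a` relative to `b`.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    ranks = _rank(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    if max(n1, n2) <= 10:
        p = _ranksum_exact(ranks, n1, w, alternative)
        return RankSumResult(w, p, "exact", alternative)

    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n * (n - 1)) if n > 1 else 1)
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return RankSumResult(w, 1.0, "normal", alternative)
    # continuity correction toward the mean
    if alternative == "greater":
        z = (w - mu - 0.5) / math.sqrt(var)
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (w - mu + 0.5) / math.sqrt(var)
        p = float(sps.norm.cdf(z))
    else:
        z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var) if w != mu else 0.0
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return RankSumResult(w, p, "normal", alternative)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank_i, idx in enumerate(order):
        running = max(running, (m - rank_i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_methods(
    reports: list[DamageReport],
    metric: str = "MD",
    n_permutations: int = 10_000,
    rng_seed: int = 0,
) -> MethodComparison:
    """Pair template/individual reports and compare the two methods.

    Discrepancy = template % - individual % per subject x tract pair;
    Spearman correlation of (template %, discrepancy) across pairs
    (permutation p); paired Wilcoxon signed-rank across pairs for the
    overall method effect.  Unpaired entries raise with the offending keys.
    """
    tmpl: dict[tuple[str, str], DamageReport] = {}
    indiv: dict[tuple[str, str], DamageReport] = {}
    for r in reports:
        if r.metric != metric:
            continue
        key = (r.subject_id, r.tract_id)
        (tmpl if r.method == "template" else indiv)[key] = r
    missing = set(tmpl) ^ set(indiv)
    if missing:
        raise ValueError(f"unpaired template/individual entries: {sorted(missing)}")
    if not tmpl:
        raise ValueError(f"no reports for metric {metric!r}")

    keys = sorted(tmpl)
    t = np.array([tmpl[k].pct_abnormal for k in keys])
    i = np.array([indiv[k].pct_abnormal for k in keys])
    disc = t - i

    sp: SpearmanResult | None = None
    if len(keys) >= 3 and not (np.all(t == t[0]) or np.all(disc == disc[0])):
        sp = spearman(t, disc, n_permutations=n_permutations, rng_seed=rng_seed)

    if np.allclose(disc, 0.0):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.wilcoxon(t, i, zero_method="wilcox")
    return MethodComparison(
        discrepancies=disc,
        template_pct=t,
        individual_pct=i,
        pair_labels=keys,
        spearman_rho_vs_discrepancy=sp,
        paired_stat=float(stat),
        paired_p=float(p),
    )
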