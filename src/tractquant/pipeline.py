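"""End-to-end workflow: phantom -> fit -> track -> template -> mask -> assess.

`analyze_cohort` is the in-memory engine (used by the tests and the
acceptance script); `run_pipeline` wraps it with file I/O, a YAML-loadable
configuration, and a checksummed artifact manifest.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as tio
from .core import dice
from .damage import (
    CohortStats,
    DamageReport,
    MethodComparison,
    assess_cohort,
    compare_methods,
    control_stats,
)
from .masking import MASK_CONFIGS, SamplingMask, make_sampling_mask, skeletonize
from .phantom import Cohort, CohortSpec, make_cohort, nn_warp
from .templates import TractTemplate, build_template, resample_to_common, volume_matched_binarize
from .tensors import ScalarMap, dispersion_map, fa_md, fit_ball_and_stick, fit_tensor
from .tracking import ConnectivityMap, TrackingConfig, track, tract_success_rate

log = logging.getLogger("tractquant")

__all__ = ["WorkflowConfig", "SubjectResult", "CohortResult", "analyze_cohort", "run_pipeline"]


@dataclass(frozen=True)
class WorkflowConfig:
    """Single-file configuration of the full workflow."""

    cohort: CohortSpec = field(
        default_factory=lambda: CohortSpec(
            n_controls=10,
            n_patients=5,
            damage_severities=(0.1, 0.3, 0.5, 0.7, 0.9),
            rng_seed=0,
        )
    )
    tracking: TrackingConfig = field(
        default_factory=lambda: TrackingConfig(
            n_samples_per_seed_voxel=300, max_steps=300, rng_seed=0
        )
    )
    template_percentile: float = 95.0
    masking_config: str = "skeleton+gm+csf"
    fa_floor: float = 0.2
    z_threshold: float = 3.0
    two_sided: bool = False
    bootstrap_samples: int = 50
    fit_seed: int = 0
    fit_fa_threshold: float = 0.15
    min_sample_voxels: int = 12

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "damage_severities" in c:
                c["damage_severities"] = tuple(c["damage_severities"])
            d["cohort"] = CohortSpec(**c)
        if "tracking" in d:
            d["tracking"] = TrackingConfig(**d["tracking"])
        cfg = cls(**d)
        if cfg.masking_config not in MASK_CONFIGS:
            raise ValueError(f"unknown masking_config {cfg.masking_config!r}")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["damage_severities"] = list(d["cohort"]["damage_severities"])
        return d


@dataclass
class SubjectResult:
    """Per-subject outputs, all resampled into the common grid."""

    subject_id: str
    role: str
    severity: float
    fa: ScalarMap
    md: ScalarMap
    dispersion: ScalarMap
    cmaps: dict[str, ConnectivityMap]  # warped, normalized
    success: dict[str, float]
    indiv_masks: dict[str, np.ndarray | None]  # volume-matched binaries
    indiv_shortfall: dict[str, bool]


@dataclass
class CohortResult:
    cohort: Cohort
    config: WorkflowConfig
    subjects: dict[str, SubjectResult]
    templates: dict[str, TractTemplate]
    skeleton: np.ndarray
    sampling_masks: dict[str, dict[str, SamplingMask]]  # tract -> config -> mask
    cstats: dict[str, dict[str, CohortStats]]  # tract -> metric -> stats
    reports: list[DamageReport]
    comparison: MethodComparison | None

    def by_role(self, role: str) -> list[SubjectResult]:
        order = [s.subject_id for s in self.cohort.subjects if s.role == role]
        return [self.subjects[sid] for sid in order]

    def sampled_mean(self, sid: str, tract_id: str, metric: str, config: str,
                     method: str = "template") -> float:
        """Mean FA/MD of one subject sampled in a tract under a mask config."""
        sm = self.sampling_masks[tract_id][config]
        sub = self.subjects[sid]
        smap = sub.fa if metric == "FA" else sub.md
        region = sm.mask & smap.valid
        if method == "individual":
            im = sub.indiv_masks[tract_id]
            if im is None:
                return float("nan")
            region = region & im
        vals = smap.values[region]
        return float(vals.mean()) if vals.size else float("nan")


def _stable_seed(*parts) -> int:
    """Deterministic (process-independent) seed offset from string parts."""
    return zlib.crc32("|".join(map(str, parts)).encode()) % 100_000


def _process_subject(subject, cohort, cfg: WorkflowConfig) -> SubjectResult:
    t0 = time.perf_counter()
    tf = fit_tensor(subject.dwi)
    fa, md = fa_md(tf)

    from scipy import ndimage as ndi

    # coherent anisotropic voxels only: opening kills isolated noise-FA
    # voxels; keep only connected components anchored at a seed or target,
    # so background noise blobs never balloon the nonlinear-fit workload
    raw = ndi.binary_opening(fa.values >= cfg.fit_fa_threshold)
    anchors = np.zeros(raw.shape, bool)
    for rs in subject.rois.values():
        anchors |= rs.seed
        for t in rs.targets.values():
            anchors |= t
    labels, n_lab = ndi.label(raw)
    keep = np.unique(labels[anchors & raw])
    keep = keep[keep > 0]
    fitmask = np.isin(labels, keep) if len(keep) else raw
    fitmask = ndi.binary_dilation(fitmask, iterations=2) | anchors

    samples = fit_ball_and_stick(
        subject.dwi,
        fitmask,
        n_fibers=2,
        n_samples=cfg.bootstrap_samples,
        rng_seed=cfg.fit_seed + _stable_seed(subject.subject_id),
    )
    disp_map = dispersion_map(samples, fiber_index=0)

    cmaps: dict[str, ConnectivityMap] = {}
    success: dict[str, float] = {}
    for tract_id, rois in subject.rois.items():
        tc = replace(
            cfg.tracking,
            rng_seed=cfg.tracking.rng_seed + _stable_seed(subject.subject_id, tract_id),
        )
        cmap = track(samples, rois, "cortex", tc, tract_id=tract_id)
        success[tract_id] = tract_success_rate(cmap)
        cmaps[tract_id] = resample_to_common(cmap, subject.to_common_disp)

    u = subject.to_common_disp
    fa_c = ScalarMap(nn_warp(fa.values, u), "FA", nn_warp(fa.valid, u, fill=False))
    md_c = ScalarMap(nn_warp(md.values, u), "MD", nn_warp(md.valid, u, fill=False))
    dp_c = ScalarMap(
        nn_warp(disp_map.values, u), "dispersion", nn_warp(disp_map.valid, u, fill=False)
    )
    log.info("subject %s processed in %.1fs", subject.subject_id, time.perf_counter() - t0)
    return SubjectResult(
        subject_id=subject.subject_id,
        role=subject.role,
        severity=subject.severity,
        fa=fa_c,
        md=md_c,
        dispersion=dp_c,
        cmaps=cmaps,
        success=success,
        indiv_masks={},
        indiv_shortfall={},
    )


def analyze_cohort(cohort: Cohort, cfg: WorkflowConfig | None = None) -> CohortResult:
    """Run the full analysis on an in-memory phantom cohort."""
    cfg = cfg or WorkflowConfig(cohort=cohort.spec)
    results: dict[str, SubjectResult] = {}
    for subject in cohort.subjects:
        results[subject.subject_id] = _process_subject(subject, cohort, cfg)

    tract_ids = list(cohort.base_rois)
    control_ids = [s.subject_id for s in cohort.controls]

    templates: dict[str, TractTemplate] = {}
    for tid in tract_ids:
        templates[tid] = build_template(
            [results[sid].cmaps[tid] for sid in control_ids],
            percentile=cfg.template_percentile,
            tract_id=tid,
            provenance=tuple(control_ids),
        )

    mean_fa = np.mean([results[sid].fa.values for sid in control_ids], axis=0)
    skeleton = skeletonize(mean_fa, fa_floor=cfg.fa_floor)

    sampling_masks: dict[str, dict[str, SamplingMask]] = {}
    for tid in tract_ids:
        rois = cohort.base_rois[tid]
        sampling_masks[tid] = {
            label: make_sampling_mask(templates[tid], skeleton, rois.csf, rois.gm, label)
            for label in MASK_CONFIGS
        }

    # volume-matched individual binarization for every subject
    for sid, res in results.items():
        for tid in tract_ids:
            cmap = res.cmaps[tid]
            if cmap.counts.sum() == 0:
                res.indiv_masks[tid] = None
                res.indiv_shortfall[tid] = True
                continue
            m, short = volume_matched_binarize(cmap, templates[tid])
            res.indiv_masks[tid] = m
            res.indiv_shortfall[tid] = short

    # control statistics within the configured sampling mask
    stats_ids = [s.subject_id for s in cohort.controls + cohort.heldout]
    cstats: dict[str, dict[str, CohortStats]] = {}
    for tid in tract_ids:
        sm = sampling_masks[tid][cfg.masking_config]
        cstats[tid] = {
            "FA": control_stats([results[sid].fa for sid in stats_ids], sm, "FA"),
            "MD": control_stats([results[sid].md for sid in stats_ids], sm, "MD"),
        }

    assessed_ids = [s.subject_id for s in cohort.patients + cohort.heldout]
    patient_maps = {
        sid: {"FA": results[sid].fa, "MD": results[sid].md} for sid in assessed_ids
    }
    indiv = {sid: results[sid].indiv_masks for sid in assessed_ids}
    reports = assess_cohort(
        patient_maps, cstats, indiv, z_threshold=cfg.z_threshold,
        two_sided=cfg.two_sided, min_voxels=cfg.min_sample_voxels,
    )

    patient_ids = {s.subject_id for s in cohort.patients}
    patient_reports = [r for r in reports if r.subject_id in patient_ids]
    comparison = None
    if len(patient_reports) >= 6:
        try:
            comparison = compare_methods(patient_reports, metric="MD")
        except ValueError:
            comparison = None

    return CohortResult(
        cohort=cohort,
        config=cfg,
        subjects=results,
        templates=templates,
        skeleton=skeleton,
        sampling_masks=sampling_masks,
        cstats=cstats,
        reports=reports,
        comparison=comparison,
    )


def reports_frame(reports: list[DamageReport]) -> pd.DataFrame:
    """Tidy table: one row per subject x tract x method x metric."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "tract_id": r.tract_id,
                "method": r.method,
                "metric": r.metric,
                "pct_abnormal": r.pct_abnormal,
                "n_voxels": r.n_voxels,
                "mean_value": r.mean_value,
                "absent": r.absent,
            }
            for r in reports
        ]
    )


def run_pipeline(cfg: WorkflowConfig, outdir) -> CohortResult:
    """Generate a cohort, analyze it, and write the artifact tree."""
    from pathlib import Path

    outdir = Path(outdir)
    written: list = []
    t0 = time.perf_counter()
    log.info("stage phantom: generating cohort")
    cohort = make_cohort(cfg.cohort)
    res = analyze_cohort(cohort, cfg)

    for subject in cohort.subjects:
        sdir = outdir / "subjects" / subject.subject_id
        written.append(tio.write_nifti(subject.dwi.signal.astype(np.float32), sdir / "dwi.nii.gz"))
        tio.write_bvalbvec(cohort.scheme, sdir / "bvals.txt", sdir / "bvecs.txt")
        written += [sdir / "bvals.txt", sdir / "bvecs.txt"]
        sr = res.subjects[subject.subject_id]
        written.append(tio.write_nifti(sr.fa.values.astype(np.float32), sdir / "fa.nii.gz"))
        written.append(tio.write_nifti(sr.md.values.astype(np.float32), sdir / "md.nii.gz"))
        for tid, cmap in sr.cmaps.items():
            written.append(
                tio.write_nifti(cmap.counts.astype(np.int32), sdir / f"counts_{tid}.nii.gz")
            )
            written.append(
                tio.write_nifti(
                    cmap.normalized.astype(np.float32), sdir / f"connectivity_{tid}.nii.gz"
                )
            )
        written.append(
            tio.write_mask(subject.truth.damage_mask, sdir / "truth_damage.nii.gz")
        )

    for tid, tpl in res.templates.items():
        written.append(tio.write_mask(tpl.mask, outdir / "templates" / f"{tid}.nii.gz"))
        meta = outdir / "templates" / f"{tid}.json"
        meta.write_text(
            json.dumps(
                {
                    "tract_id": tpl.tract_id,
                    "n_subjects": tpl.n_subjects,
                    "percentile": tpl.percentile,
                    "threshold": tpl.threshold,
                    "provenance": list(tpl.provenance),
                },
                indent=2,
            )
        )
        written.append(meta)
    written.append(tio.write_mask(res.skeleton, outdir / "skeleton.nii.gz"))

    df = reports_frame(res.reports)
    rep_csv = outdir / "damage_reports.csv"
    df.to_csv(rep_csv, index=False)
    written.append(rep_csv)

    if res.comparison is not None:
        comp = res.comparison
        summary = {
            "paired_wilcoxon_stat": comp.paired_stat,
            "paired_wilcoxon_p": comp.paired_p,
            "mean_discrepancy": float(np.mean(comp.discrepancies)),
        }
        if comp.spearman_rho_vs_discrepancy is not None:
            sp = comp.spearman_rho_vs_discrepancy
            summary.update(
                {"spearman_rho": sp.rho, "spearman_p_perm": sp.p_value, "spearman_p_asym": sp.p_asymptotic}
            )
        comp_path = outdir / "method_comparison.json"
        comp_path.write_text(json.dumps(summary, indent=2))
        written.append(comp_path)

    manifest = tio.write_manifest(
        written,
        outdir / "manifest.json",
        extra={"config": cfg.to_dict(), "elapsed_s": round(time.perf_counter() - t0, 2)},
    )
    log.info("pipeline complete in %.1fs; manifest at %s", time.perf_counter() - t0, manifest)
    return res
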