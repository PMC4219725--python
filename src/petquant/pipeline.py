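"""End-to-end orchestration: VOI quantification, group statistics and the
lesion-count correlation, on an in-memory phantom cohort or a cohort
directory written by :func:`petquant.phantom.write_cohort`.

All stages are deterministic given (config, data); every tabular output
carries the config hash in a ``config_hash`` column and the effective
config is echoed as ``config.yaml`` into the output directory.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .masking import PSFModel, binarize_tissue_map, hemispheric_split, spillin_free_pair
from .phantom import Cohort, read_manifest
from .quantify import (SubjectRecord, VOISummary, compute_suv, compute_suvt,
                       read_cohort_csv, summaries_to_frame, summarize_subject,
                       wm_gm_ratio)
from .stats import (ClusterSet, GroupTestResult, TMap, ancova_group_age,
                    cluster_fwe, mann_whitney, pearson_r2, smooth_cohort,
                    voxelwise_glm_t)
from .volumes import BinaryMask, Volume3D, read_volume, voi_mean, write_volume

__all__ = [
    "SubjectImages", "SubjectAnalysis",
    "subjects_from_cohort", "load_cohort_dir",
    "analyze_subject", "run_voi_analysis",
    "run_group_comparison", "run_lesion_correlation", "run_all",
    "save_mask_with_sidecar",
]

log = logging.getLogger("petquant.pipeline")


@dataclass(frozen=True)
class SubjectImages:
    """The raw inputs of one subject, already co-registered on one grid."""

    record: SubjectRecord
    pet_activity: Volume3D        # kBq/mL
    gm_prob: Volume3D
    wm_prob: Volume3D
    csf_prob: Volume3D
    thalamus: BinaryMask
    hemisphere_left: BinaryMask
    hemisphere_right: BinaryMask


@dataclass(frozen=True)
class SubjectAnalysis:
    """Everything derived for one subject by the VOI stage."""

    record: SubjectRecord
    suv: Volume3D
    suvt: Volume3D
    masks: dict                   # region name -> BinaryMask
    summaries: list


def subjects_from_cohort(cohort: Cohort) -> list[SubjectImages]:
    return [SubjectImages(
        record=s.record, pet_activity=s.pet_activity, gm_prob=s.gm_prob,
        wm_prob=s.wm_prob, csf_prob=s.csf_prob, thalamus=s.thalamus_mask,
        hemisphere_left=s.hemisphere_left, hemisphere_right=s.hemisphere_right)
        for s in cohort.subjects]


def load_cohort_dir(directory: str | os.PathLike) -> list[SubjectImages]:
    """Load a cohort directory (manifest.json + cohort.csv + NIfTI files)."""
    directory = os.fspath(directory)
    manifest = read_manifest(directory)
    records = {r.subject_id: r for r in
               read_cohort_csv(os.path.join(directory, manifest["cohort_csv"]))}
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        files = entry["files"]

        def vol(stem, units=""):
            return read_volume(os.path.join(directory, files[stem]), units=units)

        def mask(stem):
            return read_volume(os.path.join(directory, files[stem]),
                               as_mask=True, region_name=stem)

        subjects.append(SubjectImages(
            record=records[sid],
            pet_activity=vol("pet", "kBq/mL"),
            gm_prob=vol("tpm_gm", "probability"),
            wm_prob=vol("tpm_wm", "probability"),
            csf_prob=vol("tpm_csf", "probability"),
            thalamus=mask("thalamus_bilateral"),
            hemisphere_left=mask("hemisphere_left"),
            hemisphere_right=mask("hemisphere_right")))
    return subjects


def analyze_subject(img: SubjectImages, config: RunConfig) -> SubjectAnalysis:
    """VOI stage for one subject: masks, spill-in-free masks, SUV, SUVt,
    regional summaries (raw and spill-in-free variants)."""
    rec = img.record
    gm = binarize_tissue_map(img.gm_prob, config.mask_fraction, region_name="gm")
    wm = binarize_tissue_map(img.wm_prob, config.mask_fraction, region_name="wm")
    psf = PSFModel(fwhm_mm=config.psf_fwhm_mm)
    pair = spillin_free_pair(gm, wm, psf, config.spillin_tau)
    log.info("subject %s: GM %d->%d voxels, WM %d->%d voxels after erosion",
             rec.subject_id, gm.voxel_count, pair.gm_free.voxel_count,
             wm.voxel_count, pair.wm_free.voxel_count)

    suv = compute_suv(img.pet_activity, rec.injected_dose_mbq, rec.body_weight_kg)
    suvt = compute_suvt(suv, img.thalamus)

    masks = {"gm": gm, "wm": wm,
             "gm_spillin_free": pair.gm_free, "wm_spillin_free": pair.wm_free,
             config.reference_region: img.thalamus}
    summaries = (
        summarize_subject(suv, suvt, [gm, wm, img.thalamus],
                          rec.subject_id, "raw")
        + summarize_subject(suv, suvt, [pair.gm_free, pair.wm_free],
                            rec.subject_id, "spillin_free"))
    return SubjectAnalysis(rec, suv, suvt, masks, summaries)


def run_voi_analysis(subjects: Sequence[SubjectImages], config: RunConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, list[SubjectAnalysis]]:
    """Quantify every subject.

    Returns (tidy per-region table, wide per-subject report with GM SUVt /
    WM SUVt / WM-GM ratio from the raw 35%-threshold masks, analyses).
    """
    analyses = [analyze_subject(s, config) for s in subjects]
    tidy = summaries_to_frame([s for a in analyses for s in a.summaries])
    rows = []
    for a in analyses:
        by = {(s.region_name, s.mask_variant): s for s in a.summaries}
        gm_s = by[("gm", "raw")]
        wm_s = by[("wm", "raw")]
        rows.append({
            "subject_id": a.record.subject_id, "group": a.record.group,
            "age": a.record.age,
            "gm_suvt": gm_s.mean_suvt, "wm_suvt": wm_s.mean_suvt,
            "wm_gm_ratio": wm_gm_ratio(wm_s.mean_suvt, gm_s.mean_suvt)})
    report = pd.DataFrame(rows)
    h = config.config_hash()
    tidy["config_hash"] = h
    report["config_hash"] = h
    return tidy, report, analyses


_SCALAR_OUTCOMES = ("gm_suvt", "wm_suvt", "wm_gm_ratio")


def _scalar_outcome_table(analyses: Sequence[SubjectAnalysis],
                          variant: str) -> pd.DataFrame:
    rows = []
    for a in analyses:
        by = {(s.region_name, s.mask_variant): s for s in a.summaries}
        gm_key = ("gm" if variant == "raw" else "gm_spillin_free", variant)
        wm_key = ("wm" if variant == "raw" else "wm_spillin_free", variant)
        rows.append({"subject_id": a.record.subject_id, "group": a.record.group,
                     "age": a.record.age,
                     "gm_suvt": by[gm_key].mean_suvt,
                     "wm_suvt": by[wm_key].mean_suvt,
                     "wm_gm_ratio": wm_gm_ratio(by[wm_key].mean_suvt,
                                                by[gm_key].mean_suvt)})
    return pd.DataFrame(rows)


def run_group_comparison(analyses: Sequence[SubjectAnalysis], config: RunConfig
                         ) -> dict:
    """Regional Mann-Whitney + ANCOVA (raw and spill-in-free variants) and
    the voxel-wise age-adjusted t map with permutation cluster FWE in both
    contrast directions."""
    scalar_rows = []
    for variant in ("raw", "spillin_free"):
        tab = _scalar_outcome_table(analyses, variant)
        ms = tab[tab.group == "MS"]
        hv = tab[tab.group == "HV"]
        for outcome in _SCALAR_OUTCOMES:
            mw = mann_whitney(ms[outcome].to_numpy(), hv[outcome].to_numpy(),
                              mode="exact")
            an = ancova_group_age(tab[outcome].to_numpy(), tab.group.to_numpy(),
                                  tab.age.to_numpy())
            for res in (mw, an):
                scalar_rows.append({
                    "outcome": outcome, "variant": variant,
                    "method": res.method, "statistic": res.statistic,
                    "df": res.df, "p_two_sided": res.p_two_sided,
                    "mean_ms": float(ms[outcome].mean()),
                    "mean_hv": float(hv[outcome].mean())})
    scalar = pd.DataFrame(scalar_rows)

    # voxel-wise GLM on smoothed SUVt within the common GM+WM mask
    vols = smooth_cohort([a.suvt for a in analyses],
                         fwhm_mm=config.smoothing_fwhm_mm)
    common = None
    for a in analyses:
        gw = a.masks["gm"].union(a.masks["wm"], name="gm+wm")
        common = gw if common is None else common.intersect(gw, name="gm+wm")
    groups = [a.record.group for a in analyses]
    ages = [a.record.age for a in analyses]
    tmap_ms = voxelwise_glm_t(vols, groups, ages, common)
    g_flip = [1 - (1 if g == "MS" else 0) for g in groups]
    tmap_hv = voxelwise_glm_t(vols, g_flip, ages, common)
    kw = dict(forming_p=config.stats_forming_p, n_perm=config.stats_n_perm,
              seed=config.stats_seed, connectivity=config.stats_connectivity)
    clusters_ms = cluster_fwe(tmap_ms, **kw)
    clusters_hv = cluster_fwe(tmap_hv, **kw)
    h = config.config_hash()
    scalar["config_hash"] = h
    return {"scalar": scalar,
            "tmap_ms_gt_hv": tmap_ms, "tmap_hv_gt_ms": tmap_hv,
            "clusters_ms_gt_hv": clusters_ms, "clusters_hv_gt_ms": clusters_hv,
            "analysis_mask": common}


def run_lesion_correlation(analyses: Sequence[SubjectAnalysis], config: RunConfig,
                           use: str = "suv") -> pd.DataFrame:
    """Hemispheric mean uptake vs per-hemisphere lesion counts in the MS
    group: Pearson r, R^2 and p for {GM, WM} x {T1 black holes, T2
    lesions}; each of the 2 hemispheres of each patient is one observation.
    """
    obs: dict = {("gm", "t1"): ([], []), ("gm", "t2"): ([], []),
                 ("wm", "t1"): ([], []), ("wm", "t2"): ([], [])}
    skipped = 0
    for a in analyses:
        if a.record.group != "MS":
            continue
        counts = {("t1", "left"): a.record.t1_lesions_left,
                  ("t1", "right"): a.record.t1_lesions_right,
                  ("t2", "left"): a.record.t2_lesions_left,
                  ("t2", "right"): a.record.t2_lesions_right}
        if any(v is None for v in counts.values()):
            log.warning("subject %s missing lesion counts; skipped",
                        a.record.subject_id)
            skipped += 1
            continue
        vol = a.suv if use == "suv" else a.suvt
        for tissue in ("gm", "wm"):
            tissue_mask = a.masks[tissue]
            left, right = hemispheric_split(tissue_mask)
            for hemi, hmask in (("left", left), ("right", right)):
                mu, _ = voi_mean(vol, hmask)
                for modality in ("t1", "t2"):
                    xs, ys = obs[(tissue, modality)]
                    xs.append(counts[(modality, hemi)])
                    ys.append(mu)
    rows = []
    for (tissue, modality), (xs, ys) in obs.items():
        if len(xs) < 3:
            continue
        res = pearson_r2(xs, ys)
        rows.append({"tissue": tissue, "lesion_type": modality,
                     "uptake_measure": use, "n_hemispheres": len(xs),
                     "r": res.effect_summary["r"], "r2": res.effect_summary["r2"],
                     "p_two_sided": res.p_two_sided})
    out = pd.DataFrame(rows)
    if len(out):
        out["config_hash"] = config.config_hash()
    return out


def save_mask_with_sidecar(mask: BinaryMask, path: str, config: RunConfig) -> None:
    """Write a mask plus a JSON sidecar recording the construction
    parameters and its voxel count."""
    write_volume(mask, path)
    sidecar = {
        "region_name": mask.region_name,
        "voxel_count": mask.voxel_count,
        "mask_fraction": config.mask_fraction,
        "psf_fwhm_mm": config.psf_fwhm_mm,
        "spillin_tau": config.spillin_tau,
        "config_hash": config.config_hash(),
    }
    with open(os.path.splitext(path.removesuffix(".gz"))[0] + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def run_all(subjects: Sequence[SubjectImages], config: RunConfig,
            output_dir: str | os.PathLike, write_masks: bool = False) -> dict:
    """Full pipeline; writes CSV/NIfTI outputs plus the config echo.

    With ``write_masks=True`` every derived VOI is also written, each with
    a JSON sidecar recording its parameters and voxel count.
    """
    output_dir = os.fspath(output_dir)
    os.makedirs(output_dir, exist_ok=True)
    config.to_yaml(os.path.join(output_dir, "config.yaml"))
    tidy, report, analyses = run_voi_analysis(subjects, config)
    if write_masks:
        mask_dir = os.path.join(output_dir, "masks")
        os.makedirs(mask_dir, exist_ok=True)
        for a in analyses:
            for name, mask in a.masks.items():
                save_mask_with_sidecar(
                    mask, os.path.join(
                        mask_dir, f"{a.record.subject_id}_{name}.nii.gz"),
                    config)
    tidy.to_csv(os.path.join(output_dir, "voi_summaries.csv"), index=False)
    report.to_csv(os.path.join(output_dir, "subject_report.csv"), index=False)
    group = run_group_comparison(analyses, config)
    group["scalar"].to_csv(os.path.join(output_dir, "group_tests.csv"), index=False)
    for tag in ("ms_gt_hv", "hv_gt_ms"):
        write_volume(group[f"tmap_{tag}"].vol,
                     os.path.join(output_dir, f"tmap_{tag}.nii.gz"))
        group[f"clusters_{tag}"].to_frame().to_csv(
            os.path.join(output_dir, f"clusters_{tag}.csv"), index=False)
    lesion = run_lesion_correlation(analyses, config)
    lesion.to_csv(os.path.join(output_dir, "lesion_correlation.csv"), index=False)
    with open(os.path.join(output_dir, "run_metadata.json"), "w") as fh:
        json.dump({"config_hash": config.config_hash(),
                   "n_subjects": len(subjects),
                   "tmap_df": group["tmap_ms_gt_hv"].df}, fh, indent=2)
    return {"tidy": tidy, "report": report, "group": group, "lesion": lesion,
            "analyses": analyses}
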