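"""Synthetic brain-phantom cohorts with known ground truth.

The phantom is deliberately schematic — nested ellipsoids, not anatomy —
because every property it must support concerns quantification and
statistics, not morphology:

* a CSF shell wrapping a cortical GM shell wrapping a WM core;
* two lateral-ventricle ellipsoids (CSF) and two thalamic ellipsoids
  (deep GM, the reference region) inside the WM core;
* piecewise-constant tracer uptake per tissue, expressed on the SUVt scale
  (thalamus = 1 by definition), with per-subject jitter and an arbitrary
  per-subject global calibration factor;
* MS subjects carry white-matter lesions — small spheres with an uptake
  increment — whose per-hemisphere counts drive the hemispheric
  uptake/lesion-count correlation by construction;
* the simulated PET is the truth blurred by the scanner PSF plus additive
  Gaussian voxel noise, emitted as an activity image in kBq/mL so the
  SUV -> SUVt chain is exercised end to end;
* an age confound mirrors the study design (MS younger than HV).

One master seed; per-subject, per-stage substreams via
``numpy.random.SeedSequence`` spawn keys, so identical specs reproduce
bitwise-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .masking import PSFModel, gaussian_blur
from .quantify import SubjectRecord, cohort_to_frame
from .volumes import BinaryMask, Volume3D, write_volume

__all__ = ["PhantomSpec", "PhantomSubject", "Cohort",
           "make_phantom_subject", "make_cohort", "write_cohort",
           "read_manifest"]

_STAGE_DEMOGRAPHICS = 0
_STAGE_LESIONS = 1
_STAGE_NOISE = 2
_STAGE_UPTAKE = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, uptake, noise and cohort parameters of a phantom study.

    Uptake values are on the SUVt scale (thalamus = 1).  Defaults emulate a
    6-vs-6 relapsing-remitting-MS / healthy-volunteer acetate-PET cohort:
    GM 1.04 (MS) vs 0.95 (HV), WM 0.93 vs 0.79, an 8-mm scanner PSF, voxel
    noise at 5% of the HV white-matter level, and group mean ages 46 vs 58.
    """

    shape: tuple[int, int, int] = (64, 76, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # ellipsoid semi-axes (mm), centred on world origin
    csf_outer_mm: tuple[float, float, float] = (54.0, 64.0, 50.0)
    gm_outer_mm: tuple[float, float, float] = (48.0, 58.0, 44.0)
    wm_outer_mm: tuple[float, float, float] = (30.0, 40.0, 28.0)
    ventricle_semi_mm: tuple[float, float, float] = (5.0, 12.0, 6.0)
    ventricle_centre_mm: tuple[float, float, float] = (8.0, 10.0, 0.0)  # mirrored in x
    thalamus_semi_mm: tuple[float, float, float] = (11.0, 14.0, 10.0)
    thalamus_centre_mm: tuple[float, float, float] = (11.0, -8.0, 0.0)  # mirrored in x
    # uptake on the SUVt scale
    # diffuse (lesion-free) tissue levels; MS WM lesions add ~0.06 on top,
    # so the effective MS WM level sits near 0.93
    gm_uptake: dict = field(default_factory=lambda: {"MS": 1.04, "HV": 0.95})
    wm_uptake: dict = field(default_factory=lambda: {"MS": 0.87, "HV": 0.79})
    csf_uptake: float = 0.35
    thalamus_uptake: float = 1.0
    subject_uptake_sd: float = 0.015     # per-subject GM/WM jitter
    calibration_sd_log: float = 0.02     # lognormal global scanner scale
    # degradation
    psf_fwhm_mm: float = 8.0
    noise_sd: float = 0.0395             # 5% of the HV WM level (0.79)
    tpm_smooth_sigma_mm: float = 2.0
    # cohort
    n_per_group: int = 6
    age_mean: dict = field(default_factory=lambda: {"MS": 46.0, "HV": 58.0})
    age_sd: dict = field(default_factory=lambda: {"MS": 6.5, "HV": 8.7})
    dose_mean_mbq: float = 370.0
    dose_sd_mbq: float = 10.0
    weight_mean_kg: float = 60.0
    weight_sd_kg: float = 8.0
    # lesion model (MS only)
    t2_lesions_per_hemisphere: float = 8.0   # Poisson mean
    t1_fraction: float = 0.5                 # T1 black holes ~ Binomial(T2, f)
    lesion_radius_mm: float = 6.0
    lesion_uptake_increment: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        for g in ("MS", "HV"):
            if self.gm_uptake[g] <= 0 or self.wm_uptake[g] <= 0:
                raise ValueError("uptake values must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def coarse(cls, **overrides) -> "PhantomSpec":
        """Reduced 32^3 / 4-mm grid for simulation-heavy calibration runs."""
        base = dict(
            shape=(32, 32, 32), spacing_mm=(4.0, 4.0, 4.0),
            csf_outer_mm=(50.0, 54.0, 48.0), gm_outer_mm=(44.0, 48.0, 42.0),
            wm_outer_mm=(28.0, 34.0, 26.0),
            ventricle_semi_mm=(5.0, 10.0, 5.0), ventricle_centre_mm=(7.0, 8.0, 0.0),
            thalamus_semi_mm=(10.0, 12.0, 9.0), thalamus_centre_mm=(10.0, -6.0, 0.0),
        )
        base.update(overrides)
        return cls(**base)

    def as_null(self) -> "PhantomSpec":
        """Same phantom with zero group effect (both groups at HV uptake,
        no lesion uptake increment) — for type-I-error calibration."""
        return dataclasses.replace(
            self,
            gm_uptake={"MS": self.gm_uptake["HV"], "HV": self.gm_uptake["HV"]},
            wm_uptake={"MS": self.wm_uptake["HV"], "HV": self.wm_uptake["HV"]},
            lesion_uptake_increment=0.0)

    def affine(self) -> np.ndarray:
        sp = np.asarray(self.spacing_mm)
        sh = np.asarray(self.shape)
        A = np.eye(4)
        A[:3, :3] = np.diag(sp)
        A[:3, 3] = -sp * (sh - 1) / 2.0   # world origin at the grid centre
        return A


@dataclass(frozen=True)
class PhantomSubject:
    """One simulated participant: demographics, tissue maps, truth, PET."""

    record: SubjectRecord
    gm_prob: Volume3D
    wm_prob: Volume3D
    csf_prob: Volume3D
    thalamus_mask: BinaryMask
    hemisphere_left: BinaryMask
    hemisphere_right: BinaryMask
    truth: Volume3D               # pre-PSF uptake on the SUVt scale
    pet_activity: Volume3D        # simulated scan, kBq/mL
    true_uptake: dict             # subject-level tissue values (SUVt scale)
    calibration: float            # global SUV-scale factor of this scan


@dataclass(frozen=True)
class Cohort:
    spec: PhantomSpec
    subjects: list[PhantomSubject]

    @property
    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]


def _rng(spec: PhantomSpec, subject_index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(subject_index, stage)))


def _world_grids(spec: PhantomSpec):
    A = spec.affine()
    axes = [A[i, i] * np.arange(spec.shape[i]) + A[i, 3] for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grids, centre, semi) -> np.ndarray:
    X, Y, Z = grids
    cx, cy, cz = centre
    ax, ay, az = semi
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _labels(spec: PhantomSpec):
    """Boolean tissue label arrays: csf, gm (cortex+thalami), wm, thalami,
    head, plus the world-coordinate grids."""
    grids = _world_grids(spec)
    head = _ellipsoid(grids, (0, 0, 0), spec.csf_outer_mm)
    gm_region = _ellipsoid(grids, (0, 0, 0), spec.gm_outer_mm)
    wm_region = _ellipsoid(grids, (0, 0, 0), spec.wm_outer_mm)
    vc, vs = spec.ventricle_centre_mm, spec.ventricle_semi_mm
    tc, ts = spec.thalamus_centre_mm, spec.thalamus_semi_mm
    vent = (_ellipsoid(grids, (vc[0], vc[1], vc[2]), vs)
            | _ellipsoid(grids, (-vc[0], vc[1], vc[2]), vs))
    thal = (_ellipsoid(grids, (tc[0], tc[1], tc[2]), ts)
            | _ellipsoid(grids, (-tc[0], tc[1], tc[2]), ts))
    vent &= wm_region
    thal &= wm_region & ~vent
    csf = (head & ~gm_region) | vent
    cortex = gm_region & ~wm_region
    gm = cortex | thal
    wm = wm_region & ~vent & ~thal
    for name, lab in (("CSF", csf), ("cortical GM", cortex), ("WM", wm),
                      ("thalamus", thal)):
        if not lab.any():
            raise ValueError(f"phantom geometry produced an empty {name} class")
    return {"csf": csf, "gm": gm, "wm": wm, "thal": thal, "head": head,
            "cortex": cortex, "grids": grids}


def _smooth_probability(label: np.ndarray, spec: PhantomSpec,
                        affine: np.ndarray, units: str) -> Volume3D:
    sigma_vox = spec.tpm_smooth_sigma_mm / np.asarray(spec.spacing_mm)
    from scipy import ndimage
    sm = ndimage.gaussian_filter(label.astype(np.float64), sigma=sigma_vox,
                                 mode="mirror")
    return Volume3D(sm.astype(np.float32), affine, units)


def make_phantom_subject(spec: PhantomSpec, subject_index: int,
                         group: str) -> PhantomSubject:
    """Build one phantom participant (deterministic in (spec, index, group))."""
    if group not in ("MS", "HV"):
        raise ValueError("group must be MS or HV")
    affine = spec.affine()
    lab = _labels(spec)

    rng_demo = _rng(spec, subject_index, _STAGE_DEMOGRAPHICS)
    age = round(float(np.clip(
        rng_demo.normal(spec.age_mean[group], spec.age_sd[group]), 25.0, 80.0)), 1)
    # dose/weight rounded here so the record and the kBq/mL conversion agree
    dose = round(float(max(50.0, rng_demo.normal(spec.dose_mean_mbq,
                                                 spec.dose_sd_mbq))), 1)
    weight = round(float(np.clip(rng_demo.normal(spec.weight_mean_kg,
                                                 spec.weight_sd_kg),
                                 40.0, 110.0)), 1)
    edss = float(rng_demo.choice(np.arange(1.0, 7.5, 0.5))) if group == "MS" else None
    duration = float(np.round(rng_demo.exponential(6.0), 1)) if group == "MS" else None

    rng_up = _rng(spec, subject_index, _STAGE_UPTAKE)
    gm_val = spec.gm_uptake[group] + rng_up.normal(0.0, spec.subject_uptake_sd)
    wm_val = spec.wm_uptake[group] + rng_up.normal(0.0, spec.subject_uptake_sd)
    calibration = float(np.exp(rng_up.normal(0.0, spec.calibration_sd_log)))

    truth = np.zeros(spec.shape, dtype=np.float64)
    truth[lab["csf"]] = spec.csf_uptake
    truth[lab["cortex"]] = gm_val
    truth[lab["thal"]] = spec.thalamus_uptake
    truth[lab["wm"]] = wm_val

    # lesions: spheres of elevated uptake in WM, counted per hemisphere
    t1_counts = {"left": None, "right": None}
    t2_counts = {"left": None, "right": None}
    if group == "MS":
        rng_les = _rng(spec, subject_index, _STAGE_LESIONS)
        X, Y, Z = lab["grids"]
        wm_idx = np.argwhere(lab["wm"])
        for hemi, sign in (("left", -1), ("right", 1)):
            n_t2 = int(rng_les.poisson(spec.t2_lesions_per_hemisphere))
            t2_counts[hemi] = n_t2
            t1_counts[hemi] = int(rng_les.binomial(n_t2, spec.t1_fraction))
            hemi_wm = wm_idx[np.sign(X[tuple(wm_idx.T)]) == sign] \
                if len(wm_idx) else wm_idx
            for _ in range(n_t2):
                if len(hemi_wm) == 0:
                    break
                ci, cj, ck = hemi_wm[rng_les.integers(len(hemi_wm))]
                d2 = ((X - X[ci, cj, ck]) ** 2 + (Y - Y[ci, cj, ck]) ** 2
                      + (Z - Z[ci, cj, ck]) ** 2)
                sphere = (d2 <= spec.lesion_radius_mm ** 2) & lab["wm"]
                truth[sphere] += spec.lesion_uptake_increment
    else:
        t1_counts = {"left": None, "right": None}
        t2_counts = {"left": None, "right": None}

    truth_vol = Volume3D(truth.astype(np.float32), affine, "suvt-truth")

    # scanner: global calibration, PSF blur, additive voxel noise
    psf = PSFModel(fwhm_mm=spec.psf_fwhm_mm)
    suv_clean = gaussian_blur(
        Volume3D(truth * calibration, affine, "suv"), psf)
    rng_noise = _rng(spec, subject_index, _STAGE_NOISE)
    noisy = suv_clean.data + rng_noise.normal(
        0.0, spec.noise_sd * calibration, size=spec.shape)
    activity = noisy * (dose / weight)      # SUV -> kBq/mL
    pet = Volume3D(activity.astype(np.float32), affine, "kBq/mL")

    gm_p = _smooth_probability(lab["gm"], spec, affine, "probability")
    wm_p = _smooth_probability(lab["wm"], spec, affine, "probability")
    csf_p = _smooth_probability(lab["csf"], spec, affine, "probability")
    total = gm_p.data + wm_p.data + csf_p.data
    scale = np.where(total > 1.0, total, 1.0)
    gm_p = gm_p.with_data(gm_p.data / scale)
    wm_p = wm_p.with_data(wm_p.data / scale)
    csf_p = csf_p.with_data(csf_p.data / scale)

    thal_mask = BinaryMask(lab["thal"].astype(np.uint8), affine, "mask",
                           region_name="thalamus_bilateral")
    X = lab["grids"][0]
    left = BinaryMask(((X < 0) & lab["head"]).astype(np.uint8), affine, "mask",
                      region_name="hemisphere_left")
    right = BinaryMask(((X >= 0) & lab["head"]).astype(np.uint8), affine, "mask",
                       region_name="hemisphere_right")

    record = SubjectRecord(
        subject_id=f"{group}{subject_index + 1:02d}", group=group, sex="F",
        age=age, injected_dose_mbq=dose,
        body_weight_kg=weight, edss=edss,
        disease_duration_y=duration,
        t1_lesions_left=t1_counts["left"], t1_lesions_right=t1_counts["right"],
        t2_lesions_left=t2_counts["left"], t2_lesions_right=t2_counts["right"])

    return PhantomSubject(
        record=record, gm_prob=gm_p, wm_prob=wm_p, csf_prob=csf_p,
        thalamus_mask=thal_mask, hemisphere_left=left, hemisphere_right=right,
        truth=truth_vol, pet_activity=pet,
        true_uptake={"gm": float(gm_val), "wm": float(wm_val),
                     "csf": spec.csf_uptake, "thalamus": spec.thalamus_uptake},
        calibration=calibration)


def make_cohort(spec: PhantomSpec) -> Cohort:
    """n_per_group MS subjects followed by n_per_group HV subjects."""
    subjects = []
    idx = 0
    for group in ("MS", "HV"):
        for _ in range(spec.n_per_group):
            subjects.append(make_phantom_subject(spec, idx, group))
            idx += 1
    return Cohort(spec=spec, subjects=subjects)


_VOLUME_FILES = {
    "pet_activity": ("pet", "kBq/mL"),
    "gm_prob": ("tpm_gm", "probability"),
    "wm_prob": ("tpm_wm", "probability"),
    "csf_prob": ("tpm_csf", "probability"),
    "truth": ("truth", "suvt-truth"),
}
_MASK_FILES = {
    "thalamus_mask": "thalamus_bilateral",
    "hemisphere_left": "hemisphere_left",
    "hemisphere_right": "hemisphere_right",
}


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> dict:
    """Write NIfTI volumes, the cohort CSV and a JSON manifest.

    The manifest records the full spec (including the seed) and every file
    written, so a fresh pipeline run on the directory reproduces all
    downstream statistics.
    """
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise IOError(f"directory does not exist: {directory}")
    manifest: dict = {
        "spec": _spec_to_json(cohort.spec),
        "seed": cohort.spec.seed,
        "subjects": [],
    }
    for subj in cohort.subjects:
        sid = subj.record.subject_id
        entry = {"subject_id": sid, "files": {}}
        for attr, (stem, _units) in _VOLUME_FILES.items():
            fn = f"{sid}_{stem}.nii.gz"
            write_volume(getattr(subj, attr), os.path.join(directory, fn))
            entry["files"][stem] = fn
        for attr, stem in _MASK_FILES.items():
            fn = f"{sid}_{stem}.nii.gz"
            write_volume(getattr(subj, attr), os.path.join(directory, fn))
            entry["files"][stem] = fn
        manifest["subjects"].append(entry)
    cohort_to_frame(cohort.records).to_csv(
        os.path.join(directory, "cohort.csv"), index=False)
    manifest["cohort_csv"] = "cohort.csv"
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_manifest(directory: str | os.PathLike) -> dict:
    with open(os.path.join(os.fspath(directory), "manifest.json")) as fh:
        return json.load(fh)


def _spec_to_json(spec: PhantomSpec) -> dict:
    out = {}
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out
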