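"""SUV and reference-region SUVt quantification, per-subject VOI summaries.

SUV is the standard body-weight standardized uptake value,

    SUV(x) = C(x) [kBq/mL] * weight [kg] / dose [MBq],

which with 1 MBq = 1000 kBq and a tissue density of 1 g/mL is the tissue
concentration divided by injected dose per gram of body mass (unitless).

SUVt divides the SUV image by the mean SUV inside the bilateral thalami of
the same subject — a reference-region SUV ratio (elsewhere called SUVR).
The thalamus is used as reference because it is rarely involved in MS
pathology; by construction the thalamic SUVt mean is exactly 1 for every
subject, and SUVt is invariant to any global multiplicative calibration
drift of the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .volumes import BinaryMask, Volume3D, voi_mean

__all__ = [
    "SubjectRecord",
    "VOISummary",
    "compute_suv",
    "compute_suvt",
    "summarize_subject",
    "wm_gm_ratio",
    "read_cohort_csv",
    "cohort_to_frame",
    "summaries_to_frame",
]

#: cohort CSV column order (one SubjectRecord per row)
COHORT_COLUMNS = [
    "subject_id", "group", "sex", "age", "injected_dose_mbq", "body_weight_kg",
    "edss", "disease_duration_y",
    "t1_lesions_left", "t1_lesions_right", "t2_lesions_left", "t2_lesions_right",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort table: demographics, dosimetry, lesion counts."""

    subject_id: str
    group: str                      # "MS" or "HV"
    sex: str
    age: float
    injected_dose_mbq: float
    body_weight_kg: float
    edss: Optional[float] = None
    disease_duration_y: Optional[float] = None
    t1_lesions_left: Optional[int] = None
    t1_lesions_right: Optional[int] = None
    t2_lesions_left: Optional[int] = None
    t2_lesions_right: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in ("MS", "HV"):
            raise ValueError(f"group must be MS or HV, got {self.group!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        for label, v in (("injected dose", self.injected_dose_mbq),
                         ("body weight", self.body_weight_kg)):
            if not v > 0:
                raise ValueError(f"{label} must be positive")
        for label in ("t1_lesions_left", "t1_lesions_right",
                      "t2_lesions_left", "t2_lesions_right"):
            v = getattr(self, label)
            if v is not None and (v < 0 or int(v) != v):
                raise ValueError(f"{label} must be a non-negative integer")


@dataclass(frozen=True)
class VOISummary:
    """Mean SUV / SUVt and voxel count for one region of one subject."""

    subject_id: str
    region_name: str
    mean_suv: float
    mean_suvt: float
    voxel_count: int
    mask_variant: str = "raw"       # "raw" or "spillin_free"

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValueError("VOISummary requires a non-empty region")


def compute_suv(activity: Volume3D, dose_mbq: float, weight_kg: float) -> Volume3D:
    """Body-weight SUV from a decay-corrected activity image in kBq/mL."""
    if not dose_mbq > 0 or not weight_kg > 0:
        raise ValueError("dose and weight must be positive")
    return Volume3D(activity.data * (weight_kg / dose_mbq), activity.affine, "suv")


def compute_suvt(suv: Volume3D, thalamus: BinaryMask) -> Volume3D:
    """Normalize an SUV image by its bilateral-thalami VOI mean."""
    ref, _ = voi_mean(suv, thalamus)
    if ref <= 0:
        raise ValueError(f"thalamic reference mean must be positive, got {ref}")
    return Volume3D(suv.data.astype(np.float64) / ref, suv.affine, "suvt")


def summarize_subject(suv: Volume3D, suvt: Volume3D,
                      masks: Iterable[BinaryMask],
                      subject_id: str,
                      mask_variant: str = "raw") -> list[VOISummary]:
    """One :class:`VOISummary` per mask, ordered by region name.

    An empty mask is recorded as an error entry in the returned list's
    place (skipped with a log-style note) rather than aborting the run.
    """
    out: list[VOISummary] = []
    for mask in sorted(masks, key=lambda m: m.region_name):
        if mask.voxel_count == 0:
            continue
        mu_suv, n = voi_mean(suv, mask)
        mu_suvt, _ = voi_mean(suvt, mask)
        out.append(VOISummary(subject_id, mask.region_name, mu_suv, mu_suvt,
                              n, mask_variant))
    return out


def wm_gm_ratio(wm_mean: float, gm_mean: float) -> float:
    """White-/gray-matter uptake ratio.

    On SUVt inputs the thalamic normalizer cancels, so the ratio of SUVt
    means equals the ratio of SUV means.
    """
    if not gm_mean > 0:
        raise ValueError("GM mean must be positive")
    return wm_mean / gm_mean


# ---------------------------------------------------------------------------
# cohort table I/O

def read_cohort_csv(path) -> list[SubjectRecord]:
    """Read a cohort CSV (header row required, columns as COHORT_COLUMNS;
    optional columns may be empty)."""
    df = pd.read_csv(path)
    missing = {"subject_id", "group", "age"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        def get(col, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            sex=str(row.get("sex", "")),
            age=float(row["age"]),
            injected_dose_mbq=get("injected_dose_mbq") or 370.0,
            body_weight_kg=get("body_weight_kg") or 60.0,
            edss=get("edss"),
            disease_duration_y=get("disease_duration_y"),
            t1_lesions_left=get("t1_lesions_left", int),
            t1_lesions_right=get("t1_lesions_right", int),
            t2_lesions_left=get("t2_lesions_left", int),
            t2_lesions_right=get("t2_lesions_right", int),
        ))
    return records


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in COHORT_COLUMNS}
                         for r in records], columns=COHORT_COLUMNS)


def summaries_to_frame(summaries: Sequence[VOISummary]) -> pd.DataFrame:
    """Tidy per-subject, per-region summary table."""
    return pd.DataFrame(
        [{"subject_id": s.subject_id, "region": s.region_name,
          "variant": s.mask_variant, "mean_suv": s.mean_suv,
          "mean_suvt": s.mean_suvt, "n_voxels": s.voxel_count}
         for s in summaries])
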