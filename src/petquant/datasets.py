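"""Bundled reference data.

``load_reference_cohort`` returns the per-subject quantification table of a
published 6-vs-6 clinical ¹¹C-acetate brain-PET study (six relapsing-
remitting MS patients, six healthy volunteers, all female): thalamus-
referenced gray- and white-matter SUVt means, their WM/GM ratio, age,
EDSS and disease duration.  It is the canonical small worked example for
the scalar statistics in :mod:`petquant.stats` — the ratio-consistency
check, the exact Mann-Whitney test and the age-adjusted ANCOVA all run on
it in well under a second.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_cohort"]

_ROWS = [
    # subject_id, group, sex, age, edss, disease_duration_y, gm_suvt, wm_suvt, wm_gm_ratio
    ("MS1", "MS", "F", 47, 7.0, 10.3, 1.0494, 0.9415, 0.8972),
    ("MS2", "MS", "F", 45, 2.0, 6.8, 1.1069, 1.0529, 0.9512),
    ("MS3", "MS", "F", 48, 1.0, 5.7, 1.0282, 0.8874, 0.8631),
    ("MS4", "MS", "F", 53, 2.5, 7.4, 1.0837, 0.9434, 0.8705),
    ("MS5", "MS", "F", 34, 4.0, 3.3, 0.9633, 0.8244, 0.8558),
    ("MS6", "MS", "F", 49, 1.0, 1.4, 1.0336, 0.9044, 0.8750),
    ("HV1", "HV", "F", 54, None, None, 0.9149, 0.7320, 0.8001),
    ("HV2", "HV", "F", 61, None, None, 0.9671, 0.8121, 0.8397),
    ("HV3", "HV", "F", 41, None, None, 0.9518, 0.7789, 0.8183),
    ("HV4", "HV", "F", 67, None, None, 0.9341, 0.7946, 0.8507),
    ("HV5", "HV", "F", 62, None, None, 0.9449, 0.8021, 0.8489),
    ("HV6", "HV", "F", 63, None, None, 0.9758, 0.8096, 0.8297),
]


def load_reference_cohort() -> pd.DataFrame:
    """Per-subject GM/WM SUVt table of the reference clinical cohort."""
    return pd.DataFrame(
        _ROWS,
        columns=["subject_id", "group", "sex", "age", "edss",
                 "disease_duration_y", "gm_suvt", "wm_suvt", "wm_gm_ratio"],
    )
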