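"""Bundled reference data.

``patient_zscore_table.tsv`` is the published individual-level table of
age-adjusted Z-scores and centile ranks for the dysexecutive (dAD) and
amnestic (AD) Alzheimer's disease patients and the cognitively unimpaired
controls (CU), across the five biomarkers (NFQ, meta-ROI cortical
thickness, left/right hippocampal volume, inferior parietal thickness).
Centile ranks are printed to 2 decimals; a handful of printed ranks differ
from Phi(z) rounded to 2 decimals by exactly 0.01 (the published table was
rounded from unrounded Z-scores with more digits than printed).

``group_median_suvr`` holds the published group-median amyloid and tau PET
standardized uptake value ratios used by the A/T positivity rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

BIOMARKERS = (
    "nfq",
    "meta_roi",
    "left_hippocampus",
    "right_hippocampus",
    "inferior_parietal",
)

#: group-median (amyloid, tau) PET SUVRs
GROUP_MEDIAN_SUVR = {
    "dAD": {"amyloid": 2.48, "tau": 2.14},
    "AD": {"amyloid": 2.62, "tau": 1.89},
    "control": {"amyloid": 1.30, "tau": 1.21},
}


def load_patient_zscore_table() -> pd.DataFrame:
    """Long-format table: subject, group, biomarker, z, centile (printed)."""
    ref = resources.files("netfailq").joinpath("data/patient_zscore_table.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
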