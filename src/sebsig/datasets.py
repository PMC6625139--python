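"""Bundled six-lesion sebaceous cohort metrics.

The package was developed around a six-lesion tumor/normal exome cohort:
three MMR-deficient sebaceous lesions from germline MSH2 mutation carriers
(Lynch syndrome) and three MMR-proficient lesions from non-carriers. The
raw sequence data are not public; what is bundled here are the per-sample
summary metrics of that cohort — mutational load, TMB, exonic
microsatellite indel counts, read-level MSI scores, and the combined
contribution of the two defective-MMR signatures (6 + 15) per
MMR-deficient lesion — which are the inputs for the cohort-level group
comparisons.

For the MMR-proficient group only the combined-signature summary
(mean 2.3, SD 4.0, n = 3) is available, so that comparison runs through
the summary-statistics entry point of
:func:`sebsig.group_stats.students_t_test`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_stats import GroupSummary
from .report import GROUP_DEFICIENT, GROUP_PROFICIENT

#: Implied capture-region size (megabases), back-derived from the cohort's
#: load/TMB ratios (e.g. 2421 SSNVs at 36.0 mutations/Mb); reproduces all
#: six TMB values at one decimal place.
CAPTURE_MB = 67.25

#: Per-lesion combined signature 6 + 15 contribution (%), MMR-deficient.
DEFICIENT_COMBINED_SIG_PERCENT = (39.0, 50.0, 34.0)

#: Combined signature 6 + 15 contribution of the MMR-proficient group,
#: available as summary statistics only.
PROFICIENT_COMBINED_SIG_SUMMARY = GroupSummary(n=3, mean=2.3, sd=4.0)

#: Mean/SD of the signature-6-only contribution per group (percent).
DEFICIENT_SIG6_SUMMARY = GroupSummary(n=3, mean=31.3, sd=8.5)

_ROWS = [
    # id, lesion, group, load, tmb, exonic ms indels, msi score, second hit
    ("31001", "adenoma", GROUP_PROFICIENT, 184, 2.7, 13, 0.34, "none"),
    ("44001", "adenoma", GROUP_PROFICIENT, 80, 1.2, 11, 0.02, "none"),
    ("67001", "adenoma", GROUP_PROFICIENT, 100, 1.5, 15, 0.24, "none"),
    ("10101", "adenoma", GROUP_DEFICIENT, 943, 14.0, 139, 2.54, "somatic_mutation"),
    ("00011", "carcinoma", GROUP_DEFICIENT, 1341, 19.9, 555, 21.11, "somatic_mutation"),
    ("04001", "carcinoma", GROUP_DEFICIENT, 2421, 36.0, 674, 23.53, "LOH"),
]


def load_sebaceous_cohort() -> pd.DataFrame:
    """Per-sample metrics of the six-lesion cohort.

    Columns: sample_id (index), lesion, group, mutational_load, tmb,
    exonic_ms_indels, msi_score, second_hit, combined_sig6_15 (percent;
    NaN for the MMR-proficient samples, whose per-sample signature
    compositions are summarised only at group level).
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "sample_id", "lesion", "group", "mutational_load", "tmb",
            "exonic_ms_indels", "msi_score", "second_hit",
        ],
    ).set_index("sample_id")
    combined = {"10101": 39.0, "00011": 50.0, "04001": 34.0}
    df["combined_sig6_15"] = [combined.get(i, np.nan) for i in df.index]
    return df


def group_values(df: pd.DataFrame, metric: str, group: str) -> list[float]:
    return df.loc[df["group"] == group, metric].dropna().tolist()
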