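"""Published a-priori group summaries bundled as worked-example inputs.

The two validation studies of the paradigm reported their a-priori group
comparisons (sex distribution, age, working-memory IQ, alertness, education)
as per-group counts or means with standard deviations.  Those printed
summaries are bundled here so the summary-statistic paths of the test
routines can be demonstrated and checked: five of the published cells are
exactly recomputable from the summaries alone (the two sex chi-squares, the
two one-way-ANOVA effect sizes, and the age Cohen's d of the two-group
study).  The age Kruskal-Wallis and the education Wilcoxon test of the
published tables require raw data and are not recomputable here.
"""

from __future__ import annotations

import numpy as np

from .stats import (
    GroupSummary,
    StatResult,
    anova_oneway,
    chi_square_independence,
    t_test_two_sample,
)

__all__ = [
    "STUDY1_APRIORI",
    "STUDY2_APRIORI",
    "worked_examples",
    "WORKED_EXAMPLE_PRINTED",
]

# three-group study: EC / YC / CC
STUDY1_APRIORI = {
    "n": (27, 26, 27),
    "sex_counts": {  # rows: female, male; columns: EC, YC, CC
        "female": (15, 15, 15),
        "male": (12, 11, 12),
    },
    "age": (
        GroupSummary("EC", 27, 23.48, 3.74),
        GroupSummary("YC", 26, 25.0, 4.26),
        GroupSummary("CC", 27, 25.85, 4.3),
    ),
    "wm_iq": (
        GroupSummary("EC", 27, 100.89, 9.55),
        GroupSummary("YC", 26, 104.58, 11.53),
        GroupSummary("CC", 27, 104.3, 13.99),
    ),
    "alertness": (
        GroupSummary("EC", 27, 45.3, 6.31),
        GroupSummary("YC", 26, 43.96, 6.99),
        GroupSummary("CC", 27, 42.11, 6.31),
    ),
}

# two-group study: EC / YC
STUDY2_APRIORI = {
    "n": (62, 38),
    "sex_counts": {  # rows: female, male; columns: EC, YC
        "female": (33, 22),
        "male": (29, 16),
    },
    "age": (
        GroupSummary("EC", 62, 22.77, 3.99),
        GroupSummary("YC", 38, 24.26, 4.2),
    ),
    "education": (
        GroupSummary("EC", 62, 7.84, 1.43),
        GroupSummary("YC", 38, 8.03, 1.55),
    ),
}

# the published (rounded) values the worked examples reproduce
WORKED_EXAMPLE_PRINTED = {
    "sex_chi2_study1": 0.03,  # 2x3 table, no continuity correction
    "sex_chi2_study2": 0.06,  # 2x2 table, Yates correction
    "wm_iq_partial_eta2": 0.02,
    "alertness_partial_eta2": 0.04,
    "age_cohen_d_study2": -0.36,
}


def worked_examples() -> dict[str, StatResult]:
    """Recompute the five a-priori statistics that follow from the printed
    summaries alone.  Keys match :data:`WORKED_EXAMPLE_PRINTED`."""
    sex1 = np.array([STUDY1_APRIORI["sex_counts"]["female"],
                     STUDY1_APRIORI["sex_counts"]["male"]])
    sex2 = np.array([STUDY2_APRIORI["sex_counts"]["female"],
                     STUDY2_APRIORI["sex_counts"]["male"]])
    return {
        "sex_chi2_study1": chi_square_independence(sex1.T),
        "sex_chi2_study2": chi_square_independence(sex2.T),
        "wm_iq_partial_eta2": anova_oneway(STUDY1_APRIORI["wm_iq"]),
        "alertness_partial_eta2": anova_oneway(STUDY1_APRIORI["alertness"]),
        "age_cohen_d_study2": t_test_two_sample(STUDY2_APRIORI["age"]),
    }
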