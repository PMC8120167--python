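"""Reference values from the published development cohort.

The computerized-TSR study cohort comprised 240 invasive breast-cancer
patients on seven tissue microarrays (two cores per specimen).  This module
stores the printed cohort-level quantities that the package uses as inputs:
the covariate marginals of the clinico-pathological table, the multivariable
Cox hazard ratios that define the nomogram, the TSR dichotomization cutoff,
and the total-points risk-group cutoffs.  Everything here is a published
table transcribed verbatim; nothing is estimated by this package.
"""

from __future__ import annotations

import math

#: TSR cutoff (fraction of core area that is stroma); TSR <= cutoff is
#: "stroma-low", TSR > cutoff is "stroma-high".
TSR_CUTOFF = 0.555

#: Overall 5-year disease-free survival of the cohort.
FIVE_YEAR_DFS = 0.62

#: Administrative follow-up horizon in months.
FOLLOWUP_MONTHS = 60.0

#: Covariate marginal frequencies (per-level probabilities) of the cohort.
#: Keys are ClinicalTable column names; each maps level -> frequency.
COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "age_group": {"<=50": 149 / 240, ">50": 91 / 240},
    "menopausal": {"pre": 134 / 240, "post": 106 / 240},
    "histotype": {"IDC": 191 / 240, "other": 49 / 240},
    "t_stage": {"T1": 35 / 240, "T2": 162 / 240, "T3": 43 / 240},
    "n_status": {"neg": 109 / 240, "pos": 131 / 240},
    "grade": {"I": 40 / 240, "II": 141 / 240, "III": 59 / 240},
    "er": {"pos": 106 / 240, "neg": 134 / 240},
    "pr": {"pos": 107 / 240, "neg": 133 / 240},
    "her2": {"non-amp": 189 / 240, "amp": 51 / 240},
}

#: Fraction of specimens classified stroma-high at the 55.5% cutoff.
STROMA_HIGH_FRAC = 147 / 240

#: Multivariable hazard ratios of the best-fit Cox model (reference level
#: listed first with HR 1.0).  These define the published nomogram.
MULTIVARIABLE_HR: dict[str, dict[str, float]] = {
    "t_stage": {"T1": 1.0, "T2": 2.576, "T3": 3.506},
    "n_status": {"neg": 1.0, "pos": 3.854},
    "grade": {"I": 1.0, "II": 1.479, "III": 4.250},
    # ER-positive is protective: HR 0.568 vs the ER-negative reference.
    "er": {"neg": 1.0, "pos": 0.568},
    "her2": {"non-amp": 1.0, "amp": 2.045},
    # Stroma-low is protective: HR 0.643 vs the stroma-high reference.
    "tsr_group": {"high": 1.0, "low": 0.643},
}

#: PR stayed in the multivariable table but was dropped from the nomogram.
PR_HR = {"neg": 1.0, "pos": 1.076}

#: Published per-level nomogram points (for cross-checks; ER printed points
#: deviate from the log-HR scaling and are excluded from reproduction).
PUBLISHED_POINTS: dict[str, dict[str, float]] = {
    "t_stage": {"T1": 0.0, "T2": 65.1, "T3": 87.0},
    "n_status": {"neg": 0.0, "pos": 93.4},
    "grade": {"I": 0.0, "II": 27.3, "III": 100.0},
    "er": {"pos": 0.0, "neg": 36.34},
    "her2": {"non-amp": 0.0, "amp": 49.6},
    "tsr_group": {"low": 0.0, "high": 30.8},
}

#: Total-points cutoffs splitting the cohort into risk groups I/II/III.
TOTAL_POINTS_CUTOFFS = (222.2, 316.8)


def multivariable_log_hazards() -> dict[str, dict[str, float]]:
    """Per-level log-hazards (natural log of the published HRs)."""
    return {
        cov: {lvl: math.log(hr) for lvl, hr in levels.items()}
        for cov, levels in MULTIVARIABLE_HR.items()
    }
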