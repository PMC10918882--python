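"""Bundled worked example: educational attainment and respiratory disease.

Input values are summary estimates reported by a published two-sample MR
study of educational attainment (EA, per 4.2-year SD of schooling), three
modifiable mediators (BMI, cigarettes per day, physical activity) and
five respiratory outcomes (FEV1, FVC, FEV1/FVC, lung cancer, asthma).
They are *inputs*, printed to 2-4 decimals: the underlying GWAS data are
not bundled, so the estimates themselves are not recomputed here — only
the mediation arithmetic built on them is.  Binary-outcome effects are
carried on the log-odds scale (ORs are logged on entry); SEs are
recovered from printed symmetric 95% CIs where not printed directly.
"""

from __future__ import annotations

import math

import pandas as pd

from .mediation import (
    Estimate,
    difference_indirect,
    product_indirect,
    proportion_mediated,
)

_LN = math.log

#: a paths — univariable IVW effect of EA on each mediator (SD units)
A_PATHS = {
    "BMI": Estimate(-0.1604, 0.0314),
    "cigarettes_per_day": Estimate(-0.3218, 0.0414),
    "physical_activity": Estimate(0.1953, 0.0186),
}

#: total effects c — univariable IVW effect of EA on each outcome
TOTAL_EFFECTS = {
    "FEV1": Estimate.from_ci(0.10, 0.06, 0.14, scale="sd"),
    "FVC": Estimate.from_ci(0.12, 0.07, 0.16, scale="sd"),
    "FEV1_FVC": Estimate.from_ci(-0.005, -0.05, 0.04, scale="sd"),
    "lung_cancer": Estimate.from_ci(_LN(0.54), _LN(0.45), _LN(0.65), scale="log-odds"),
    "asthma": Estimate.from_ci(_LN(0.86), _LN(0.78), _LN(0.94), scale="log-odds"),
}

#: b paths — MVMR effect of mediator on outcome adjusted for EA
B_PATHS = {
    ("BMI", "FEV1"): Estimate.from_ci(-0.09, -0.12, -0.06, scale="sd"),
    ("BMI", "FVC"): Estimate.from_ci(-0.17, -0.20, -0.14, scale="sd"),
    ("BMI", "FEV1_FVC"): Estimate.from_ci(0.11, 0.09, 0.14, scale="sd"),
    ("BMI", "lung_cancer"): Estimate.from_ci(_LN(1.12), _LN(0.98), _LN(1.28), scale="log-odds"),
    ("BMI", "asthma"): Estimate.from_ci(_LN(1.15), _LN(1.08), _LN(1.22), scale="log-odds"),
    ("cigarettes_per_day", "FEV1"): Estimate.from_ci(-0.08, -0.12, -0.04, scale="sd"),
    ("cigarettes_per_day", "FVC"): Estimate.from_ci(-0.07, -0.11, -0.02, scale="sd"),
    ("cigarettes_per_day", "FEV1_FVC"): Estimate.from_ci(-0.04, -0.08, -0.004, scale="sd"),
    ("cigarettes_per_day", "lung_cancer"): Estimate.from_ci(_LN(1.41), _LN(1.14), _LN(1.74), scale="log-odds"),
    ("cigarettes_per_day", "asthma"): Estimate.from_ci(_LN(1.05), _LN(0.98), _LN(1.12), scale="log-odds"),
}

#: direct effects c' of EA on each outcome adjusted for BMI + cigarettes.
#: The printed FEV1/FVC interval is internally inconsistent and is omitted.
DIRECT_COMBINED = {
    "FEV1": Estimate.from_ci(0.10, 0.04, 0.16, scale="sd"),
    "FVC": Estimate.from_ci(0.07, 0.01, 0.12, scale="sd"),
    "lung_cancer": Estimate.from_ci(_LN(0.55), _LN(0.42), _LN(0.71), scale="log-odds"),
    "asthma": Estimate.from_ci(_LN(0.88), _LN(0.78), _LN(0.99), scale="log-odds"),
}

MEDIATORS = ("BMI", "cigarettes_per_day")
OUTCOMES = ("FEV1", "FVC", "FEV1_FVC", "lung_cancer", "asthma")


def worked_example() -> pd.DataFrame:
    """Mediation decomposition over the bundled published estimates.

    For every outcome: the product-method indirect effect and proportion
    mediated through BMI and through cigarettes per day, plus the
    difference-method decomposition for both mediators combined where a
    combined-adjusted direct effect is available.  Pure deterministic
    arithmetic; runs in well under a second.
    """
    rows = []
    for outcome in OUTCOMES:
        total = TOTAL_EFFECTS[outcome]
        for mediator in MEDIATORS:
            a = A_PATHS[mediator]
            b = B_PATHS[(mediator, outcome)]
            frag = product_indirect(a, b, ci_method="sobel", mediator=mediator)
            prop = proportion_mediated(
                Estimate(frag.indirect, frag.indirect_se, scale=b.scale), total)
            rows.append({
                "outcome": outcome, "pathway": f"via {mediator}",
                "method": "product", "indirect": frag.indirect,
                "indirect_se": frag.indirect_se,
                "ci_low": frag.indirect_ci[0], "ci_high": frag.indirect_ci[1],
                "sobel_p": frag.sobel_p, "proportion": prop["proportion"],
                "proportion_se": prop["se"],
            })
        if outcome in DIRECT_COMBINED:
            frag = difference_indirect(total, DIRECT_COMBINED[outcome],
                                       mediators=list(MEDIATORS))
            prop = proportion_mediated(
                Estimate(frag.indirect, frag.indirect_se, scale=total.scale), total)
            rows.append({
                "outcome": outcome, "pathway": "via BMI + cigarettes_per_day",
                "method": "difference", "indirect": frag.indirect,
                "indirect_se": frag.indirect_se,
                "ci_low": frag.indirect_ci[0], "ci_high": frag.indirect_ci[1],
                "sobel_p": None, "proportion": prop["proportion"],
                "proportion_se": prop["se"],
            })
    return pd.DataFrame(rows)
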