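"""Worked-example inputs: per-cohort detection counts and agreement values
printed by a large free-living validation study of bilateral foot-worn IMU
gait-event detection (six cohorts: congestive heart failure, chronic
obstructive pulmonary disease, multiple sclerosis, Parkinson's disease,
proximal femoral fracture, healthy adults).

These are *inputs* to the metrics layer — raw true-positive/false-negative/
false-positive counts and per-cohort stance/swing bias values — from which
recall, precision, F1, totals, and the stride-time bias identity can be
recomputed and checked against the published percentages.
"""

#: cohort -> {"IC": (tp, fn, fp), "FC": (tp, fn, fp)}
COHORT_EVENT_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "CHF": {"IC": (408, 3, 18), "FC": (401, 1, 23)},
    "COPD": {"IC": (2294, 58, 86), "FC": (2235, 37, 147)},
    "MS": {"IC": (2563, 19, 72), "FC": (2518, 12, 95)},
    "PD": {"IC": (2431, 23, 40), "FC": (2411, 3, 55)},
    "PFF": {"IC": (1642, 11, 15), "FC": (1614, 18, 45)},
    "HA": {"IC": (3627, 55, 98), "FC": (3568, 20, 141)},
}

#: Cells of the printed table whose own arithmetic disagrees with the printed
#: percentage: COPD FC recall = 2235/2272 = 98.37% rounds to 98, printed as 99.
PRINTED_INCONSISTENCIES: dict[tuple[str, str], dict[str, int]] = {
    ("COPD", "FC"): {"recall": 98},
}

#: cohort -> {"IC"/"FC": (recall %, precision %, F1 %)} as printed (integer percent)
COHORT_PRINTED_SCORES: dict[str, dict[str, tuple[int, int, int]]] = {
    "CHF": {"IC": (99, 96, 97), "FC": (100, 95, 97)},
    "COPD": {"IC": (98, 96, 97), "FC": (99, 94, 96)},
    "MS": {"IC": (99, 97, 98), "FC": (100, 96, 98)},
    "PD": {"IC": (99, 98, 99), "FC": (100, 98, 99)},
    "PFF": {"IC": (99, 99, 99), "FC": (99, 97, 98)},
    "HA": {"IC": (99, 97, 98), "FC": (99, 96, 98)},
}

#: cohort -> (stance bias s, swing bias s, stride bias s) as printed
COHORT_PARAM_BIAS: dict[str, tuple[float, float, float]] = {
    "CHF": (-0.00, 0.00, -0.00),
    "COPD": (0.01, -0.01, 0.00),
    "MS": (0.02, -0.02, -0.00),
    "PD": (-0.01, 0.01, 0.00),
    "PFF": (0.07, -0.07, 0.00),
    "HA": (0.00, -0.00, 0.00),
}

#: published per-kind totals: events annotated, detected, missed
PUBLISHED_TOTALS = {"IC": {"annotated": 13134, "missed": 169}, "FC": {"annotated": 12838, "missed": 91}}
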