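"""Reference marginals of the contraception case-control cohort.

The package's synthetic generator and the replay inputs for the metric
panels are calibrated against a published two-group questionnaire cohort
(n = 119 women with histologically confirmed endometriosis, n = 109
examination-negative controls, all using hormonal contraception).  Only
per-group marginal summaries are public: per-item yes/no counts, NRS
means with SDs, PainDETECT band counts and the 2x2 tables of the derived
scores and the hand-crafted decision tree.  Everything in this module is
a plain transcription of those summaries; all probabilities derived from
them are exact rationals (count / group size).

Group keys used throughout: ``"EMS"`` (cases) and ``"NO_EMS"`` (controls).
"""

from __future__ import annotations

from fractions import Fraction

N_EMS = 119
N_NO_EMS = 109
GROUP_N = {"EMS": N_EMS, "NO_EMS": N_NO_EMS}

# Per-item "yes" counts, (EMS, NO_EMS).  Keys are codebook item ids where
# the item is a stored answer; the ``*_pos`` keys are presence indicators
# (NRS > 0) of the three PainDETECT intensity scales and ``paindetect_ge4``
# is the dichotomized final score (>= 4).
ITEM_YES_COUNTS: dict[str, tuple[int, int]] = {
    "smoker": (32, 19),
    "allergies": (66, 52),
    "analgesic_use": (102, 40),
    "dysmenorrhea": (89, 48),
    "cpp": (84, 15),
    "dysuria": (42, 1),
    "dyschezia": (68, 14),
    "dyspareunia": (92, 31),
    "obstipation": (51, 11),
    "diarrhea": (66, 26),
    "adj_cramping": (97, 43),
    "adj_tearing": (54, 14),
    "adj_pulling": (87, 35),
    "adj_stinging": (73, 29),
    "adj_pulsatile": (37, 10),
    "adj_touch_sensitive": (55, 22),
    "adj_burning": (24, 8),
    "adj_pressing": (58, 14),
    "adj_diffuse": (15, 7),
    "adj_cold_warmth": (19, 1),
    "adj_flashing": (67, 7),
    "loc_lower_abdomen": (112, 33),
    "loc_lumbar_spine": (75, 26),
    "loc_thighs_legs": (52, 6),
    "loc_hips_groins": (53, 8),
    "loc_upper_abdomen": (18, 5),
    "loc_vagina_mons": (24, 3),
    "loc_gluteal": (7, 0),
    "pain_now_pos": (85, 15),
    "strongest_4wks_pos": (116, 35),
    "average_4wks_pos": (115, 28),
    "paindetect_ge4": (105, 26),
}

# Dysmenorrhea severity: among women reporting it, how many score NRS > 3.
DYSMENORRHEA_GT3_COUNTS = {"EMS": 88, "NO_EMS": 37}

# Pain-course pattern "yes" counts (patterns are a single-choice question;
# the remainder of each group picked none).
COURSE_PATTERN_COUNTS: dict[str, tuple[int, int]] = {
    "PERSISTENT_SLIGHT_FLUCT": (13, 8),
    "PERSISTENT_WITH_ATTACKS": (46, 8),
    "ATTACKS_NO_PAIN_BETWEEN": (33, 13),
    "ATTACKS_WITH_PAIN_BETWEEN": (22, 5),
}

# Menstrual-pain timing, mutually exclusive categories among women with
# dysmenorrhea; the printed timing rows do not sum to the group sizes, so
# they are read as exclusive combinations of before/during/after.  The
# remainder (including the printed missing-timing counts) gave no timing.
MENSES_TIMING_COUNTS: dict[str, tuple[int, int]] = {
    "BEFORE": (4, 2),
    "DURING": (8, 4),
    "AFTER": (1, 1),
    "BEFORE_DURING": (43, 16),
    "DURING_AFTER": (1, 0),
    "BEFORE_AFTER": (1, 1),
    "BEFORE_DURING_AFTER": (19, 8),
}

# Unconditional NRS moments (mean, SD) per group.  The EMS dysmenorrhea
# mean is not printed legibly in the source tables; 6.3 is the value
# implied by the printed group mean of the eight scales (8 x 4.45 minus
# the seven printed means) and is a generator default, not a quoted fact.
NRS_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "EMS": {
        "dysmenorrhea_nrs": (6.3, 3.9),
        "cpp_nrs": (4.5, 3.6),
        "dysuria_nrs": (1.53, 2.5),
        "dyschezia_nrs": (3.2, 3.3),
        "dyspareunia_nrs": (4.5, 3.1),
        "pain_now_nrs": (2.82, 2.72),
        "strongest_4wks_nrs": (7.7, 2.5),
        "average_4wks_nrs": (5.08, 2.3),
    },
    "NO_EMS": {
        "dysmenorrhea_nrs": (2.9, 3.8),
        "cpp_nrs": (0.78, 2.2),
        "dysuria_nrs": (0.05, 0.5),
        "dyschezia_nrs": (0.77, 2.2),
        "dyspareunia_nrs": (1.43, 2.7),
        "pain_now_nrs": (0.48, 1.46),
        "strongest_4wks_nrs": (1.8, 3.1),
        "average_4wks_nrs": (1.07, 2.25),
    },
}

# The eight control-group NRS means as printed, in the order of the
# eight-item sum-VAS definition (dysmenorrhea, dyspareunia, dysuria,
# dyschezia, CPP, pain now, strongest in 4 wks, average in 4 wks).
NO_EMS_NRS_MEANS = [2.9, 1.43, 0.05, 0.77, 0.78, 0.48, 1.8, 1.07]

# PainDETECT final-score bands: counts per group.
PAINDETECT_BAND_COUNTS = {
    "EMS": {"NEG_0_12": 86, "UNCLEAR_13_18": 23, "POS_19_38": 10, "LE3": 14},
    "NO_EMS": {"NEG_0_12": 105, "UNCLEAR_13_18": 2, "POS_19_38": 2, "LE3": 83},
}

# Demographics (mean, SD) per group.
DEMOGRAPHIC_MOMENTS = {
    "EMS": {"age_yrs": (30.8, 6.8), "bmi": (24.7, 4.8), "age_menarche_yrs": (12.7, 1.6)},
    "NO_EMS": {"age_yrs": (31.0, 8.3), "bmi": (24.3, 6.0), "age_menarche_yrs": (13.0, 1.6)},
}

# Contraceptive preparation counts per group (remainder unreported).
CONTRACEPTIVE_COUNTS = {
    "EMS": {"DNG": 64, "LNG": 20, "DSG": 20, "E_OTHER": 7, "OTHER": 3},
    "NO_EMS": {"DNG": 42, "LNG": 25, "DSG": 21, "E_OTHER": 7, "OTHER": 8},
}

# Yes-counts of the 34 significant parameters in registry order,
# (EMS, NO_EMS).  SP 4 uses the printed before/during timing row; SP 34
# is the derived sum-VAS > 8.5 indicator.
SP_YES_COUNTS: list[tuple[int, int]] = [
    ITEM_YES_COUNTS["analgesic_use"],            # 1
    ITEM_YES_COUNTS["dysmenorrhea"],             # 2
    (88, 37),                                    # 3  dysmenorrhea NRS > 3
    (43, 16),                                    # 4  pain before AND during menses
    ITEM_YES_COUNTS["cpp"],                      # 5
    ITEM_YES_COUNTS["dysuria"],                  # 6
    ITEM_YES_COUNTS["dyschezia"],                # 7
    ITEM_YES_COUNTS["dyspareunia"],              # 8
    ITEM_YES_COUNTS["obstipation"],              # 9
    ITEM_YES_COUNTS["diarrhea"],                 # 10
    ITEM_YES_COUNTS["adj_cramping"],             # 11
    ITEM_YES_COUNTS["adj_tearing"],              # 12
    ITEM_YES_COUNTS["adj_pulling"],              # 13
    ITEM_YES_COUNTS["adj_stinging"],             # 14
    ITEM_YES_COUNTS["adj_pulsatile"],            # 15
    ITEM_YES_COUNTS["adj_touch_sensitive"],      # 16
    ITEM_YES_COUNTS["adj_pressing"],             # 17
    ITEM_YES_COUNTS["adj_cold_warmth"],          # 18
    ITEM_YES_COUNTS["adj_flashing"],             # 19
    ITEM_YES_COUNTS["pain_now_pos"],             # 20
    ITEM_YES_COUNTS["strongest_4wks_pos"],       # 21
    ITEM_YES_COUNTS["average_4wks_pos"],         # 22
    ITEM_YES_COUNTS["loc_lower_abdomen"],        # 23
    ITEM_YES_COUNTS["loc_lumbar_spine"],         # 24
    ITEM_YES_COUNTS["loc_thighs_legs"],          # 25
    ITEM_YES_COUNTS["loc_hips_groins"],          # 26
    ITEM_YES_COUNTS["loc_upper_abdomen"],        # 27
    ITEM_YES_COUNTS["loc_vagina_mons"],          # 28
    ITEM_YES_COUNTS["loc_gluteal"],              # 29
    COURSE_PATTERN_COUNTS["PERSISTENT_WITH_ATTACKS"],   # 30
    COURSE_PATTERN_COUNTS["ATTACKS_NO_PAIN_BETWEEN"],   # 31
    COURSE_PATTERN_COUNTS["ATTACKS_WITH_PAIN_BETWEEN"], # 32
    ITEM_YES_COUNTS["paindetect_ge4"],           # 33
    (102, 23),                                   # 34 sum VAS > 8.5
]

# Published summary statistics of the derived scores.
SUM_SP_MEAN_SD = {"EMS": (18.88, 4.38), "NO_EMS": (5.98, 5.94)}
SUM_VAS_MEAN_SD = {"EMS": (19.2, 6.58), "NO_EMS": (5.13, 5.94)}

# Published 2x2 tables, oriented (tn, fp, fn, tp): rows = condition
# (control / case), columns = test (negative / positive).
TREE_TABLE = (100, 9, 9, 110)
SP_CUTOFF_TABLE = (76, 33, 4, 115)
VAS_CUTOFF_TABLE = (86, 23, 17, 102)


def expected_sum_sp(group: str) -> float:
    """Expected significant-parameter count under independent items.

    By linearity of expectation the mean of a sum of Bernoulli indicators
    is the sum of their prevalences, whatever their correlation; this is
    the identity linking the per-item counts to the published group means
    of the SP sum.
    """
    idx = 0 if group == "EMS" else 1
    n = GROUP_N[group]
    return float(sum(Fraction(c[idx], n) for c in SP_YES_COUNTS))


def item_prevalence(group: str, item_id: str) -> float:
    idx = 0 if group == "EMS" else 1
    return ITEM_YES_COUNTS[item_id][idx] / GROUP_N[group]
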