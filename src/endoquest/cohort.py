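"""Synthetic case-control questionnaire cohorts.

Only per-group marginal summaries of the reference cohort are public, so
the generator emulates a two-group cohort whose *marginals* match those
summaries while the dependence between items is a modeling choice:

* Binary answers are drawn through a Gaussian copula with exchangeable
  latent correlation ``copula_rho`` and the specified Bernoulli
  marginals, so each item's prevalence is honored exactly while a single
  common factor induces the "symptomatic patients have many symptoms"
  clustering.  The mean of any indicator sum is invariant to the
  correlation (linearity of expectation); its variance, and therefore
  classifier performance, is not.
* Each pain NRS is zero-inflated: 0 exactly when its presence indicator
  is false, otherwise an integer from a moment-matched truncated normal
  on [1, 10] (conditional mean = unconditional mean / prevalence).
* The dysmenorrhea scale additionally honors the printed severity split
  (NRS > 3 among reporters).
* The PainDETECT final score is drawn band-first (the dichotomized
  final >= 4 is a copula item; band and integer score are sampled
  conditionally) and then decomposed into seven 0-5 sensory items, the
  course-pattern adjustment and radiating pain so that re-scoring the
  record reproduces the drawn band exactly.
* Missingness is applied independently per item at the specified rates.

Cohorts are fully reproducible from the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import ndtr

from . import calibration as cal
from .model import (
    Contraceptive, CoursePattern, Label, PatientRecord, SensoryItem,
    get_item_value, set_item_value,
)
from .scoring import NotScorableError, paindetect_final_score

__all__ = ["CohortSpec", "default_spec", "generate", "recover_marginals",
           "MarginalEstimate", "diff_report"]

GROUPS = ("EMS", "NO_EMS")

# Copula-driven binary items, in sampling order.  ``*_pos`` entries are
# presence indicators (NRS > 0) of the PainDETECT intensity scales;
# ``paindetect_ge4`` is the dichotomized final score.
BINARY_ITEMS: tuple[str, ...] = (
    "smoker", "allergies", "analgesic_use",
    "dysmenorrhea", "cpp", "dysuria", "dyschezia", "dyspareunia",
    "obstipation", "diarrhea",
    "adj_cramping", "adj_tearing", "adj_pulling", "adj_stinging",
    "adj_pulsatile", "adj_touch_sensitive", "adj_burning", "adj_pressing",
    "adj_diffuse", "adj_cold_warmth", "adj_flashing",
    "loc_lower_abdomen", "loc_lumbar_spine", "loc_thighs_legs",
    "loc_hips_groins", "loc_upper_abdomen", "loc_vagina_mons", "loc_gluteal",
    "pain_now_pos", "strongest_4wks_pos", "average_4wks_pos",
    "paindetect_ge4", "radiating_pain",
)

# Radiating pain is not reported in the reference summaries; these are
# package defaults (a plausible minority symptom, commoner in cases).
_RADIATING_DEFAULT = {"EMS": 0.25, "NO_EMS": 0.08}

_NRS_PRESENCE = {
    "cpp_nrs": "cpp",
    "dysuria_nrs": "dysuria",
    "dyschezia_nrs": "dyschezia",
    "dyspareunia_nrs": "dyspareunia",
    "pain_now_nrs": "pain_now_pos",
    "strongest_4wks_nrs": "strongest_4wks_pos",
    "average_4wks_nrs": "average_4wks_pos",
}

_TIMING_BOOLS = {
    "BEFORE": (True, False, False),
    "DURING": (False, True, False),
    "AFTER": (False, False, True),
    "BEFORE_DURING": (True, True, False),
    "DURING_AFTER": (False, True, True),
    "BEFORE_AFTER": (True, False, True),
    "BEFORE_DURING_AFTER": (True, True, True),
}

# Within-band (lo, hi, mean, sd) for the PainDETECT final score; the
# 0-3 and 4-12 moments are group-specific so the group means land near
# the published 10 (cases) and 2.3 (controls).
_PD_BAND_PARAMS = {
    "EMS": {"LE3": (0, 3, 1.5, 1.2), "4_12": (4, 12, 8.5, 2.5),
            "13_18": (13, 18, 15.0, 1.8), "19_38": (19, 38, 22.0, 3.5)},
    "NO_EMS": {"LE3": (0, 3, 0.5, 1.0), "4_12": (4, 12, 6.5, 2.0),
               "13_18": (13, 18, 15.0, 1.8), "19_38": (19, 38, 22.0, 3.5)},
}

_PATTERN_ADJ = {CoursePattern.PERSISTENT_SLIGHT_FLUCT: 0,
                CoursePattern.PERSISTENT_WITH_ATTACKS: -1,
                CoursePattern.ATTACKS_NO_PAIN_BETWEEN: 1,
                CoursePattern.ATTACKS_WITH_PAIN_BETWEEN: 1}


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic two-group cohort."""

    n_ems: int = cal.N_EMS
    n_no_ems: int = cal.N_NO_EMS
    item_prevalence: dict = field(default_factory=dict)   # group -> item -> p
    nrs_moments: dict = field(default_factory=dict)       # group -> item -> (mean, sd)
    dysmenorrhea_gt3_given_present: dict = field(default_factory=dict)
    course_pattern_freq: dict = field(default_factory=dict)
    menses_timing_given_dysmenorrhea: dict = field(default_factory=dict)
    paindetect_band_given_ge4: dict = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)      # group -> field -> (mean, sd)
    contraceptive_freq: dict = field(default_factory=dict)
    copula_rho: float = 0.3
    missing_rate: dict = field(default_factory=dict)      # item -> p
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.copula_rho < 1.0:
            raise ValueError("copula_rho must be in [0, 1)")
        for group, items in self.item_prevalence.items():
            for item, p in items.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence [{group}][{item}] outside [0,1]")
        for rate in self.missing_rate.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rate outside [0,1]")

    def scaled(self, factor: int) -> "CohortSpec":
        """Same marginals with group sizes multiplied by ``factor``."""
        return replace(self, n_ems=self.n_ems * factor,
                       n_no_ems=self.n_no_ems * factor)


def default_spec(seed: Optional[int] = None) -> CohortSpec:
    """Spec calibrated to the reference cohort's printed marginals.

    Every prevalence is the exact printed fraction (count / group size);
    n defaults to 119 cases and 109 controls.
    """
    prevalence = {g: {} for g in GROUPS}
    for item, (c_ems, c_no) in cal.ITEM_YES_COUNTS.items():
        prevalence["EMS"][item] = c_ems / cal.N_EMS
        prevalence["NO_EMS"][item] = c_no / cal.N_NO_EMS
    for g in GROUPS:
        prevalence[g]["radiating_pain"] = _RADIATING_DEFAULT[g]

    course = {g: {} for g in GROUPS}
    for pattern, (c_ems, c_no) in cal.COURSE_PATTERN_COUNTS.items():
        course["EMS"][pattern] = c_ems / cal.N_EMS
        course["NO_EMS"][pattern] = c_no / cal.N_NO_EMS

    timing = {g: {} for g in GROUPS}
    dys_counts = {"EMS": cal.ITEM_YES_COUNTS["dysmenorrhea"][0],
                  "NO_EMS": cal.ITEM_YES_COUNTS["dysmenorrhea"][1]}
    for combo, (c_ems, c_no) in cal.MENSES_TIMING_COUNTS.items():
        timing["EMS"][combo] = c_ems / dys_counts["EMS"]
        timing["NO_EMS"][combo] = c_no / dys_counts["NO_EMS"]

    bands = {}
    for g in GROUPS:
        bc = cal.PAINDETECT_BAND_COUNTS[g]
        ge4 = cal.ITEM_YES_COUNTS["paindetect_ge4"][0 if g == "EMS" else 1]
        mid = ge4 - bc["UNCLEAR_13_18"] - bc["POS_19_38"]  # final in 4-12
        bands[g] = {"4_12": mid / ge4, "13_18": bc["UNCLEAR_13_18"] / ge4,
                    "19_38": bc["POS_19_38"] / ge4}

    gt3 = {g: cal.DYSMENORRHEA_GT3_COUNTS[g] / dys_counts[g] for g in GROUPS}

    contra = {}
    for g in GROUPS:
        n = cal.GROUP_N[g]
        contra[g] = {tok: c / n for tok, c in cal.CONTRACEPTIVE_COUNTS[g].items()}

    # Small missing rates mirroring the printed missing-data counts.
    missing = {"bmi": 1 / 228, "cpp_nrs": 1 / 228,
               "average_4wks_nrs": 1 / 228, "course_pattern": 1 / 228}

    return CohortSpec(
        item_prevalence=prevalence,
        nrs_moments={g: dict(cal.NRS_MOMENTS[g]) for g in GROUPS},
        dysmenorrhea_gt3_given_present=gt3,
        course_pattern_freq=course,
        menses_timing_given_dysmenorrhea=timing,
        paindetect_band_given_ge4=bands,
        demographics={g: dict(cal.DEMOGRAPHIC_MOMENTS[g]) for g in GROUPS},
        contraceptive_freq=contra,
        missing_rate=missing,
        seed=seed,
    )


def _trunc_normal_int(rng, n, mean, sd, lo, hi):
    """Rounded, clipped normal draws — a discrete truncated normal."""
    if n == 0:
        return np.empty(0, dtype=int)
    return np.clip(np.rint(rng.normal(mean, sd, size=n)), lo, hi).astype(int)


def _conditional_moments(mean: float, sd: float, prev: float,
                         item: str) -> tuple[float, float]:
    """Moments of the positive part of a zero-inflated scale."""
    if prev <= 0:
        return 0.0, 0.0
    m_c = mean / prev
    if m_c > 10:
        warnings.warn(f"{item}: mean/prevalence = {m_c:.2f} > 10; clipping")
        m_c = 10.0
    m_c = max(1.0, m_c)
    e2 = (sd * sd + mean * mean) / prev
    var_c = e2 - m_c * m_c
    sd_c = math.sqrt(var_c) if var_c > 0.25 else 0.5
    return m_c, sd_c


def _spread_sensory(total: int, rng) -> list[int]:
    """Random composition of ``total`` (<= 35) into seven 0-5 items."""
    alloc = np.zeros(7, dtype=int)
    for _ in range(min(total, 35)):
        room = np.flatnonzero(alloc < 5)
        alloc[room[rng.integers(room.size)]] += 1
    return [int(v) for v in alloc]


def _choice_with_none(rng, n, options, probs):
    """Categorical draw where leftover probability mass means None."""
    rest = max(0.0, 1.0 - sum(probs))
    idx = rng.choice(len(options) + 1, size=n, p=list(probs) + [rest])
    return [options[i] if i < len(options) else None for i in idx]


def _generate_group(spec: CohortSpec, group: str, n: int, rng,
                    id_prefix: str) -> list[PatientRecord]:
    if n == 0:
        return []
    prev_map = spec.item_prevalence[group]
    items = [it for it in BINARY_ITEMS if it in prev_map]
    p = np.array([prev_map[it] for it in items])

    rho = spec.copula_rho
    w = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(items)))
    z = math.sqrt(rho) * w[:, None] + math.sqrt(1 - rho) * eps
    flags = ndtr(z) < p  # shape (n, K); marginals honored exactly
    flag = {it: flags[:, j] for j, it in enumerate(items)}

    # zero-inflated NRS scales
    nrs: dict[str, np.ndarray] = {}
    moments = spec.nrs_moments.get(group, {})
    for item, presence in _NRS_PRESENCE.items():
        values = np.zeros(n, dtype=int)
        if item in moments and presence in flag:
            mean, sd = moments[item]
            pos = flag[presence]
            m_c, sd_c = _conditional_moments(mean, sd, prev_map[presence], item)
            values[pos] = _trunc_normal_int(rng, int(pos.sum()), m_c, sd_c, 1, 10)
        nrs[item] = values

    # dysmenorrhea honors the printed severity split (NRS > 3)
    dys_nrs = np.zeros(n, dtype=int)
    if "dysmenorrhea_nrs" in moments:
        mean, sd = moments["dysmenorrhea_nrs"]
        dys = flag["dysmenorrhea"]
        p_dys = prev_map["dysmenorrhea"]
        p_gt3 = spec.dysmenorrhea_gt3_given_present.get(group, 0.8)
        m_low = 2.0
        if p_dys > 0 and p_gt3 > 0:
            m_hi = (mean / p_dys - (1 - p_gt3) * m_low) / p_gt3
            m_hi = min(max(m_hi, 4.0), 10.0)
        else:
            m_hi = 6.0
        severe = dys & (rng.random(n) < p_gt3)
        mild = dys & ~severe
        dys_nrs[severe] = _trunc_normal_int(rng, int(severe.sum()), m_hi, 1.6, 4, 10)
        dys_nrs[mild] = _trunc_normal_int(rng, int(mild.sum()), m_low, 1.0, 1, 3)
    nrs["dysmenorrhea_nrs"] = dys_nrs

    # menstrual-pain timing, conditional on dysmenorrhea
    timing_freq = spec.menses_timing_given_dysmenorrhea.get(group, {})
    combos = list(timing_freq)
    timing = _choice_with_none(rng, n, combos, [timing_freq[c] for c in combos])

    # pain-course pattern (single choice; leftover mass = none chosen)
    cp_freq = spec.course_pattern_freq.get(group, {})
    patterns = [CoursePattern(k) for k in cp_freq]
    course = _choice_with_none(rng, n, patterns, list(cp_freq.values()))

    # PainDETECT final score, band-first
    band_split = spec.paindetect_band_given_ge4.get(group, {})
    band_names = list(band_split) or ["4_12"]
    band_probs = [band_split.get(b, 1.0) for b in band_names]
    band_probs = [q / sum(band_probs) for q in band_probs]
    ge4 = flag.get("paindetect_ge4", np.zeros(n, bool))
    band_draw = rng.choice(len(band_names), size=n, p=band_probs)
    params = _PD_BAND_PARAMS[group]
    finals = np.zeros(n, dtype=int)
    for i in range(n):
        key = band_names[band_draw[i]] if ge4[i] else "LE3"
        lo, hi, m, s = params[key]
        finals[i] = _trunc_normal_int(rng, 1, m, s, lo, hi)[0]

    # demographics and contraceptive
    demo = spec.demographics.get(group, {})
    demo_vals = {}
    clips = {"age_yrs": (15.0, 55.0), "bmi": (15.0, 50.0),
             "age_menarche_yrs": (8.0, 18.0)}
    for fname, (m, s) in demo.items():
        lo, hi = clips.get(fname, (0.0, 1e9))
        demo_vals[fname] = np.round(np.clip(rng.normal(m, s, n), lo, hi), 1)
    contra_freq = spec.contraceptive_freq.get(group, {})
    contra_opts = [Contraceptive(k) for k in contra_freq]
    contra = _choice_with_none(rng, n, contra_opts, list(contra_freq.values()))

    records = []
    rad = flag.get("radiating_pain", np.zeros(n, bool))
    for i in range(n):
        rec = PatientRecord(patient_id=f"{id_prefix}{i + 1:05d}",
                            label=Label(group))
        for fname, arr in demo_vals.items():
            setattr(rec, fname, float(arr[i]))
        rec.contraceptive = contra[i]
        for it in items:
            if it in ("pain_now_pos", "strongest_4wks_pos",
                      "average_4wks_pos", "paindetect_ge4"):
                continue
            set_item_value(rec, it, bool(flag[it][i]))
        for item in ("dysmenorrhea_nrs", "cpp_nrs", "dysuria_nrs",
                     "dyschezia_nrs", "dyspareunia_nrs", "pain_now_nrs",
                     "strongest_4wks_nrs", "average_4wks_nrs"):
            set_item_value(rec, item, int(nrs[item][i]))
        if timing[i] is None:
            if not flag["dysmenorrhea"][i]:
                rec.pain_before_menses = False
                rec.pain_during_menses = False
                rec.pain_after_menses = False
            # dysmenorrhea present but no timing given -> left missing
        else:
            b, d, a = _TIMING_BOOLS[timing[i]]
            if flag["dysmenorrhea"][i]:
                rec.pain_before_menses, rec.pain_during_menses, \
                    rec.pain_after_menses = b, d, a
            else:
                rec.pain_before_menses = False
                rec.pain_during_menses = False
                rec.pain_after_menses = False
        rec.course_pattern = course[i]
        adj = _PATTERN_ADJ[course[i]] if course[i] is not None else 0
        target = int(finals[i]) - adj - (2 if rad[i] else 0)
        sensory = _spread_sensory(max(0, min(35, target)), rng)
        for s_item, v in zip(SensoryItem, sensory):
            rec.sensory_items[s_item] = v
        records.append(rec)

    # independent missingness
    for item, rate in spec.missing_rate.items():
        if rate <= 0:
            continue
        mask = rng.random(n) < rate
        for i in np.flatnonzero(mask):
            set_item_value(records[i], item, None)
    return records


def generate(spec: CohortSpec, seed: Optional[int] = None) -> list[PatientRecord]:
    """Draw a labeled synthetic cohort; reproducible from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cohort = _generate_group(spec, "EMS", spec.n_ems, rng, "EMS-")
    cohort += _generate_group(spec, "NO_EMS", spec.n_no_ems, rng, "CTRL-")
    return cohort


# --- calibration audit ---------------------------------------------------

@dataclass(frozen=True)
class MarginalEstimate:
    fraction: float
    se: float
    n_obs: int


def _indicator(record: PatientRecord, item: str) -> Optional[bool]:
    if item == "pain_now_pos":
        v = record.pain_now_nrs
        return None if v is None else v > 0
    if item == "strongest_4wks_pos":
        v = record.strongest_4wks_nrs
        return None if v is None else v > 0
    if item == "average_4wks_pos":
        v = record.average_4wks_nrs
        return None if v is None else v > 0
    if item == "paindetect_ge4":
        try:
            final, _ = paindetect_final_score(record)
        except NotScorableError:
            return None
        return final >= 4
    v = get_item_value(record, item)
    return None if v is None else bool(v)


def recover_marginals(cohort: list[PatientRecord],
                      items: tuple[str, ...] = BINARY_ITEMS):
    """Observed per-group item fractions with binomial standard errors.

    Missing answers are excluded from the denominator.  Empty cohort
    yields an empty map.
    """
    out: dict[str, dict[str, MarginalEstimate]] = {}
    for group in GROUPS:
        members = [r for r in cohort if r.label is Label(group)]
        if not members:
            continue
        out[group] = {}
        for item in items:
            vals = [_indicator(r, item) for r in members]
            obs = [v for v in vals if v is not None]
            if not obs:
                continue
            f = sum(obs) / len(obs)
            se = math.sqrt(f * (1 - f) / len(obs))
            out[group][item] = MarginalEstimate(f, se, len(obs))
    return out


def diff_report(marginals, spec: CohortSpec):
    """Tabular comparison of recovered marginals against a spec."""
    import pandas as pd

    rows = []
    for group, ests in marginals.items():
        for item, est in ests.items():
            expected = spec.item_prevalence.get(group, {}).get(item)
            if expected is None:
                continue
            z = ((est.fraction - expected) / est.se) if est.se > 0 else 0.0
            rows.append({"group": group, "item": item, "expected": expected,
                         "observed": est.fraction, "se": est.se,
                         "n_obs": est.n_obs, "z": z})
    return pd.DataFrame(rows)
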