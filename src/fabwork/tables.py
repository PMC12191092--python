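"""Default calibration constants for the synthetic SED-style cohort.

The values below are the published summary statistics of the Supported
Employment Demonstration Public Use File (SED-PUF): per-year means and
standard deviations of the seven WD-FAB functioning scales and their
changes from baseline, presence rates of the Community Mobility scores,
per-year steady-work rates, and per-year moments of the medical /
health-care-utilization variables.  They parameterize
:class:`fabwork.cohort.CohortConfig` defaults; every entry is
config-overridable.
"""

from __future__ import annotations

N_PARTICIPANTS = 2944
N_YEARS = 4  # baseline + 3 follow-up years

#: steady-work rate per post-baseline study year (years 1, 2, 3)
STEADY_WORK_RATE_BY_YEAR = (0.155, 0.192, 0.173)
#: pooled post-baseline steady-work rate
STEADY_WORK_RATE_OVERALL = 0.173

#: WD-FAB scales carried as scores (Community Mobility is presence-only).
#: Each entry: baseline (mean, sd) and change-from-baseline (mean, sd)
#: for years 1..3, on the WD-FAB T-score-like metric.
FAB_SCALES: dict[str, dict] = {
    "fine_motor": {
        "label": "Fine Motor Function",
        "baseline": (43.0, 5.6),
        "change": [(-0.5, 5.6), (0.4, 5.5), (-0.0, 5.2)],
        "mdc90": 8.2,
    },
    "upper_body": {
        "label": "Upper Body Function",
        "baseline": (39.4, 5.8),
        "change": [(-0.2, 4.8), (0.3, 5.0), (0.2, 4.7)],
        "mdc90": 4.6,
    },
    "comm_cog": {
        "label": "Communication & Cognition",
        "baseline": (41.8, 6.6),
        "change": [(0.7, 6.7), (0.7, 7.0), (0.5, 7.1)],
        "mdc90": 7.1,
    },
    "basic_mobility": {
        "label": "Basic Mobility",
        "baseline": (40.2, 6.0),
        "change": [(0.3, 4.8), (0.1, 4.9), (0.1, 4.5)],
        "mdc90": 4.7,
    },
    "resilience": {
        "label": "Resilience & Sociability",
        "baseline": (47.6, 9.6),
        "change": [(0.2, 10.1), (1.2, 10.1), (0.5, 10.3)],
        "mdc90": 8.2,
    },
    "interpersonal": {
        "label": "Interpersonal Interactions",
        "baseline": (44.4, 8.8),
        "change": [(2.1, 10.6), (1.3, 12.2), (1.0, 12.1)],
        "mdc90": 8.6,
    },
    "mood_emotions": {
        "label": "Mood & Emotions",
        "baseline": (38.6, 12.0),
        "change": [(4.0, 12.9), (1.3, 13.5), (1.0, 12.7)],
        "mdc90": 10.6,
    },
}

FAB_SCALE_NAMES = tuple(FAB_SCALES)

#: Community Mobility presence-flag rates per study year (years 0..3).
#: The pooled complements give the ~60% (Drive) and ~80% (Ride / public
#: transit) marginal missingness of those scores.
PRESENCE_RATES_BY_YEAR: dict[str, tuple[float, ...]] = {
    "has_drive": (0.51, 0.36, 0.38, 0.36),
    "has_ride": (0.31, 0.22, 0.17, 0.13),
    "has_wheelchair": (0.04, 0.03, 0.03, 0.03),
}

PRESENCE_FLAG_NAMES = tuple(PRESENCE_RATES_BY_YEAR)

#: Medical / utilization variables: per-year (mean, sd) for years 0..3.
#: kind "score" -> >=0 truncated normal; kind "count" -> negative binomial
#: (Poisson fallback when under-dispersed).
MEDICAL_VARIABLES: dict[str, dict] = {
    "csi": {
        "label": "Colorado Symptom Index",
        "kind": "score",
        "by_year": [(25.2, 11.2), (22.2, 12.7), (20.4, 12.7), (19.2, 12.5)],
    },
    "bmi": {
        "label": "Body Mass Index",
        "kind": "score",
        "by_year": [(31.1, 8.9), (31.5, 8.6), (31.6, 8.5), (32.2, 8.8)],
    },
    "inpatient_admissions": {
        "label": "Inpatient hospital admissions",
        "kind": "count",
        "by_year": [(0.5, 0.9), (0.3, 0.8), (0.2, 0.8), (0.2, 0.6)],
    },
    "dast": {
        "label": "Drug Abuse Screening Test",
        "kind": "score",
        "by_year": [(1.1, 2.0), (0.7, 1.6), (0.6, 1.5), (0.6, 1.6)],
    },
    "audit": {
        "label": "Alcohol Use Disorders Identification Test",
        "kind": "score",
        "by_year": [(3.5, 5.7), (2.7, 5.8), (2.5, 4.6), (2.5, 4.6)],
    },
    "total_er_visits": {
        "label": "Total ER visits",
        "kind": "count",
        "by_year": [(1.2, 1.9), (0.88, 1.6), (0.71, 1.5), (0.59, 1.3)],
    },
    "er_physical_visits": {
        "label": "ER visits, physical health",
        "kind": "count",
        "by_year": [(0.98, 1.6), (0.73, 1.4), (0.56, 1.5), (0.41, 1.1)],
    },
    "er_mental_visits": {
        "label": "ER visits, mental health",
        "kind": "count",
        "by_year": [(0.21, 0.82), (0.12, 0.49), (0.07, 0.44), (0.05, 0.33)],
    },
    "er_drug_visits": {
        "label": "ER visits, drug-related",
        "kind": "count",
        "by_year": [(0.03, 0.26), (0.01, 0.12), (0.005, 0.07), (0.003, 0.06)],
    },
    "er_alcohol_visits": {
        "label": "ER visits, alcohol-related",
        "kind": "count",
        "by_year": [(0.020, 0.204), (0.012, 0.140), (0.008, 0.126), (0.004, 0.071)],
    },
    "total_inpatient_nights": {
        "label": "Total inpatient nights",
        "kind": "count",
        "by_year": [(1.9, 6.6), (1.0, 4.2), (1.0, 4.7), (0.9, 3.8)],
    },
    "admitted_after_alcohol_er": {
        "label": "Admitted after alcohol ER visit",
        "kind": "count",
        "by_year": [(0.012, 0.141), (0.004, 0.071), (0.007, 0.110), (0.003, 0.052)],
    },
    "admitted_after_drug_er": {
        "label": "Admitted after drug ER visit",
        "kind": "count",
        "by_year": [(0.014, 0.50), (0.006, 0.09), (0.004, 0.07), (0.002, 0.04)],
    },
    "admitted_after_mental_er": {
        "label": "Admitted after mental health ER visit",
        "kind": "count",
        "by_year": [(0.12, 0.50), (0.068, 0.36), (0.038, 0.28), (0.025, 0.24)],
    },
    "admitted_after_physical_er": {
        "label": "Admitted after physical health ER visit",
        "kind": "count",
        "by_year": [(0.23, 0.66), (0.16, 0.56), (0.14, 0.56), (0.11, 0.50)],
    },
    "admitted_after_other_er": {
        "label": "Admitted after other ER visit",
        "kind": "count",
        "by_year": [(0.02, 0.16), (0.02, 0.19), (0.02, 0.19), (0.01, 0.13)],
    },
    "er_other_visits": {
        "label": "ER visits for other problems",
        "kind": "count",
        "by_year": [(0.08, 0.94), (0.09, 0.38), (0.05, 0.39), (0.05, 0.28)],
    },
    "hospital_stays_drug": {
        "label": "Hospital stays, drug problems",
        "kind": "count",
        "by_year": [(0.005, 0.08), (0.003, 0.07), (0.002, 0.04), (0.002, 0.05)],
    },
    "hospital_stays_mental": {
        "label": "Hospital stays, mental health",
        "kind": "count",
        "by_year": [(0.04, 0.25), (0.03, 0.19), (0.02, 0.14), (0.01, 0.12)],
    },
    "hospital_stays_physical": {
        "label": "Hospital stays, physical health",
        "kind": "count",
        "by_year": [(0.09, 0.38), (0.06, 0.28), (0.05, 0.27), (0.04, 0.21)],
    },
    "hospital_stays_other": {
        "label": "Hospital stays, other problems",
        "kind": "count",
        "by_year": [(0.02, 0.12), (0.01, 0.12), (0.01, 0.11), (0.01, 0.10)],
    },
    "outpatient_mental_visits": {
        "label": "Routine outpatient mental health visits",
        "kind": "count",
        "by_year": [(2.2, 4.6), (5.5, 9.7), (4.0, 8.5), (3.3, 7.8)],
    },
    "self_help_visits": {
        "label": "Self-help group visits",
        "kind": "count",
        "by_year": [(0.66, 2.9), (1.3, 5.5), (0.93, 4.8), (0.66, 4.5)],
    },
    "public_clinic_visits": {
        "label": "Public clinic visits",
        "kind": "count",
        "by_year": [(0.21, 1.1), (0.48, 2.1), (0.29, 1.2), (0.26, 1.3)],
    },
    "private_physician_visits": {
        "label": "Private outpatient physician visits",
        "kind": "count",
        "by_year": [(0.75, 1.8), (1.8, 3.2), (1.4, 2.7), (1.2, 2.7)],
    },
    "outpatient_psych_visits": {
        "label": "Outpatient psychiatric visits",
        "kind": "count",
        "by_year": [(0.55, 1.5), (1.4, 2.7), (1.0, 2.1), (0.87, 2.1)],
    },
    "outpatient_other_mh_visits": {
        "label": "Outpatient other mental health visits",
        "kind": "count",
        "by_year": [(0.82, 2.1), (2.3, 4.8), (1.8, 4.6), (1.6, 4.2)],
    },
    "outpatient_other_prof_visits": {
        "label": "Outpatient other professional visits",
        "kind": "count",
        "by_year": [(0.18, 1.2), (0.43, 1.7), (0.21, 0.92), (0.14, 0.71)],
    },
    "other_outpatient_visits": {
        "label": "Other outpatient visits",
        "kind": "count",
        "by_year": [(0.13, 0.92), (0.30, 1.4), (0.24, 1.6), (0.24, 1.4)],
    },
}

MEDICAL_VARIABLE_NAMES = tuple(MEDICAL_VARIABLES)

#: Demographic marginals.  The SED recruited applicants aged 18-49; the
#: categorical splits are plausible defaults (no frequency table is
#: published) and are config-overridable.
DEMOGRAPHIC_DEFAULTS: dict = {
    "age_range": (18.0, 49.0),
    "baseline_working_rate": 0.25,
    "worked_past_2yr_rate": 0.50,
    "education_probs": {
        "less_hs": 0.25,
        "hs": 0.35,
        "some_college": 0.25,
        "bachelor": 0.15,
    },
    "race_probs": {"white": 0.50, "black": 0.35, "other": 0.15},
    "stable_housing_rate": 0.70,
    "vehicle_access_rate": 0.50,
}

#: Study arm assignment probabilities (full / basic / usual service).
ARM_PROBABILITIES = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

#: Participant-level counts of missing functioning measurements cluster at
#: 0, 7, 14 or 21 (all seven scales blank in 0-3 follow-up waves).
MISSING_PATTERNS = (0, 7, 14, 21)
DEFAULT_PATTERN_WEIGHTS = (0.55, 0.20, 0.15, 0.10)

#: Default true effects of the outcome mechanism, on the generator's
#: standardized design scale.  Signs and ordering mirror the reported top
#: predictors of steady work: baseline working status dominates, function
#: changes (Communication & Cognition, Upper Body, Resilience, Basic
#: Mobility) and Community Mobility Drive presence are positive, ER
#: utilization is negative, BMI mildly positive.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "baseline_working": 0.90,
    "comm_cog_change": 0.45,
    "has_drive": 0.35,
    "upper_body_change": 0.30,
    "race_other": 0.30,
    "edu_bachelor": 0.30,
    "worked_past_2yr": 0.35,
    "arm_full": 0.25,
    "arm_basic": 0.20,
    "upper_body_base": 0.20,
    "resilience_change": 0.25,
    "basic_mobility_change": 0.20,
    "bmi_change": 0.15,
    "bmi_base": 0.15,
    "er_mental_visits_base": -0.20,
    "total_er_visits_change": -0.10,
    "dast_change": -0.10,
    "total_inpatient_nights_change": -0.10,
}
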