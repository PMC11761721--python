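"""Published summary tables from an Italian regional inpatient PREM observatory (2022 discharges).

The respondent-level data behind these tables are confidential, but the published
aggregates — respondent counts per departmental area, socio-demographic counts per
stratum, and the per-area proportional-odds regression estimates — are reproduced
here.  They serve two purposes:

* the regression estimates parameterize :func:`premopt.synthetic_data.default_scenario`,
  so simulated surveys share the satisfaction structure observed in the field;
* the count tables are inputs for the descriptive-statistics checks (percentages,
  chi-square tests) that validate :mod:`premopt.survey_data`.

Coefficients are on the cumulative-logit scale: positive values mean a better
experience on that item raises the odds of a higher overall-satisfaction category.
Two cells in the medical column of the regression table are typographically
ambiguous in the published source (the discharge-therapy standard error and the
third cutpoint's standard error); the values stored here are the consistent
readings (Wald z reproduces the printed p-value).
"""

from __future__ import annotations

# Responding patients per departmental area of discharge (2022).
RESPONDENTS_BY_AREA: dict[str, int] = {
    "surgical": 14_975,
    "medical": 9_187,
    "traumatological_orthopaedic": 2_867,
    "emergency": 109,
    "other": 1_596,
}

#: The two areas retained for analysis (largest response volumes).
ANALYSIS_AREAS = ("surgical", "medical")

# Socio-demographic counts per stratum: variable -> category -> (surgical, medical).
DEMOGRAPHIC_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {
        "female": (8_127, 2_975),
        "male": (4_542, 3_736),
    },
    "age_group": {
        "<18": (34, 512),
        "18-44": (4_073, 527),
        "45-64": (7_336, 3_168),
        ">=65": (3_527, 4_980),
    },
    "education": {
        "low": (4_372, 3_897),
        "medium": (5_009, 1_933),
        "high": (3_285, 879),
    },
    "perceived_health": {
        "bad": (241, 769),
        "sufficient": (2_964, 2_510),
        "good": (5_101, 2_195),
        "very_good": (3_422, 959),
        "excellent": (942, 269),
    },
    "chronic": {
        "no": (7_866, 1_943),
        "yes": (4_143, 4_251),
        "unknown": (660, 514),
    },
    "admission": {
        "urgent": (672, 2_772),
        "planned": (13_374, 5_241),
    },
}

# Mean length of stay (days) and overall satisfaction (mean, SEM) per stratum.
MEAN_LENGTH_OF_STAY = {"surgical": 3.67, "medical": 8.15}
SATISFACTION_SUMMARY = {"surgical": (4.6, 0.0059), "medical": (4.5, 0.0097)}

# Experience items in questionnaire order (the regression's predictor order).
EXPERIENCE_ITEMS: tuple[str, ...] = (
    "kind_reception",
    "fear_anxiety_doctors",
    "fear_anxiety_nurses",
    "pain_management",
    "talk_in_front_doctors",
    "talk_in_front_nurses",
    "talk_in_front_other_staff",
    "respect_dignity_doctors",
    "respect_dignity_nurses",
    "respect_dignity_other_staff",
    "involvement",
    "clarity_answers_doctors",
    "clarity_answers_nurses",
    "information_caregivers",
    "teamwork",
    "silence",
    "cleaning",
    "discharge_selfcare",
    "discharge_therapy",
)

# Per-area proportional-odds estimates: item -> (b, SE, p); plus cutpoints and fit stats.
REGRESSION_ESTIMATES: dict[str, dict] = {
    "surgical": {
        "coefficients": {
            "kind_reception": (0.2859, 0.059, 0.000),
            "fear_anxiety_doctors": (0.0753, 0.0553, 0.174),
            "fear_anxiety_nurses": (0.3086, 0.060, 0.000),
            "pain_management": (0.5542, 0.065, 0.000),
            "talk_in_front_doctors": (0.0202, 0.0596, 0.735),
            "talk_in_front_nurses": (0.0707, 0.0698, 0.311),
            "talk_in_front_other_staff": (0.0474, 0.0622, 0.446),
            "respect_dignity_doctors": (0.2615, 0.0913, 0.004),
            "respect_dignity_nurses": (0.245, 0.0975, 0.012),
            "respect_dignity_other_staff": (0.1049, 0.0619, 0.090),
            "involvement": (0.1917, 0.0511, 0.000),
            "clarity_answers_doctors": (-0.083, 0.0807, 0.304),
            "clarity_answers_nurses": (0.1717, 0.0787, 0.029),
            "information_caregivers": (0.1662, 0.0382, 0.000),
            "teamwork": (1.698, 0.0742, 0.000),
            "silence": (0.1973, 0.0453, 0.000),
            "cleaning": (-0.5276, 0.0527, 0.000),
            "discharge_selfcare": (0.4815, 0.091, 0.000),
            "discharge_therapy": (0.2377, 0.1041, 0.022),
        },
        "cutpoints": (7.842, 10.83, 14.71, 19.44),
        "cutpoint_se": (0.5219, 0.4998, 0.5563, 0.6269),
        "log_likelihood": -2226.151,
        "n": 5_434,
    },
    "medical": {
        "coefficients": {
            "kind_reception": (0.4153, 0.1047, 0.000),
            "fear_anxiety_doctors": (0.0412, 0.0986, 0.676),
            "fear_anxiety_nurses": (0.0938, 0.0948, 0.322),
            "pain_management": (0.4682, 0.1094, 0.000),
            "talk_in_front_doctors": (0.0632, 0.0985, 0.521),
            "talk_in_front_nurses": (-0.1038, 0.1249, 0.406),
            "talk_in_front_other_staff": (0.1087, 0.1028, 0.290),
            "respect_dignity_doctors": (0.3905, 0.1497, 0.009),
            "respect_dignity_nurses": (0.0351, 0.1628, 0.829),
            "respect_dignity_other_staff": (0.1501, 0.099, 0.131),
            "involvement": (0.1516, 0.0766, 0.048),
            "clarity_answers_doctors": (-0.1613, 0.1355, 0.234),
            "clarity_answers_nurses": (0.1613, 0.1265, 0.202),
            "information_caregivers": (0.1463, 0.0766, 0.056),
            "teamwork": (1.931, 0.1247, 0.000),
            "silence": (0.0856, 0.0775, 0.270),
            "cleaning": (-0.5097, 0.0911, 0.000),
            "discharge_selfcare": (0.4889, 0.159, 0.002),
            "discharge_therapy": (0.4436, 0.1721, 0.010),
        },
        "cutpoints": (5.848, 10.57, 14.88, 18.83),
        "cutpoint_se": (0.817, 0.801, 0.9, 1.008),
        "log_likelihood": -806.513,
        "n": 1_867,
    },
}
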