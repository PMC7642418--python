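"""Published summary statistics from a wrist-device validation study.

These constants are the printed results of a 35-subject clinical validation
of a cuff-less wristwatch BP monitor against a manual sphygmomanometer
(105 paired readings).  They are shipped as *inputs*: worked examples and
consistency checks (e.g. the RMSE decomposition identity, the 2-of-3
hypertension concordance) run against them, exactly as one would check a
published table by recomputation.

Notes on internal consistency, preserved as printed:

* The SBP difference SD is printed as 6.1 mmHg in the study's abstract but
  7.3 mmHg in its results section; only 6.1 is consistent with the printed
  RMSE of 6.5 mmHg through rmse^2 = bias^2 + sd^2.  Both values are kept.
* Recomputing the per-measurement >135/>85 mmHg marks from the printed
  per-subject digits does not exactly reproduce the study's marked counts
  (two borderline cells differ), so the printed per-subject classifications
  ("hypertensive" flags below) are the ground truth for the concordance
  figure, not re-derived marks.
"""
from __future__ import annotations

STUDY_N_SUBJECTS = 35
STUDY_N_PAIRS = 105

# Channel summaries: means/SDs over the 105 paired readings, printed
# difference statistics, accuracy bins and correlation.
STUDY_SUMMARY = {
    "sbp": {
        "manual_mean": 127.2,
        "manual_sd": 20.9,
        "device_mean": 129.4,
        "device_sd": 22.8,
        "mean_diff": 2.2,
        "sd_diff_abstract": 6.1,
        "sd_diff_results": 7.3,
        "rmse": 6.5,
        "pearson_r": 0.964,
        "p_value": 0.472,
        "pct_within_5": 71.4,
        "pct_within_10": 86.7,
        "pct_within_15": 97.1,
    },
    "dbp": {
        "manual_mean": 69.7,
        "manual_sd": 12.3,
        "device_mean": 69.5,
        "device_sd": 11.5,
        "mean_diff": -0.2,
        "sd_diff_abstract": 4.2,
        "sd_diff_results": 4.2,
        "rmse": 4.2,
        "pearson_r": 0.939,
        "p_value": 0.880,
        "pct_within_5": 83.8,
        "pct_within_10": 98.1,
        "pct_within_15": 99.0,
    },
}

# Study cohort descriptors (used as synthetic-cohort defaults elsewhere).
STUDY_COHORT = {
    "age_mean": 57.1,
    "age_sd": 17.9,
    "sbp_mean": 129.6,
    "sbp_sd": 23.6,
    "dbp_mean": 69.5,
    "dbp_sd": 12.9,
    "height_mean": 162.2,
    "height_sd": 8.6,
    "weight_mean": 67.5,
    "weight_sd": 12.3,
}

# Per-subject hypertension table: the subjects the study listed (those with
# at least one reading near or above the 135/85 mmHg thresholds).  Each row
# holds the three device/manual SBP and DBP readings and the printed
# hypertension classifications.  Subjects not listed were concordant
# non-hypertensive.
HYPERTENSION_TABLE = [
    {
        "device_sbp": (130, 127, 133), "manual_sbp": (138, 138, 139),
        "device_dbp": (74, 70, 78), "manual_dbp": (72, 70, 79),
        "device_hypertensive": False, "manual_hypertensive": True,
    },
    {
        "device_sbp": (146, 133, 132), "manual_sbp": (123, 122, 120),
        "device_dbp": (79, 73, 72), "manual_dbp": (68, 68, 70),
        "device_hypertensive": False, "manual_hypertensive": False,
    },
    {
        "device_sbp": (136, 137, 134), "manual_sbp": (135, 131, 129),
        "device_dbp": (102, 103, 100), "manual_dbp": (106, 104, 103),
        "device_hypertensive": True, "manual_hypertensive": True,
    },
    {
        "device_sbp": (153, 146, 147), "manual_sbp": (147, 138, 134),
        "device_dbp": (57, 51, 58), "manual_dbp": (52, 50, 50),
        "device_hypertensive": True, "manual_hypertensive": True,
    },
    {
        "device_sbp": (141, 139, 136), "manual_sbp": (144, 135, 133),
        "device_dbp": (82, 79, 80), "manual_dbp": (82, 82, 79),
        "device_hypertensive": True, "manual_hypertensive": True,
    },
    {
        "device_sbp": (141, 138, 130), "manual_sbp": (136, 133, 128),
        "device_dbp": (93, 92, 92), "manual_dbp": (93, 92, 91),
        "device_hypertensive": True, "manual_hypertensive": True,
    },
    {
        "device_sbp": (155, 160, 146), "manual_sbp": (153, 160, 153),
        "device_dbp": (81, 87, 72), "manual_dbp": (88, 89, 90),
        "device_hypertensive": True, "manual_hypertensive": True,
    },
]


def printed_classifications() -> tuple[dict[str, bool], dict[str, bool]]:
    """The printed per-subject device/manual hypertension flags, keyed by a
    synthetic row id, for feeding :func:`wristbp.validation.diagnostic_concordance`."""
    dev = {f"row{i}": r["device_hypertensive"] for i, r in enumerate(HYPERTENSION_TABLE)}
    man = {f"row{i}": r["manual_hypertensive"] for i, r in enumerate(HYPERTENSION_TABLE)}
    return dev, man
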