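"""Published ALSPAC calibration constants for the synthetic-cohort generator.

The generator defaults are anchored to estimates published for the Avon
Longitudinal Study of Parents and Children (ALSPAC): the 4x4 joint
distribution of soiling and constipation trajectory classes, qualitative
per-wave symptom-probability profiles for the four classes of each process,
and covariate-class odds ratios for the early-childhood risk factors.

Class order is fixed throughout the package:

* soiling:       normative, delayed, relapse, persistent
* constipation:  normative, early, late, persistent
* composite:     normative, constipation_alone, soiling_alone,
                 constipation_with_soiling
"""

from __future__ import annotations

import numpy as np

SOILING_CLASS_NAMES = ["normative", "delayed", "relapse", "persistent"]
CONSTIPATION_CLASS_NAMES = ["normative", "early", "late", "persistent"]
COMPOSITE_CLASS_NAMES = [
    "normative",
    "constipation_alone",
    "soiling_alone",
    "constipation_with_soiling",
]

SOILING_WAVE_LABELS = ["4y6m", "5y6m", "6y6m", "7y6m", "9y6m"]
CONSTIPATION_WAVE_LABELS = ["4y9m", "5y9m", "6y9m", "7y7m", "8y7m", "10y8m"]

#: Joint class distribution (percent of children), rows = soiling classes,
#: columns = constipation classes, as estimated on the ALSPAC analytic
#: sample (n=8435).  The one censored cell published as "<0.1" is carried
#: as 0; the printed cells already sum to 100 within rounding.
REPORTED_JOINT_PERCENT = np.array(
    [
        # constipation:  normative  early  late  persistent
        [74.5, 5.5, 5.8, 1.9],  # soiling normative
        [4.3, 1.1, 0.6, 0.4],  # soiling delayed
        [2.2, 0.0, 0.9, 0.5],  # soiling relapse  (early cell censored "<0.1")
        [1.0, 0.5, 0.3, 0.5],  # soiling persistent
    ]
)

#: Composite-group shares implied by collapsing the joint table (percent).
REPORTED_COMPOSITE_PERCENT = np.array([74.5, 13.2, 7.5, 4.8])

#: Unconditional 4-class split for constipation alone (percent), estimated
#: on the n=8979 sample with >=3 non-missing constipation waves.
REPORTED_CONSTIPATION_SPLIT_PERCENT = np.array([82.0, 7.0, 8.0, 3.0])

#: Reported prevalence of male sex in the analytic sample.
MALE_PREVALENCE = 0.48

#: Published univariable odds ratio for male sex on soiling-alone
#: membership (reference: female, normative class).
MALE_SOILING_ALONE_OR = 1.78


def default_joint_weights() -> np.ndarray:
    """Joint class weights (probabilities summing to one)."""
    w = REPORTED_JOINT_PERCENT / 100.0
    return w / w.sum()


def well_separated_soiling_profiles() -> np.ndarray:
    """Per-wave soiling probabilities for the four soiling classes.

    Shapes follow the published trajectory plot: a normative class with
    near-zero probability throughout, delayed attainment (high early,
    resolving), relapse (low early, rising), and persistent soiling.
    Calibrated so the implied per-wave marginal prevalence is close to the
    published 5-7% range.
    """
    return np.array(
        [
            [0.02, 0.02, 0.02, 0.02, 0.02],  # normative
            [0.75, 0.55, 0.30, 0.15, 0.05],  # delayed attainment
            [0.10, 0.15, 0.55, 0.70, 0.65],  # relapse
            [0.80, 0.80, 0.80, 0.80, 0.75],  # persistent
        ]
    )


def well_separated_constipation_profiles() -> np.ndarray:
    """Per-wave constipation probabilities for the four constipation classes.

    Normative stays at or below 0.05 throughout; early occurrence is high
    until about age 6 then resolves; late occurrence emerges after age 6;
    persistent stays at or above 0.7.
    """
    return np.array(
        [
            [0.05, 0.04, 0.04, 0.03, 0.03, 0.03],  # normative
            [0.85, 0.70, 0.45, 0.15, 0.08, 0.05],  # early occurrence
            [0.05, 0.08, 0.20, 0.65, 0.80, 0.85],  # late occurrence
            [0.80, 0.78, 0.75, 0.75, 0.75, 0.72],  # persistent
        ]
    )
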