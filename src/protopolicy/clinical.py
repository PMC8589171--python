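"""Schema of the restricted clinical depression cohort (interface only).

The clinical benchmark pools five antidepressant trials into one cohort of
categorical baseline questionnaire features, a treatment label out of six
arms, and a binary remission outcome.  The underlying patient-level data
is access-restricted and is **not** shipped or downloaded here; this
module only documents the expected CSV layout and validates a file a user
supplies themselves, returning a :class:`~protopolicy.synthetic.Cohort`
(without counterfactuals, so only RR/AUC-style metrics apply).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort

#: the 26 baseline features (categorical questionnaire and demographic items)
CLINICAL_FEATURES = [
    "hamd_appetite",
    "hamd_family_friends_impact",
    "hamd_early_morning_insomnia",
    "hamd_energy_fatigability",
    "hamd_pleasure_enjoyment",
    "hamd_mood_reactivity",
    "hamd_suicidal_ideation",
    "hamd_sympathetic_arousal",
    "hamd_future_outlook",
    "hamd_fatigue",
    "has_private_insurance",
    "qids_total_score",
    "n_relatives_in_household",
    "qids_appetite_increase",
    "qids_concentration",
    "qids_energy_fatigability",
    "qids_involvement",
    "qids_mood_sadness",
    "qids_mid_nocturnal_insomnia",
    "qids_suicidal_ideation",
    "climbs_several_flights",
    "currently_employed",
    "education_16plus_years",
    "n_friends_in_household",
    "one_to_four_relatives_in_household",
    "one_to_five_persons_in_household",
]

#: the six antidepressant treatment arms
CLINICAL_TREATMENTS = [
    "escitalopram",
    "citalopram",
    "venlafaxine",
    "sertraline",
    "bupropion+escitalopram",
    "mirtazapine+venlafaxine",
]


def load_clinical_cohort(path: str | Path) -> Cohort:
    """Load and validate a user-supplied clinical cohort CSV.

    Expected columns: the 26 :data:`CLINICAL_FEATURES`, ``treatment`` (one
    of :data:`CLINICAL_TREATMENTS`) and ``outcome`` (0/1).
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_FEATURES + ["treatment", "outcome"] if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV is missing columns: {missing}")
    bad = set(df["treatment"].unique()) - set(CLINICAL_TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment arms: {sorted(bad)}")
    if not df["outcome"].isin([0, 1]).all():
        raise ValueError("outcome column must be binary 0/1")
    arm_index = {name: i for i, name in enumerate(CLINICAL_TREATMENTS)}
    return Cohort(
        X=df[CLINICAL_FEATURES].to_numpy(dtype=float),
        t=df["treatment"].map(arm_index).to_numpy(dtype=int),
        y=df["outcome"].to_numpy(dtype=int),
    )
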