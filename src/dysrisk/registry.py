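"""Canonical questionnaire item registry and reference-cohort summary counts.

The screening instrument asks 15 yes/no questions about exposures known to
deplete gut-microbiota richness (birth mode, infant feeding, diet, alcohol,
physical activity, stress, smoking, medication, bowel habit, surgery).
Antibiotic and NSAID use are held as two separate items.

``REFERENCE_COUNTS`` stores, for each item, the number of "yes" answers in a
published 219-subject cross-sectional cohort (167 chronic-disease patients,
52 healthy controls).  These counts seed the simulator's default per-group
prevalences and the two-group contingency comparisons; they are inputs, not
results.
"""

from __future__ import annotations

from typing import Mapping

#: Ordered canonical item identifiers (the strict-mode registry).
ITEM_IDS: tuple[str, ...] = (
    "cesarean_birth",
    "breastfed_lt6mo",
    "low_produce_intake",
    "daily_refined_sugar",
    "frequent_ultraprocessed",
    "alcohol_gt4_weekly",
    "low_physical_activity",
    "high_stress",
    "smoking",
    "recent_antibiotics",
    "recent_nsaids",
    "polypharmacy",
    "ongoing_treatment",
    "altered_bowel_habit",
    "recent_major_surgery",
)

#: Human-readable wording of each item ("yes" = exposure to a harmful factor).
ITEM_LABELS: Mapping[str, str] = {
    "cesarean_birth": "Born by cesarean section",
    "breastfed_lt6mo": "Breastfed for less than 6 months",
    "low_produce_intake": (
        "Less than 5 daily servings of fruits, vegetables, legumes and/or whole grains"
    ),
    "daily_refined_sugar": (
        "Refined sugar or artificial sweeteners more than once a day"
    ),
    "frequent_ultraprocessed": "Ultraprocessed foods more than 3 times a week",
    "alcohol_gt4_weekly": "More than 4 doses of alcoholic beverages per week",
    "low_physical_activity": "Less than 150 min of physical activity per week",
    "high_stress": "High self-reported psychological stress",
    "smoking": "Smoking",
    "recent_antibiotics": "Use of antibiotics in the last 3 months",
    "recent_nsaids": "Use of nonsteroidal anti-inflammatory drugs in the last 3 months",
    "polypharmacy": "Continuous use of more than 3 medications",
    "ongoing_treatment": "Current treatment or monitoring for any health condition",
    "altered_bowel_habit": (
        "Three or more liquid bowel movements per day or difficult bowel movements"
    ),
    "recent_major_surgery": (
        "Medium/major surgery in the last 60 days or bariatric surgery ever"
    ),
}

#: Reference-cohort group sizes.
N_CD: int = 167
N_HC: int = 52

#: "Yes" counts per item in the reference cohort: item -> (CD yes, HC yes).
REFERENCE_COUNTS: Mapping[str, tuple[int, int]] = {
    "cesarean_birth": (30, 25),
    "breastfed_lt6mo": (104, 32),
    "low_produce_intake": (155, 44),
    "daily_refined_sugar": (156, 40),
    "frequent_ultraprocessed": (75, 19),
    "alcohol_gt4_weekly": (2, 3),
    "low_physical_activity": (135, 30),
    "high_stress": (56, 11),
    "smoking": (16, 1),
    "recent_antibiotics": (45, 5),
    "recent_nsaids": (38, 7),
    "polypharmacy": (74, 0),
    "ongoing_treatment": (167, 52),
    "altered_bowel_habit": (44, 5),
    "recent_major_surgery": (2, 1),
}


def reference_prevalences() -> dict[str, tuple[float, float]]:
    """Per-item (CD, HC) yes-probabilities from the reference counts."""
    return {
        item: (cd / N_CD, hc / N_HC) for item, (cd, hc) in REFERENCE_COUNTS.items()
    }


def contingency_2x2(item: str) -> tuple[int, int, int, int]:
    """Item's 2x2 table (CD yes, CD no, HC yes, HC no) from reference counts."""
    cd_yes, hc_yes = REFERENCE_COUNTS[item]
    return cd_yes, N_CD - cd_yes, hc_yes, N_HC - hc_yes
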