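"""PHQ-9 severity semantics, improvement labels, and treatment episodes.

The PHQ-9 total score (nine items, 0-3 points each, range 0-27) maps to
five severity levels; *improvement* after treatment is a decrease of at
least five points between the baseline score at treatment start and the
follow-up score ~90 days later.  Note a 5-point drop does not always cross
a severity-level boundary (27 -> 22 stays severe); the 5-point rule is
primary here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

PHQ9_MIN = 0
PHQ9_MAX = 27
IMPROVEMENT_POINTS = 5

#: (low, high, level) bins partitioning 0..27.
SEVERITY_BINS = [
    (0, 4, "minimal"),
    (5, 9, "mild"),
    (10, 14, "moderate"),
    (15, 19, "moderately_severe"),
    (20, 27, "severe"),
]


class SeverityLevel(enum.IntEnum):
    """Ordered PHQ-9 severity levels."""

    minimal = 0
    mild = 1
    moderate = 2
    moderately_severe = 3
    severe = 4


_EDGES = np.array([b[0] for b in SEVERITY_BINS] + [PHQ9_MAX + 1])


def phq9_severity(score: int) -> SeverityLevel:
    """Map a PHQ-9 total score to its severity level."""
    if not (PHQ9_MIN <= score <= PHQ9_MAX):
        raise ValueError(f"PHQ-9 score {score} outside [{PHQ9_MIN}, {PHQ9_MAX}]")
    idx = int(np.searchsorted(_EDGES, score, side="right")) - 1
    return SeverityLevel(idx)


def phq9_severity_array(scores) -> np.ndarray:
    """Vectorised severity levels (integer codes) for an array of scores."""
    scores = np.asarray(scores)
    if ((scores < PHQ9_MIN) | (scores > PHQ9_MAX)).any():
        raise ValueError("PHQ-9 scores outside [0, 27]")
    return np.searchsorted(_EDGES, scores, side="right") - 1


def label_improvement(baseline: float, followup: float) -> bool:
    """True when the score dropped by at least five points."""
    for score in (baseline, followup):
        if not (PHQ9_MIN <= score <= PHQ9_MAX):
            raise ValueError(f"PHQ-9 score {score} outside [{PHQ9_MIN}, {PHQ9_MAX}]")
    return baseline - followup >= IMPROVEMENT_POINTS


MEDICATION = "medication"
PSYCHOTHERAPY = "psychotherapy"
BOTH = "both"


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    modality: str  # medication | psychotherapy | both
    start_day: int
    baseline_phq9: int
    followup_phq9: int

    @property
    def improved(self) -> bool:
        return label_improvement(self.baseline_phq9, self.followup_phq9)

    @property
    def change(self) -> int:
        """Baseline minus follow-up: positive = symptoms decreased."""
        return self.baseline_phq9 - self.followup_phq9


def first_treatment_episodes(treatments: pd.DataFrame) -> pd.DataFrame:
    """Reduce a treatments table to one first-treatment episode per patient.

    Input columns: patient_id, start_day, modality, baseline_phq9,
    followup_phq9.  The earliest start wins; two modalities starting the
    same day collapse to modality ``both`` (flagged for exclusion from the
    single-modality response models).  Baseline and follow-up scores come
    from the first treatment only.

    Output adds ``improved`` (>= 5-point drop) and ``change``.
    """
    frame = treatments.sort_values(["patient_id", "start_day"], kind="stable")
    first_day = frame.groupby("patient_id", observed=True)["start_day"].transform("min")
    firsts = frame[frame["start_day"] == first_day]
    n_modalities = firsts.groupby("patient_id", observed=True)["modality"].nunique()
    episodes = firsts.drop_duplicates("patient_id").copy().reset_index(drop=True)
    tied = episodes["patient_id"].map(n_modalities).to_numpy() > 1
    episodes["modality"] = np.where(tied, BOTH, episodes["modality"])
    episodes = episodes[
        ["patient_id", "start_day", "modality", "baseline_phq9", "followup_phq9"]
    ]
    episodes["change"] = episodes["baseline_phq9"] - episodes["followup_phq9"]
    episodes["improved"] = episodes["change"] >= IMPROVEMENT_POINTS
    return episodes


def improvement_summary(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-modality counts and improvement percentage (one decimal)."""
    rows = []
    for modality, group in episodes.groupby("modality", observed=True):
        n = len(group)
        n_improved = int(group["improved"].sum())
        rows.append(
            {
                "modality": modality,
                "n": n,
                "n_improved": n_improved,
                "percent_improved": round(100.0 * n_improved / n, 1) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
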