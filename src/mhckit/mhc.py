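"""Minor-health-complaint (MHC) scores and the cohort median split.

The four MHC items are fixed sums of raw 1-4 responses: lack of vigor
(Q01-Q03, higher = better status), irritability (Q04-Q06), fatigue (Q07-Q09),
and somatic symptoms (Q19-Q26 plus Q28, nine items); higher is worse for the
last three.  Each score is split at its cohort median: subjects at or below
the median are labelled "low", strictly above "high".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bjsq import ValidationError, _check_likert, ITEM_CODES

MHC_ITEM_SETS: dict[str, list[str]] = {
    "lack_of_vigor": ["Q01", "Q02", "Q03"],
    "irritability": ["Q04", "Q05", "Q06"],
    "fatigue": ["Q07", "Q08", "Q09"],
    "somatic": [f"Q{i:02d}" for i in range(19, 27)] + ["Q28"],
}

#: Which split label is the better-status subgroup (vigor is reverse-scored).
DIRECTION: dict[str, str] = {
    "lack_of_vigor": "high",
    "irritability": "low",
    "fatigue": "low",
    "somatic": "low",
}

SCORE_RANGES: dict[str, tuple[int, int]] = {
    "lack_of_vigor": (3, 12),
    "irritability": (3, 12),
    "fatigue": (3, 12),
    "somatic": (9, 36),
}


def score_mhc(responses: pd.DataFrame) -> pd.DataFrame:
    """Four integer MHC sums per subject."""
    vals = _check_likert(responses)
    data = pd.DataFrame(vals, columns=ITEM_CODES, index=responses.index)
    out = pd.DataFrame(index=responses.index)
    if "subject_id" in responses.columns:
        out["subject_id"] = responses["subject_id"].to_numpy()
    for name, items in MHC_ITEM_SETS.items():
        out[name] = data[items].sum(axis=1)
    return out


@dataclass
class MedianSplit:
    medians: dict[str, float]
    labels: pd.DataFrame        # subject_id + {item}_split columns, "low"/"high"
    direction: dict[str, str]

    def better_mask(self, item: str) -> pd.Series:
        return self.labels[f"{item}_split"] == self.direction[item]


def median_split(scores: pd.DataFrame) -> MedianSplit:
    """Split each MHC score at its cohort median ("low" iff score <= median).

    Even-n medians are the midpoint of the central order statistics.  A score
    with no variation cannot be split and raises a per-item error.
    """
    if len(scores) < 2:
        raise ValidationError("median split requires at least 2 subjects")
    labels = pd.DataFrame(index=scores.index)
    if "subject_id" in scores.columns:
        labels["subject_id"] = scores["subject_id"].to_numpy()
    medians: dict[str, float] = {}
    degenerate = []
    for item in MHC_ITEM_SETS:
        if item not in scores.columns:
            raise ValidationError(f"scores table lacks MHC item '{item}'")
        col = scores[item].to_numpy()
        med = float(np.median(col))
        medians[item] = med
        if col.min() == col.max():
            degenerate.append(item)
            continue
        labels[f"{item}_split"] = np.where(col <= med, "low", "high")
    if degenerate:
        raise ValidationError(
            f"degenerate median split (all scores identical) for: {degenerate}"
        )
    return MedianSplit(medians=medians, labels=labels, direction=dict(DIRECTION))
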