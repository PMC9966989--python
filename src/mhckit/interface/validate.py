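"""Schema, range and key-consistency checks on the three input tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..bjsq import ITEM_CODES
from ..nutrient_screen import NUTRIENT_COLUMNS


def validate_tables(
    subjects: pd.DataFrame,
    bjsq: pd.DataFrame,
    intakes: pd.DataFrame,
) -> dict:
    """Report-only validation; the pipeline driver decides whether to abort.

    Checks required columns, Likert range 1-4, strictly positive intakes, and
    orphan subject ids across the three tables.
    """
    report: dict[str, list] = {
        "missing_columns": [],
        "range_violations": [],
        "orphan_ids": [],
    }
    for name, df, required in (
        ("subjects", subjects, ["subject_id", "occupation_flag", "high_stress_flag"]),
        ("bjsq", bjsq, ["subject_id"] + ITEM_CODES),
        ("nutrients", intakes, ["subject_id"] + NUTRIENT_COLUMNS),
    ):
        for col in required:
            if col not in df.columns:
                report["missing_columns"].append((name, col))

    if not [m for m in report["missing_columns"] if m[0] == "bjsq"]:
        vals = bjsq[ITEM_CODES].to_numpy(dtype=float)
        bad = ~np.isin(vals, (1.0, 2.0, 3.0, 4.0)) | np.isnan(vals)
        for r, c in zip(*np.nonzero(bad)):
            report["range_violations"].append(
                ("bjsq", str(bjsq["subject_id"].iloc[r]), ITEM_CODES[c],
                 None if np.isnan(vals[r, c]) else float(vals[r, c]))
            )
    if not [m for m in report["missing_columns"] if m[0] == "nutrients"]:
        vals = intakes[NUTRIENT_COLUMNS].to_numpy(dtype=float)
        bad = ~(vals > 0) | np.isnan(vals)
        for r, c in zip(*np.nonzero(bad)):
            report["range_violations"].append(
                ("nutrients", str(intakes["subject_id"].iloc[r]),
                 NUTRIENT_COLUMNS[c],
                 None if np.isnan(vals[r, c]) else float(vals[r, c]))
            )

    if "subject_id" in subjects.columns:
        base = set(subjects["subject_id"])
        for name, df in (("bjsq", bjsq), ("nutrients", intakes)):
            if "subject_id" in df.columns:
                for sid in sorted(set(df["subject_id"]) - base):
                    report["orphan_ids"].append((name, str(sid)))

    report["ok"] = not (report["missing_columns"] or report["range_violations"]
                        or report["orphan_ids"])
    return report
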