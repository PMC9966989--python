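import numpy as np
import pandas as pd
import pytest

from mhckit import bjsq, mhc
from mhckit.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default 887-subject cohort, seed 0 (the canonical fixture seed)."""
    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def analyzed(default_cohort):
    """Cohort restricted to the 794 included subjects, plus derived tables."""
    included, report = bjsq.filter_population(default_cohort.subjects)
    responses = default_cohort.responses[
        default_cohort.responses["subject_id"].isin(included)
    ].reset_index(drop=True)
    intakes = default_cohort.intakes[
        default_cohort.intakes["subject_id"].isin(included)
    ].reset_index(drop=True)
    binary = bjsq.recode_binary(responses)
    scores = mhc.score_mhc(responses)
    split = mhc.median_split(scores)
    return {
        "included": included,
        "report": report,
        "responses": responses,
        "intakes": intakes,
        "binary": binary,
        "scores": scores,
        "split": split,
    }


@pytest.fixture()
def likert_row():
    """Single-subject response table filled with a constant, editable."""
    def make(value=1, **overrides):
        row = {q: value for q in bjsq.ITEM_CODES}
        row.update(overrides)
        row["subject_id"] = "S1"
        return pd.DataFrame([row])
    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
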