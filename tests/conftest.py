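import numpy as np
import pandas as pd
import pytest

from ordsustain import (
    Cohort,
    EvidenceTensor,
    ScoredEventsLikelihood,
    SymptomDef,
    SymptomDictionary,
    build_event_index,
)


@pytest.fixture
def binary_pair_dict() -> SymptomDictionary:
    """Two binary symptoms A, B -> events [A:1, B:1]."""
    return SymptomDictionary(
        (
            SymptomDef("A", "test", ("ref", "hi")),
            SymptomDef("B", "test", ("ref", "hi")),
        )
    )


@pytest.fixture
def small_dict() -> SymptomDictionary:
    """One 3-level and three binary symptoms -> N = 5 events."""
    return SymptomDictionary(
        (
            SymptomDef("tremor", "Tremors", ("none", "mild", "severe")),
            SymptomDef("ataxia", "Ataxia", ("no", "yes")),
            SymptomDef("mood", "SCID", ("no", "yes")),
            SymptomDef("mri", "MRI", ("no", "yes")),
        )
    )


def make_cohort(
    dictionary: SymptomDictionary,
    case_obs: np.ndarray,
    control_obs: np.ndarray,
    strata: dict | None = None,
) -> Cohort:
    case_obs = np.atleast_2d(np.asarray(case_obs, dtype=np.int64))
    control_obs = np.atleast_2d(np.asarray(control_obs, dtype=np.int64))
    n_cases, n_controls = case_obs.shape[0], control_obs.shape[0]
    n = n_cases + n_controls
    strata_df = pd.DataFrame(strata if strata else {}, index=range(n), dtype=object)
    cohort = Cohort(
        participant_ids=tuple(f"p{i}" for i in range(n)),
        groups=np.array(["case"] * n_cases + ["control"] * n_controls),
        strata=strata_df,
        observations=np.vstack([case_obs, control_obs]),
        symptom_names=tuple(dictionary.names),
    )
    cohort.validate_against(dictionary)
    return cohort


def evidence_from_rows(
    dictionary: SymptomDictionary, rows: list[dict[str, list[float]]]
) -> EvidenceTensor:
    """Build an evidence tensor directly from per-symptom probability rows."""
    n = len(rows)
    values = []
    for s in dictionary:
        block = np.array([rows[i][s.name] for i in range(n)], dtype=float)
        assert block.shape == (n, s.n_levels)
        values.append(block)
    return EvidenceTensor(
        values=tuple(values),
        provenance=np.zeros((n, len(dictionary)), dtype=np.int8),
        symptom_names=tuple(dictionary.names),
        participant_ids=tuple(f"p{i}" for i in range(n)),
    )


@pytest.fixture
def flat_engine(small_dict) -> ScoredEventsLikelihood:
    """Uninformative evidence: all-ones vectors for every subject/symptom."""
    rows = [
        {s.name: [1.0] * s.n_levels for s in small_dict} for _ in range(12)
    ]
    tensor = evidence_from_rows(small_dict, rows)
    return ScoredEventsLikelihood(tensor, build_event_index(small_dict))
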