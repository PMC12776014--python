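"""Synthetic case/control cohorts with known progression ground truth.

The generator mirrors the generative assumptions of the scored-events model:
each case draws a latent subtype (mixture fractions), a stage along that
subtype's event sequence, and the implied true underlying levels; every
symptom is then *observed* through the measurement-noise channel (correct
with probability ``p_correct``, otherwise uniform over the other levels) and
finally masked missing-at-random at a per-symptom rate.  Controls sit at the
reference level of every symptom and pass through the same noise channel.

The default configuration emulates the FXTAS study's scale: 253 cases and 44
controls over the built-in 27-symptom dictionary, ~60% male cases, correct-
scoring probability 0.9 and 11.5% missingness per symptom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, MISSING, Cohort
from .dictionary import EventIndex, SymptomDictionary, build_event_index, fxtas_symptom_dictionary
from .sequences import EventSequence, random_valid_sequence, stage_levels


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``sequences`` may be given explicitly (one per subtype) or left ``None``
    to draw random valid sequences.  ``stage_weights`` defaults to uniform
    over stages ``0..N``.  ``sequence_by_stratum`` optionally couples a
    covariate to the generating sequence (each label maps to a subtype index),
    which powers group-comparison tests; by default covariates are untied.
    """

    dictionary: SymptomDictionary = field(default_factory=fxtas_symptom_dictionary)
    n_cases: int = 253
    n_controls: int = 44
    fractions: tuple[float, ...] = (1.0,)
    sequences: tuple[EventSequence, ...] | None = None
    stage_weights: tuple[float, ...] | None = None
    p_correct: float | dict[str, float] = 0.9
    missing_rate: float | dict[str, float] = 0.115
    male_fraction: float = 0.6
    sequence_by_stratum: dict[str, int] | None = None
    stratum_name: str = "sex"

    @property
    def n_subtypes(self) -> int:
        return len(self.fractions)

    def p_correct_for(self, symptom: str) -> float:
        if isinstance(self.p_correct, dict):
            return self.p_correct[symptom]
        return float(self.p_correct)

    def missing_rate_for(self, symptom: str) -> float:
        if isinstance(self.missing_rate, dict):
            return self.missing_rate[symptom]
        return float(self.missing_rate)

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("subtype fractions must be a probability vector")
        if self.sequences is not None and len(self.sequences) != len(self.fractions):
            raise ValueError("need one sequence per subtype fraction")
        for s in self.dictionary:
            p = self.p_correct_for(s.name)
            if not 0.0 < p <= 1.0:
                raise ValueError(f"p_correct for {s.name!r} outside (0, 1]")
            m = self.missing_rate_for(s.name)
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"missing rate for {s.name!r} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-subject ground truth emitted alongside a simulated cohort."""

    sequences: tuple[EventSequence, ...]
    fractions: tuple[float, ...]
    subtype: np.ndarray  # per case
    stage: np.ndarray  # per case
    true_levels: np.ndarray  # (n_cases, n_symptoms)
    index: EventIndex
    config: SimulationConfig

    def to_dict(self) -> dict:
        return {
            "sequences": [s.labels(self.index) for s in self.sequences],
            "fractions": list(self.fractions),
            "subtype": self.subtype.tolist(),
            "stage": self.stage.tolist(),
            "true_levels": self.true_levels.tolist(),
            "symptoms": list(self.index.symptom_names),
        }


def _observe(
    true_levels: np.ndarray, n_levels: int, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Push true levels through the uniform-misclassification noise channel."""
    n = true_levels.shape[0]
    obs = true_levels.copy()
    wrong = rng.random(n) >= p
    if n_levels > 1 and np.any(wrong):
        # uniform over the L-1 other levels
        offsets = rng.integers(1, n_levels, size=int(wrong.sum()))
        obs[wrong] = (true_levels[wrong] + offsets) % n_levels
    return obs


def generate_cohort(
    config: SimulationConfig, seed: int = 0
) -> tuple[Cohort, SyntheticTruth]:
    """Draw a case/control cohort and its ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    dictionary = config.dictionary
    index = build_event_index(dictionary)
    N = index.n_events

    sequences = config.sequences
    if sequences is None:
        sequences = tuple(
            random_valid_sequence(index, rng) for _ in range(config.n_subtypes)
        )
    stage_w = (
        np.full(N + 1, 1.0 / (N + 1))
        if config.stage_weights is None
        else np.asarray(config.stage_weights, dtype=float)
    )
    if stage_w.size != N + 1 or not np.isclose(stage_w.sum(), 1.0):
        raise ValueError("stage_weights must be a probability vector of length N+1")

    n_cases, n_controls = config.n_cases, config.n_controls
    sex = np.where(
        rng.random(n_cases + n_controls) < config.male_fraction, "male", "female"
    ).astype(object)

    if config.sequence_by_stratum is not None:
        subtype = np.array(
            [config.sequence_by_stratum[sex[i]] for i in range(n_cases)], dtype=np.int64
        )
    else:
        subtype = rng.choice(config.n_subtypes, size=n_cases, p=np.asarray(config.fractions))
    stage = rng.choice(N + 1, size=n_cases, p=stage_w)

    n_symptoms = len(dictionary)
    true_levels = np.zeros((n_cases, n_symptoms), dtype=np.int64)
    for i in range(n_cases):
        z = stage_levels(sequences[subtype[i]], int(stage[i]), index)
        true_levels[i] = [z[name] for name in dictionary.names]

    obs = np.empty((n_cases + n_controls, n_symptoms), dtype=np.int64)
    for j, s in enumerate(dictionary):
        p = config.p_correct_for(s.name)
        truth_col = np.concatenate(
            [true_levels[:, j], np.zeros(n_controls, dtype=np.int64)]
        )
        col = _observe(truth_col, s.n_levels, p, rng)
        miss = rng.random(n_cases + n_controls) < config.missing_rate_for(s.name)
        col[miss] = MISSING
        obs[:, j] = col

    ids = tuple(
        [f"case{i:04d}" for i in range(n_cases)]
        + [f"ctrl{i:04d}" for i in range(n_controls)]
    )
    groups = np.array([CASE] * n_cases + [CONTROL] * n_controls)
    strata = pd.DataFrame({config.stratum_name: sex})
    cohort = Cohort(
        participant_ids=ids,
        groups=groups,
        strata=strata,
        observations=obs,
        symptom_names=tuple(dictionary.names),
    )
    cohort.validate_against(dictionary)
    truth = SyntheticTruth(
        sequences=sequences,
        fractions=tuple(config.fractions),
        subtype=subtype,
        stage=stage,
        true_levels=true_levels,
        index=index,
        config=config,
    )
    return cohort, truth


def null_relabel(cohort: Cohort, label_name: str, seed: int = 0) -> Cohort:
    """Shuffle one covariate among the cases; everything else unchanged.

    Produces exchangeable-label datasets for permutation-test calibration.
    """
    if label_name not in cohort.strata.columns:
        raise KeyError(label_name)
    rng = np.random.default_rng(seed)
    values = cohort.strata[label_name].to_numpy().copy()
    case_idx = np.flatnonzero(cohort.is_case)
    values[case_idx] = values[case_idx[rng.permutation(case_idx.size)]]
    return cohort.with_stratum(label_name, values)
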