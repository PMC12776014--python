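"""Measurement noise and soft imputation: from ordinal scores to evidence.

The scored-events likelihood treats each observed ordinal value as a noisy
readout of the participant's true underlying level.  Per symptom there is a
single *correct-scoring probability* ``p_b``: the chance the recorded score
equals the underlying level.  ``p_b`` is estimated from controls — the
fraction of observed controls scored at the reference level — capped at 0.95
so that some background symptom prevalence unrelated to disease progression
is always allowed for, and floored (default 0.5) so that a symptom common in
controls cannot invert the evidence.

Missing values are handled as soft evidence: the cell's evidence vector is
the marginal level distribution observed among cases, which keeps runs
deterministic given the data (no sampled imputations).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import MISSING, Cohort
from .dictionary import SymptomDictionary

logger = logging.getLogger(__name__)

OBSERVED = 0
IMPUTED = 1


@dataclass(frozen=True)
class NoiseModel:
    """Per-symptom correct-scoring probabilities with their cap and floor."""

    p_correct: dict[str, float]
    cap: float = 0.95
    floor: float = 0.5

    def __post_init__(self) -> None:
        if self.cap <= self.floor:
            raise ValueError(f"cap ({self.cap}) must exceed floor ({self.floor})")
        for name, p in self.p_correct.items():
            if not (self.floor <= p <= self.cap):
                raise ValueError(
                    f"p_correct[{name!r}]={p} outside [{self.floor}, {self.cap}]"
                )


def estimate_correct_scoring(
    cohort: Cohort,
    dictionary: SymptomDictionary,
    cap: float = 0.95,
    floor: float = 0.5,
) -> NoiseModel:
    """Estimate correct-scoring probabilities from the control group.

    For each symptom, ``p_correct = clamp(#controls at reference /
    #controls observed, floor, cap)``.  A symptom with no observed control
    values cannot be calibrated and raises.
    """
    if cap <= floor:
        raise ValueError(f"cap ({cap}) must exceed floor ({floor})")
    control_obs = cohort.observations[~cohort.is_case]
    p_correct: dict[str, float] = {}
    for j, s in enumerate(dictionary):
        col = control_obs[:, j]
        observed = col != MISSING
        n_obs = int(np.sum(observed))
        if n_obs == 0:
            raise ValueError(f"no control observations for symptom {s.name!r}")
        raw = float(np.sum(col[observed] == 0)) / n_obs
        if raw < floor:
            logger.warning(
                "symptom %r: control reference fraction %.3f below floor %.2f; "
                "flooring", s.name, raw, floor,
            )
        p_correct[s.name] = float(min(max(raw, floor), cap))
    return NoiseModel(p_correct=p_correct, cap=cap, floor=floor)


def marginal_distribution(cohort: Cohort, symptom: str, n_levels: int | None = None) -> np.ndarray:
    """Observed-case level frequencies of one symptom (sums to 1).

    ``n_levels`` pads the vector to the symptom's full level count so levels
    never observed still appear with probability 0.
    """
    col = cohort.column(symptom)[cohort.is_case]
    observed = col[col != MISSING]
    if observed.size == 0:
        raise ValueError(f"all cases missing for symptom {symptom!r}")
    top = int(observed.max()) + 1
    length = max(top, n_levels or 0)
    counts = np.bincount(observed, minlength=length).astype(float)
    return counts / counts.sum()


def missing_fraction(cohort: Cohort, symptom: str) -> float:
    """Fraction of cases with a missing value for ``symptom``."""
    col = cohort.column(symptom)[cohort.is_case]
    if col.size == 0:
        raise ValueError("cohort has no cases")
    return float(np.mean(col == MISSING))


@dataclass(frozen=True)
class EvidenceTensor:
    """Per (subject, symptom) probability vectors over underlying levels.

    ``values[j]`` is an ``(n_subjects, L_j)`` array for symptom ``j``:
    row ``i`` is ``P(evidence_i | true level z)`` for each level ``z``.
    ``provenance`` marks each cell ``OBSERVED`` or ``IMPUTED``.
    """

    values: tuple[np.ndarray, ...]
    provenance: np.ndarray
    symptom_names: tuple[str, ...]
    dictionary_hash: str = ""
    participant_ids: tuple[str, ...] = field(default=())

    @property
    def n_subjects(self) -> int:
        return self.values[0].shape[0] if self.values else 0

    @property
    def n_symptoms(self) -> int:
        return len(self.values)

    def subset(self, idx: np.ndarray) -> "EvidenceTensor":
        idx = np.asarray(idx)
        ids = tuple(self.participant_ids[i] for i in idx) if self.participant_ids else ()
        return EvidenceTensor(
            values=tuple(v[idx] for v in self.values),
            provenance=self.provenance[idx],
            symptom_names=self.symptom_names,
            dictionary_hash=self.dictionary_hash,
            participant_ids=ids,
        )

    def save(self, path: str | Path) -> None:
        arrays = {f"values_{j}": v for j, v in enumerate(self.values)}
        np.savez(
            path,
            provenance=self.provenance,
            symptom_names=np.array(self.symptom_names),
            participant_ids=np.array(self.participant_ids),
            dictionary_hash=np.array(self.dictionary_hash),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "EvidenceTensor":
        with np.load(path, allow_pickle=False) as z:
            names = tuple(str(x) for x in z["symptom_names"])
            values = tuple(z[f"values_{j}"] for j in range(len(names)))
            return cls(
                values=values,
                provenance=z["provenance"],
                symptom_names=names,
                dictionary_hash=str(z["dictionary_hash"]),
                participant_ids=tuple(str(x) for x in z["participant_ids"]),
            )


def dictionary_hash(dictionary: SymptomDictionary) -> str:
    payload = json.dumps(dictionary.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def observation_vector(level: int, n_levels: int, p_correct: float) -> np.ndarray:
    """Noise-model likelihood row for an observed level.

    The correct level carries ``p_correct``; the remaining mass is spread
    uniformly over the other ``L - 1`` levels, which conserves probability
    and reduces to the exact two-point model for binary symptoms.
    """
    v = np.full(n_levels, (1.0 - p_correct) / (n_levels - 1))
    v[level] = p_correct
    return v


def build_evidence(
    cohort: Cohort,
    dictionary: SymptomDictionary,
    noise: NoiseModel,
    marginals: dict[str, np.ndarray] | None = None,
) -> EvidenceTensor:
    """Assemble the evidence tensor for the *cases* of a cohort.

    Observed cells get the noise-model likelihood row; missing cells get the
    case marginal distribution (soft imputation).  ``marginals`` may be
    supplied to reuse distributions estimated on a different (e.g. full)
    dataset, as in cross-validation.
    """
    cohort.validate_against(dictionary)
    for s in dictionary:
        if s.name not in noise.p_correct:
            raise ValueError(f"noise model lacks symptom {s.name!r}")
    cases = cohort.cases()
    n = cases.n_participants
    values: list[np.ndarray] = []
    provenance = np.full((n, len(dictionary)), OBSERVED, dtype=np.int8)
    for j, s in enumerate(dictionary):
        L = s.n_levels
        p = noise.p_correct[s.name]
        col = cases.observations[:, j]
        block = np.empty((n, L))
        for level in range(L):
            block[col == level] = observation_vector(level, L, p)
        miss = col == MISSING
        if np.any(miss):
            if marginals is not None and s.name in marginals:
                marg = np.asarray(marginals[s.name], dtype=float)
                if marg.shape != (L,):
                    raise ValueError(f"marginal for {s.name!r} has wrong length")
            else:
                marg = marginal_distribution(cohort, s.name, n_levels=L)
            block[miss] = marg
            provenance[miss, j] = IMPUTED
        values.append(block)
    return EvidenceTensor(
        values=tuple(values),
        provenance=provenance,
        symptom_names=tuple(dictionary.names),
        dictionary_hash=dictionary_hash(dictionary),
        participant_ids=tuple(cases.participant_ids),
    )
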