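"""Cohort data model: wide-format case/control tables of ordinal observations.

A cohort row is one participant: a ``case``/``control`` group label, optional
stratifying covariates (sex, CGG class, ...) and one observed level index per
symptom, with missing values carried explicitly.  Level indices are 0-based
and 0 is always the reference level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dictionary import SymptomDef, SymptomDictionary

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel level index for a missing observation

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class Cohort:
    """Wide cohort table bound to a symptom dictionary's symptom set.

    Attributes
    ----------
    participant_ids : tuple of str
    groups : numpy array of str, ``case`` or ``control``
    strata : DataFrame of covariate labels, index-aligned with participants
    observations : int array (n_participants, n_symptoms); ``MISSING`` = -1
    symptom_names : tuple of str, column order of ``observations``
    """

    participant_ids: tuple[str, ...]
    groups: np.ndarray
    strata: pd.DataFrame
    observations: np.ndarray
    symptom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise ValueError("participant_ids are not unique")
        bad = set(np.unique(self.groups)) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.observations.shape != (len(self.participant_ids), len(self.symptom_names)):
            raise ValueError("observations shape inconsistent with ids/symptoms")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def is_case(self) -> np.ndarray:
        return self.groups == CASE

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.is_case))

    @property
    def n_controls(self) -> int:
        return int(np.sum(~self.is_case))

    def column(self, symptom: str) -> np.ndarray:
        return self.observations[:, self.symptom_names.index(symptom)]

    def validate_against(self, dictionary: SymptomDictionary) -> None:
        """Raise if any observed level index is invalid for its symptom."""
        if tuple(dictionary.names) != tuple(self.symptom_names):
            raise ValueError(
                "cohort symptom columns do not match the dictionary: "
                f"{self.symptom_names} vs {tuple(dictionary.names)}"
            )
        for j, s in enumerate(dictionary):
            col = self.observations[:, j]
            ok = (col == MISSING) | ((col >= 0) & (col < s.n_levels))
            if not np.all(ok):
                bad = np.unique(col[~ok]).tolist()
                raise ValueError(f"invalid level indices {bad} for symptom {s.name!r}")

    def subset(self, mask: np.ndarray) -> "Cohort":
        idx = np.flatnonzero(mask)
        return Cohort(
            participant_ids=tuple(self.participant_ids[i] for i in idx),
            groups=self.groups[idx],
            strata=self.strata.iloc[idx].reset_index(drop=True),
            observations=self.observations[idx],
            symptom_names=self.symptom_names,
        )

    def cases(self) -> "Cohort":
        return self.subset(self.is_case)

    def with_stratum(self, name: str, values) -> "Cohort":
        strata = self.strata.copy()
        strata[name] = np.asarray(values, dtype=object)
        return replace(self, strata=strata)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"participant_id": self.participant_ids, "group": self.groups})
        for c in self.strata.columns:
            df[c] = self.strata[c].to_numpy()
        obs = self.observations.astype(object)
        obs[self.observations == MISSING] = None
        for j, name in enumerate(self.symptom_names):
            df[name] = pd.array(
                [None if v is None else int(v) for v in obs[:, j]], dtype="Int64"
            )
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def cohort_from_frame(df: pd.DataFrame, dictionary: SymptomDictionary) -> Cohort:
    """Build a :class:`Cohort` from a wide DataFrame; empty cells are missing."""
    required = {"participant_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    symptom_names = tuple(dictionary.names)
    missing_cols = [s for s in symptom_names if s not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks symptom columns: {missing_cols}")
    covariates = [
        c for c in df.columns if c not in required and c not in symptom_names
    ]
    n = len(df)
    obs = np.full((n, len(symptom_names)), MISSING, dtype=np.int64)
    for j, name in enumerate(symptom_names):
        col = pd.to_numeric(df[name], errors="raise")
        filled = col.fillna(MISSING).to_numpy()
        obs[:, j] = filled.astype(np.int64)
    cohort = Cohort(
        participant_ids=tuple(str(p) for p in df["participant_id"]),
        groups=df["group"].astype(str).to_numpy(),
        strata=df[covariates].reset_index(drop=True).astype(object),
        observations=obs,
        symptom_names=symptom_names,
    )
    cohort.validate_against(dictionary)
    return cohort


def load_cohort(path: str | Path, dictionary: SymptomDictionary) -> Cohort:
    """Read a wide CSV cohort (one symptom column per dictionary entry)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    return cohort_from_frame(df, dictionary)


def check_level_support(
    cohort: Cohort, dictionary: SymptomDictionary, min_count: int = 3
) -> list[tuple[str, int, int]]:
    """List elevated levels observed fewer than ``min_count`` times among cases.

    Sparse levels make the correct-scoring likelihood uninformative; the usual
    remedy is an explicit :func:`merge_levels` call.  Missing values never
    count toward support.  Returns ``(symptom, level, count)`` violations;
    an empty list means every elevated level has adequate support.
    """
    cohort.validate_against(dictionary)
    case_obs = cohort.observations[cohort.is_case]
    violations: list[tuple[str, int, int]] = []
    for j, s in enumerate(dictionary):
        col = case_obs[:, j]
        for level in range(1, s.n_levels):
            count = int(np.sum(col == level))
            if count < min_count:
                violations.append((s.name, level, count))
    if violations:
        logger.warning("level-support violations (min %d): %s", min_count, violations)
    return violations


def merge_levels(
    cohort: Cohort,
    dictionary: SymptomDictionary,
    symptom: str,
    levels_to_merge: list[int],
) -> tuple[Cohort, SymptomDictionary]:
    """Collapse contiguous elevated levels of one symptom into a single level.

    The merged level is labelled by joining the original labels with ``/``
    (e.g. ``Moderate/Severe``); observations are remapped and the event count
    drops by ``len(levels_to_merge) - 1``.  The reference level can never be
    merged.
    """
    sdef = dictionary[symptom]
    levels = sorted(levels_to_merge)
    if not levels:
        raise ValueError("levels_to_merge is empty")
    if levels[0] < 1:
        raise ValueError("the reference level (0) cannot be merged")
    if levels[-1] >= sdef.n_levels:
        raise ValueError(f"level {levels[-1]} out of range for {symptom!r}")
    if levels != list(range(levels[0], levels[-1] + 1)):
        raise ValueError(f"levels to merge must be contiguous, got {levels}")

    lo, hi = levels[0], levels[-1]
    new_labels = (
        list(sdef.levels[:lo])
        + ["/".join(sdef.levels[lo : hi + 1])]
        + list(sdef.levels[hi + 1 :])
    )
    new_def = SymptomDef(
        name=sdef.name,
        category=sdef.category,
        levels=tuple(new_labels),
        staging_anchor=sdef.staging_anchor,
    )
    new_dict = SymptomDictionary(
        tuple(new_def if s.name == symptom else s for s in dictionary)
    )

    j = dictionary.index_of(symptom)
    col = cohort.observations[:, j]
    remapped = col.copy()
    shift = hi - lo  # levels above the block slide down
    above = (col > hi) & (col != MISSING)
    inside = (col >= lo) & (col <= hi)
    remapped[inside] = lo
    remapped[above] = col[above] - shift
    new_obs = cohort.observations.copy()
    new_obs[:, j] = remapped
    new_cohort = replace(cohort, observations=new_obs)
    new_cohort.validate_against(new_dict)
    return new_cohort, new_dict
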