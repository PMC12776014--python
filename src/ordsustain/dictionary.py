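"""Symptom dictionaries and the event index.

An ordinal symptom has an ordered list of levels; the first level is the
*reference* (unaffected) level and every transition to the next elevated level
is an *event* in the progression model.  A symptom with ``L`` levels therefore
contributes ``L - 1`` events, and the global event set is the concatenation of
all symptoms' elevated levels in dictionary order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

MIN_LEVELS = 2
MAX_LEVELS = 6


@dataclass(frozen=True)
class SymptomDef:
    """One ordinal symptom: a name, a category and its ordered levels."""

    name: str
    category: str
    levels: tuple[str, ...]
    staging_anchor: bool = False

    def __post_init__(self) -> None:
        if not (MIN_LEVELS <= len(self.levels) <= MAX_LEVELS):
            raise ValueError(
                f"symptom {self.name!r} has {len(self.levels)} levels; "
                f"must have between {MIN_LEVELS} and {MAX_LEVELS}"
            )
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_events(self) -> int:
        return len(self.levels) - 1


@dataclass(frozen=True)
class SymptomDictionary:
    """Ordered collection of :class:`SymptomDef` defining the event set."""

    symptoms: tuple[SymptomDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symptoms", tuple(self.symptoms))
        names = [s.name for s in self.symptoms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate symptom names: {dupes}")
        anchors = [s.name for s in self.symptoms if s.staging_anchor]
        if len(anchors) > 1:
            raise ValueError(f"more than one staging anchor: {anchors}")

    def __iter__(self) -> Iterator[SymptomDef]:
        return iter(self.symptoms)

    def __len__(self) -> int:
        return len(self.symptoms)

    def __getitem__(self, name: str) -> SymptomDef:
        for s in self.symptoms:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.symptoms]

    @property
    def staging_anchor(self) -> str | None:
        for s in self.symptoms:
            if s.staging_anchor:
                return s.name
        return None

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def to_dict(self) -> dict:
        return {
            "symptoms": [
                {
                    "name": s.name,
                    "category": s.category,
                    "levels": list(s.levels),
                    "staging_anchor": s.staging_anchor,
                }
                for s in self.symptoms
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SymptomDictionary":
        try:
            entries = payload["symptoms"]
        except (KeyError, TypeError) as exc:
            raise ValueError("dictionary payload must have a 'symptoms' list") from exc
        symptoms = [
            SymptomDef(
                name=e["name"],
                category=e.get("category", ""),
                levels=tuple(e["levels"]),
                staging_anchor=bool(e.get("staging_anchor", False)),
            )
            for e in entries
        ]
        return cls(tuple(symptoms))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_symptom_dictionary(path: str | Path) -> SymptomDictionary:
    """Load and validate a symptom dictionary from its JSON sidecar format."""
    payload = json.loads(Path(path).read_text())
    return SymptomDictionary.from_dict(payload)


@dataclass(frozen=True)
class EventIndex:
    """Bidirectional enumeration of events ``(symptom, target level >= 1)``.

    Events of one symptom get consecutive ids in ascending level order, so the
    ordinal-monotonicity constraint on sequences can be checked from ids alone.
    """

    events: tuple[tuple[str, int], ...]
    symptom_names: tuple[str, ...] = field(default=())

    @property
    def n_events(self) -> int:
        return len(self.events)

    def event_id(self, symptom: str, level: int) -> int:
        return self.events.index((symptom, level))

    def event(self, event_id: int) -> tuple[str, int]:
        return self.events[event_id]

    def label(self, event_id: int) -> str:
        symptom, level = self.events[event_id]
        return f"{symptom}:{level}"

    def labels(self) -> list[str]:
        return [self.label(i) for i in range(self.n_events)]

    def symptom_of(self, event_id: int) -> str:
        return self.events[event_id][0]


def build_event_index(dictionary: SymptomDictionary) -> EventIndex:
    """Enumerate all elevated-level transitions of a dictionary as events."""
    if len(dictionary) == 0:
        raise ValueError("cannot build an event index from an empty dictionary")
    events: list[tuple[str, int]] = []
    for s in dictionary:
        for level in range(1, s.n_levels):
            events.append((s.name, level))
    return EventIndex(events=tuple(events), symptom_names=tuple(dictionary.names))


def _t2(name: str, category: str, levels: Iterable[str]) -> SymptomDef:
    return SymptomDef(name=name, category=category, levels=tuple(levels))


def fxtas_symptom_dictionary(include_staging_anchor: bool = True) -> SymptomDictionary:
    """The built-in FXTAS symptom dictionary (27 clinical/MRI symptoms).

    With ``include_staging_anchor=True`` the clinical FXTAS stage (0-5) is
    appended as a 28th ordinal variable flagged as the staging anchor, so its
    events can be rendered as stage bands in positional difference graphs.
    """
    symptoms = [
        _t2("tandem_walk", "Ataxia", ["normal", "abnormal", "unable"]),
        _t2("ataxia_severity", "Ataxia", ["0", "1", "2", "3", "4"]),
        _t2("cantab_pal_total_errors", "CANTAB", ["<=13", ">13"]),
        _t2("cantab_rti_movement_time", "CANTAB", ["<=368.57", ">368.57"]),
        _t2("cantab_swm_between_errors", "CANTAB", ["<=26", ">26"]),
        _t2("cc_thickness", "MRI", ["normal", "thin"]),
        _t2("genu_wm_hyperintensity", "MRI", ["no", "yes"]),
        _t2("mcp_wm_hyperintensity", "MRI", ["none", "mild", "moderate/severe"]),
        _t2("mri_cerebellar", "MRI", ["none", "mild", "moderate/severe"]),
        _t2("mri_cerebral", "MRI", ["none", "mild", "moderate/severe"]),
        _t2("splenium_wm_hyperintensity", "MRI", ["none", "mild", "moderate/severe"]),
        _t2("parkinsons_disease", "Parkinson's disease", ["no", "yes"]),
        _t2("parkinsonian_features", "Parkinson's disease", ["no", "yes"]),
        _t2("scid_anxiety", "SCID", ["absent/sub-threshold", "threshold"]),
        _t2("scid_mood", "SCID", ["absent/sub-threshold", "threshold"]),
        _t2("scid_somatoform", "SCID", ["absent/sub-threshold", "threshold"]),
        _t2("scid_substance_use", "SCID", ["absent/sub-threshold", "threshold"]),
        _t2("bds2_total", "Scores", [">=20", "<20"]),
        _t2("mmse_total", "Scores", ["normal", "mild", "moderate"]),
        _t2("hyperthyroid", "Thyroid", ["no", "yes"]),
        _t2("hypothyroid", "Thyroid", ["no", "yes"]),
        _t2("autoimmune", "Thyroid", ["no", "yes"]),
        _t2("head_tremor", "Tremors", ["no", "yes"]),
        _t2("intention_tremor", "Tremors", ["no", "yes"]),
        _t2("intermittent_tremor", "Tremors", ["no", "yes"]),
        _t2("postural_tremor", "Tremors", ["no", "yes"]),
        _t2("resting_tremor", "Tremors", ["no", "yes"]),
    ]
    if include_staging_anchor:
        symptoms.append(
            SymptomDef(
                name="fxtas_stage",
                category="Staging",
                levels=("0", "1", "2", "3", "4", "5"),
                staging_anchor=True,
            )
        )
    return SymptomDictionary(tuple(symptoms))
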