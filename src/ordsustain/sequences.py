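"""Event sequences: constrained permutations of the event set.

A sequence is a total order over all events.  Because an ordinal symptom can
only worsen one level at a time, the events of one symptom must appear in
ascending level order; sequences violating this are not part of the model
space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .dictionary import EventIndex


def event_arrays(index: EventIndex) -> tuple[np.ndarray, np.ndarray]:
    """Per-event symptom index and within-symptom level rank (1-based)."""
    name_to_idx = {n: i for i, n in enumerate(index.symptom_names)}
    symptom = np.array([name_to_idx[s] for s, _ in index.events], dtype=np.int64)
    rank = np.array([lvl for _, lvl in index.events], dtype=np.int64)
    return symptom, rank


def is_valid_order(
    order: np.ndarray, event_symptom: np.ndarray, event_rank: np.ndarray
) -> bool:
    """True iff each symptom's events appear in ascending level order."""
    seen = np.zeros(int(event_symptom.max()) + 1 if event_symptom.size else 0, dtype=np.int64)
    for e in order:
        s = event_symptom[e]
        if event_rank[e] != seen[s] + 1:
            return False
        seen[s] += 1
    return True


@dataclass(frozen=True)
class EventSequence:
    """A valid ordering of event ids (position 0 = earliest event)."""

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "order", tuple(int(e) for e in self.order))

    def __len__(self) -> int:
        return len(self.order)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.order, dtype=np.int64)

    def positions(self) -> np.ndarray:
        """Position of each event id in the sequence."""
        pos = np.empty(len(self.order), dtype=np.int64)
        pos[list(self.order)] = np.arange(len(self.order))
        return pos

    def labels(self, index: EventIndex) -> list[str]:
        return [index.label(e) for e in self.order]

    @classmethod
    def from_labels(cls, labels: list[str], index: EventIndex) -> "EventSequence":
        ids = []
        for lab in labels:
            symptom, level = lab.rsplit(":", 1)
            ids.append(index.event_id(symptom, int(level)))
        return cls(tuple(ids))


def validate_sequence(seq: EventSequence | np.ndarray, index: EventIndex) -> bool:
    """Check ordinal monotonicity of a permutation of the event ids."""
    order = seq.array if isinstance(seq, EventSequence) else np.asarray(seq)
    n = index.n_events
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError("sequence is not a permutation of the event ids")
    symptom, rank = event_arrays(index)
    return is_valid_order(order, symptom, rank)


def stage_levels(
    seq: EventSequence | np.ndarray, k: int, index: EventIndex
) -> dict[str, int]:
    """Underlying level of each symptom after the first ``k`` events.

    A symptom's level at stage ``k`` is the number of its events occurring at
    positions ``< k`` along the sequence; stage 0 is all-reference and stage
    ``N`` is every symptom at its maximum level.
    """
    order = seq.array if isinstance(seq, EventSequence) else np.asarray(seq)
    if not 0 <= k <= index.n_events:
        raise ValueError(f"stage {k} outside [0, {index.n_events}]")
    levels = {name: 0 for name in index.symptom_names}
    for e in order[:k]:
        symptom, level = index.event(int(e))
        levels[symptom] = level
    return levels


def random_valid_sequence(index: EventIndex, rng: np.random.Generator) -> EventSequence:
    """Uniform draw from the valid orderings.

    A uniformly shuffled multiset of symptom slots, filled with each symptom's
    events in ascending order, is uniform over valid orders (each valid order
    corresponds to exactly one slot arrangement).
    """
    symptom, _ = event_arrays(index)
    slots = rng.permutation(symptom)
    next_rank = {}
    order = []
    per_symptom_events: dict[int, list[int]] = {}
    for e in range(index.n_events):
        per_symptom_events.setdefault(int(symptom[e]), []).append(e)
    for s in slots:
        s = int(s)
        i = next_rank.get(s, 0)
        order.append(per_symptom_events[s][i])
        next_rank[s] = i + 1
    return EventSequence(tuple(order))


def enumerate_valid_sequences(index: EventIndex) -> Iterator[np.ndarray]:
    """Yield every valid ordering (exhaustive; intended for small event sets)."""
    symptom, _ = event_arrays(index)
    n = index.n_events
    per_symptom: dict[int, list[int]] = {}
    for e in range(n):
        per_symptom.setdefault(int(symptom[e]), []).append(e)
    symptoms = sorted(per_symptom)
    counts = {s: len(per_symptom[s]) for s in symptoms}

    order = np.empty(n, dtype=np.int64)

    def rec(pos: int, used: dict[int, int]):
        if pos == n:
            yield order.copy()
            return
        for s in symptoms:
            u = used[s]
            if u < counts[s]:
                order[pos] = per_symptom[s][u]
                used[s] = u + 1
                yield from rec(pos + 1, used)
                used[s] = u

    yield from rec(0, {s: 0 for s in symptoms})
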