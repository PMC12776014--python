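"""Positional variance diagrams and positional difference graphs.

A PVD summarizes the MCMC posterior over orderings as an event-by-position
heatmap: entry ``(e, q)`` is the posterior probability that event ``e``
occupies sequence position ``q``.  Averaging permutation matrices makes the
matrix doubly stochastic.  A PDG compares two fitted orderings by connecting
each event's most-likely position in the left and right fits; line colour
encodes the direction of movement and opacity its magnitude, and the events
of a staging-anchor symptom (e.g. the clinical FXTAS stage) are drawn as
black reference lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "ordsustain"  # reproducible SVG ids
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .model import SubtypeFit

# Okabe-Ito colour-blind-safe palette, keyed by ordinal level of the event
LEVEL_COLOURS = ["#0072B2", "#D55E00", "#009E73", "#CC79A7", "#E69F00"]

EARLIER, LATER, SAME = "earlier", "later", "same"
MOVEMENT_COLOURS = {EARLIER: "#0072B2", LATER: "#D55E00", SAME: "#999999"}
ANCHOR_COLOUR = "#000000"


@dataclass(frozen=True)
class PVDMatrix:
    """Event-by-position posterior occupancy matrix with display ordering."""

    matrix: np.ndarray  # (N, N), rows in event-id order
    row_order: np.ndarray  # event ids sorted for display
    labels: tuple[str, ...]  # per event id
    categories: tuple[str, ...]
    levels: tuple[int, ...]

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    def ordered(self) -> np.ndarray:
        return self.matrix[self.row_order]

    def most_likely_positions(self) -> np.ndarray:
        """Per event id: argmax position of its PVD row."""
        return np.argmax(self.matrix, axis=1)


def _display_order(matrix: np.ndarray) -> np.ndarray:
    """Events sorted by most-likely position; ties by mean position, then id."""
    ml = np.argmax(matrix, axis=1)
    mean_pos = matrix @ np.arange(matrix.shape[1])
    return np.lexsort((np.arange(matrix.shape[0]), mean_pos, ml))


def pvd_matrix(fit: SubtypeFit, subtype: int = 0) -> PVDMatrix:
    """Posterior position-occupancy matrix of one subtype's ordering."""
    if fit.n_samples == 0:
        raise ValueError("fit carries no posterior samples")
    if not 0 <= subtype < fit.n_subtypes:
        raise ValueError(f"subtype {subtype} out of range")
    index = fit.model.event_index
    N = index.n_events
    M = np.zeros((N, N))
    samples = fit.samples_orders[:, subtype, :]
    for s in samples:
        M[s, np.arange(N)] += 1.0
    M /= samples.shape[0]
    dictionary = getattr(fit.model, "dictionary", None)
    categories = []
    levels = []
    for e in range(N):
        name, lvl = index.event(e)
        categories.append(dictionary[name].category if dictionary is not None else name)
        levels.append(lvl)
    return PVDMatrix(
        matrix=M,
        row_order=_display_order(M),
        labels=tuple(index.labels()),
        categories=tuple(categories),
        levels=tuple(levels),
    )


@dataclass(frozen=True)
class PDGSpec:
    """Paired-ordering comparison of one event set under two fits."""

    left_order: tuple[int, ...]  # event ids by most-likely position, left fit
    right_order: tuple[int, ...]
    left_positions: np.ndarray  # per event id
    right_positions: np.ndarray
    movement: tuple[str, ...]  # per event id: earlier | later | same
    delta: np.ndarray  # right minus left position, per event id
    anchor_events: tuple[int, ...]
    labels: tuple[str, ...]
    highlight: tuple[int, ...] = ()


def _ml_position_ranking(pvd: PVDMatrix) -> np.ndarray:
    """Display rank of each event id (0 = earliest)."""
    ranks = np.empty(pvd.n_events, dtype=np.int64)
    ranks[pvd.row_order] = np.arange(pvd.n_events)
    return ranks


def pdg(
    fit_left: SubtypeFit,
    fit_right: SubtypeFit,
    subtype_left: int = 0,
    subtype_right: int = 0,
    highlight: tuple[int, ...] = (),
) -> PDGSpec:
    """Positional difference graph between two fitted orderings."""
    index_l = fit_left.model.event_index
    index_r = fit_right.model.event_index
    if index_l.events != index_r.events:
        raise ValueError("fits do not share an event set")
    pvd_l = pvd_matrix(fit_left, subtype_left)
    pvd_r = pvd_matrix(fit_right, subtype_right)
    pos_l = _ml_position_ranking(pvd_l)
    pos_r = _ml_position_ranking(pvd_r)
    delta = pos_r - pos_l
    movement = tuple(
        EARLIER if d < 0 else LATER if d > 0 else SAME for d in delta
    )
    anchor = [
        e
        for e in range(index_l.n_events)
        if _is_anchor(fit_left, index_l.symptom_of(e))
    ]
    return PDGSpec(
        left_order=tuple(int(e) for e in np.argsort(pos_l)),
        right_order=tuple(int(e) for e in np.argsort(pos_r)),
        left_positions=pos_l,
        right_positions=pos_r,
        movement=movement,
        delta=delta,
        anchor_events=tuple(anchor or ()),
        labels=tuple(index_l.labels()),
        highlight=tuple(highlight),
    )


def _is_anchor(fit: SubtypeFit, symptom_name: str) -> bool:
    dictionary = getattr(fit.model, "dictionary", None)
    if dictionary is not None:
        return symptom_name == dictionary.staging_anchor
    return False


def render_pvd(pvd: PVDMatrix, path: str | Path, title: str = "") -> Path:
    """Write a PVD heatmap (SVG/PNG by extension); deterministic layout."""
    N = pvd.n_events
    fig, ax = plt.subplots(figsize=(max(4.0, 0.28 * N + 2.5), max(3.0, 0.24 * N + 1.5)))
    ordered = pvd.ordered()
    rgba = np.ones((N, N, 4))
    for row, e in enumerate(pvd.row_order):
        colour = LEVEL_COLOURS[(pvd.levels[e] - 1) % len(LEVEL_COLOURS)]
        cmap = LinearSegmentedColormap.from_list(f"lvl{e}", ["#ffffff", colour])
        rgba[row] = cmap(ordered[row])
    ax.imshow(rgba, aspect="auto", interpolation="nearest")
    ax.set_yticks(range(N))
    ax.set_yticklabels([pvd.labels[e] for e in pvd.row_order], fontsize=6)
    ax.set_xticks(range(0, N, max(1, N // 10)))
    ax.set_xticklabels([str(q + 1) for q in range(0, N, max(1, N // 10))], fontsize=6)
    ax.set_xlabel("sequence position")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, metadata=_stable_metadata(out))
    plt.close(fig)
    return out


def render_pdg(
    spec: PDGSpec,
    path: str | Path,
    left_label: str = "left",
    right_label: str = "right",
) -> Path:
    """Write a PDG: two ordered symptom lists joined by movement lines."""
    N = len(spec.labels)
    fig, ax = plt.subplots(figsize=(7.0, max(3.0, 0.24 * N + 1.5)))
    max_delta = max(1, int(np.max(np.abs(spec.delta))))
    for e in range(N):
        y0, y1 = N - 1 - spec.left_positions[e], N - 1 - spec.right_positions[e]
        if e in spec.anchor_events:
            colour, alpha, lw, gid = ANCHOR_COLOUR, 1.0, 1.6, f"anchor-{e}"
        else:
            colour = MOVEMENT_COLOURS[spec.movement[e]]
            alpha = 0.25 + 0.75 * abs(int(spec.delta[e])) / max_delta
            lw, gid = 1.1, f"event-{e}"
        ax.plot([0.0, 1.0], [y0, y1], color=colour, alpha=alpha, lw=lw, gid=gid)
        weight = "bold" if e in spec.highlight else "normal"
        bbox = (
            dict(facecolor="#ffe873", edgecolor="none", pad=1.0)
            if e in spec.highlight
            else None
        )
        ax.text(-0.02, y0, spec.labels[e], ha="right", va="center", fontsize=6,
                fontweight=weight, bbox=bbox)
        ax.text(1.02, y1, spec.labels[e], ha="left", va="center", fontsize=6,
                fontweight=weight, bbox=bbox)
    ax.set_xlim(-0.6, 1.6)
    ax.set_ylim(-1, N)
    ax.set_xticks([0.0, 1.0])
    ax.set_xticklabels([left_label, right_label])
    ax.set_yticks([])
    for spine in ax.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, metadata=_stable_metadata(out))
    plt.close(fig)
    return out


def _stable_metadata(path: Path) -> dict | None:
    # strip timestamps so re-rendering is byte-identical
    suffix = path.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None


def render(obj: PVDMatrix | PDGSpec, path: str | Path, **kwargs) -> Path:
    """Render either diagram type to an image file."""
    if isinstance(obj, PVDMatrix):
        return render_pvd(obj, path, **kwargs)
    if isinstance(obj, PDGSpec):
        return render_pdg(obj, path, **kwargs)
    raise TypeError(f"cannot render {type(obj).__name__}")
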