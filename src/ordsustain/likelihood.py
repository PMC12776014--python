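"""The scored-events likelihood.

Given a sequence ``S`` and a stage ``k``, a subject's true underlying levels
are fixed by counting accrued events, and the data likelihood is the product
over symptoms of the evidence vector entry at the underlying level:

    P(x_i | S, k) = prod_b  e_{i,b}[ z_b(S, k) ]

Marginalizing the unknown stage under a stage prior gives the subject
likelihood, and a mixture over subtype sequences with fractions ``f_c`` gives
the full model likelihood.  Everything heavy runs in log space: the stage
log-likelihood matrix of a sequence is a running sum of per-event increments
``log e[level] - log e[level-1]``, which telescopes exactly because events of
a symptom appear in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .dictionary import EventIndex
from .noise import EvidenceTensor
from .sequences import EventSequence, event_arrays, stage_levels

PROB_FLOOR = 1e-12  # guards log(0) on imputed marginals with unobserved levels


@dataclass(frozen=True)
class StagePrior:
    """Prior over the model stage 0..N; default uniform."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("stage prior must be a 1-d probability vector")
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, n_events: int) -> "StagePrior":
        return cls(np.full(n_events + 1, 1.0 / (n_events + 1)))

    @property
    def log_weights(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.weights)


class ScoredEventsLikelihood:
    """Vectorized likelihood engine bound to one evidence tensor.

    Parameters
    ----------
    evidence : EvidenceTensor
    index : EventIndex
        Must enumerate the same symptoms, in the same order.
    prior : StagePrior, optional
        Defaults to uniform over stages ``0..N``.
    """

    def __init__(
        self,
        evidence: EvidenceTensor,
        index: EventIndex,
        prior: StagePrior | None = None,
    ):
        if tuple(evidence.symptom_names) != tuple(index.symptom_names):
            raise ValueError("evidence and event index disagree on symptoms")
        self.evidence = evidence
        self.index = index
        self.n_subjects = evidence.n_subjects
        self.n_events = index.n_events
        self.prior = prior or StagePrior.uniform(self.n_events)
        if len(self.prior.weights) != self.n_events + 1:
            raise ValueError("stage prior length must be n_events + 1")
        self.event_symptom, self.event_rank = event_arrays(index)

        log_e = [np.log(np.clip(v, PROB_FLOOR, None)) for v in evidence.values]
        self.log_base = np.sum([le[:, 0] for le in log_e], axis=0)
        delta = np.empty((self.n_subjects, self.n_events))
        for e in range(self.n_events):
            j = self.event_symptom[e]
            lvl = self.event_rank[e]
            delta[:, e] = log_e[j][:, lvl] - log_e[j][:, lvl - 1]
        self.delta = delta

        # within-symptom consecutive event pairs, for O(1)-ish validity checks
        pairs_a, pairs_b = [], []
        for e in range(self.n_events - 1):
            if self.event_symptom[e + 1] == self.event_symptom[e]:
                pairs_a.append(e)
                pairs_b.append(e + 1)
        self._pairs_a = np.asarray(pairs_a, dtype=np.int64)
        self._pairs_b = np.asarray(pairs_b, dtype=np.int64)

    # -- sequence evaluation -------------------------------------------------

    def is_valid(self, order: np.ndarray) -> bool:
        if self._pairs_a.size == 0:
            return True
        pos = np.empty(self.n_events, dtype=np.int64)
        pos[order] = np.arange(self.n_events)
        return bool(np.all(pos[self._pairs_a] < pos[self._pairs_b]))

    def stage_logliks(self, order: np.ndarray) -> np.ndarray:
        """(n_subjects, k+1) log-likelihood at each stage along ``order``.

        ``order`` may be a prefix of a full sequence (used by greedy
        construction); then only stages ``0..len(order)`` exist.
        """
        order = np.asarray(order, dtype=np.int64)
        out = np.empty((self.n_subjects, order.size + 1))
        out[:, 0] = self.log_base
        if order.size:
            np.cumsum(self.delta[:, order], axis=1, out=out[:, 1:])
            out[:, 1:] += self.log_base[:, None]
        return out

    def subject_logliks(self, order: np.ndarray) -> np.ndarray:
        """Per-subject log of the stage-marginalized likelihood."""
        order = np.asarray(order, dtype=np.int64)
        S = self.stage_logliks(order)
        if order.size == self.n_events:
            logw = self.prior.log_weights
        else:  # prefix sequence: uniform over the available stages
            logw = np.full(order.size + 1, -np.log(order.size + 1))
        # hot path: hand-rolled log-sum-exp beats the general scipy routine
        S += logw[None, :]
        m = S.max(axis=1)
        with np.errstate(invalid="ignore"):
            out = m + np.log(np.exp(S - m[:, None]).sum(axis=1))
        return np.where(np.isfinite(m), out, m)

    def total_loglik(self, order: np.ndarray) -> float:
        return float(np.sum(self.subject_logliks(order)))

    # -- mixtures ------------------------------------------------------------

    def mixture_subject_matrix(self, orders: np.ndarray) -> np.ndarray:
        """(n_subjects, C) per-subtype subject log-likelihoods."""
        orders = np.atleast_2d(np.asarray(orders, dtype=np.int64))
        return np.stack([self.subject_logliks(o) for o in orders], axis=1)

    def mixture_loglik(self, orders: np.ndarray, fractions: np.ndarray) -> float:
        """Total data log-likelihood of a subtype mixture."""
        fractions = np.asarray(fractions, dtype=float)
        if fractions.size == 0:
            raise ValueError("empty mixture")
        if not np.isclose(fractions.sum(), 1.0):
            raise ValueError("mixture fractions must sum to 1")
        A = self.mixture_subject_matrix(orders)
        with np.errstate(divide="ignore"):
            return float(np.sum(logsumexp(A + np.log(fractions)[None, :], axis=1)))

    def subset(self, idx: np.ndarray) -> "ScoredEventsLikelihood":
        return ScoredEventsLikelihood(self.evidence.subset(idx), self.index, self.prior)


# -- reference (linear-space) implementations --------------------------------
#
# Straightforward per-subject product/sum forms of the same quantities.  They
# mirror the definitions one-to-one and serve as the numerical cross-check for
# the log-space engine; do not use them on realistically sized event sets.


def subject_stage_likelihood(
    evidence_row: dict[str, np.ndarray],
    seq: EventSequence,
    k: int,
    index: EventIndex,
) -> float:
    """prod_b evidence[b][z_b(seq, k)] — the stage-conditional likelihood."""
    z = stage_levels(seq, k, index)
    out = 1.0
    for name in index.symptom_names:
        out *= float(evidence_row[name][z[name]])
    return out


def subject_likelihood(
    evidence_row: dict[str, np.ndarray],
    seq: EventSequence,
    prior: StagePrior,
    index: EventIndex,
) -> float:
    """Stage-marginalized subject likelihood under a stage prior."""
    if len(prior.weights) != index.n_events + 1:
        raise ValueError("prior length must be n_events + 1")
    return float(
        sum(
            prior.weights[k] * subject_stage_likelihood(evidence_row, seq, k, index)
            for k in range(index.n_events + 1)
        )
    )


def mixture_loglik(
    evidence: EvidenceTensor,
    sequences: list[EventSequence],
    fractions: np.ndarray,
    index: EventIndex,
    prior: StagePrior | None = None,
) -> float:
    """Reference total mixture log-likelihood (linear-space per subject)."""
    if len(sequences) == 0:
        raise ValueError("empty mixture")
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("mixture fractions must sum to 1")
    prior = prior or StagePrior.uniform(index.n_events)
    total = 0.0
    for i in range(evidence.n_subjects):
        row = {
            name: evidence.values[j][i]
            for j, name in enumerate(evidence.symptom_names)
        }
        lik = sum(
            f * subject_likelihood(row, s, prior, index)
            for f, s in zip(fractions, sequences)
        )
        total += np.log(lik)
    return float(total)


def exact_sequence_posterior(
    engine: ScoredEventsLikelihood,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Posterior over *all* valid sequences by exhaustive enumeration.

    Uniform prior over valid orderings.  Returns the sequences and their
    normalized posterior probabilities.  Exponential in the event count;
    intended as the exact oracle on small instances.
    """
    from .sequences import enumerate_valid_sequences

    seqs = list(enumerate_valid_sequences(engine.index))
    logliks = np.array([engine.total_loglik(s) for s in seqs])
    post = np.exp(logliks - logsumexp(logliks))
    return seqs, post / post.sum()


def position_marginals(seqs: list[np.ndarray], weights: np.ndarray) -> np.ndarray:
    """(event, position) occupancy probabilities of a weighted sequence set."""
    n = len(seqs[0])
    M = np.zeros((n, n))
    for s, w in zip(seqs, weights):
        M[s, np.arange(n)] += w
    return M / weights.sum()
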