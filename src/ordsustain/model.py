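"""Model fitting: greedy ascent, Metropolis-Hastings MCMC and subtyping.

`OrdinalSuStaIn` is the user-facing model object, built from an evidence
tensor (or directly from a cohort) and a subtype count ``C``.  ``fit()``
returns a :class:`SubtypeFit` results object carrying the maximum-likelihood
sequences, mixture fractions, the MCMC posterior samples and staging/
summary/plotting helpers.

The sampler walks the space of valid orderings with a symmetric single-event
relocation proposal (draw an event and a new position uniformly; orderings
violating ordinal monotonicity are rejected before any likelihood work), so
the Hastings correction is 1 and acceptance is by likelihood ratio under a
uniform prior over valid orderings.  Mixture fractions are point-optimized by
EM at a fixed cadence rather than sampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import Cohort
from .dictionary import EventIndex, SymptomDictionary, build_event_index
from .likelihood import ScoredEventsLikelihood, StagePrior
from .noise import EvidenceTensor, NoiseModel, build_evidence, estimate_correct_scoring
from .sequences import EventSequence, random_valid_sequence


@dataclass(frozen=True)
class MCMCSettings:
    """Chain settings; the defaults favour reproducible desk-scale runs."""

    n_iter: int = 100_000
    burn_in: float = 0.1  # fraction of iterations discarded
    thinning: int = 10
    n_restarts: int = 4  # greedy initializer restarts
    em_every: int = 100  # EM fraction-update cadence (iterations)
    n_startpoints: int = 5  # random bipartitions tried per cluster split

    def scaled(self, fraction: float) -> "MCMCSettings":
        """Same settings with the iteration budget scaled down."""
        return replace(self, n_iter=max(1, int(self.n_iter * fraction)))


# ---------------------------------------------------------------------------
# fitting primitives


def _greedy_improve(
    engine: ScoredEventsLikelihood, order: np.ndarray, max_passes: int = 20
) -> tuple[np.ndarray, float]:
    """Relocation hill-climbing until no single move improves the likelihood."""
    order = order.copy()
    best = engine.total_loglik(order)
    n = order.size
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            e = order[i]
            rest = np.delete(order, i)
            for j in range(n):
                if j == i:
                    continue
                cand = np.insert(rest, j, e)
                if not engine.is_valid(cand):
                    continue
                ll = engine.total_loglik(cand)
                if ll > best + 1e-12:
                    order, best = cand, ll
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return order, best


def greedy_fit_sequence(
    engine: ScoredEventsLikelihood,
    rng: np.random.Generator,
    n_restarts: int = 4,
) -> tuple[np.ndarray, float]:
    """Best sequence from randomized greedy insertion plus improvement passes.

    Each restart inserts the events in a random (monotonicity-respecting)
    order, each at its best valid position of the partial sequence, then
    polishes with single-event relocation until a local optimum.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best_order: np.ndarray | None = None
    best_ll = -np.inf
    for _ in range(n_restarts):
        insertion = random_valid_sequence(engine.index, rng).array
        order = np.empty(0, dtype=np.int64)
        for e in insertion:
            cand_best, cand_ll = None, -np.inf
            for j in range(order.size + 1):
                cand = np.insert(order, j, e)
                # partial prefixes only need the within-prefix constraint
                if not _prefix_valid(cand, engine):
                    continue
                ll = float(np.sum(engine.subject_logliks(cand)))
                if ll > cand_ll:
                    cand_best, cand_ll = cand, ll
            order = cand_best
        order, ll = _greedy_improve(engine, order)
        if ll > best_ll:
            best_order, best_ll = order, ll
    return best_order, best_ll


def _prefix_valid(prefix: np.ndarray, engine: ScoredEventsLikelihood) -> bool:
    seen: dict[int, int] = {}
    for e in prefix:
        s = int(engine.event_symptom[e])
        r = int(engine.event_rank[e])
        if r != seen.get(s, 0) + 1:
            return False
        seen[s] = r
    return True


def _em_fractions(A: np.ndarray, f: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """EM point-optimization of mixture fractions given subject loglik matrix."""
    f = f.copy()
    for _ in range(n_iter):
        with np.errstate(divide="ignore"):
            logr = A + np.log(np.clip(f, 1e-300, None))[None, :]
        logr -= logsumexp(logr, axis=1, keepdims=True)
        new = np.exp(logr).mean(axis=0)
        new /= new.sum()
        if np.allclose(new, f, atol=1e-10):
            f = new
            break
        f = new
    return f


@dataclass
class _MCMCState:
    orders: np.ndarray  # (C, N)
    fractions: np.ndarray  # (C,)
    A: np.ndarray  # (n_subjects, C) subject logliks per subtype
    loglik: float


def _mixture_ll(A: np.ndarray, f: np.ndarray) -> float:
    if A.shape[1] == 1:
        return float(A.sum())
    with np.errstate(divide="ignore"):
        B = A + np.log(np.clip(f, 1e-300, None))[None, :]
    m = B.max(axis=1)
    return float(np.sum(m + np.log(np.exp(B - m[:, None]).sum(axis=1))))


def mcmc_sample(
    engine: ScoredEventsLikelihood,
    init_orders: np.ndarray,
    init_fractions: np.ndarray,
    settings: MCMCSettings,
    rng: np.random.Generator,
    optimize_fractions: bool = True,
) -> dict:
    """Metropolis-Hastings over (tuples of) valid orderings.

    Returns a dict with thinned post-burn-in samples (`orders`, `fractions`,
    `loglik`), the best state visited, and the acceptance rate.
    """
    if settings.n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    orders = np.atleast_2d(np.asarray(init_orders, dtype=np.int64)).copy()
    C, N = orders.shape
    f = np.asarray(init_fractions, dtype=float).copy()
    A = engine.mixture_subject_matrix(orders)
    if optimize_fractions and C > 1:
        f = _em_fractions(A, f)
    state = _MCMCState(orders, f, A, _mixture_ll(A, f))
    best = (orders.copy(), f.copy(), state.loglik)

    burn = int(settings.burn_in * settings.n_iter)
    samples_orders, samples_f, samples_ll = [], [], []
    n_accept = 0

    for it in range(settings.n_iter):
        c = int(rng.integers(C)) if C > 1 else 0
        order = state.orders[c]
        i = int(rng.integers(N))
        j = int(rng.integers(N))
        accepted = False
        if i != j:
            e = order[i]
            cand = np.insert(np.delete(order, i), j, e)
            if engine.is_valid(cand):
                a_new = engine.subject_logliks(cand)
                A_new = state.A.copy()
                A_new[:, c] = a_new
                ll_new = _mixture_ll(A_new, state.fractions)
                if np.log(rng.random()) < ll_new - state.loglik:
                    state.orders[c] = cand
                    state.A = A_new
                    state.loglik = ll_new
                    accepted = True
        n_accept += accepted
        if optimize_fractions and C > 1 and (it + 1) % settings.em_every == 0:
            f_new = _em_fractions(state.A, state.fractions)
            state.fractions = f_new
            state.loglik = _mixture_ll(state.A, f_new)
        if state.loglik > best[2]:
            best = (state.orders.copy(), state.fractions.copy(), state.loglik)
        if it >= burn and (it - burn) % settings.thinning == 0:
            samples_orders.append(state.orders.copy())
            samples_f.append(state.fractions.copy())
            samples_ll.append(state.loglik)

    return {
        "samples_orders": np.array(samples_orders, dtype=np.int64),
        "samples_fractions": np.array(samples_f),
        "samples_loglik": np.array(samples_ll),
        "ml_orders": best[0],
        "ml_fractions": best[1],
        "ml_loglik": best[2],
        "acceptance_rate": n_accept / settings.n_iter,
    }


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class StageAssignment:
    """Per-subject posterior over (subtype, stage) with ML point calls.

    Subjects whose most likely stage is 0 have accrued no detectable events
    and are flagged unclassifiable: their subtype call carries no signal and
    they are excluded from subtype demographic summaries.
    """

    posterior: np.ndarray  # (n_subjects, C, N+1)
    ml_subtype: np.ndarray
    ml_stage: np.ndarray
    classifiable: np.ndarray
    participant_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        n = self.posterior.shape[0]
        ids = self.participant_ids or tuple(str(i) for i in range(n))
        p_max = self.posterior.reshape(n, -1).max(axis=1)
        return pd.DataFrame(
            {
                "participant_id": ids,
                "ml_subtype": self.ml_subtype,
                "ml_stage": self.ml_stage,
                "classifiable": self.classifiable,
                "p_max": p_max,
            }
        )


def assign_stages(
    engine: ScoredEventsLikelihood,
    orders: np.ndarray,
    fractions: np.ndarray,
) -> StageAssignment:
    """Joint subtype-and-stage posterior: ``post(c,k) ∝ f_c prior_k P(x|S_c,k)``.

    Argmax ties break toward the smallest stage, then the smallest subtype.
    """
    orders = np.atleast_2d(np.asarray(orders, dtype=np.int64))
    C = orders.shape[0]
    n = engine.n_subjects
    N = engine.n_events
    logp = np.empty((n, C, N + 1))
    with np.errstate(divide="ignore"):
        logf = np.log(np.clip(np.asarray(fractions, dtype=float), 1e-300, None))
    for c in range(C):
        logp[:, c, :] = (
            engine.stage_logliks(orders[c])
            + engine.prior.log_weights[None, :]
            + logf[c]
        )
    flat = logp.reshape(n, -1)
    flat = flat - logsumexp(flat, axis=1, keepdims=True)
    posterior = np.exp(flat).reshape(n, C, N + 1)
    # scan order (stage-major, then subtype) encodes the tie-break
    scan = np.transpose(posterior, (0, 2, 1)).reshape(n, -1)
    arg = np.argmax(np.isclose(scan, scan.max(axis=1, keepdims=True)), axis=1)
    ml_stage = arg // C
    ml_subtype = arg % C
    return StageAssignment(
        posterior=posterior,
        ml_subtype=ml_subtype,
        ml_stage=ml_stage,
        classifiable=ml_stage > 0,
        participant_ids=tuple(engine.evidence.participant_ids),
    )


@dataclass(frozen=True)
class SubtypeFit:
    """Results of fitting an :class:`OrdinalSuStaIn` model.

    Carries the maximum-likelihood sequences and fractions, the thinned MCMC
    posterior samples, and the chain provenance (seed, settings).
    """

    model: "OrdinalSuStaIn"
    n_subtypes: int
    sequences: tuple[EventSequence, ...]
    fractions: np.ndarray
    samples_orders: np.ndarray  # (S, C, N)
    samples_fractions: np.ndarray  # (S, C)
    samples_loglik: np.ndarray  # (S,)
    loglik: float
    acceptance_rate: float
    seed: int
    settings: MCMCSettings

    def __post_init__(self) -> None:
        if self.samples_orders.shape[0] == 0:
            raise ValueError("fit carries no posterior samples")
        if not np.isclose(np.sum(self.fractions), 1.0):
            raise ValueError("fractions must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.samples_orders.shape[0]

    @property
    def ml_orders(self) -> np.ndarray:
        return np.array([s.order for s in self.sequences], dtype=np.int64)

    def stage_assignments(self, engine: ScoredEventsLikelihood | None = None) -> StageAssignment:
        engine = engine or self.model.engine
        return assign_stages(engine, self.ml_orders, self.fractions)

    def mean_sample_loglik(self, engine: ScoredEventsLikelihood | None = None) -> float:
        """Data log-likelihood averaged over the posterior samples.

        With an ``engine`` for held-out evidence this is the out-of-fold
        log-likelihood contribution of that fold.
        """
        engine = engine or self.model.engine
        vals = [
            engine.mixture_loglik(self.samples_orders[s], self.samples_fractions[s])
            for s in range(self.n_samples)
        ]
        return float(np.mean(vals))

    def pvd(self, subtype: int = 0):
        from .viz import pvd_matrix

        return pvd_matrix(self, subtype)

    def relabel_by_covariate(self, values: np.ndarray, descending: bool = True) -> "SubtypeFit":
        """Reorder subtype labels by a per-subject covariate mean (e.g. CGG).

        Mirrors labelling subtypes in descending order of mean CGG repeats;
        the default ordering is by descending mixture fraction.
        """
        assign = self.stage_assignments()
        values = np.asarray(values, dtype=float)
        means = np.array(
            [
                np.nanmean(values[(assign.ml_subtype == c) & assign.classifiable])
                if np.any((assign.ml_subtype == c) & assign.classifiable)
                else -np.inf
                for c in range(self.n_subtypes)
            ]
        )
        perm = np.argsort(-means if descending else means, kind="stable")
        return self._permute_subtypes(perm)

    def _permute_subtypes(self, perm: np.ndarray) -> "SubtypeFit":
        return replace(
            self,
            sequences=tuple(self.sequences[c] for c in perm),
            fractions=self.fractions[perm],
            samples_orders=self.samples_orders[:, perm, :],
            samples_fractions=self.samples_fractions[:, perm],
        )

    def summary(self) -> str:
        index = self.model.event_index
        lines = [
            "Ordinal subtype-and-stage fit",
            "=" * 64,
            f"subjects: {self.model.engine.n_subjects}    events: {index.n_events}"
            f"    subtypes: {self.n_subtypes}",
            f"log-likelihood (ML): {self.loglik:.2f}"
            f"    posterior samples: {self.n_samples}"
            f"    acceptance rate: {self.acceptance_rate:.3f}",
            f"seed: {self.seed}    chain: {self.settings.n_iter} iter, "
            f"burn-in {self.settings.burn_in:.0%}, thinning {self.settings.thinning}",
            "-" * 64,
        ]
        for c, (seq, f) in enumerate(zip(self.sequences, self.fractions)):
            lines.append(f"subtype {c + 1}  (fraction {f:.3f}) event order:")
            for q, lab in enumerate(seq.labels(index), start=1):
                lines.append(f"  {q:3d}. {lab}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        index = self.model.event_index
        return {
            "n_subtypes": self.n_subtypes,
            "sequences": [s.labels(index) for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "loglik": self.loglik,
            "acceptance_rate": self.acceptance_rate,
            "seed": self.seed,
            "settings": {
                "n_iter": self.settings.n_iter,
                "burn_in": self.settings.burn_in,
                "thinning": self.settings.thinning,
                "n_restarts": self.settings.n_restarts,
                "em_every": self.settings.em_every,
                "n_startpoints": self.settings.n_startpoints,
            },
            "samples_orders": self.samples_orders.tolist(),
            "samples_fractions": self.samples_fractions.tolist(),
            "samples_loglik": self.samples_loglik.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")


# ---------------------------------------------------------------------------
# model


class OrdinalSuStaIn:
    """Ordinal subtype-and-stage inference model.

    Parameters
    ----------
    evidence : EvidenceTensor
        Case evidence vectors (observed through the noise model, missing
        cells softly imputed).
    event_index : EventIndex
    n_subtypes : int
        Number of latent subtypes ``C``; subgroup analyses use ``C=1``.
    stage_prior : StagePrior, optional
        Defaults to uniform over stages ``0..N``.
    """

    def __init__(
        self,
        evidence: EvidenceTensor,
        event_index: EventIndex,
        n_subtypes: int = 1,
        stage_prior: StagePrior | None = None,
    ):
        if n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if n_subtypes > evidence.n_subjects:
            raise ValueError("more subtypes than subjects")
        self.evidence = evidence
        self.event_index = event_index
        self.n_subtypes = n_subtypes
        self.engine = ScoredEventsLikelihood(evidence, event_index, stage_prior)
        self.dictionary: SymptomDictionary | None = None  # set by from_cohort

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        dictionary: SymptomDictionary,
        n_subtypes: int = 1,
        cap: float = 0.95,
        floor: float = 0.5,
        noise: NoiseModel | None = None,
        stage_prior: StagePrior | None = None,
    ) -> "OrdinalSuStaIn":
        """Build the model straight from a case/control cohort table."""
        noise = noise or estimate_correct_scoring(cohort, dictionary, cap=cap, floor=floor)
        evidence = build_evidence(cohort, dictionary, noise)
        index = build_event_index(dictionary)
        obj = cls(evidence, index, n_subtypes=n_subtypes, stage_prior=stage_prior)
        obj.dictionary = dictionary
        return obj

    def fit(
        self,
        seed: int = 0,
        settings: MCMCSettings | None = None,
    ) -> SubtypeFit:
        """Greedy initialization followed by MCMC refinement.

        For ``C > 1`` subtypes the solution is grown hierarchically from the
        ``C-1`` fit by cluster splitting (see :func:`fit_subtypes`); this
        method returns the fit for this model's own ``C``.
        """
        fits = fit_subtypes(
            self.engine,
            C_max=self.n_subtypes,
            settings=settings or MCMCSettings(),
            seed=seed,
            model=self,
        )
        return fits[self.n_subtypes]


def _fit_from_sampler(
    model: OrdinalSuStaIn, out: dict, seed: int, settings: MCMCSettings
) -> SubtypeFit:
    return SubtypeFit(
        model=model,
        n_subtypes=out["ml_orders"].shape[0],
        sequences=tuple(EventSequence(tuple(o)) for o in out["ml_orders"]),
        fractions=np.asarray(out["ml_fractions"], dtype=float),
        samples_orders=out["samples_orders"],
        samples_fractions=out["samples_fractions"],
        samples_loglik=out["samples_loglik"],
        loglik=out["ml_loglik"],
        acceptance_rate=out["acceptance_rate"],
        seed=seed,
        settings=settings,
    )


def fit_subtypes(
    engine: ScoredEventsLikelihood,
    C_max: int,
    settings: MCMCSettings | None = None,
    seed: int = 0,
    model: OrdinalSuStaIn | None = None,
) -> dict[int, SubtypeFit]:
    """Hierarchical subtype fitting for ``C = 1 .. C_max``.

    The ``C``-subtype solution is seeded from the ``C-1`` solution: each
    existing cluster is split by random bipartition (``n_startpoints`` tries),
    each half seeding a greedy sequence fit; the best-likelihood split is kept
    and the whole mixture refined jointly by MCMC.
    """
    settings = settings or MCMCSettings()
    if C_max < 1:
        raise ValueError("C_max must be >= 1")
    if C_max > engine.n_subjects:
        raise ValueError("C_max exceeds the number of subjects")
    rng = np.random.default_rng(seed)
    fits: dict[int, SubtypeFit] = {}

    base_model = model if (model is not None and model.n_subtypes == 1) else OrdinalSuStaIn(
        engine.evidence, engine.index, n_subtypes=1, stage_prior=engine.prior
    )
    order0, _ = greedy_fit_sequence(engine, rng, n_restarts=settings.n_restarts)
    out = mcmc_sample(engine, order0[None, :], np.array([1.0]), settings, rng)
    fits[1] = _fit_from_sampler(base_model, out, seed, settings)

    for C in range(2, C_max + 1):
        prev = fits[C - 1]
        assign = assign_stages(engine, prev.ml_orders, prev.fractions)
        best_orders, best_f, best_ll = None, None, -np.inf
        for c_split in range(C - 1):
            members = np.flatnonzero(assign.ml_subtype == c_split)
            if members.size < 2:
                continue
            sub_engine = engine.subset(members)
            for _ in range(settings.n_startpoints):
                mask = rng.random(members.size) < 0.5
                if mask.all() or not mask.any():
                    continue
                halves = []
                for half_mask in (mask, ~mask):
                    half = sub_engine.subset(np.flatnonzero(half_mask))
                    o, _ = greedy_fit_sequence(half, rng, n_restarts=1)
                    halves.append(o)
                orders = np.vstack(
                    [np.delete(prev.ml_orders, c_split, axis=0)] + [h[None, :] for h in halves]
                )
                f0 = np.full(C, 1.0 / C)
                A = engine.mixture_subject_matrix(orders)
                f_opt = _em_fractions(A, f0)
                ll = _mixture_ll(A, f_opt)
                if ll > best_ll:
                    best_orders, best_f, best_ll = orders, f_opt, ll
        if best_orders is None:  # degenerate clusters everywhere: random restart
            best_orders = np.vstack(
                [prev.ml_orders, random_valid_sequence(engine.index, rng).array[None, :]]
            )
            best_f = np.full(C, 1.0 / C)
        c_model = OrdinalSuStaIn(
            engine.evidence, engine.index, n_subtypes=C, stage_prior=engine.prior
        ) if (model is None or model.n_subtypes != C) else model
        out = mcmc_sample(engine, best_orders, best_f, settings, rng)
        fits[C] = _fit_from_sampler(c_model, out, seed, settings)
    return fits
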