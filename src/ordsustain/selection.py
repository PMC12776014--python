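"""Choosing the number of subtypes by k-fold cross-validation.

For each candidate subtype count ``C`` and each fold, the mixture is fitted
on the training cases and the held-out cases' total log-likelihood, averaged
over the fit's MCMC posterior samples, is the out-of-fold log-likelihood
(OOFLL).  The cross-validation information criterion aggregates folds:

    CVIC(C) = sum over folds of  -2 * OOFLL(C, fold)

Lower is better.  `choose_C` applies parsimony: the smallest ``C`` whose CVIC
is within a small tolerance of the minimum — a flat CVIC profile then yields
the simplest model rather than the literal argmin.

Held-out evidence keeps the noise model and imputation marginals estimated
on the full dataset: they are measurement-model constants calibrated from
controls, not per-fold parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .likelihood import ScoredEventsLikelihood
from .model import MCMCSettings, fit_subtypes


@dataclass(frozen=True)
class CVResult:
    """Per-(C, fold) OOFLL, per-C CVIC and the parsimony choice of C."""

    folds: int
    oofll: dict[tuple[int, int], float]  # (C, fold) -> held-out mean loglik
    cvic: dict[int, float]
    chosen_C: int
    fold_assignments: dict[str, int]
    seed: int

    def oofll_frame(self) -> pd.DataFrame:
        rows = [
            {"C": C, "fold": fold, "oofll": v} for (C, fold), v in sorted(self.oofll.items())
        ]
        return pd.DataFrame(rows)

    def cvic_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"C": sorted(self.cvic), "cvic": [self.cvic[C] for C in sorted(self.cvic)]}
        )


def choose_C(cv: CVResult | dict[int, float], tolerance: float = 0.01) -> int:
    """Smallest C whose CVIC is within ``tolerance * |min CVIC|`` of the minimum."""
    cvic = cv.cvic if isinstance(cv, CVResult) else cv
    if not cvic:
        raise ValueError("no CVIC values")
    best = min(cvic.values())
    cutoff = best + tolerance * abs(best)
    return min(C for C, v in cvic.items() if v <= cutoff)


def crossvalidate(
    engine: ScoredEventsLikelihood,
    C_range: list[int] | range,
    k_folds: int = 10,
    seed: int = 0,
    settings: MCMCSettings | None = None,
    stratify_by: np.ndarray | None = None,
    tolerance: float = 0.01,
) -> CVResult:
    """k-fold cross-validation of subtype counts with OOFLL and CVIC.

    Parameters
    ----------
    engine : ScoredEventsLikelihood
        Evidence for the full case set.
    C_range : iterable of int
        Candidate subtype counts (each fold fits up to ``max(C_range)``
        hierarchically, so the per-fold cost is a single growth pass).
    stratify_by : array, optional
        Covariate labels to stratify fold assignment on.
    """
    settings = settings or MCMCSettings()
    C_range = sorted(set(int(C) for C in C_range))
    if not C_range or C_range[0] < 1:
        raise ValueError("C_range must contain positive integers")
    n = engine.n_subjects
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError(f"k_folds ({k_folds}) exceeds the number of cases ({n})")

    if stratify_by is not None:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), np.asarray(stratify_by))
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))

    ids = engine.evidence.participant_ids or tuple(str(i) for i in range(n))
    oofll: dict[tuple[int, int], float] = {}
    fold_assignments: dict[str, int] = {}
    for fold, (train_idx, test_idx) in enumerate(splits):
        for i in test_idx:
            fold_assignments[ids[i]] = fold
        if max(C_range) > train_idx.size:
            raise ValueError("C larger than the training-fold size")
        train = engine.subset(train_idx)
        test = engine.subset(test_idx)
        fits = fit_subtypes(train, C_max=max(C_range), settings=settings, seed=seed + fold)
        for C in C_range:
            oofll[(C, fold)] = fits[C].mean_sample_loglik(test)

    cvic = {
        C: float(sum(-2.0 * oofll[(C, fold)] for fold in range(k_folds)))
        for C in C_range
    }
    result = CVResult(
        folds=k_folds,
        oofll=oofll,
        cvic=cvic,
        chosen_C=0,
        fold_assignments=fold_assignments,
        seed=seed,
    )
    return CVResult(
        folds=k_folds,
        oofll=oofll,
        cvic=cvic,
        chosen_C=choose_C(result, tolerance=tolerance),
        fold_assignments=fold_assignments,
        seed=seed,
    )
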