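# Methods

This note documents the statistical model implemented by `ordsustain`, the
choices made where the design was genuinely open, the defaults and why, and
what the synthetic-data generator does and does not emulate.

## Data model

The unit of analysis is a wide cohort table: one row per participant with a
`case`/`control` label, optional stratifying covariates (sex, CGG-repeat
class, ...) and one ordinal value per symptom; an empty cell is a missing
value. A JSON symptom dictionary — not inferred from the data, so that
levels with zero observations still exist — defines each symptom's ordered
levels. Level indices are 0-based with 0 always the reference level. Each
elevated level is one event; a symptom with `L` levels contributes `L - 1`
events and the ordering constraint is that a symptom's events appear in
ascending level order (an ordinal scale cannot skip backwards).

The built-in FXTAS dictionary has 27 clinical, neuropsychological and MRI
symptoms with 2–6 levels each (36 events). The clinical FXTAS stage (0–5)
can be included as a 28th ordinal variable (41 events); it is flagged as the
*staging anchor*, which makes its events render as black reference lines in
positional difference graphs so that other symptoms can be read as occurring
"before stage 2", "between stages 3 and 4", and so on.

Sparse levels make the likelihood uninformative. `check_level_support`
reports every elevated level with fewer than three case observations but
never merges automatically: merging is an explicit `merge_levels` call
(contiguous elevated levels only; the merged level is labelled by joining
the originals, e.g. `Moderate/Severe`), because sensible merges depend on
instrument semantics that the data cannot supply.

## Measurement noise and missing data

Each symptom has one correct-scoring probability `p_b`: the chance an
observed score equals the true underlying level. It is estimated from
controls as the fraction of observed controls at the reference level,

- **capped at 0.95**, so that some background prevalence of symptoms
  unrelated to disease progression is always allowed for;
- **floored at 0.5** (configurable, with a logged warning), a guard we add
  because a symptom highly prevalent in controls would otherwise make an
  observed score evidence *against* the matching underlying level.

The misclassification mass `1 - p_b` is spread uniformly over the `L_b - 1`
non-true levels. The noise model specifies only the correct-scoring
probability; uniform spread is the minimal-assumption completion, conserves
probability exactly, and is exact for binary symptoms.

Missing values are assumed missing at random (plausible when missingness
stems from instruments being added to a protocol over time). A missing cell
contributes *soft evidence*: its evidence vector is the marginal level
distribution among observed cases for that symptom, used as-is (not
convolved again with the noise model — the marginal already describes
observed scores). This makes runs deterministic given the data; no sampled
imputations, and consequently no between-imputation variance component.
Marginals are computed from cases only, never controls or the pooled sample.

## Likelihood

For sequence `S`, stage `k` and subject `i`,
`P(x_i | S, k) = Π_b e_{i,b}[z_b(S, k)]` with `z_b(S, k)` the level implied
by counting `b`'s events among the first `k` positions. Stages are
marginalized under a stage prior, uniform over `0..N` by default (an
observed-stage-frequency weighting can be supplied); model stage 0 ("no
events yet") is distinct from clinical FXTAS stage 0, which enters only as
data. Subtypes form a finite mixture with fractions `f_c`.

All heavy computation runs in log space. The stage log-likelihood row of a
sequence is a cumulative sum of per-event increments
`log e[level] - log e[level - 1]`, which telescopes exactly because events
of one symptom occur in ascending order; this makes one sequence evaluation
`O(n_subjects × N)`. Evidence entries are clipped at 1e-12 before taking
logs so that imputed marginals with unobserved levels cannot produce
NaNs. A straightforward linear-space implementation of the same quantities
is kept alongside and pinned to the log-space engine to 1e-9 in the tests.

## Fitting

**Initialization.** Randomized greedy insertion: events are taken in a
random monotonicity-respecting order and each inserted at the best valid
position of the growing partial sequence (scored with a uniform prior over
the stages that exist so far), followed by single-event relocation
hill-climbing to a local optimum; the best of `n_restarts` restarts wins.

**MCMC.** Metropolis–Hastings over valid orderings. The proposal relocates
one uniformly chosen event to a uniformly chosen position; proposals that
violate ordinal monotonicity are rejected before any likelihood work. The
proposal is symmetric, so acceptance is by likelihood ratio under the
uniform prior over valid orderings. For mixtures, each iteration perturbs
one subtype's sequence; mixture fractions are point-optimized by EM every
`em_every` iterations (they are not sampled, so the posterior samples
carry the fractions current at each draw). Chains are reproducible given
the seed. Defaults: 100 000 iterations, 10% burn-in, thinning 10,
`em_every=100` — these are desk-scale completions, configurable, not
prescribed by the method itself.

**Subtype hierarchy.** The `C`-subtype solution is grown from the `C-1`
solution: each existing cluster (by most-likely-subtype membership) is
randomly bipartitioned `n_startpoints` times, each half seeds a greedy
sequence fit, the best-likelihood split is kept, and the whole mixture is
refined by joint MCMC. `C = 1` is exactly greedy + MCMC.

**Staging.** The per-subject posterior over (subtype, stage) is
`∝ f_c · prior_k · P(x_i | S_c, k)`. Point calls use the argmax with ties
broken toward the smallest stage, then the smallest subtype index
(determinism). Subjects whose most likely stage is 0 have accrued no
detectable events; they are flagged unclassifiable and excluded from
subtype demographic summaries. Subtype labels order by descending mixture
fraction; `relabel_by_covariate` reorders them by a covariate mean (e.g.
descending mean CGG repeats) as a post-processing option.

## Choosing the number of subtypes

k-fold cross-validation over the cases (10 folds by default, optionally
stratified on a covariate). Per fold and per `C`, the mixture is fitted on
the training cases and the held-out total log-likelihood is averaged over
the fit's posterior samples — the OOFLL. The criterion is

    CVIC(C) = Σ_folds  −2 × OOFLL(C, fold)

(lower is better); this operationalizes the cited SuStaIn convention, which
names but does not define the quantity. `choose_C` returns the smallest `C`
whose CVIC is within `tolerance × |min CVIC|` (default 1%) of the minimum —
a codified parsimony rule. A genuinely flat CVIC profile is a judgement
call in practice; the tolerance makes the rule explicit and testable but
cannot reproduce clinical-interpretability judgements. Held-out evidence
reuses the noise model and imputation marginals estimated on the full
dataset: they are measurement-model constants calibrated once from
controls, not per-fold parameters.

## Group comparison

To test whether two or more strata (sex, CGG class, their combination)
share an event sequence, a single-subtype model is fitted per stratum (no
latent clusters in subgroup analyses), the stratum log-likelihood is
averaged over posterior samples and summed across strata. The null
distribution comes from `B` refits after shuffling the stratifying label
among the same participants (evidence and noise model fixed; only the
label moves). The two-sided empirical p-value doubles the reflected
percentile (midrank for ties) of the observed statistic in the permuted
distribution; when the observed value falls outside the permuted range,
only the resolution bound `1/B` can be reported, and `p_is_bound` marks it.
`B = 1000` by default.

Permuted replicates default to the *same* MCMC budget as the observed
statistic (`permuted_budget_fraction = 1.0`): the test uses only ranks, and
equal budgets keep the observed statistic exchangeable with the permuted
ones under the null, which is what makes the test exact. The fraction is
configurable downward when wall-clock dominates; since only ranks matter,
moderate reductions perturb the test little, but they do break strict
exchangeability, so the calibration-sensitive default is 1.0.

## Synthetic cohorts

`generate_cohort` draws, per case: a subtype from the mixture fractions, a
stage from the stage distribution (uniform over `0..N` unless given), the
implied underlying levels, then observes each symptom through the noise
channel (correct with probability `p_correct`, else uniform over other
levels) and masks values missing-at-random at a per-symptom rate. Controls
sit at reference for every symptom and pass through the same noise channel
and missingness. Defaults mirror the emulated study's scale: 253 cases, 44
controls, the 28-symptom dictionary, ~60% male cases, `p_correct = 0.9`
(a realistic instrument reliability in this setting), and 11.5% missingness
per symptom (the level of missingness reported for ataxia severity in the
emulated cohort). An optional covariate–sequence coupling
(`sequence_by_stratum`) assigns strata different generating sequences to
power group-comparison tests; it is off by default.

What the generator does **not** emulate: real covariate joint distributions
(age, CGG length as numbers), correlated measurement errors across
symptoms, informative missingness, longitudinal visits, or symptom
prevalences tied to particular instruments. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions — not robustness to the ways real clinical data
violate them.

## Visualization

The positional variance diagram (PVD) entry `(e, q)` is the fraction of
posterior samples placing event `e` at position `q`; as an average of
permutation matrices it is doubly stochastic, which the tests pin to 1e-9.
Rows are displayed sorted by most-likely position (argmax of the row), with
ties broken by earliest mean position, then event id. The positional
difference graph (PDG) connects each event's most-likely position in two
fits; "most-likely position" is the argmax of the event's PVD row, matching
PVD brightness semantics. Line colour encodes direction (earlier/later/
same), opacity is proportional to the position delta, and the staging-anchor
symptom's events are drawn black. The position axis is sequence position,
not calendar time — the method cannot date event onsets, only order them.
Rendering uses a colour-blind-safe Okabe–Ito palette and writes
deterministic SVG/PNG (fixed hash salt, timestamp metadata stripped), so
re-rendering the same object is byte-identical.

## Numerical and testing choices

Problem sizes in the test-suite simulations are deliberately modest — e.g.
sequence recovery at n=300 subjects and N=14 events over 10 seeds, subtype
recovery at n=300 with two opposite orderings, permutation-test calibration
at 200 replicates of B=200 with 24-case cohorts and short chains — chosen
as the smallest instances that still discriminate correct from incorrect
implementations. In the two-subtype recovery scenario the stage
distribution concentrates on interior stages (2–8 of 10): subjects at stage
0 or N have identical level profiles under both orderings, so their subtype
is unidentifiable by construction and any accuracy target must be assessed
where the signal exists.

Known limitations: no continuous (z-score) biomarker likelihood; no
longitudinal/time-to-event modelling; no reversible-jump over the subtype
count (each `C` is fitted explicitly); no multiple-testing correction
across subgroup contrasts; EM point estimates rather than posterior
sampling for mixture fractions.
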