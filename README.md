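# ordsustain

Ordinal event-based subtype and stage inference for cross-sectional
case/control cohorts of scored clinical symptoms.

## The problem

In slowly progressing neurodegenerative conditions such as the fragile
X-associated tremor/ataxia syndrome (FXTAS), the order in which symptoms
appear — tremor, ataxia, psychiatric co-morbidities, MRI white-matter
changes — is scientifically central but hard to observe directly: cohorts
are cross-sectional or sparsely longitudinal, and symptom onset times are
unknown. Event-based disease progression modelling sidesteps onset times by
treating each transition of an ordinal symptom to its next clinically
elevated level as an *event* and inferring the most probable total ordering
of all events from a single cross-section of patients at mixed disease
stages, using a control group to calibrate measurement noise.

`ordsustain` implements the ordinal ("scored events") variant of subtype and
stage inference (SuStaIn) for this setting: sequence estimation by MCMC over
constrained permutations, latent subtype mixtures, per-patient staging,
cross-validated choice of the number of subtypes, a permutation test for
sequence differences between subgroups (e.g. males vs females), and the
field's standard visualizations (positional variance diagrams, positional
difference graphs). A synthetic-cohort generator with known ground truth
makes every stage of the pipeline testable without patient data.

## The model

Each symptom `b` has ordered levels `0..L_b - 1` (level 0 = reference);
symptom `b` contributes `L_b - 1` events, and `N = Σ_b (L_b - 1)` events in
total. A disease sequence `S` is a permutation of the events in which each
symptom's levels appear in ascending order. A subject at stage
`k ∈ {0..N}` has underlying level `z_b(S, k)` = the number of `b`'s events
among the first `k` of `S`. Observed scores are noisy readouts of the
underlying level: with probability `p_b` the score is correct, otherwise it
is uniform over the other levels. `p_b` is estimated as the fraction of
controls observed at the reference level, capped at 0.95 and floored at 0.5.
Missing values contribute soft evidence equal to the marginal level
distribution observed among cases.

The likelihood of subject `i` under sequence `S` and a uniform stage prior is

    P(x_i | S) = (1 / (N+1)) Σ_k  Π_b  e_{i,b}[ z_b(S, k) ]

where `e_{i,b}` is the subject's evidence vector for symptom `b`. With `C`
latent subtypes, sequences `S_1..S_C` and mixture fractions `f_c`, the data
log-likelihood is `Σ_i log Σ_c f_c P(x_i | S_c)`. Sequences are fitted by
randomized greedy ascent followed by Metropolis–Hastings MCMC with a
single-event relocation proposal (uniform prior over valid orderings);
fractions are point-optimized by EM. The number of subtypes is chosen by
k-fold cross-validation via the out-of-fold log-likelihood (OOFLL) and the
cross-validation information criterion (CVIC = Σ folds of −2 × OOFLL),
with parsimony preferring the smallest count within tolerance of the
minimum. Details, defaults and caveats are in `docs/methods.md`.

## Worked example

```python
import ordsustain as o

d = o.SymptomDictionary((
    o.SymptomDef("tremor", "Tremors", ("none", "mild", "severe")),
    o.SymptomDef("ataxia", "Ataxia", ("no", "yes")),
    o.SymptomDef("mood", "SCID", ("no", "yes")),
    o.SymptomDef("mri", "MRI", ("no", "yes")),
))
cfg = o.SimulationConfig(dictionary=d, n_cases=120, n_controls=40,
                         p_correct=0.9, missing_rate=0.1)
cohort, truth = o.generate_cohort(cfg, seed=7)

model = o.OrdinalSuStaIn.from_cohort(cohort, d)
fit = model.fit(seed=7, settings=o.MCMCSettings(n_iter=20_000, burn_in=0.2,
                                                thinning=10))
print(fit.summary())
```

prints

```
Ordinal subtype-and-stage fit
================================================================
subjects: 120    events: 5    subtypes: 1
log-likelihood (ML): -313.68    posterior samples: 1600    acceptance rate: 0.000
seed: 7    chain: 20000 iter, burn-in 20%, thinning 10
----------------------------------------------------------------
subtype 1  (fraction 1.000) event order:
    1. ataxia:1
    2. tremor:1
    3. mri:1
    4. tremor:2
    5. mood:1
```

The fitted maximum-likelihood order is read top to bottom: ataxia is
inferred to turn abnormal first, mild tremor second, and so on — here it
matches the generating ground truth (`truth.sequences[0]`) exactly. The
acceptance rate is low because at this sample size the posterior
concentrates sharply on the modal ordering. Per-subject staging comes from
the same fit:

```python
print(fit.stage_assignments().to_frame().head(4).to_string(index=False))
```

```
participant_id  ml_subtype  ml_stage  classifiable    p_max
      case0000           0         1          True 0.849494
      case0001           0         3          True 0.903889
      case0002           0         4          True 0.754153
      case0003           0         2          True 0.906034
```

`ml_stage` is the number of events the subject has most probably accrued;
subjects whose most likely stage is 0 are flagged `classifiable=False` and
excluded from subtype summaries. `fit.pvd(0)` gives the positional variance
matrix and `o.render(fit.pvd(0), "pvd.svg")` renders it; `o.pdg(fit_a,
fit_b)` compares two fitted orderings.

The same pipeline is scriptable from the shell (`ordsustain simulate`,
`evidence`, `fit`, `cv`, `permtest`, `stage`, `plot-pvd`, `plot-pdg`, `run`);
`ordsustain run --config run.yaml` executes all stages from one YAML file
and writes a reproducibility manifest.

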