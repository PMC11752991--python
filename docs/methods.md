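# Methods

## The prediction problem

The package models a binary poor-prognosis outcome (GOS 1–3 at six months)
after endovascular treatment of intracranial aneurysms from routinely
collected tabular predictors. The emulated reference cohort has 303
patients (207 good / 96 poor prognosis), eight categorical and two
continuous variables that differ between groups, and eight variables
(gender plus seven laboratory/anthropometric measures) carrying no outcome
signal.

## Prairie Dog Optimization and the improved variant

PDO is a population metaheuristic whose iteration budget `T` is split into
four phases — two exploratory (Lévy-flight foraging, burrow building) in
the first half and two exploitative (food-alarm response, predator-alarm
response) in the second. The update equations and coefficient defaults
adopted here (food-alarm constant ρ = 0.1, food-source quality ε = 0.1,
digging-strength/predator-effect amplitude 1.5 with decay
`(1 − t/T)^(2t/T)` and alternating sign, Mantegna Lévy steps with exponent
1.5) follow the original formulation of the algorithm and are documented in
`affwdi/pdo.py`. Candidates are clipped to the box bounds and accepted
greedily per individual, so the best-so-far trace is monotone
non-increasing and all iterates stay feasible.

IPDO changes two things:

1. **Tent chaotic initialization.** The initial population comes from
   iterating `x' = x/α` (x < α), `(1−x)/(1−α)` otherwise, with α = 0.5.
   Rational seeds can collapse onto 0 or the map's fixed point, so an orbit
   that leaves (0, 1) or stalls receives an additive 1e-6 jitter re-wrapped
   into the unit interval. A seed equal to α is nudged the same way.
2. **t-distribution mutation.** After each update every individual is
   perturbed multiplicatively, `x' = x + x·t_df`, per coordinate with
   probability 0.5, with `df` equal to the current iteration index (heavy
   tails early, near-normal late); the mutant is kept only if strictly
   better. Zero coordinates are fixed points of the multiplicative scheme,
   which is intentional: the mutation scales positions rather than
   translating them.

Early termination is available through `patience` (stalled best fitness)
and `target_fitness`; both are off in the benchmark protocol, where the
convergence trace must have exactly `max_iterations` entries, and on inside
AFFWDI fits, where fitness is bounded by 1 and a saturated run cannot
improve further.

The benchmark suite is the classical 23-function set (seven unimodal and
six multimodal functions at dimension 30, ten fixed-dimension multimodal
functions). Optimum values for functions whose minimizers are only known
numerically are stored as slightly conservative literature floors; the
quartic function's additive noise comes from an injected generator so runs
are seed-reproducible, and it evaluates noise-free when no generator is
passed.

## The AFFWDI chromosome and fitness

Chromosome length is `2p + q` for `p` candidate features and `q` learner
hyperparameters; all genes live in [0, 1]. Decoding: mask genes select at
the inclusive 0.5 threshold (empty masks repaired by argmax); weight genes
map affinely to [0.01, 1] — the floor keeps a selected feature from being
silently erased by a zero weight; hyper genes map to the learner ranges
below (log-scaled where the parameter is scale-free):

| learner | tuned parameters |
|---|---|
| LR | C ∈ [1e-3, 1e3] (log) |
| SVM (RBF) | C ∈ [1e-2, 1e3] (log), γ ∈ [1e-4, 10] (log) |
| BPNN | hidden units 2–32, learning rate [1e-4, 0.1] (log) |
| XGBoost | trees 50–500, depth 2–8, learning rate 0.01–0.3, subsample 0.5–1 |

Fitness is the mean accuracy of a stratified 5-fold cross-validation on the
training partition, with Z-score parameters computed inside each fold's
training side and reused on its validation side (never on scored data —
standardizing before splitting would leak test information, so the package
deliberately standardizes per-partition). Weights multiply the standardized
features, making the encoding scale-meaningful: with a full mask and unit
weights the fitness reduces exactly to a plain CV of the base learner,
which is asserted to 1e-12 against an independently coded CV.

Equal-fitness solutions are tie-broken by fewer selected features, then by
higher full-training F1, then by evaluation order (deterministic). The
protocol splits the cohort 80/20 stratified on outcome with floor rounding
on the test side, so the default cohort yields exactly 60 test patients
(41 good / 19 poor).

## Synthetic cohort generator

Categorical variables are Bernoulli draws at the published per-group
prevalences (entered as exact count fractions, e.g. hypertension 111/207 vs
77/96); continuous variables are per-group normals (age 55.45 ± 10.34 vs
58.28 ± 11.23 years; operating time 156.34 ± 21.99 vs 40.23 ± 7.28 min).
Noise variables are drawn identically in both groups at plausible adult
reference values (weight 65 ± 10 kg, platelets 220 ± 50 ×10⁹/L, PDW
12.5 ± 2 fL, PT 12 ± 1 s, APTT 30 ± 4 s, TT 16 ± 1.5 s, fibrinogen
3.0 ± 0.6 g/L); gender, absent from the published group comparison, is a
group-invariant Bernoulli(0.5). Ordinal gradings are generated at the
dichotomized level at which prevalences are published (Hunt-Hess III–V,
Fisher 3–4, ASA III–IV), not on the full grade scale.

**What the generator does not emulate:** inter-variable correlation (only
marginals are published, so variables are independent within group),
non-normal continuous distributions, missingness, and site effects.
Consequently, passing tests demonstrate that the machinery behaves
correctly under the published marginal structure — not that the clinical
performance figures transfer to real cohorts.

**A consequence worth stating plainly:** at the published effect sizes,
operating time alone (156 vs 40 min with small SDs) separates the groups
almost perfectly. Cross-validated accuracy — the fitness the framework is
defined to maximize — therefore saturates at ~1.0 for any subset containing
that variable, and the fewest-features tie-break returns small subsets.
Full recovery of all ten informative variables is not an achievable target
on this cohort; the feature-recovery behaviour of the optimizer is instead
demonstrated on a moderate-effect cohort (six effects of comparable
individual strength), where the jointly optimized mask recovers the
informative set (Jaccard ≥ 0.6) in nearly every seeded run, and by an
exhaustive 63-subset enumeration showing that every subset outranking the
true one contains it.

## Clinical statistics

The χ² test is uncorrected Pearson `Σ(O−E)²/E` with 1 df — recomputation of
the published categorical rows matches the printed statistics only without
the Yates correction, which fixes the dialect. The t-test is the pooled-
variance two-sample test computed from summary statistics (pooling, not
Welch, reproduces both printed continuous rows). One published row
(intubation, printed 61.096) does not reproduce from its own printed
counts, which give 63.096; the table command reports the recomputed value.
Logistic regression is Newton maximum likelihood (tolerance 1e-8, ≤ 100
iterations) with Wald χ² = (β/SE)², OR = exp(β) and 95% CI =
exp(β ± 1.96·SE); complete separation and rank-deficient designs are
rejected with diagnostics naming the offending columns. Forward-stepwise
entry at p < 0.05 is available behind a flag; the default fits all supplied
variables because the published step order is not recoverable.

## Metrics

Threshold metrics derive from raw confusion counts at the inclusive 0.5
probability threshold (a probability of exactly 0.5 is labelled poor).
Precision and F1 of a predictor with no predicted positives are *undefined*
and stay NaN, rendered "-" — never coerced to 0. ROC-AUC is the trapezoidal
area (equal to the normalized Mann–Whitney U, asserted against brute-force
pair counting); PR-AUC is the average-precision construction without
interpolation.

## Problem sizes and numerical choices

Defaults follow the emulated study: population 30, 200 iterations, 5-fold
CV, 80/20 split. The package's own test and acceptance runs use 10
matched-seed repeats for the optimizer comparison and a reduced search
budget (population 15, 50 iterations) for the ten end-to-end cohort runs;
these sizes are the package's choice of a desk-scale experiment and are
stated with each result. Determinism: every stochastic component (cohort
draws, fold shuffling, optimizer, learners, Platt scaling, noise of the
quartic benchmark) is driven by explicit integer seeds, and fixed seeds
give bit-identical results. Division guards use Δ = 2.22e-16; constant
columns pass through standardization centred with unit scale.

## Known limitations

* The optimizer's fourth phase contracts toward scaled multiples of the
  best position, which on origin-centred benchmarks favours the origin — a
  known trait of this algorithm family; conclusions about IPDO vs PDO rest
  on paired comparisons under matched seeds, which share the trait.
* Wrapper selection under a saturated fitness is non-identifiable (see
  above); reported subsets on near-separable cohorts should be read as
  minimal sufficient sets, not as the full informative set.
* The BPNN uses a fixed epoch budget rather than convergence-based
  stopping; with few units and small cohorts this is fast and deterministic
  but not tuned for accuracy.
* SVM probabilities come from Platt scaling inside the adapter and can be
  mildly miscalibrated on small partitions.
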