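# Methods

## Design and data model

The unit of analysis is a probe × sample matrix of log2 intensities over a
balanced factorial design: 2 tissues (pancreatic islet β-cells, skin
keratinocytes) × 2 treatments (ligand-activated oncogene vs vehicle) × 4
time points (4, 8, 16, 32 h) × R replicates (default R = 3, 48 samples).
The pipeline assumes the matrix is already normalized (e.g. by a
multi-array method at probe level); normalization itself is out of scope.
Two nuisance variables ride along in the sample table: a categorical
processing batch (assigned round-robin over samples, default 2 batches) and
a continuous RNA-quality score (RIN-like, drawn Normal(8, 0.5) truncated
positive in simulation).

## Per-gene factorial model

Each probe is fit by ordinary least squares with treatment (T), tissue (S)
and time (H, categorical — the design has only 4 discrete points and no
trend model is assumed) plus all interactions, a categorical batch term and
a centered linear RNA-quality term. Per-term significance uses Type-II sums
of squares: for term τ, the RSS drop from adding τ to the model containing
every term except τ and any term containing τ, divided by τ's degrees of
freedom and by the full model's mean squared error. Type II respects
marginality, is order-invariant, and in a balanced design coincides with
the sequential decomposition. The implementation is vectorized: the design
matrix is shared by all probes, so each model's residual maker is one QR
decomposition applied to the whole probe × sample block.

Conventions: a probe constant across samples gets p = 1 for every term
(zero-signal convention); zero residual degrees of freedom is an error;
negative SS from floating-point cancellation is clipped at zero.

### Covariate policy

Both covariates are included in every probe's model by default
(`always_include`). A screening variant (`screen_then_include`) — keep a
covariate only if its own Type-II p ≤ 0.05, then refit — is implemented and
tested, but it is not the default: the pre-test makes the selected model
data-dependent, which measurably inflates the extreme tail of the null F
distribution (BH family-wise error ≈ 0.074 instead of the exact 0.05 in
pure-noise simulation). Exact null calibration matters more here than the
marginal power gain from dropping weak covariates, because the
classification step consumes BH-adjusted tails directly.

### FDR and classification

Benjamini–Hochberg is applied across probes separately within each term
family, preserving per-term significance semantics for the classifier.
Each probe is then assigned to the highest-order significant
treatment-involving term: three-way first; else whichever of
treatment×tissue / treatment×time has the smaller adjusted p (tie →
treatment×tissue, a fixed deterministic rule); else the treatment main
effect; else not significant. Terms not involving treatment never confer
significance. Gene-level tables collapse probes by gene symbol, keeping the
probe with the smallest classifying p per gene (`best_p`; an `any_hit` OR
rule is also available); unmapped probes are dropped with a logged count.
Gene counts are therefore always ≤ probe counts.

### Contrasts and the early-responder screen

Treated-vs-vehicle contrasts are pooled-variance Student t tests per
(tissue, time) group, df = n₁ + n₂ − 2 (Welch is available but not the
default: with 3 samples per arm the Satterthwaite df estimate is
unstable). Star flags use the conventional ** p ≤ 0.01, * p ≤ 0.05.
Degenerate zero-variance groups yield t = 0, p = 1 when means agree and a
flagged p = 0 otherwise. The early screen flags probes with |log2 FC| ≥
log2(2) and contrast p ≤ 0.05 at any time within the 8-hour window, both
thresholds inclusive; direction is the fold-change sign at the earliest
qualifying time.

## Probe filtering

Control probes are dropped by annotation flag. "Non-responsive" probes are
dropped by an unsupervised variance-and-level floor: across-sample sd <
0.1 or mean log2 value < a configurable background level (default 0, i.e.
off). The filter never looks at treatment labels, so it cannot bias the
contrasts; it is idempotent, and an empty result is a warning rather than
an error.

## Fold-change profiles

Within each (tissue, time) cell, log2 FC = mean(log2 treated) − mean(log2
vehicle); replicates are not paired (they are different animals), so group
means rather than per-replicate ratios are the natural estimator. Each
probe carries an 8-value profile (pancreas 4/8/16/32 h, then skin), the
common currency of the screens and the clustering.

## QT clustering

Classic quality-threshold clustering under d = 1 − Pearson, diameter
criterion: every remaining probe seeds a candidate grown greedily by the
addition that minimizes the resulting diameter (tie → lowest probe index),
stopping when no addition keeps the diameter ≤ 1 − 0.9; the largest
candidate is extracted (tie → lowest seed index), and the procedure repeats
until the largest falls below 14 members. Growth bookkeeping keeps, per
probe, its maximum distance to current members, so one addition is O(n) and
the whole procedure comfortably handles thousands of profiles. A
seed-linkage variant (members within threshold of the seed only) and a
jackknife correlation (min over leave-one-timepoint-out Pearson, robust to
a single outlying cell) are selectable; the defaults are full diameter and
plain Pearson. Zero-variance profiles are excluded before clustering
(Pearson is undefined for them). Emitted clusters are disjoint, ordered by
non-increasing size, and each satisfies both constraints exactly —
properties asserted post-hoc in tests. By default the pipeline clusters the
tissue-dependent responders (three-way and treatment×tissue classes),
whose profiles differ between the two tissue halves.

## Enrichment

Over-representation: upper-tail hypergeometric P(X ≥ k) for k of n selected
genes hitting a set with K members in a universe of N, summed in log space;
BH across sets. The background universe is an explicit argument and the
selected list must be a subset of it — enrichment p-values against an
unstated background are meaningless, and annotation-database versions make
externally computed values non-portable. Preranked mode: the weighted
running-sum enrichment score (hits advance by |score|^w normalized over
hits, default w = 1; misses retreat by 1/(N−K); ES = signed maximum
deviation), with a gene-label permutation null (applicable to preranked
input at any sample size, unlike phenotype permutation), sign-matched NES,
and tail-ratio q-values. The pipeline's default ranking metric is signed
−log10(contrast p) × sign(log2 FC) at a chosen tissue and time (pancreas,
8 h unless configured).

## Synthetic data generator

The generator emulates the study design's statistical structure, not its
biology. Five effect classes with default proportions 60% null and 10%
each for treatment-only, treatment×tissue, treatment×time and three-way;
treated-arm shifts of ±1.5 log2 units (≈2.8-fold — large enough that the
2-fold screen is well powered at R = 3, with sign random per probe);
treatment×tissue confines the shift to one random tissue;
treatment×time applies it late (≥16 h by default, configurable), mirroring
late-onset expression programs; three-way combines both. Noise is i.i.d.
Gaussian (default sd 0.25 log2 units); nuisance structure is a per-(probe,
batch) Normal(0, 0.1) offset and a shared linear RNA-quality slope (0.1
log2 units per quality unit). Flat probes (near-zero variance, no nuisance
structure — emulating dead probe sets) and annotation-flagged control
probes exercise the filter. The probe→gene annotation gives ~10% of probes
a shared symbol and leaves ~2% unmapped, so gene-level collapse is
non-trivial. Gene sets can be planted: half of the generated sets draw a
configurable fraction of members from truly responsive probes.

What the generator does not emulate: probe-level intensity distributions or
probe affinity artifacts, correlated gene programs (probes are independent
given the design), heavy-tailed or heteroskedastic noise, and
tissue-specific baselines. Passing recovery tests therefore demonstrates
correctness of the inferential machinery under the assumed model, not
performance on real arrays.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds carried in
configs; regenerating with the same seed is bit-identical, and the pipeline
report is byte-identical across runs. Oracle agreement tolerances in tests:
1e-8 relative for ANOVA F against the brute-force oracle (two independent
code paths through double-precision least squares), 1e-10 for the t²
identity, 1e-10 relative for hypergeometric tails against exact rational
enumeration. The QT diameter constraint is checked with a 1e-12 absolute
slack for floating-point accumulation.

## Problem sizes

Simulation-based checks use 2,000-probe matrices (20 replicate simulations
for the null-calibration study) and a 5,000-probe end-to-end run; oracle
comparisons use 100 random fixtures (ANOVA) and 100 twelve-profile
instances (QT, where exhaustive subset enumeration is feasible). These
sizes give stable estimates of the monitored rates while keeping the whole
suite fast on a single CPU.

## Known limitations

- The per-family FDR guarantee is the BH one: expected FDP ≤ α within each
  term family. Nothing is claimed for the union of discoveries across
  families.
- The four-category classification inherits the discreteness of its
  threshold: a probe whose true class's term sits near α can legitimately
  land in a neighbouring category (observed ≈2–4% of significant planted
  probes at default settings).
- QT clustering is deterministic but greedy; it is not guaranteed to find
  the maximum feasible cluster in adversarial geometries (on random and
  planted-structure instances it matches exhaustive search in every tested
  case).
- With only 3 replicates per arm, the pooled-t contrasts assume equal
  within-group variances; strong heteroskedasticity would call for the
  Welch option despite its df instability.
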