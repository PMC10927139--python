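# Methods

## The problem

Bulk and single-cell expression matrices routinely carry 10³–10⁴ features
for at most a couple of hundred labelled samples. Classifiers trained on
the full matrix suffer from the redundancy and noise of the uninformative
majority of genes, and wrapper-style feature selection — scoring candidate
subsets by classifier accuracy — is both expensive and prone to local
optima in so large a search space. The hybrid selector implemented here
attacks both problems by ordering the search space before searching it.

## The selector

The pipeline has three stages.

**1. Information-gain ranking.** Every feature `f` is scored by

    IG(f) = H(C) − H(C | f)

with entropies in bits and probabilities estimated from sample frequencies.
`H(C)` is the class entropy, and `H(C|f)` the class entropy conditional on
the discretized feature. Continuous expression values are discretized by
equal-width binning with `n_bins = 10` (configurable, `DiscretizationScheme`);
a constant feature collapses to one bin and scores 0. Equal-width binning
is the simplest reproducible estimator and the standard default in the
filter-selection literature; no supervised (MDL-style) discretization is
attempted. Empirical IG is non-negative by construction; values are clipped
at 0 against rounding. Features are sorted by descending IG with ties broken
by ascending original index, so rankings are identical across platforms.

**2. Information-index grouping.** The ranked list is cut into

    k = ceil(M / γ)

contiguous groups, where `M` is the feature count and `γ` (default 100) is
the target number of features per group. The *information index*

    I_index = Σ_i |IG(f_i)| / k

is the per-group share of the total IG. A greedy sweep down the ranking
closes a group as soon as its cumulative IG reaches `I_index`, subject to
two guarantees: every one of the `k` groups is non-empty (a group is closed
early if exactly enough features remain to populate the later groups), and
any remainder joins the final group, so the groups always form an exact
partition of the ranking. Because the ranking is front-loaded, early groups
are small and information-dense, later groups large and sparse.

**3. Grouped binary particle-swarm search.** A swarm of `swarm_size`
particles searches subsets of an *active pool* of features, initially the
first (highest-IG) group. Each particle is a bit vector (1 = feature
selected) with a real-valued velocity per bit, updated by the canonical
rule

    v′ = w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x),  clamped to ±v_max

with `r1, r2 ~ U(0,1)` drawn fresh per particle per iteration, and bits
resampled through the sigmoid transfer `P(bit = 1) = 1/(1+e^(−v′))` — the
standard binary-PSO realization, chosen because the position update is
defined continuously but the encoding is explicitly binary. An all-zero
position is repaired by setting the largest-velocity bit, keeping the
fitness well-defined without biasing toward large subsets.

Two fitness functions drive the search. *In-group* fitness is simply the
cross-validated accuracy (ACC) of the candidate subset; it is what the
swarm maximizes while a pool is active. When the global best stalls for
`patience` consecutive iterations, or `max_iter` iterations elapse, the
pool phase ends and the phase's best subset is scored by the *out-group*
fitness

    λ·ACC − (1−λ)·|subset| / M

which trades accuracy against feature scale (FS). If unconsumed groups
remain, the next group's features are appended to the pool — existing
particles are extended with fresh random bits and velocities in the new
dimensions while personal and global bests are zero-extended, preserving
the learned structure while restoring diversity — and the search continues.
The final answer is the single subset with the best out-group fitness over
all phases (the per-phase bests remain inspectable in the run history).

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `n_bins` | 10 | equal-width discretization bins for IG |
| `γ` (gamma) | 100 | target features per group; `k = ceil(M/γ)` |
| `w` | 0.7 | inertia weight |
| `c1`, `c2` | 2.0 | cognitive / social acceleration |
| `v_max` | 6.0 | velocity clamp (sigmoid is ~saturated beyond ±6) |
| `swarm_size` | 20 | particles |
| `max_iter` | 50 | iterations per active-pool phase |
| `patience` | 10 | stagnant iterations before the pool grows |
| `λ` | 0.9 | accuracy weight in the out-group fitness |

The swarm constants are canonical binary-PSO settings; λ near 1 makes
accuracy dominate while still preferring the smaller of two equally
accurate subsets. All are configurable (`GPSOConfig`).

## Subset evaluation

Accuracy is estimated by stratified 5-fold cross-validation with
seed-fixed folds; features are standardized to zero mean / unit variance
using training-fold statistics only. With ≲100 samples a single train/test
split is too unstable to drive a wrapper, which is why cross-validation is
used throughout, inside the swarm as well as for final reporting. The
default classifier is a linear-kernel SVM with `C = 1` (a 5-nearest-
neighbour classifier is the drop-in alternative); neither is tuned.
Repeated evaluations of the same subset are served from a cache keyed on
the selected-feature set; the cache is purely transparent (a run with the
cache disabled returns identical results).

## Baselines

Three filters (IG, chi-square of the binned-feature × class contingency
table, absolute Pearson correlation with the class), a plain binary-PSO
wrapper (the grouped search with a single all-features group — the two are
trajectory-identical by construction), and filter+PSO hybrids. Filters keep
the top `ceil(n_informative/2)` features by score, where *informative*
means a strictly positive score. Pearson correlation against a multi-class
label is ill-defined, so the score is the maximum |r| over one-vs-rest
binary encodings, which keeps it in [0,1] and class-symmetric. For
multi-class problems the chi-square and IG scores handle the classes
natively.

## Friedman comparison statistics

To compare k selectors over N dataset/metric rows, each row is ranked
(rank 1 = best; accuracy rows rank descending, feature-scale rows
ascending; ties get average ranks) and the classical statistic

    χ²_F = 12N / (k(k+1)) · (Σ_j R_j² − k(k+1)²/4)

is refined into the F-form

    F_F = (N−1)·χ²_F / (N(k−1) − χ²_F)

with (k−1, (N−1)(k−1)) degrees of freedom. The statistic is implemented in
its classical, uncorrected form; a tie correction (dividing by
`1 − Σ(t³−t)/(Nk(k²−1))`) is available behind an off-by-default flag, since
real score tables contain ties but the uncorrected statistic is what the
reference comparisons use. The package ships an 8×13 SVM and an 8×13 KNN
score table (four expression benchmarks × {ACC, FS} rows, 13 selectors) as
CSV data; on the SVM table the machinery yields χ²_F = 75.43, F_F = 25.67
against F(0.05; 12, 84) = 1.869, rejecting the hypothesis that the
selectors are equivalent. On the KNN table the uncorrected statistic
evaluates to 79.68; published values for that table appear to use a
slightly different tie convention, and no attempt is made to match them
beyond the formula as defined.

## Synthetic data

The generator plants three feature roles in a Gaussian class-shift model:
informative features are `N(μ_c, 1)` with class means spaced `effect_size`
within-class SDs apart (a per-feature random permutation assigns classes to
means so informative features do not all point the same way); redundant
features are a random informative feature plus `N(0, redundancy_noise_sd²)`
noise (default SD 0.5, correlation ≈0.9 with the parent — strong enough for
plain correlation to expose the redundancy); irrelevant features are
independent `N(0, 1)`. Class sizes follow largest-remainder apportionment
of the requested proportions, and feature columns are shuffled so planted
structure is not positional. Four presets reproduce the shape regime of
well-known benchmarks: (5966 × 102, 2 classes), (5748 × 171, 4),
(4434 × 50, 4), (325 × 73, 4).

The Gaussian model was chosen over log-normal count realism because it
gives analytically controllable IG separation — exactly what the tests
need. It omits heavy tails, batch effects, dropout and feature-feature
correlation beyond the planted redundancy, so passing tests demonstrate
correct mechanics and recoverability of planted signal, not performance on
real sequencing noise.

The standard study condition used throughout the tests is 100 samples ×
2000 features with 20 informative + 30 redundant planted features, 2
balanced classes, effect size 1.5. At that scale one full hybrid run (IG
ranking, 20 groups, grouped swarm with defaults) takes well under a minute
on one CPU; the recovery test repeats it for 5 seeds and checks median
accuracy, subset size, and the fraction of selected features that are
planted.

## Numerical choices and edge cases

- Entropies use log₂; zero-probability terms contribute exactly 0.
- IG ties in the ranking break by ascending feature index; score ties in
  the filters likewise — all orderings are deterministic.
- The greedy group sweep compares cumulative IG to the target with a 1e-12
  absolute tolerance so exact-division cases close where intended.
- `chi²_F` at its theoretical maximum `N(k−1)` makes the F-form's
  denominator zero; this raises an error rather than returning infinity.
- Zero-variance features score 0 under all three filters (never NaN).
- Standardization inside a CV fold maps a constant-in-fold feature to 0
  (its SD is replaced by 1).
- Generated datasets are bit-identical for a given seed; every stochastic
  component takes an explicit seed and run outputs embed the seed and an
  effective-config hash.

## Known limitations

- γ has no principled default; 100 features per group works across the
  10²–10⁴-feature regime but is a convention, not an estimate.
- The grouped search assumes the IG ranking is informative; under a
  completely uninformative ranking it degrades to plain binary PSO with
  extra bookkeeping.
- Genetic-algorithm and ant-colony wrapper baselines are not included; the
  benchmark harness accepts any selector callable, so external engines can
  be plugged in.
- The Friedman module stops at the omnibus test; no post-hoc (Nemenyi)
  procedure is provided.
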