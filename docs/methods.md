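# Methods

This note documents the models behind `bowtie-grn`, the parameter
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter
when reproducing results.

## Inference model

Each target gene *g* is scored by a lasso regression of its expression
at time *t* on regulator expression at lags 1..l_max:

    x_g(t) ≈ Σ_{r, l} β_{r,l} x_r(t − l),      l = 1..l_max

with an L1 penalty `alpha · λ_{r,g} · |β_{r,l}|` per coefficient, where
λ_{r,g} = λ_prior (default 0.5) when (r, g) is in the prior set and
λ_nonprior (default 1.0) otherwise.  The per-coefficient weights are
realized by the standard reparameterization (scale column j by 1/w_j
under a uniform penalty); predictors and the response are standardized
per regression, so λ values act on the correlation scale.  The edge
score is Σ_l |β_{r,l}| — the absolute sum avoids cancellation across
lags — and the sign of Σ_l β_{r,l} gives the edge sign.  Zero-score
edges are omitted.

Choices worth knowing:

* **Replicates** are treated as independent lagged samples; lag windows
  never cross replicate or condition boundaries.
* **Self-lags** are excluded from a target's design by default
  (`include_self=False`): with them, autocorrelation produces trivial
  self-edges that pollute consensus and evaluation.  They can be
  enabled to absorb autocorrelation when self-regulation is of
  interest.
* **Overall regularization** `alpha` (default 0.01 in sklearn's
  objective scaling) was fixed by pilot runs on the small synthetic
  preset: it is small enough that true lag-1 effects at coefficient
  magnitudes ≥ 0.3 survive standardization, and large enough that the
  raw network stays far from complete.  The λ values then act as
  relative prior/non-prior weights on top of it.
* **Monotone lag constraints** (|β| non-increasing in lag) are declared
  in `LassoConfig` but not implemented; the unconstrained
  per-coefficient-penalty lasso is the reference scoring model.
* **Degenerate designs**: constant targets get no incoming edges;
  zero-variance predictor columns are dropped from the design.

## Null filtering

The null distribution pools the edge scores of one inference run on
randomized data (sample order permuted and gene labels permuted,
independently, by a seeded generator).  Edges survive when their score
strictly exceeds the type-7 empirical (1 − α) quantile of the null,
α = 0.05 by default.  One pooled null is used for the whole run; when
observed and null scores are exchangeable this retains α of the edges
by construction (verified at n = 10,000 in the acceptance suite).

## Consensus

Network similarity is the Jaccard index of edge sets (an asymmetric
overlap |Ei ∩ Ej|/|Ei| is available since the denominator convention is
not canonical).  Grouping is complete-linkage agglomerative clustering
on 1 − similarity with deterministic tie-breaking; consensus networks
are plain edge-set unions with per-edge support counts kept as
metadata.  Ranking of subset combinations reports PFE and AUFE for
every non-empty subset (capped at 16 networks); *selection* is a ranked
report, not an automatic choice.

## Evaluation

PFE = (p/n)/(k/K).  For whole networks, the universe defining K is the
gold standard's regulator × target universe restricted to genes present
in the network.  Per-regulator PFE uses n_r = predicted edges into the
target universe and K_r = |target universe|; regulators predicting
nothing score 0.  AUFE is computed as the mean of per-regulator PFE
values, which equals the area under the piecewise-constant survival
curve of those values (the survival-curve form is exposed for
plotting).  AUPR against knockdown-correlation tables integrates,
step-wise without interpolation, precision over recall as the |PCC|
positivity cutoff sweeps the observed values; the prediction set stays
fixed while the positive set varies, matching how cut-off-dependent
validation experiments are reported.

Random expectations come from (a) the network density E/(R·T) and
(b) degree-preserving double edge swaps: two edges (u→v), (s→t) swap
targets to (u→t), (s→v); moves creating self-loops or duplicate edges
are rejected; the default ensemble is 100 replicas of 10·|E| accepted
swaps.  Z-scores use the sample standard deviation of the ensemble.

## Structural layers

The module graph W[a][b] counts edges from genes in module a to genes
in module b.  A module is *output* when its outgoing inter-module
weight is ≤ tol of its total incident weight, *input* when its incoming
inter-module weight is, *core* otherwise, *isolated* at zero incident
weight.  The tolerance (default tol = 0.01) exists because observed
layered networks carry a small fraction of pattern-violating edges — a
strict zero test classifies almost nothing.  Pattern compliance reports
the fractions of total weight in downward (input→core, input→output,
core→output), within-layer and upward cells; they sum to 1 exactly.

## Module recovery

Empirical modules are the five differential-expression classes
(strong/weak up, strong/weak down at padj < 0.05 with a log2 fold-change
threshold of 1, and everything else).  Recovery of an empirical module
by a structural partition uses the maximum Jaccard index across
structural modules, standardized by a robust Z-score,
(x − median)/(1.4826·MAD), against a null of per-shuffle maxima from
1,000 size-preserving permutations of both membership vectors; a module
is recovered at Z > 1.96.  The max-statistic null makes the test
family-wise across structural modules.  The information-theoretic
variant uses adjusted mutual information with a permutation Z; its
"adjusted Z" Bonferroni-corrects the one-sided normal p across the
declared number of tests (default 36) and maps back through the inverse
normal, clipped to the resolution implied by the null size.

The built-in partition fitter is a deliberately simple greedy
minimum-description-length baseline for a degree-corrected stochastic
block model (random initial partitions, greedy single-node moves,
greedy merges, best of 20 restarts; the fit term is −E × the mutual
information between edge-endpoint group labels, the complexity term
B²·ln E/2 + n·ln B).  It recovers well-separated planted blocks but is
*not* a replacement for full Bayesian SBM machinery; externally fitted
partitions are first-class TSV inputs.

## Screen statistics

* **Max-|PCC| resampling**: observed Pearson correlations between a
  knocked-down regulator's replicate ΔΔCT vector and each target's are
  compared against 1,000 iterations of the maximum |PCC| across all
  targets with every target vector shuffled independently; because the
  null is a maximum, the p-values are family-wise adjusted by
  construction.  At least six replicates are required.
* **Survival arithmetic**: the percentage formula (100 · dead / mean
  total) is implemented as printed, with a documented `alive` mode,
  since the printed numerator is a death count.  Normalization against
  same-round controls requires an explicit mode: `center50`
  (50 · test/control, so control-level survival maps to 50) or
  `ratio50` (ratio + 50, the literal "+50" reading); the two are
  arithmetically incompatible, so neither is a default.
* **Survival testing**: two-group logrank (via lifelines), Fisher's
  method across biological replicates, Bonferroni across conditions.
* **Resampling enrichment**: label counts in random Nt-subsets of the
  Ng background; matches the exact hypergeometric tail within
  Monte-Carlo error (checked against scipy's hypergeometric in the
  test suite).
* All resampling p-values use the add-one form
  (1 + #extreme)/(1 + iterations), so finite nulls never report 0.

## Synthetic worlds

`make_bowtie_grn` plants input/core/output module layers and draws
directed edges per ordered module pair: downward pairs at `p_forward`,
within-module pairs at `p_within`, upward pairs at `violation_rate`,
none between distinct same-layer modules.  Coefficients are
±Uniform(0.3, 0.9) rescaled to spectral radius 0.9, which guarantees a
stationary VAR(1); rescaling is skipped (with a warning) for
near-nilpotent draws, which are already stable.  Expression is
x_t = A·x_{t−1} + ε with Gaussian noise and independent per-replicate
initial states.  Knockdown responses propagate a sustained −effect
input through (I − A)^{-1}, so genes unreachable from the regulator
shift exactly zero.

Two presets encode the two study regimes:

* `bowtie-small` (2,3,1 modules × 10 genes, p_forward 0.15, p_within
  0.10, violation 0.005): sparse enough that a 20-timepoint,
  3-replicate series supports inference, and that a gold standard of
  density k/K ≈ 0.08 leaves headroom for PFE well above 2.
* `bowtie-layers` (2,3,1 × 25 genes, p_forward 0.8, p_within 0.3,
  violation 0.005): used for layer classification.  The expected
  upward/incident weight ratio of a boundary module is approximately
  violation_rate/p_forward, so recovering layers at tolerance 0.01 with
  violation rate 0.005 *requires* dense downward flow; at p_forward 0.8
  a Poisson fluctuation analysis puts the per-module misclassification
  probability below 1%.  This is a property of the threshold-based
  classifier, not a tuning artifact: sparse layered networks with the
  same violation rate are genuinely ambiguous at that tolerance.

What the generator does **not** emulate: count noise (no negative
binomial sampling or library-size effects), mRNA decay as a separate
process, non-linear or combinatorial regulation, unmeasured
confounders, and transcriptome scale (worlds stay ≤ a few hundred
genes).  Passing tests therefore demonstrate correctness of the
statistical machinery and qualitative behavior of the workflow, not
performance on real RNA-seq.

## Numerical conventions

Genomic intervals are 0-based half-open (BED) throughout; overlap means
≥ 1 shared base; merging joins overlapping *or* bookended intervals
(bedtools default, cross-checked against the bedtools CLI in the test
suite); replicate consensus is defined by per-base support counting,
which is order-independent; `bedtools window` semantics extend the
site, not the TSS.  Strand is ignored in all overlap tests.  TSV is the
single on-disk dialect (header required, UTF-8, `#` comments); gene
identifiers are opaque case-sensitive strings.  Missing expression
values are a load-time error unless per-gene linear interpolation is
requested.  Empirical quantiles are type 7; the null filter uses strict
inequality at the threshold.  All stochastic routines take integer
seeds and are deterministic given them.

## Problem sizes

The test and acceptance suites run at deliberately small scale: 60-gene
worlds for end-to-end inference (three noise replicas, seeds 1–3),
150-gene worlds for layer recovery (10 seeds), 10,000-draw calibrations
for the null filter and enrichment, 200 null experiments × 1,000
iterations for the max-|PCC| family-wise error, and 1,000-gene
partitions for module recovery.  These sizes give stable Monte-Carlo
estimates while keeping the full suite under a minute of compute.

## Known limitations

* The lasso solver treats λ values as relative weights on one global
  `alpha`; it does not search a regularization path.
* The greedy MDL fitter can merge weakly separated blocks; restarts
  mitigate but do not eliminate local minima.
* `evaluate_combinations` enumerates ≤ 2^16 subsets; larger collections
  must be pre-grouped.
* The layer classifier is threshold-based per module; a probabilistic
  classification (posterior over layer assignments) is out of scope.
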