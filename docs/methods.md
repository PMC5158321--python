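# Methods

## Feature construction

A promoter of length `L` bp is partitioned into `⌈L / w⌉` half-open bands
`[b·w, (b+1)·w)` of width `w` (default 50 bp; the last band may be shorter
when `w` does not divide `L`). A motif hit is assigned to the single band
containing its start coordinate (0-based, forward-strand for both strands;
strands are pooled). The PSMM entry `(m, b)` is the number of hits of motif
`m` starting in band `b` — occurrence counts, not presence flags, so
multiple hits of one motif in one band are distinguishable. PSMM rows are
concatenated in lexicographic motif order (bands ascending within a motif)
into the feature vector, and the two labelled sets are stacked, set A
first, into the feature matrix. The flatten/stack step is exactly
information-preserving: reshaping a row recovers the promoter's PSMM, and
the matrix total equals the number of in-range hits.

Band labels like `0-50` denote the half-open interval `[0, 50)`. Inclusive
printed ranges such as "0–50, 51–100" are ambiguous about the boundary base
and inconsistent in width; the half-open reading is the only self-consistent
one and is what the display labels mean here.

## Feature selection

**Cumulative variance.** Per-column variance over *all* samples (class
labels ignored), sample variance with denominator `n−1` by default
(`ddof=0` available — the convention affects ranking not at all, only the
printed values, since every variance scales by the same factor). Features
are ranked by decreasing variance, ties by ascending column index; the
selected set is the shortest rank prefix whose cumulative variance reaches
`(P × T_V)/100`. A cumulative sum exactly equal to the cutoff terminates
the prefix. At `P = 100` zero-variance features are never selected because
the cutoff is reached without them. `T_V = 0` is an error: nothing is
selectable.

**t-test P value.** Per feature, a two-sided two-sample t-test between the
classes — Welch's unequal-variance form by default because band counts are
Poisson-like and class variances need not match; a pooled-variance option
(`equal_var=True`) is provided. Features with zero variance in both classes
are outside the t statistic's domain; they get `P = 1` when the class means
agree and `P = 0` when they differ, the statistic's limits. The selected
count is `k = ⌊n × T / 100⌋` with a floor of one, features ordered by
increasing P value, ties by ascending index.

**mRMR-MIQ.** Features are discretized per column by z-score with cuts at
±0.5 (three states), the discretization convention of the original mRMR
work; mutual information is the plug-in estimate in nats. The first pick
maximizes MI with the class label; each later pick maximizes the quotient
`MI(f; class) / mean_{s∈selected} MI(f; s)`, ties by ascending index. A
zero mean redundancy makes the quotient +∞, so fully novel features win.

**PCA / SVD.** PCA operates on the column-centered matrix and returns the
top-k component scores; SVD operates on the raw (uncentered) matrix and
returns `U_k S_k`. Keeping the centered/uncentered distinction preserves
the conventional difference between the two transforms being compared.

All selectors are deterministic: identical inputs give identical selections.

## Classification harness

Stratified random split: per class, `⌊train% × class size⌋` samples are
drawn to the training side by a seeded shuffle, the remainder to test;
ratios 50:50 through 90:10. Each configuration runs `repetitions` times
(default 25) with per-repetition seeds derived from the configuration seed,
and the mean test accuracy is reported (per-class recalls are recorded but
not part of any contract).

Feature reduction inside the harness is fitted on the training rows only —
selection indices or transform loadings are functions of the training split
and are applied unchanged to the test split. Fitting the reduction once on
the full matrix before splitting (which leaks test information into the
selection and typically inflates accuracy) is available behind
`presplit_reduction=True` for comparison.

KNN is native: Euclidean distance, majority vote among the k nearest,
vote ties resolved by the class of the single nearest neighbour, equal
distances ranked by ascending training index (stable sort) — fully
deterministic. SVM kernels map the historical kernel menu: quadratic →
polynomial degree 2, polynomial → degree 3, MLP → sigmoid; box constraint
and kernel scale are the library defaults (C = 1, `gamma="scale"`), since
no principled values exist for arbitrary count matrices. Decision trees
use the default CART with a per-repetition random state.

The experiment grid enumerates, per promoter-set pair, every classifier
setting × ratio cell once with the complete feature set and once per
(reduction method, level) with five methods and five levels, giving
650 cells per pair for KNN/SVM (5 settings × 5 ratios × 26) and 130 for
decision trees — 5200 and 1040 over eight pairs. The default level menu in
the grid is {50, 40, 30, 20, 10}%; the CLI also offers 5%.

## Synthetic benchmark

The generator emulates the *structure* of a two-set promoter comparison,
not its sequence content: per promoter and motif, a background hit count is
drawn from Poisson(`background_rate`) with positions uniform over the
promoter; each planted `(motif, band, class, rate_delta)` effect adds
Poisson(`rate_delta`) hits uniformly within its band to promoters of its
enriched class. Band counts are therefore exactly Poisson, so the expected
feature means, variances and t statistics are analytically checkable, and
generation is byte-reproducible under a fixed seed.

Defaults define the simulated study: 100 promoters per class, 2500 bp
(a −2000..+500 window), 50-bp bands, 20 motifs with JASPAR-style ids,
background rate 1.0 hit/motif/promoter (so ~20 background hits per
promoter, a realistic density for a scanned promoter window), and five
planted effects of size 3.0 alternating between the classes in well
separated bands. A background band count has mean 0.02; a planted band adds
mean 3.0 to one class, a strong but not degenerate effect.

What passing tests on this benchmark do **not** show about real data: real
promoter sets have correlated motif occurrences (CpG islands, co-occurring
modules, homologous promoters), non-uniform positional background
(TSS-proximal enrichment), heavy-tailed per-promoter hit counts from
scanner thresholds, and many more motifs (hundreds of JASPAR profiles, so
thousands of features with heavy multiple-testing burden). Recovery rates
and accuracies here characterize the method's mechanics, not its real-data
performance.

## Numerical and design choices

- Cumulative-variance boundary uses a relative tolerance of 1e-12 so a
  prefix sum mathematically equal to the cutoff terminates the prefix
  despite float rounding.
- The convenience scanner scores log-odds against a uniform 0.25 background
  with +0.01 pseudocount per PFM cell; a hit requires score ≥
  `score_fraction` × the PFM's maximum attainable score, windows containing
  N never match, and reverse-strand hits are reported by forward-strand
  start. The maximum attainable score is strand-invariant, so both strands
  share one threshold.
- Null-control testing: the 25 harness repetitions resample splits of the
  *same* promoters, so their accuracies are correlated and `reps × n_test`
  overstates the effective sample size; the chance-level band is computed
  from a single repetition's binomial standard error, `sqrt(0.25/n_test)`.
- Degenerate inputs: empty promoter sets, single-sample variance, classes
  with fewer than two samples, selections that would empty the feature
  set, and out-of-vocabulary motifs are all errors, not silent fallbacks;
  hits at or beyond the promoter length are errors in strict mode and
  dropped otherwise.

## Known limitations

- Only two-class comparisons; multi-class behaviour of the P-value filter
  is undefined and unimplemented.
- Hits are weighted equally; scanner scores are carried through the I/O
  layer but do not weight PSMM counts.
- mRMR discretization conventions differ between implementations, so
  feature-by-feature agreement with other mRMR packages is not guaranteed,
  only the greedy-MIQ contract.
- SVM accuracies depend on unstated hyperparameters (box constraint,
  kernel scale); results are reproducible under this package's defaults
  but not bit-comparable to other toolchains.
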