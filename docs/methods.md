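# Methods notes

This note records the modelling assumptions, defaults, and numerical
choices behind each module, and what the synthetic-data generator does and
does not emulate.

## Synthetic worlds

The generator produces the statistical structure the analyses assume, not
instrument-level realism.

**Interactome.** Preferential attachment (Barabási–Albert, default m = 2
attachment edges on 300 proteins) is the default because real interactome
degree distributions are heavy-tailed; an Erdős–Rényi model is provided
for null studies, where hub-free topology keeps first-order neighbourhoods
nearly disjoint and their scores close to independent. Edge confidences
are i.i.d. draws (uniform on [0,1] by default) so that the 0.119
confidence filter removes a nontrivial edge fraction. Genes and proteins
share one symbol namespace; a probe→gene table with at least one
two-probe gene is emitted to exercise the mean-factor rule.

**Expression.** Per-gene baselines N(7, 1) on the log2 scale with i.i.d.
Gaussian residuals (SD 0.5, a typical post-normalization array residual);
no batch, probe-level, or mean–variance structure, since preprocessing is
out of scope. A planted neighbourhood shifts its members by a fixed log2
effect in group A only. Default cohort: 20 vs 20 samples, 2000 genes.

**Flow cytometry.** Per marker, events are Gaussian mixtures on log10
fluorescence (100 000 events per marker by default). The default panel
cycles through a unimodal normal-positive marker (mean 2.5, SD 0.15), a
bimodal negative/positive marker (means 0.5/2.5, weights 0.4/0.6), and a
broad marker (mean 2.5, SD 0.55 — its 10%-of-peak extent, 2·√(2·ln10)·σ ≈
2.4 decades, clears the broad rule for every marker class). Component
means sit mid-partition so truth scores are unambiguous; a first draft
with a component mean exactly on a scoring boundary made the truth a coin
flip and was corrected. What a green recovery test establishes is that
the density machinery recovers *well-separated* mixtures; it says nothing
about overlapping populations, spectral spillover, debris, or gating.

**Outcome.** log10 MRD = −3.5 + Σ log10(fold) · 1[marker at level] + ε,
ε ~ N(0, 1), defaults chosen to match a cohort whose median EOI MRD is
~10⁻³ with a wide interquartile range. The default planted effect is a
6.47-fold MRD increase for CD34 normal/bright versus CD34-negative. With
this placement ~7% of reference-group values fall below the 10⁻⁵
detection limit; the below-LOD sentinel (an explicit string token, never
a numeric zero) keeps censoring a visible pipeline step, and the induced
censoring bias on the fitted fold is ≲ 10%, well inside a 95% CI at
n = 200. Ages and WBC are plausible paediatric-cohort draws and carry no
effect unless configured.

## Flow scoring

The published practice scores markers from contour plots; that idiom has
no algorithmic definition, so modality is operationalized in 1-D: a
binned kernel density estimate (512 bins, Gaussian smoothing at the
Silverman bandwidth 0.9·min(σ, IQR/1.34)·n^(−1/5)), peaks found with a
prominence floor of 5% of the global density maximum (configurable;
suppresses noise peaks), events assigned to the density basin between
minima, and subpopulations at ≤ 1% of blasts merged into the nearest
larger one before modality is decided. Broad expression is a single peak
whose extent at 10% of its maximum spans ≥ 1.5 score units (B-/
non-lineage) or ≥ 1.5 log10 decades (cross-lineage); one score unit is a
third of the span between the negative/dim and normal/bright boundaries,
because the reference tables in routine use are not published and the
score-to-decade conversion must be derivable from the boundaries
themselves. Values exactly on a boundary go to the higher category
(half-open intervals). Reference intervals default to the 99.5th
percentile of the marker-negative control lymphocytes (neg/dim) and the
quartiles of the positive controls (dim/normal, normal/bright), all
configurable. Fewer than 200 events is refused; all-constant controls
raise a degenerate-interval error rather than producing zero-width
partitions. Only per-marker 1-D analysis is supported — multi-marker
gating is out of scope.

## Differential expression

The moderated t uses a fixed prior: d₀ = 4 pseudo-observations and prior
variance equal to the mean per-gene pooled variance. A full empirical-
Bayes fit would estimate both; the fixed default keeps the implementation
dependency-free and testable, and at the default cohort size (d = 38) the
shrinkage weight d₀/(d₀+d) ≈ 0.10 makes the difference to a fitted prior
negligible. d₀ = 0 reproduces the ordinary pooled two-sample t exactly.
Group A is the lexicographically smaller label, making label-swap
antisymmetry exact. Genes with zero variance and zero prior get p = 1
with a warning, never NaN. p-values are two-sided throughout. The
direction-neutral band is |log2FC| ≤ 0.1.

## Subnetwork significance

The Irwin–Hall CDF's alternating sum cancels catastrophically in floating
point (terms reach ~10⁸⁴ at n = 50 while the result is O(1)), so for
n ≤ 50 it is evaluated in exact rational arithmetic and converted to
float once; above 50 the N(n/2, n/12) approximation is used, which at
the crossover agrees with the exact value to < 5·10⁻³ — far below
permutation resolution.

Permutation calibration shuffles the gene→p-value assignment, preserving
network topology and the p-value pool; one shared shuffle serves all
networks within a permutation index so scores are comparable under a
common null draw. Because the Irwin–Hall CDF is monotone in S at fixed
n, "equal or better integrated p" is counted as S_perm ≤ S_obs without
evaluating the CDF per permutation. The permutation pool is a deliberate
design point: the library default shuffles over all measured genes, but
the pipeline restricts the pool to genes mapped onto the interactome.
When the mapped genes are a small subset of the measured ones, their
chance deviation from the full pool shifts every network's score
together, and only the mapped-pool test is exactly conditional on the
p-values networks can draw from — with genome-scale overlap the two
choices coincide. Unmeasured members are excluded from S and n (not
imputed at 0.5), with exclusion counts recorded.

The empirical p-value uses the add-one estimator (c+1)/(B+1) to avoid
zeros, but *selection* applies the strict raw-count rule c < rate·B
(rate 10⁻⁴, the published 1000-of-10⁷ cutoff) so the selection boundary
is unchanged by the estimator. B < 1000 is refused as tail-unstable.
Network size bounds default to 3–500 members, excluding degenerate
singletons and hub-dominated giants. Selected networks are ordered by
empirical p, ties by |S/n − ½| (more extreme mean member p first), then
seed symbol, so output order is independent of enumeration order. The
study-level FDR divides the mean number of selections under label
permutation by the observed number (mean, not median, so a single
inflated permutation is not hidden); with zero observed selections the
estimate is reported as undefined rather than zero or infinity.

## Ph-like consensus

Clustering defaults are the common expression idiom — average linkage on
correlation distance, cut at k = 2 — with metric, linkage and k all
configurable, since the originating analyses name none of them. "Most
compatible cluster" is operationalized as the cluster with the highest
mean mock-PAM score. The top-5% flag count uses the ceiling (⌈0.05·160⌉ =
8); boundary ties are all included, so the count can exceed the nominal
one only under exact ties. Constant samples make correlation distance
undefined; they are treated as identical, and a single-cluster cut flags
nobody, with a warning. Without a labelled reference cohort the top-25
strategy cannot run and the consensus degenerates to requiring both
remaining strategies. The signature is accepted as an arbitrary signed
probe-level table; no attempt is made to reproduce the original
nearest-shrunken-centroid training.

## Enrichment statistics

Preranked GSEA uses the classic weighted running sum (weight 1 by
default; weight 0 is the unweighted KS limit) with a gene-label
permutation null — random same-size member sets — because only the
ranking, not the sample-level matrix, is assumed available. NES divides
ES by the mean |ES| of same-sign permutations, and the reported p is
(r+1)/(b+1) among same-sign permutations, so its resolution is set by the
same-sign count, not the total. The two-sided Fisher test follows the
point-probability convention (summing all fixed-margin tables no more
probable than the observed one) with the conditional odds ratio; the
Yates chi-square clamps |O−E|−½ at zero. Both are delegated to scipy and
cross-checked in the test suite against exhaustive enumeration and hand
evaluation respectively.

## Outcome models

MRD is modelled on log10 so exponentiated coefficients read directly as
decade-fold effects (any log base is equivalent up to scaling); age
enters as age/10 so its coefficient reads per 10-year increase.
Categorical markers are dummy-coded against explicit reference levels.
Rank-deficient designs raise an error naming the aliased terms rather
than silently pseudo-inverting. Stepwise selection runs forward and
backward AIC searches independently, takes the union, keeps covariates
with any term below p = 0.05 in the union fit, and refits; a Bonferroni
column with configurable family size (default: the number of covariates)
is reported alongside raw p-values. The ROC AUC is the Mann–Whitney
pairwise-concordance form with ties scored ½; its CI is a stratified
percentile bootstrap (2000 resamples, seeded), chosen because no
analytic CI convention is implied by the source analyses. The LASSO-based
third selection route is deliberately omitted; survival endpoints are out
of scope.

## Known limitations

- Flow modality is 1-D per marker; co-expression gating, doublet and
  viability filtering are not modelled.
- The moderated t's fixed prior is slightly miscalibrated relative to a
  fitted empirical-Bayes prior at very small sample sizes (d ≲ 10).
- Network empirical p-values are mutually dependent through member
  overlap (strongly so around scale-free hubs) and the shared permutation
  stream; marginal calibration holds, but independence-assuming
  diagnostics applied across networks (e.g. a KS uniformity test) can
  over-reject on hub-rich graphs.
- The label-permutation FDR reruns the full pipeline and is therefore the
  most expensive operation; at desk scale use reduced permutation counts.
- Generated cohorts have uncorrelated genes apart from planted shifts, so
  power estimates on them are optimistic relative to co-regulated real
  transcriptomes.
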