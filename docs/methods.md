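# Methods

`ripchip` reimplements the computational arm of a RIP-Chip (RNA
co-immunoprecipitation + microarray) study: identifying the mRNAs associated
with an RNA-binding protein from two-color spotted-array profiles of specific
IP, mock (isotype-control IgG) IP and total RNA, each hybridized against a
common universal-reference RNA. This note records the models, conventions and
numerical choices behind each stage, and what the synthetic benchmark does and
does not establish.

## Experimental design assumed

Five biological replicates per condition (IP, mock, total), each array carrying
~3.6×10⁴ probes; the experimental sample is labeled in the Cy3 channel, the
common reference in Cy5, so each array yields a per-probe ratio
M = log2(sample/reference) and an average intensity
A = ½·log2(sample·reference) after background correction.

## Preprocessing

Fixed stage order: within-array normalization → across-array scaling → median
collapsing of replicate spots → expression filter applied as a mask.

* **Expression filter.** A probe counts as expressed when its raw sample-channel
  foreground exceeds 2× its local background in *every* replicate of at least
  one condition group (IP, mock, or total). The comparison is foreground vs.
  local background and therefore runs on raw, pre-normalization intensities.
  Statistics downstream (percentile ranks, t, fold, GSEA universe) are computed
  over the expressed universe only, since targets are defined among expressed
  transcripts.
* **Background correction.** Local background is subtracted per spot; corrected
  intensities are floored at 0.5 fluorescence units before taking logs. The
  floor is the least destructive way to avoid −∞ on empty spots; no background
  model (normexp etc.) is fitted.
* **Within-array normalization.** Loess regression of M on A — local linear,
  tricube weights, span 0.4, 3 robustness iterations (via
  `statsmodels.lowess`, with its `delta` interpolation shortcut at 1% of the
  A-range for speed). The residual M is the normalized ratio. Constant-M arrays
  normalize to exactly zero; arrays with fewer than 10 finite (M, A) pairs are
  rejected.
* **Across-array scaling.** Each array's normalized M vector is rescaled so all
  arrays share a common median absolute deviation, the common value being the
  geometric mean of the original MADs. MAD is computed on all probes, not just
  expressed ones — robust to the planted/enriched tail. An array with zero MAD
  is an error, not a silent pass-through.
* **Collapsing.** Rows sharing a probe id collapse to their per-sample median,
  in first-occurrence order; a collapsed probe is expressed if any of its spots
  passed the filter. Collapsing is idempotent and a no-op for unique ids.

## Target calling

* **Percentile ranks.** Within each replicate, fractional ranks (ties get the
  mean of the tied ranks) divided by n, so the top untied probe scores exactly
  1 and a constant vector scores (n+1)/(2n). The average percentile rank (APR)
  per condition is the arithmetic mean over the 5 replicates. Because APR is
  rank-based it is invariant to any strictly monotone per-replicate transform.
* **Fold enrichment.** 2^(mean log2 IP − mean log2 mock) — a geometric mean,
  chosen so fold = 2^logFC exactly; whether the original analysis used
  arithmetic or geometric means of linear intensities is not recorded, and the
  geometric form is self-consistent with the log-fold-change.
* **Rule.** Target ⇔ APR_IP > 0.95 ∧ APR_mock < 0.95 ∧ fold > 2, all strict.
  Tightening any cut can only shrink the target set.
* **t statistics.** Welch (unequal-variance) two-sample t per probe, IP vs
  mock, two-sided p from the t distribution; the pooled-variance form is
  available via `equal_var=True`. With 5-vs-5 replicates Welch is the safer
  default. Zero-variance probes yield signed-infinity t (p = 0) by convention;
  an optional variance floor (1st percentile of per-probe pooled variances,
  off by default) suppresses the infinities for exploratory use. BH q-values
  are reported for completeness; the target call itself never uses p-values.
* **Diagnostics.** QQ of standardized t-scores against normal quantiles at
  (i−½)/n; squared Pearson correlation between per-probe replicate means of
  conditions (IP vs totals, IP vs mock); average-linkage hierarchical
  clustering of the target submatrix on 1 − Pearson distance over both rows
  and columns (constant rows are nudged by 1e-9 before the correlation
  distance), exported in Java TreeView CDT/GTR/ATR format.

## Gene-set enrichment

* **Running sum.** On the list ranked by descending score (ties broken
  lexicographically by id), the sum gains |score|^p / Σ_members|score|^p at
  member positions and loses 1/(N − N_set) elsewhere; ES is the signed
  extremum, the leading edge the members at or before it (after it for
  negative ES). Weight p = 1 by default, p ∈ {0, 1, 2} supported. With p = 0
  the ES depends on member positions only. When every member weight is zero
  (all-identical scores at p > 0) the hits contribute nothing, the sum drifts
  monotonically to −1, and every permutation does the same — the nominal p is
  1, reflecting that such a list carries no information. When the running
  sum's maximum and minimum tie exactly in magnitude the reported sign follows
  the first extremum in list order; this tie-break is conventional.
* **Permutation null.** Gene (member) resampling: each permutation draws a
  random relabeling of the universe shared by all sets, so equal-size sets see
  identical null draws, as label permutation implies. Phenotype relabeling is
  available behind `mode="phenotype"`, but with 5 + 5 arrays only C(10,5) =
  252 distinct relabelings exist — far too few to resolve FDR q-values —
  so it is not the default. 1000 permutations by default.
* **Significance.** NES = ES / mean(|null ES| of matching sign); nominal
  p = (1 + #{null at least as extreme, same sign}) / (n_perm + 1), so p is
  never below 1/(n_perm+1); FDR q from pooled sign-matched normalized null
  scores (ratio of null to observed exceedance fractions, clipped at 1);
  FWER p from the per-permutation most-extreme same-sign NES. Sets with
  FDR q < 0.05 or FWER < 0.1 are flagged significant.
* **Rank-position test.** One-sided Wilcoxon rank-sum comparing the list ranks
  of set members vs non-members ("enriched at top" ⇔ member ranks small),
  exact (full enumeration of the rank-sum distribution, via
  `scipy.stats.mannwhitneyu(method="exact")` — ties cannot occur among
  distinct ranks) whenever C(N, n_set) ≤ 10⁶, otherwise the normal
  approximation with continuity correction. The ranking key is a parameter:
  t-score for the discovery analysis, IP APR for the cross-cell-line style
  recapitulation analysis.
* **Motif gene sets.** An id joins the set when its (sense-strand) sequence
  contains ≥ 1 match of the IUPAC degenerate pattern; scanning is
  case-insensitive and U ≡ T. The two built-in patterns, KRCTCNNNNMANAGC and
  TTTNNANAGCYR, overlap the conserved 3′-terminal stem-loop of
  replication-dependent histone mRNAs.

## Synthetic data generator

The generator is first-class code: it produces GPR-style scan files with a
known ground truth so every stage is testable without array downloads.

Model, per probe and array:

* Expressed probes (default 40%) carry a latent log2 abundance ~ N(11, 1.5);
  non-expressed probes carry a faint residual signal, log2 ~ N(4, 1), i.e.
  ~16 fluorescence units against a mean background of 200 — far below the
  2-fold filter, but enough that empty spots do not produce a degenerate
  point-mass of identical ratios.
* Local background per spot ~ Gamma(shape 4, mean 200), drawn independently
  per channel; reported background equals the true additive background, so
  background subtraction is exact and the noise-free limit is exact.
* The reference channel's expectation equals the probe's baseline abundance on
  every array (a pooled-reference stand-in resembling the samples), so
  log-ratios are (planted effect) + noise and per-probe abundance largely
  cancels — which is what makes rank-based calling on ratios sensible.
* Planted targets: round(1.5% × n_probes) probes (540 at scale), drawn from
  the expressed set, each elevated in the IP channel by exactly
  `planted_log2_fold` (default 3) log2 units. The effect is deterministic per
  probe so the noise-free limit recovers fold = 2³ exactly.
* Replicate noise: multiplicative log-normal, log2-sd 0.35, independent per
  probe/array/channel.
* Dye bias: a smooth sinusoid in A added to the sample channel, amplitude 0.5
  log2 units, half a cycle across the observed A range, random phase per
  array. Half a cycle keeps the bias within what a span-0.4 loess can remove
  in the sparse intensity tails (steeper waveforms leave residual bias where
  the windows are wide); the bias is strong enough that unnormalized decile
  means are off by up to ~0.5.
* Totals arrays are abundance-driven and independent of planting, so the
  IP-vs-totals correlation diagnostic is near zero by construction, mirroring
  the abundance-does-not-explain-binding argument qualitatively.
* Gene sets: one "histone-like" set draws 90% of its members from planted
  targets (positive control); the remaining sets are uniform draws from
  expressed probes (null sets). Sizes uniform in [20, 100], 50 sets.
* `probe_copies > 1` prints each probe id multiple times per slide to exercise
  median collapsing; default 1.

Everything is driven by one `numpy` Generator seeded from `seed`; identical
parameters give bit-identical scans.

**What the benchmark does not emulate:** print-tip or spatial artifacts,
flagged/missing spots, dye-swap designs, probe cross-hybridization, a
reference RNA genuinely different from the sample pool, correlated noise
between replicates, or effect-size spread among true targets. Recovery at the
defaults (sensitivity ≈ 1, false-discovery proportion ≈ 0) therefore shows the
machinery is correct and well-calibrated, not that real arrays — where effect
sizes straddle the thresholds — would separate this cleanly. The published
study called 189 targets of 12,468 expressed (~1.5%); those exact counts
depend on the deposited arrays and the original normalization, and are
reachable only through validation mode on the downloaded data.

## Problem sizes

Tests and the acceptance script run the generator at the design scale
(36,000 probes × 15 arrays, 1000 GSEA permutations; a few seconds end to end)
plus a 200-run null-calibration study at 900 probes per run, chosen to give
stable uniformity checks of the rank-test p-value at desk scale.

## Known limitations

* Validation mode ingests externally normalized matrices only; the exact
  column schema of deposited supplementary files is configuration, not code.
* Gene-permutation GSEA treats genes as exchangeable within the ranked list;
  correlated gene sets inflate neither the nominal p nor q here because null
  sets are drawn independently in the benchmark, but real collections with
  heavy overlap inherit the usual caveats of gene-permutation nulls.
* The loess span (0.4) is fixed per run, not chosen by cross-validation.
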