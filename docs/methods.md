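# Methods

## Model and assumptions

The pipeline treats one comparative MeDIP-chip hybridization as paired
positive intensities over a fixed promoter tiling design. The per-probe
log-ratio M = log₂(treated/control) is assumed to be, after normalization,
exchangeable noise around 0 except in differentially methylated regions,
where it carries an additive shift. Significance is assigned against an
*empirical* normal null — a Gaussian scaled to the mean and SD of all
smoothed M values in the analysis set — not against a noise model derived
from replicates. That choice mirrors the original procedure and has two
consequences worth keeping in mind: (i) real signal inflates σ̂ and makes the
test conservative, and (ii) window autocorrelation makes the nominal
probe-level p-values only approximately calibrated (the measured
false-positive rate at p < 10⁻⁴ on null data is ~2–3×10⁻⁴, within the
tolerated 5×10⁻⁴).

M/A are on the log2 scale. The printed-table convention for coordinates is
0-based half-open throughout; a region's size is end − start, which
reproduces every published "Region size(bp)" value from its Start/End
columns.

## Normalization chain

Order is fixed: MA conversion → GC-grouped loess within each array →
A-quantile across arrays → windowed-median smoothing.

- **GC groups**: 10 quantile bins of probe GC fraction (merged into a
  neighbor below 10 probes). The loess predictor is M ~ A within each GC
  group with span 0.3 and 2 robustness iterations; the fitted curve is
  subtracted. Ten groups and span 0.3 are conventional two-color choices —
  the procedure that inspired this package fixes neither — and both are
  exposed in `NormalizationParams`. The loess evaluation uses a `delta` of
  1% of the A range for speed; on array-sized inputs this changes residuals
  negligibly.
- **A-quantile**: rank k on every array maps to the mean of the arrays' k-th
  order statistics. M is untouched probewise.
- **Windowed median**: window = [midpoint − 300, midpoint + 300), pooling M
  of every same-promoter design probe whose midpoint falls inside, across
  all arrays of the analysis set; fewer than 3 distinct design probes ⇒ no
  value. `min_probes` counts probe *positions*, not pooled values, so three
  arrays over one isolated probe still yield no value. Windows never pool
  across promoter tiles or chromosomes; the *recorded* window interval is
  the full 600 bp (unclipped), which is what guarantees every site and DMR
  is ≥ 600 bp. Pooling across all arrays is the default; a per-array
  smoothing mode exists because the original description is ambiguous, and
  the per-comparison analyses below are exactly that mode.

## DMR calling

Per analysis set: fit the null (sample SD), compute z and two-sided p,
take maximal runs of consecutive probes with p < 10⁻⁴ (strict) as sites,
and merge all sites of a promoter into one DMR (interval = union span,
p = minimum member p, sign of the strongest site as direction).

Replicates are combined two ways. The **intersection** analysis calls sites
separately per comparison (each with its own null, since each hybridization
has its own scale) and keeps a promoter's DMR only when every pair of
comparisons has overlapping significant sites there; the reported p is the
worst of the per-comparison minima — the evidence *every* replicate attains.
Overlap is at the region level, not probe identity, because smoothing shifts
site edges between replicates. The **average** analysis averages the
per-comparison smoothed M (probes defined everywhere only) and runs the
same calling on that signal with its own null; it is deliberately more
permissive. Pairwise "shared site" counts are reported as the number of
overlapping site pairs between two comparisons' site sets; the original
description of these counts cannot be parsed uniquely and the alternative
(a pooled two-array analysis) is not implemented.

Because tests are two-sided, hyper- and hypomethylation both count; calls
carry a sign rather than being filtered by direction. No multiple-testing
correction is applied — the raw p < 10⁻⁴ cutoff *is* the procedure.

## Differential expression

Per gene, the additive two-factor fixed-effects model (treatment + batch, no
interaction) is tested with a type-II F-test for treatment, computed for all
genes at once via residual projectors of the shared design; on balanced
designs this is exactly the classical method-of-moments two-way ANOVA, and
tests verify agreement with both a first-principles sums-of-squares oracle
(to 10⁻⁹) and statsmodels `anova_lm(typ=2)`. Batch effects are estimated as
marginal-mean deviations (the moments estimator); unbalanced designs fall
back naturally to the type-II decomposition.

Fold change is computed from unlogged group means (2^mean-of-log2, i.e.
geometric means), consistent with the unlogged mean-difference criterion in
the same rule; whether the original fold change was logged is unstated and
unlogged is the consistent reading. Selection is the strict conjunction
p < 0.05 ∧ FC > 1.2 ∧ |Δunlogged| > 10, with a 10⁻⁹ relative tie-guard so a
gene at exactly 1.2-fold is rejected despite log2/unlog floating error.

## Synthetic data: what it emulates, what it does not

The generator reproduces the experiment's *structure*: promoter windows of
3,880 + 970 bp tiled at 100 bp median spacing with 50–75 nt probes; three
paired comparative hybridizations; planted DMRs of 600–1,200 bp (one per
promoter, uniform within the window, exactly round(fraction·n) promoters);
a smooth GC-by-intensity dye bias b(GC, A) = amplitude·(GC − 0.5)·σ(A − 10)
split antisymmetrically between channels so it contaminates M but not A;
per-channel Gaussian log2 noise; and, for expression, a balanced
3-vs-3 design in 3 preparation-date batches with additive N(0, batch_sd)
per-gene batch offsets and planted ±log2(fc) shifts.

Defaults (chosen once for realism/testability, since no noise or bias
magnitudes accompany the original procedure): noise_sd = 0.2 (MeDIP,
per channel, log2), gc_bias_amplitude = 0.3, effect_size = 1.0 M,
baseline log2 intensity N(10, 1); expression noise_sd = 0.15, batch_sd =
0.4, fold changes U(1.5, 4), baselines U(6, 11) log2. Sequences with a
target CpG density are built by planting the exact rounded number of CG
dinucleotides at non-adjacent random positions and scrubbing accidental
background CGs, so realized density equals the target to rounding.

Not emulated: spatial array artifacts, print-tip effects,
cross-hybridization, probe-sequence affinity beyond GC, fragment-level MeDIP
enrichment chemistry, or heavy-tailed intensity distributions. Passing tests
therefore demonstrate the *statistical machinery* is correct and calibrated
under the stated noise model, not that the pipeline is robust to every
pathology of real arrays.

## Validation design and problem sizes

The recovery benchmark plants effects of 4× the probe-level null SD of
normalized M (estimated from an effect-free run of the same pipeline).
The probe-level scale is the right referent for `effect_size`, which acts on
per-probe M; the 600 bp median then concentrates that effect (smoothed SD ≈
probe SD·1.25/√6), putting planted probes near z ≈ 8 and yielding
recall = precision ≈ 1 for the intersection analysis. An effect of only 4×
the *smoothed* SD would sit at z ≈ 4.0 against the z = 3.89 cutoff — a
regime where no procedure could reach high recall in all three replicates
simultaneously.

Null calibration uses 2,200 promoters (~10⁵ probes) × 3 comparisons × 5
seeds; recovery uses 200 promoters × 5 seeds; DE calibration 5,000 null
genes and recovery 3 × 2,000 genes. These sizes make the whole suite run in
well under a minute per property while keeping binomial error on the
measured rates small. All generators are pure functions of (config, seed).

## Known limitations

- The empirical null ignores spatial correlation; site-level significance is
  therefore nominal, and the intersection requirement is the real guard
  against false calls.
- Promoter tiles are the only calling universe: intergenic or gene-body
  differential methylation is invisible by design.
- The DMR-vs-site distinction is kept in output, but with sparse signal most
  DMRs consist of a single site.
- `read_dmr_table` trusts printed coordinates; it warns (not errors) when a
  printed size disagrees with end − start.
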