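# Methods

This note documents the statistical procedures implemented in `cobind`,
their assumptions, the defaults that matter, and the design choices made
where the procedure left room.

## Coordinate conventions

All coordinates are 0-based, half-open (BED native) throughout; GTF-style
1-based inputs are converted on read. A gene is stored as (TSS, TTS); on
the minus strand the TSS is the larger coordinate. Keeping one internal
convention avoids off-by-one drift between modules.

## Peak annotation

Peaks are classified by **summit position** (interval midpoint when no
summit is available), assigning each peak to exactly one class with
precedence promoter-TSS > gene body > intergenic. The promoter window is
strand-aware, default −1000..+100 bp around the TSS, configurable; TTS,
exon, intron and UTR positions all collapse into a single gene-body class,
with sub-feature labels reported for information only (without an exon
model the interior label cannot distinguish exon from intron). When a
summit falls in two genes' windows the nearest TSS wins; exact ties go to
the lexicographically smallest gene ID, making output deterministic.

Gene-level binding ("gene bound by factor F") means at least one summit in
the gene's promoter window or gene body, with duplicate hits collapsed.
The ±2 kb TSS window is *not* used for binding calls — it is the density
extraction window of the profiling module; the two procedures are kept
separate deliberately.

## Bootstrap gene-set enrichment

Each iteration draws `n_draw` **distinct** gene IDs uniformly without
replacement from the `N`-ID pool and records the overlap with the fixed
interest list of `K` IDs; `n_iter` defaults to 10,000. The empirical mean
and sd (denominator `n_iter − 1`) define the null, and the observed count
enters as `z = (mean − expect)/sd` — negative under enrichment, so both
the signed z and `|z|` are reported (the magnitude is the conventional
headline number).

Two deliberate choices:

- **Parametric tail p-values.** The p-value is the standard-normal tail at
  `|z|` (doubled for two-sided, capped at 1), not an empirical histogram
  quantile: 10⁴–10⁵ draws cannot resolve probabilities below ~10⁻⁵,
  while the z-scores of interest imply tails far below 10⁻⁹⁰.
- **Hypergeometric oracle.** Uniform sampling without replacement makes
  the overlap exactly hypergeometric, so `mean = nK/N` and
  `sd² = n(K/N)(1−K/N)(N−n)/(N−1)` are computed alongside every bootstrap
  (via scipy) and verified against it in the tests — including exhaustive
  enumeration of all C(N, n) draws for N ≤ 12.

The bootstrap draws literally (numpy `Generator.choice` without
replacement) rather than sampling hypergeometric variates; at ~75 µs per
10,600-of-26,460 draw, 10⁵ iterations take seconds, so fidelity to the
stated resampling procedure costs nothing meaningful.

## Coverage, profiles, clustering

Reads are extended 3′-ward from their 5′ end to 200 bp (the typical
sonicated-fragment length) and counted into 25 bp bins; a bin counts every
extended read overlapping it. Input normalization scales the control to
the IP's total tag count, then forms `(ip + c)/(s·input + c)` per bin with
pseudocount `c = 1.0` (the data are silent on this constant; 1 tag per
25 bp bin avoids division blow-ups and is negligible at realistic depth),
with log2 on request. The pseudocount intentionally does not scale with
depth, so exact depth-invariance of ratios holds only at `c = 0`;
with `c = 1` it is near-exact at realistic counts.

TSS matrices span ±2 kb around each TSS (the window is read as symmetric),
strand-oriented so downstream is always rightward; bins falling off a
chromosome edge are NaN and excluded from averages, never zero-filled
(zero-filling biases flank means downward). Metagene profiles keep flanks
in native bins and linearly interpolate the gene body onto a fixed number
of columns, so genes of different lengths contribute comparably.

k-means clustering concatenates several row-aligned density matrices,
scaling each to unit mean first (the linear scaling used by seqMINER-style
heatmap tools) so marks of different depth weigh equally; Lloyd iterations
run via scikit-learn with a fixed `random_state` and `n_init = 10`, and
labels are renumbered by decreasing cluster mean signal so label 1 is
always the strongest cluster. `k` has no principled default here and must
be chosen by the user (the CLI defaults to 5 with a warning in the docs).

Bivalence: a site is bivalent iff its mean window density is at or above a
threshold θ for H3K4me3 **and** H3K27me3 **and** Ezh2 jointly; factor
matrices add boolean co-occurrence columns (e.g. bivalent ∧ A⁺ ∧ B⁻). The
threshold is a free parameter because absolute density scales depend on
normalization; on synthetic data any θ between background and signal
levels recovers the planted sites exactly.

## Expression integration

Quintile groups are equal-frequency rank groups (group 5 highest), with
ties broken by stable gene-ID order and an optional positive-only filter
that drops zeros before ranking. Group assignment is invariant under
monotone transforms of the expression values.

Notched-box comparisons use `median ± 1.58·IQR/√n`; two groups' medians
are called distinct iff the notch intervals are disjoint.

Condition-specific genes are defined by a two-threshold rule — mean test
expression ≥ 1 FPKM and mean control expression ≤ 0.1 FPKM by default —
rather than by a count-based differential test, which would need read-level
data that this package treats as upstream. On the synthetic truth the rule
recovers planted specific genes exactly without noise and ≥95% at
log-normal noise sd 0.2.

## NSAF and the specificity filter

`SAF = spectral count / protein length` corrects for larger proteins
yielding more peptides; `NSAF = SAF / ΣSAF` normalizes within the run, so
NSAF sums to 1 per run (exact to 1e−9) and is invariant to uniform count
scaling. Zero-count proteins are excluded before normalization (NSAF is
undefined for unobserved proteins). The specificity filter keeps a protein
iff it is absent from the MOCK run or its IP/MOCK **NSAF** ratio is at
least 10; the ratio is taken on NSAF rather than raw counts because the
two runs generally differ in depth and NSAF is the cross-run abundance
measure. Raising the fold threshold can only remove proteins (monotone).

## FCROS

For `k` test/control pairs — all test×control cross pairs, deterministic
and information-maximal when no natural pairing exists — each pair's fold
changes are ranked across genes (average ranks on ties), ranks are
normalized by the gene count, and the per-gene mean r̄ over pairs is the
statistic. The f-value is `Φ((r̄ − μ̂)/σ̂)`; down-regulated genes satisfy
`f < α/2`, up-regulated `f > 1 − α/2`, default α = 0.05.

Null-moment estimation is the one place this implementation had to choose
carefully. r̄ is a mean of (positively correlated) uniform ranks, so its
null distribution is **lighter-tailed than normal**; fitting σ̂ from the
IQR and reading tails off a normal therefore under-covers exactly where DE
calls are made — measured type-I error ≈ 0.034 at nominal 0.05. Instead,
μ̂ is the median of r̄ and σ̂ is matched to the empirical 2.5/97.5
percentile span (`σ̂ = (q₉₇.₅ − q₂.₅)/(2·1.96)`), anchoring the normal
approximation at the working tails; measured type-I error is ≈ 0.051, and
a minority of truly differential genes shifts the anchors only mildly
(in the conservative direction). When the span collapses to zero the
exact independent-uniform null `μ = 1/2, σ = √(1/(12k))` is the fallback.
The statistic is invariant to positive rescaling of any sample, and
swapping test with control maps r̄ to `(n+1)/n − r̄`.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis relies
on, not sequence-level realism:

- **Universe**: genes placed without overlap on 3 × 50 Mb synthetic
  chromosomes, lengths log-uniform 2–100 kb, random strands. These desk-
  scale defaults cannot host a 26,460-gene universe (which would need
  ~660 Mb); large universes require larger chromosomes or a smaller
  maximum gene length, and the generator fails loudly ("cannot place
  genes") when capacity is exceeded. Set-statistic analyses that need the
  published pool size operate on ID pools directly and do not need placed
  genes.
- **Peaks**: feature classes allocated by exact largest-remainder
  apportionment of the requested mix, then randomly interleaved, so
  re-annotation recovers the mix up to rounding rather than merely within
  multinomial error. Promoter summits are placed inside the same window
  the annotator uses (recording the nearest-TSS winner as truth when
  neighbouring windows overlap); gene-body summits avoid all promoter
  windows; intergenic summits avoid genes and windows by rejection
  sampling. Peak widths are normal (mean 500, sd 150, floor 50 bp) — a
  free knob, since no width statistics constrain it.
- **Reads**: 5′ positions concentrate extended-read centres at summits
  (truncated normal, sd 50 bp) or exponentially downstream (scale 500 bp)
  of them, over uniform Poisson background. No base-level sequence, no
  aligner artefacts, no duplicate structure.
- **Expression**: log-normal baseline (log2 mean 3, sd 2) shared between
  conditions; planted specific genes are zero in control and ≥2 FPKM in
  test before noise; planted DE genes shift by the requested log2 fold
  change; measurement noise is log-normal with sd 0.25 in log2 units
  (typical replicate scatter for arrays/RNA-seq at moderate depth).
- **Spectral counts**: multinomial draws with weight ∝ protein length for
  an equimolar complex; background binders enter the IP down-weighted by
  the contamination fraction and make up the MOCK run entirely.

Consequently, passing tests demonstrate the *procedures* are correct and
calibrated under these assumptions; they do not demonstrate robustness to
mappability artefacts, copy-number bias, antibody efficiency differences,
or correlated replicate noise, none of which the generator models.

## Problem sizes and tolerances

Bootstrap acceptance checks run 10⁵ iterations (the headline procedure
specifies 10⁴; the larger count stabilizes integer rounding of means and
|z|). FCROS calibration uses 50 null runs of 2,000 genes and one recovery
run of 10,000 genes with 100 planted 4-fold genes at 3v3 replicates.
Coverage and clustering tests run on hundreds of genes/peaks on 5–50 Mb
chromosomes. The full suite completes in well under a minute on one CPU;
`scripts/acceptance.py` in under half a minute.
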