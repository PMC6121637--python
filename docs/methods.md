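# Methods

This note documents the models, defaults and design choices behind
`methlink`, and what the synthetic-data tests do and do not establish
about real data.

## Methylation levels, contexts and correction

A cytosine site is summarised by the read pair (meth, unmeth); its
level is `ML = meth / (meth + unmeth)`, undefined (never zero) at zero
coverage. Contexts are assigned from the reference sequence,
strand-aware: CG when the next base 3′ of the cytosine is G, CHG when
the base after that is G, CHH otherwise (H = A, T, C); the minus
strand is read as its reverse complement. A cytosine whose context
cannot be resolved because the contig ends is flagged ambiguous rather
than guessed.

Bisulfite non-conversion is modelled as a mixture: a site with true
level μ is observed at `μ_obs = μ + (1 − μ) r`, where r is the
fraction of truly unmethylated cytosines that escape conversion. The
correction `(ML − r)/(1 − r)` is the exact algebraic inverse, so
correcting an aggregate (region- or genome-level) apparent level is
unbiased. Correcting site by site and then averaging is slightly
upward-biased near μ = 0 because the clip at zero truncates the noise
distribution; aggregate levels are therefore corrected after
averaging. r is estimated as apparent-methylated reads over all reads
on the unmethylated spike-in contig (`lambda_control`).

"Methylated site" tallies (context summaries) call a covered site
methylated when its methylated-read count is inconsistent with
non-conversion noise alone: a one-sided binomial test against r,
BH-adjusted within context at q < 0.01 (with r = 0 this degenerates to
meth ≥ 1). Published tallies can also be consumed directly as
pre-tabulated counts (`summarize_context_counts`), which is how the
bundled petal table is analysed; the printed percentages in that table
are truncated, not rounded, to two decimals, so comparisons are made
at the printed precision (±0.01).

## Genomic features

Genes are oriented intervals (TSS→TES) with exons; derived regions are
the promoter (2 kb upstream of the TSS, identical in extent to the
upstream flank label), introns (body minus exons) and the 2-kb
downstream flank. Region labels may overlap (one gene's promoter can
lie in another's body) and positions contribute to every label that
covers them; "intergenic" means covered by no gene-derived label and
no TE. A TE is intragenic when it overlaps any gene body by at least
1 bp. Interval queries go through an interval tree; bulk masking of
sorted site positions uses binary search.

Metagene profiles use 50 fixed 40-bp bins per flank and 50
length-normalised bins across the body, oriented so bin 1 is the far
upstream edge for both strands. Averaging is gene-weighted: site
levels are averaged within each gene's bin first, then across the
group's genes, so long or site-dense genes do not dominate. Expression
groups split genes at FPKM 1 (no expression) and at the 25th/75th
FPKM percentiles of the expressed genes (linear interpolation;
boundaries inclusive upward, so a gene exactly at the 75th percentile
is "high"); computing the percentiles over expressed genes only is the
interpretation consistent with "low expression" starting at 1, and the
alternative is available via a flag. Methylation groups are quintiles
of the per-gene region level, genes without a measurable site
excluded and counted.

## Differential methylation

The replicate model is beta-binomial: at one site, replicate r of a
condition contributes m_r successes in n_r reads with
`Var(m_r/n_r) = μ(1−μ)(1 + (n_r−1)φ)/n_r`.

Calling proceeds as:

1. **Smoothing** (default window 200 bp): per replicate, counts are
   pooled over sites within ±100 bp, which is the depth-weighted moving
   average of levels. The window is deliberately smaller than the
   500 bp many callers default to: called region edges can overshoot
   true edges by roughly half a window, and at the few-hundred-bp scale
   of plant DMRs a 500-bp window costs more in boundary resolution than
   it gains in pooling. Setting the window ≤ 0 disables smoothing.
2. **Dispersion**: per site and condition, a method-of-moments estimate
   from the (pooled) replicate proportions — with pooled proportion p,
   replicate variance s² and harmonic-mean depth n̄,
   `φ̂ = (n̄s² − p(1−p)) / (p(1−p)(n̄−1))` — shrunk toward the
   context-wide mean of the raw estimates with weight
   `(R−1)/(R−1+4)` on the site, floored at 1e-4. The trend uses the
   mean rather than the median because the per-site estimate at R = 3
   is heavily right-skewed and its median underestimates φ.
3. **Wald test**: `z = (μ₁ − μ₂)/√(v₁ + v₂)` with
   `v_c = Σ_r μ(1−μ)(1 + (N_r−1)φ_c)/N_r / R²` over the pooled
   replicate depths N_r, two-sided normal p-value. Because the mean,
   its variance and the dispersion all refer to the same window-pooled
   replicate counts, the test remains calibrated with smoothing on: the
   window is treated as a single beta-binomial locus whose effective
   dispersion is estimated from the pooled proportions themselves. The
   μ(1−μ) factor uses a continuity-clamped mean so boundary sites keep
   positive variance. Sites uncovered in either condition are skipped.
4. **Merging** (defaults: p < 1e-5, min length 50 bp, ≥ 3 significant
   sites, gap ≤ 100 bp, ≥ 50% of covered sites significant): runs of
   significant same-context, same-sign sites become DMRs spanning the
   first to last such site. Direction is recomputed from raw (not
   smoothed) pooled counts inside the region — "hyper" means the first
   condition (WT by convention) is more methylated — which makes
   direction conservation against raw counts hold by construction. No
   genome-wide multiple-testing correction is applied before merging
   (the region filters act as the control); BH-adjusted per-site
   p-values are emitted alongside for transparency. Contexts are
   always tested separately. Which condition "hyper" refers to is a
   convention and is configurable.

Measured operating characteristics (recomputed by the test suite and
`scripts/acceptance.py`): per-site type-I error ≈ 0.05 on effect-free
genomes, ≲ 0.2 spurious DMRs per Mb per context at defaults, and > 90%
recovery (Jaccard ≥ 0.5, direction always correct) of planted regions
with |effect| ≥ 0.3 and ≥ 8 target-context sites at 30× depth.

## Differential expression

Counts are modelled as NB with `Var = μ + αμ²`. Libraries are scaled
by median-of-ratios size factors. The per-gene α comes from the pooled
within-condition variance by method of moments and is squeezed toward
a trend `α(μ) = a₀ + a₁/μ` fitted across genes by non-negative least
squares, with prior weight 20 against the 4 residual degrees of
freedom — strong moderation, chosen because the 4-df per-gene estimate
is so noisy that its tail drives false discoveries; the cost is that
genuine per-gene dispersion differences are mostly ignored, which is
acceptable when dispersion is roughly shared across genes and is the
documented limitation otherwise. The test is a Wald statistic on
`log(m₁+0.5) − log(m₂+0.5)` with
`se² = (1/(m₁+0.5)+α)/R₁ + (1/(m₂+0.5)+α)/R₂`, normal reference, BH
adjustment; "up" means higher in the first condition (WT), and
swapping condition labels exactly flips signs and preserves p-values.
This is a minimal re-derivation of the classic NB workflow, not a
re-implementation of any specific tool. Measured: empirical FDR ≈ 0.065
at BH 0.05 and power ≈ 97% for four-fold changes at mean 100
(dispersion 0.1, 3 vs 3).

FPKM uses total assigned counts as the library size unless one is
supplied; gene length is the summed exon length. "Expressed" means
replicate-averaged FPKM ≥ 1 in a condition; condition-specific genes
are expressed in exactly one.

## Integration

Gene-level methylation for correlations is the unweighted mean of site
levels in the region (promoter, body or downstream flank), per context
and sample group. Pearson r carries the exact t-transform p-value
(n − 2 df); no correction across strata. The cross-classification
intersects DMR-related genes (≥ 1 bp overlap of a DMR with the body or
the promoter — the minimal reading of "overlapping") with DEGs per
context and region; a gene hit by both hyper- and hypomethylated DMRs
counts in both direction classes, and those dual-class genes are
reported. The "all" DEG profile group is the union of up- and
down-regulated genes, not all tested genes. The TE layer emits one row
per (gene, TE, DMR) combination where the DMR overlaps the TE and the
TE lies in the gene's body ± 2 kb; concordance (hyper∧down or
hypo∧up) is attached as a label, never used as a filter.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the methods assume:
a 2-Mb, 2-chromosome genome at GC 0.38 with 300 non-overlapping genes
(1–3 kb, up to 4 exons, ≥ 2 kb from contig edges so flanks exist) and
300 TEs (class I/II 60/40, Copia/Gypsy/LINE-L1 vs Helitron/hAT/MuDR);
Poisson 30× depth per site and sample; beta-binomial counts at context
baselines CG 0.380, CHG 0.204, CHH 0.092 (genome-wide petal averages)
with replicate dispersion 0.05 per context (a choice — the
replicate-to-replicate dispersion of real petal WGBS is not published —
exposed in the configuration); 150 planted DMRs, 200–1000 bp, ≥ 5
target-context cytosines, effect ±0.4 applied to one context in the WT
condition (clipped at [0,1] with a logged warning, e.g. CHH
hypomethylation saturates at −0.092); placements 40% promoter / 30%
body / 20% TE / 10% intergenic; non-conversion 0.008 mixed in as
described above, with a 20-kb unmethylated spike-in; NB expression
(dispersion 0.1, log-normal baseline means around 150) with the WT
mean scaled by `exp(coupling_slope × Δ)` where Δ is the summed realised
effect of promoter-overlapping planted DMRs and the default slope is
−2 — a planted +0.4 promoter DMR therefore carries a true natural-log
fold change of −0.8, the negative methylation-expression relationship
the integration layer is built to detect. Everything is deterministic
given the seed, to the byte in the emitted files.

Deliberately not emulated: read-level artefacts (sequencing error,
M-bias, PCR duplicates — out of scope upstream of this package);
bimodality of real methylation landscapes — every simulated site of a
context shares one baseline mean, whereas real CG methylation is
strongly bimodal (mostly ~0 or ~1), so simulated methylated-site
tallies do not reproduce published site-count ratios and those are
exercised on the bundled published counts instead; CpG strand pairing
(strands are simulated independently, matching per-cytosine report
semantics); genome composition (uniform random sequence, no repeats or
isochores); and expression coupling outside promoters. Passing tests
therefore demonstrate correctness of the arithmetic and calibration
under the stated model, not robustness to real-data artefacts the
model excludes.

Problem sizes in the test suite and acceptance script (2 Mb pipeline
runs, ten 1-Mb null genomes, 10,000-gene expression simulations) were
chosen so the full suite completes in about a minute while leaving the
measured rates' Monte-Carlo error well inside the asserted bands.

## Numerical details and degenerate inputs

Zero-coverage sites are NaN everywhere and excluded from means,
histograms and tests. Proportion variances are clamped via the
continuity-corrected mean `(m+0.5)/(n+1)` where a zero would otherwise
make a Wald statistic infinite. Dispersion estimates are clipped to
[1e-4, 0.99]; NB dispersions to [1e-8, 10]. Percentiles use linear
interpolation. Degenerate grouping inputs (all-equal methylation
levels, fewer than four expressed genes) raise or collapse to a single
group with a warning rather than returning arbitrary splits. All
internal intervals are 0-based half-open; cytosine reports are 1-based
(Bismark dialect) and GFF3 is 1-based closed, converted at the I/O
boundary.
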