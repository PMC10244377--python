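# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open.  GTF input/output
converts at the boundary (GTF is 1-based closed); BED and bedGraph are
pass-through.  A single internal convention eliminates off-by-one drift
between the interval operations.

## Unique non-overlapping intron set

Candidate introns are the gaps between consecutive exons of each
transcript.  Identical candidates across isoforms are emitted once;
any candidate overlapping an exon of *any* isoform of the same gene is
excluded entirely (not truncated), keeping junction-read semantics
clean.  Residual overlapping candidates are resolved in favour of the
lexicographically smallest transcript id — the de-duplication rule
needs a deterministic tie-break, and transcript id order is stable
across runs and platforms.  Ordinals are 1-based from the 5' end of the
gene on its strand.  Genes sharing a locus on opposite strands are
processed independently.  Correctness is established against a
per-base brute-force oracle on thousands of random genes.

## Splicing efficiency

SE = ee/(ee+ei) per intron and sample; donor-side and acceptor-side
exon–intron reads enter one pooled `ei` count (readers that distinguish
them must sum).  Rows with ee+ei below `min_reads` (default 10) are
flagged missing rather than imputed or zeroed: the ratio is unstable at
low coverage, and silently treating it as 0 would masquerade as full
retention.  Gene-level SE pools counts over the gene's unique introns
before dividing, so it is a coverage-weighted summary bounded by the
per-intron extremes.  ΔSE contrasts average SE per condition over
replicates first, then difference (condition − reference).

Cluster-count bins default to {0}, {1–2}, {3–5}, {≥6}; the grouping is
configurable and the report records which bins were occupied.  Group
tests pool per-intron, per-sample SE values.

## Nonparametric testing

* Kruskal–Wallis: tie-corrected H, chi-square reference (delegated to
  scipy).
* Dunn all-pairs: pooled-rank mean differences with tie-corrected
  variance, two-sided normal p-values, Benjamini–Hochberg adjustment
  across pairs (the adjustment choice is ours; the procedure is
  calibrated against a permutation oracle in the tests).  The normal
  approximation is accurate to about the lattice width of the discrete
  permutation distribution; at 6–10 observations per group that is
  ±0.02–0.04 in mid-range p-values.
* Games–Howell: Welch standard errors, Welch–Satterthwaite df, p from
  the studentized-range distribution with k groups (scipy's
  `studentized_range`); cross-checked against an independent
  implementation and against Tukey HSD in the equal-variance balanced
  limit.
* BH step-up is implemented directly (a few lines) and verified against
  the brute-force definition and statsmodels.

## Peak analysis

Peak significance uses log2FC ≥ 3 over the size-matched input and
padj ≤ 0.001, both inclusive.  Category assignment is any-overlap
(≥1 bp), strand-matched, by the priority CDS-exon > 5'UTR > 3'UTR >
noncoding exon > protein-coding intron > noncoding intron > intergenic:
when a peak spans a boundary the exonic call wins; the order is
configurable.  Distances to features are gaps to the nearest peak
*edge* (0 for overlap), with ties broken toward the smaller genomic
start; peak centers (floor of the midpoint) are used only for motif
windows.  The <2 kb distance bound is inclusive at exactly 2000 nt.

Exon metaprofiles use internal exons only (300-nt intronic flanks on
both sides, exon body rescaled to 100 bins); terminal exons would mix
intergenic background into a flank.  Pre-miR profiles extend each
record ±2000 nt, rescale to a 5000-nt axis, take the median within
50-nt bins, and average across pre-miRs.  Cassette-exon maps use
250-nt-intron + 50-nt-exon windows at the acceptor and 50+250 at the
donor, per-position RPKM(IP)/RPKM(SMI) with a one-read pseudocount in
numerator and denominator (identical tracks give exactly 1), averaged
in 50-bp bins and then across events; events require |ΔPSI| ≥ 0.2.

## miR expression

Size factors are median-of-ratios over features nonzero in all samples,
rescaled to geometric mean 1.  baseMean is the mean of normalized
counts over all samples.  The fold change is the manual formula
log2[(N_x+1)/(N_y+1)].  DE filtering is inclusive at every boundary
(|log2FC| ≥ 1, padj ≤ 0.05, baseMean ≥ 5 for miRs / 10 for genes).  In
the synthetic pipeline p-values come from per-feature two-sided
Mann–Whitney tests with BH adjustment; externally computed DE tables
pass through the filter unchanged — negative-binomial GLM machinery is
out of scope.  Category assignment uses the mature miR position, with
precedence <2 kb > intron context > other.

## Set overlap

The representation factor is k/(n1·n2/N); the p-value is the inclusive
upper tail P(X ≥ k), summed as a logsumexp over the exact log-pmf so
that values far below 1e-12 remain meaningful.  The background universe
must be supplied explicitly — the result is sensitive to it and no
default is defensible.

## AFM Hertz analysis

The force model is the Sneddon cone, F = (2/π)·tanθ·E/(1−ν²)·δ², with
ν = 0.5 and θ = 22° fixed.  The prefactor convention (2/π with tan θ)
is stated explicitly so fitted moduli are comparable across software.

Contact-point estimation is two-stage: a coarse threshold crossing
(baseline median + 3 SD from the first 30% of the approach, sustained
for 5 samples), then refinement by profiling the piecewise model
b + c·max(z−z_c, 0)² over candidate contact positions — for soft
samples the quadratic onset hides below the noise for hundreds of
nanometres, and the refinement is what makes sub-20-nm accuracy
possible.  Given the contact point the model is linear in (E, offset),
so the fit on the 150–500 nm indentation window is a closed-form simple
linear regression of force on δ²; the closed form is used deliberately
because SVD-based least squares truncates a design whose columns differ
by ~13 orders of magnitude (m² vs constant).  Pixels with fewer than 10
samples in the window are flagged unfit, not errors.

Colony centers: the height image (ramp length minus contact position)
is thresholded at 50% of its relative range and the mask eroded by a
2-pixel margin; the pipeline backs the margin off when erosion empties
the mask on small scan grids.  MAD normalization uses the 1.4826
normal-consistency constant with an outlier cutoff of 3.5 robust SDs;
group comparisons drop flagged outliers before testing.  Both pooled
and per-colony aggregation are possible; pooled pixel values are the
default and the reports state the sample sizes used.

**Accuracy limit for soft samples.**  With the default 10 pN additive
instrument noise floor, modulus recovery at 5% multiplicative noise is
within 5% (median) for E ≥ 1 kPa; at 0.5 kPa the additive floor
dominates the ~40 pN full-scale signal and the contact-point
uncertainty (~30 nm SD) roughly doubles the error to ~9%.  This is a
statistical limit of the changepoint estimation, not an implementation
artifact; recovery experiments that isolate the multiplicative-noise
condition set the additive floor to zero.

## Synthetic-data generator

The generator is the study-conditions contract: one seed determines
every dataset, each generator draws from its own independent stream,
and every dataset ships a machine-readable truth table.

Defaults and why:

* 80 genes (2–8 exons, 100–300-nt exons, 0.5–3-kb introns), 30%
  noncoding, 25% of genes with a second isoform skipping one internal
  exon — enough structure to exercise the redundant-intron rules.
* Junction counts: 200 reads per intron, 4 replicates per genotype;
  true SE = clip(β₀ + β₁·g(c) + β₂·log2(1+d), 0.01, 0.99) with
  β₀ = 0.8, β₁ = −0.05 per cluster-count bin code g(c) ∈ {0,1,2,3}, and
  β₂ = 0.05 per log2-unit of the LIS1-dose scalar d (F/- 0.5, WT 1,
  OE 2).  Reads are binomial, so observed SE concentrates on the truth
  at these depths.
* Peaks: Poisson 1.2 per intron, donor distance ~ Exp(300 nt) —
  reproducing the donor-proximal binding asymmetry; ~87% of significant
  peaks intronic with small exonic/intergenic admixtures; 15% extra
  sub-threshold peaks exercise the significance filter.  Random peaks
  keep a 2.5-kb guard distance from non-flagged miRs so planted
  distance categories stay true.
* miRs: 120 mature miRs (25% near-peak, 35% in protein-coding introns,
  15% in noncoding introns, rest intergenic); negative-binomial counts
  (variance μ + 0.3μ²) with a +1.5 log-unit near-peak effect and a
  +0.5 effect for noncoding-intron residents.
* AFM: four groups at 1 / 3 / 5 / 6 kPa on 12×12 grids over a Gaussian
  dome colony (400 nm), 5% multiplicative force noise, 10 pN additive
  floor, ±20 nm contact jitter, 400 samples per curve, indentation to
  500 nm.
* Interactomes: 100×100 lists sharing exactly 28 members in a
  1000-protein universe (representation factor 2.8).

What the generator does *not* emulate: read-level sequencing error and
alignment artifacts, overlapping genes and antisense transcription,
GC/mappability bias in coverage, batch effects across samples,
real miRNA biogenesis (counts are feature-level), cantilever drift or
adhesion in force curves.  Passing tests therefore demonstrate that the
estimators recover planted effects under idealized sampling noise — not
that they are robust to every artifact of real libraries.

## Problem sizes in the test suite

The suite runs the full default cohort (~325 introns, ~380 peaks, 120
miRs, four 12×12 AFM grids) plus targeted experiments: 500-intron SE
recovery, 500 curves per modulus for Hertz recovery, 1000-element
brute-force comparisons per interval operation, 2000-replicate null
calibrations for the category tests, and 1e5-permutation oracles for
Dunn.  These sizes give sub-percent Monte-Carlo error on the quantities
asserted while keeping the whole suite around a minute.
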