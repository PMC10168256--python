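# Methods

## Model and assumptions

The scan targets biparental RIL panels: every line is (nearly) homozygous,
so at each informative marker a line carries one of the two parental
alleles, and the de novo mutations observed in a line accumulated on the
haplotype background it inherited.  A mutator allele linked to a marker
skews the *aggregate* mutation spectrum of the lines that inherited it,
which the cosine distance between the two groups' aggregate spectra picks
up.  The method assumes:

* mutations are private, independently observed events (each record counts
  once; exact duplicate records are rejected by default);
* spectra are comparable across groups after aggregation — cosine distance
  is scale-invariant, so unequal group sizes and unequal per-line mutation
  counts are tolerated by construction;
* heterozygous and missing genotype calls carry no usable group label and
  are excluded from both groups at the focal marker (they still contribute
  dosage 0.5 / nothing, respectively, to the genome-wide allele-frequency
  vectors used for the relatedness correlation).

## Mutation-type classification

Types are strand-collapsed so the mutated base is written as C or A; a
record with a G or T reference is reverse-complemented (ref, alt, and
context jointly) before labelling.  At k=1 with the CpG category enabled,
a C>T whose 3′ neighbour in the supplied context is G becomes CpG>TpG and
is excluded from plain C>T; disabling the category merges the two exactly.
A context too short to resolve the CpG status or the k-mer window is
rejected with a record-identifying error — silent misclassification would
corrupt spectra invisibly, so no default is guessed.  Positions are 1-based
(VCF convention); marker positions are in Mbp (GeneNetwork convention).

## Numerical choices

* **Cosine distance** uses Euclidean norms; an all-zero aggregate vector is
  an error at the API level and a flagged, excluded marker inside scans.
  Tiny negative round-off (identical directions) is clamped to 0.
* **Adjustment regression** is simple OLS with intercept, fit only on
  markers with a defined distance and similarity r; markers with an
  undefined r get no adjusted value and are excluded from peak selection
  and from permutation maxima, keeping observed and null statistics
  comparable.  If r is constant the slope is undefined and residuals fall
  back to deviations about the mean.
* **Permutations** shuffle the sample-to-spectrum assignment, within epoch
  strata when requested.  The adjustment regression is re-fit inside every
  permutation (shuffling breaks the spectrum–relatedness link but not the
  marker r values); a flag can freeze the observed fit instead.  The
  threshold is the order-statistic (type-1) percentile: N=10,000 and
  p=0.05 give exactly the 9,500th sorted maximum.
* **Bootstrap CIs** resample haplotypes with replacement, jointly taking a
  line's spectrum and genotype column, and rescan only the peak chromosome
  (the relatedness correlation is therefore computed from that chromosome's
  markers in each trial).  Peak ties break deterministically toward the
  lowest genomic coordinate.  Trials with no scannable marker are discarded
  and counted.  On a single-marker chromosome the interval degenerates to
  that marker's position.
* **Random streams**: one root seed is fanned out through
  `numpy.random.SeedSequence` substreams (per trial, and per stage in the
  CLI), so permutation, bootstrap, and simulation randomness never
  interleave and every run is reproducible.

## The generator and what it emulates

`simulate` draws unlinked biallelic genotypes (alternate-allele frequency
0.5 by default) and per-line spectra as independent Poisson counts with
per-type means λ = P·m, where P is the mouse germline 1-mer probability
vector (0.29, 0.17, 0.12, 0.075, 0.1, 0.075, 0.17) for (C>T, CpG>TpG, C>A,
C>G, A>T, A>C, A>G); 3-mer types split their central type's probability
evenly over the 16 flank combinations.  Carriers of the mutator allele have
the target type's mean multiplied by the effect size e ≥ 1.  Per-line mean
counts are either fixed at m, an evenly spaced integer grid from m to 20m
(emulating variable inbreeding durations; the grid includes both
endpoints), or uniform draws from the same range.  The whole λ vector is
scaled by M_i/m so a line's expected total matches its assigned count while
preserving spectrum shape.

The generator does **not** emulate linkage between markers, residual
heterozygosity, epoch-specific founder variants, variable callability, or
upstream variant-calling noise.  A green simulation-based test therefore
establishes the statistical behaviour of the scan under idealised panel
structure, not robustness to those real-data features.

## Power estimation and its calibration

A power trial computes the "focal" cosine distance at the mutator marker of
a fresh dataset, then builds a permutation null; the trial succeeds when
fewer than α·N null statistics reach the focal distance.  Two null
statistics are available:

* `max` (default): each permutation's maximum distance over all markers —
  the genome-wide scan null.  This matches how significance is assessed in
  a real scan.  Its type-I error *at a single pre-specified locus* is far
  below α by construction (that is the genome-wide correction working).
* `focal`: each permutation's distance at the mutator marker only — the
  single-locus null, whose p-values are uniform under no effect and whose
  type-I error is α.  This mode exists for calibration studies.

Power under the `max` null depends directly on the number of simulated
markers, because more markers raise the null maximum.  The default is 100
markers — the documented desk-scale setting — and power estimates at this
setting are *optimistic* relative to a panel genotyped at thousands of
markers: with 100 haplotypes × 500 mutations and effect 1.2 the acceptance
script measures ≈0.98 power for C>A and ≈0.35–0.45 for C>G at 100 markers,
and both fall as `n_markers` grows.  When comparing against power figures
quoted for denser panels, set `n_markers` accordingly.

## Epistasis model

Fit with statsmodels' Poisson GLM (log link, offset = log exposure with
fixed coefficient 1).  The additive model needs ≥ 4 samples spanning ≥ 3 of
the 4 genotype combinations; the interaction coefficient is identifiable
only when all four combinations are observed (the empty cell is named in
the error — a rank-deficient design is refused rather than silently
dropped).  The LRT statistic is the deviance difference against χ²(1).
Predicted counts use the Wald CI on the linear predictor, exponentiated;
predictions at exposures outside the fitted range warn.  The 2×2
target-vs-rest enrichment test uses Pearson's chi-square without continuity
correction, appropriate for the large aggregate counts these tables hold.

## Known limitations

* No kinship/mixed-model correction and no use of heterozygous genotypes in
  the association itself — the relatedness adjustment is a single-regressor
  linear control.
* Bootstrap CIs can over- or under-cover in QTL-style localisation; the
  coverage test in this repository checks ≥ 85% empirical coverage at
  nominal 90% for a strong planted effect, not general calibration.
* The similarity correlation includes the focal marker in the genome-wide
  frequency vectors (negligible for realistic marker counts).
* Upstream variant calling, filtering, and annotation are out of scope; the
  mutation table is taken at face value.
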