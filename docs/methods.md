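# Methods

This note documents the models and procedures implemented in `twinscope`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic data do and do not establish.

## Study design

The unit of analysis is a five-member nuclear family: two parents,
dizygotic twins discordant for specific reading disability (SRD), and an
older sibling with reading difficulty. Genotypes exist for all five
members; imaging phenotypes for the three siblings. Three sibling pairs
structure every comparison: the *twin-twin* pair (proband vs typically
developing twin — the baseline, expected to be most similar), the *SRD*
pair (the two affected siblings), and the *TD-OS* pair (typically
developing twin vs affected older sibling). Risk-related measures are
those on which the SRD pair is more alike than the twins; measures
tracking current reading skill are expected to align the TD-OS pair.

## Genetics

Calls are diploid, unphased, biallelic; genotype equality always compares
unordered allele pairs. The filter pipeline is fixed and order-sensitive:

1. **No-call QC.** Every call with confidence score ≤ 0.15 (GenCall
   semantics, carried in a `GC` FORMAT field) is set missing, per sample.
   The boundary is inclusive: a score of exactly 0.15 is a no-call.
2. **Family-invariant removal.** SNPs whose called genotype is identical
   across all five family members are dropped, as are SNPs with a missing
   call in any member. Parents participate in this step (it is defined on
   the whole family), but not in the pattern match.
3. **Co-segregation pattern.** A SNP matches when the two affected
   siblings carry equal genotypes and the unaffected twin's called
   genotype differs. SNPs with a missing call in any of the three siblings
   are excluded rather than imputed — the conservative choice, and the
   only one that keeps the planted-truth recovery property exact.

Per-gene and functional-class tallies are taken from the annotation
columns; the built-in interval fallback (gene body → intronic, flank →
intergenic) is approximate and only used where no annotation is supplied.
The pattern proportion among variable panel SNPs is compared with the same
proportion computed identically on off-panel SNPs.

The denominator question — whether "variable SNPs" are counted before or
after missing-call exclusion — is resolved by construction here: step 2
already drops SNPs with missing calls, so both counts coincide in the
default pipeline; `CosegregationResult` still records `n_pattern_evaluated`
separately for tables fed to the pattern match directly.

## Morphometry similarity (ICC)

The similarity of two siblings' morphometry is the single-measure ICC over
their vectors of per-(ROI, hemisphere) averages; the two siblings are the
"raters", each (ROI, hemisphere) an item. Hemispheres are kept as separate
items rather than averaged, preserving asymmetry information; a 7-ROI
region set therefore contributes 14 items. The default form is ICC(2,1)
(two-way random effects, absolute agreement): siblings are interchangeable
measurements of the same regions, and a constant offset between siblings
should reduce similarity. ICC(1,1) and ICC(3,1) are selectable and the
report records the form used. ICCs are computed from ANOVA mean squares;
confidence intervals follow Shrout–Fleiss / McGraw–Wong, and the
implementation is cross-checked in the test suite against `pingouin` as an
independent reference. With only three siblings no significance test
across pairs is attempted; ICCs are descriptive.

Degenerate inputs are explicit errors: fewer than 3 items raises an
insufficient-data error, zero between-item variance a degenerate-input
error. Exact agreement returns ICC = 1 with a collapsed interval; for
ICC(2,1) with zero residual but a nonzero rater offset the interval is
undefined and reported as such.

## Asymmetry

AI = (L − R)/((L + R)/2) ∈ (−2, 2) for positive inputs; positive is
leftward. The index is scale-invariant and antisymmetric under hemisphere
swap. Direction labels use a tolerance ε = 0.01 (configurable): indices
within ±ε are called symmetric, matching the descriptive use of
"symmetric or slightly leftward" for near-zero values.

## Mask luminosity and Q–Q comparison

Binary ROI masks live on one shared template grid (RAS+; sagittal = x,
coronal = y, axial = z — the grid orientation is a package convention).
For one (subject, ROI, axis) the nonzero slices are layered into a
composite with pixel luminosity

    lum(x, y) = min(255, round(255 · c(x, y) / α)),

where c(x, y) is the number of slices containing the pixel and α
(`alpha_ref`) is the maximum slice count over subjects for that
(ROI, axis). The linear count scaling is the simplest rule consistent with
opacity layering ("brighter = present in more slices") and makes the
per-voxel projection oracle exact; sharing α across subjects is what makes
luminosities comparable between subjects, and scaling a subject's slice
count together with α leaves the composite unchanged.

The luminosity distribution is the multiset of foreground (luminosity > 0)
pixel values; background pixels are excluded by default because they carry
no shape information, with an `include_zero` dialect available. Two
distributions are compared at quantile levels k/(n+1), k = 1..99, linear
interpolation between order statistics. The divergence score
mean|q_x − q_y| / 255 is an artifact addition — the published analysis
reads Q–Q plots visually — and is labelled as such in reports; it is zero
iff the curves coincide on the grid and symmetric in its arguments. Axes
are analysed separately and never mixed within a comparison; cohort-level
most-similar-pair readouts may pool the three axes by summing divergences.
Inter-subject comparisons yield 3 curves per ROI (one per sibling pair);
intra-subject comparisons enumerate all unordered ROI pairs within each
reading pathway (ventral 1, frontal 3, dorsal 15).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study family's data, with
defaults fixed at the reported conditions:

- **Genotypes**: an 800-SNP panel across the 28 reading genes of which 116
  SNPs are family-invariant (leaving 684 variable) and 79 carry the planted
  co-segregation pattern, plus 2000 background SNPs with the same planting
  rates (the reported pattern proportion was consistent between panel and
  genome). All child genotypes are valid Mendelian transmissions;
  non-planted variable SNPs are rejection-sampled so they never satisfy
  the pattern, making planted-truth recovery exact (set equality) when no
  calls are missing. Functional classes are drawn with the reported
  57:1:1:20 intronic/exonic/3'UTR/intergenic proportions. The default
  missing rate is zero so that the default conditions reproduce the
  reported post-QC counts; missingness is exercised explicitly in tests.
  No linkage disequilibrium, allele-frequency spectra or population
  structure are modelled — the genotype table is exchangeable across SNPs,
  which real array data is not.
- **Morphometry**: per phenotype, sibling item vectors are correlated
  Gaussians whose 3×3 correlation matrix comes from the pair-similarity
  targets (defaults: the reported reading-region ICCs — thickness
  0.76/0.66/0.54 for SRD/twins/TD-OS, area and volume ≥ 0.95). Thickness
  is Gaussian around 2.6 ± 0.3 mm; area and volume are log-normal (medians
  600 mm² and 1800 mm³, σ_log = 0.35) — cortex-typical magnitudes.
  Configured asymmetry entries (defaults: the full reported sibling × ROI ×
  phenotype asymmetry table) are then planted *exactly* by solving L and R
  from the index while preserving the pair mean. Planting asymmetry
  perturbs the planted correlations for those items, so simulations that
  measure similarity recovery plant similarity only. Spatial covariance
  between neighbouring parcels is not modelled.
- **Masks**: connected ellipsoids whose per-axis extents are drawn from
  the 30–70 slice range typical of exported mask stacks, jittered per
  subject (SD 4 slices); optionally two designated siblings share their
  perturbation (residual SD 0.5) to plant a known most-similar pair.
  Ellipsoids carry none of the folded-sheet geometry of cortex; they
  suffice because the luminosity pipeline consumes only slice stacks.

All randomness derives from a single seed; every artifact (VCF, TSV,
NIfTI, PNG, JSON) is byte-identical across regenerations.

Passing tests on these data demonstrate that the filters, statistics and
comparisons compute what they claim and recover planted structure; they do
not validate the biological interpretation of any measure on real MRI or
array data.

## Simulation sizes and recovery-study design

Problem sizes were chosen so the full suite runs in well under a minute of
simulation time: recovery studies use 200 replicate families, masks are
generated on an 80³ grid, and the genetics oracle comparisons use ≤ 1000
SNP tables.

The ICC-ordering recovery study plants thickness similarities of
0.92 / 0.60 / 0.25 rather than the reported 0.76 / 0.66 / 0.54. With 14
items per reading-set vector, the sampling SD of an ICC estimate is ≈ 0.1,
so the reported separation is statistically unresolvable at this problem
size (a power analysis puts ordering recovery near 50%, and the original
analysis itself makes no significance claim about the ordering). A
recovery check is informative about implementation correctness only when
the planted effect is recoverable in principle, so the study uses a
clearly separated ordering; the reported targets remain the generator
defaults, and the mean ICC estimates under those defaults are reported
alongside (they sit ~0.03–0.05 below target — the known small-sample bias
of ICC(2,1) at n = 14). The mask recovery study likewise pools the three
axes' divergences, the cohort-level readout with adequate power (~99%
single-ROI recovery at the default jitter).

## Known limitations

- One family, three imaged siblings: every imaging comparison is
  descriptive; the package deliberately offers no inferential statistics
  across pairs.
- The interval-based functional-class fallback is approximate (no exon
  models); supply an annotation column for real data.
- Gene footprints in the built-in panel are approximate GRCh37 intervals
  intended for simulation and interval assignment, not for clinical
  annotation.
- Composites assume binary masks; anti-aliased mask edges would introduce
  intermediate slice values the pipeline does not model.
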