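# Methods

## Copy-number model

The estimator converts a depth ratio into mitochondrial genome copies per
cell. Autosomal depth in a mixed tissue reflects *f·p + (1−f)·2* nuclear
genome copies per cell (purity *f*, mean tumour ploidy *p*); chrM depth
reflects the mitochondrial copy number directly. Hence

    mtCN = (mean.DPchrM / mean.DPauto) × (f·ploidy + (1−f)·2).

Mean depths are taken at germline-variant sites (the site mean, unweighted
by callability); when fewer than five chrM variant sites exist a caller may
fall back to the whole-chrM mean — the estimator itself only consumes the
two means, so the choice of site set lives in the depth table supplied to
it. Purity and ploidy are inputs, not estimated here; samples missing from
the purity table are treated as normal tissue (f = 1, ploidy = 2) with a
logged warning. The estimator is linear in chrM depth and reduces exactly to
2 × depth-ratio in normal tissue.

## Filter chain

All criteria are evaluated independently and every violation is reported, so
the audit table reconciles: per sample, pass count + fail count = union
size, and each failed variant lists all its reason codes. The printed
inequalities are honoured exactly as stated (≥ 10 reads, ≥ 20 base quality,
strand ratio strictly inside (0.1, 0.9), read position strictly inside
(0.15, 0.85), length difference < 25, MAPQ difference < 10, normal context
> 80%, NM difference ≤ 3); where the recipe says "lower than" the comparison
is strict, so a VAF exactly equal to the noise level passes. Boundaries are
deliberately part of the test surface: crossing any single threshold by one
grid step flips exactly that reason code and no other.

Interpretive choices the recipe leaves open, each exposed in `FilterConfig`:

* **Mean read position** is a single scalar in [0, 1] — the mean, over
  variant-supporting reads, of the variant's relative position measured
  from the nearer read end and folded onto the 5′ scale. Because the
  (0.15, 0.85) window is symmetric, requiring the 5′-scale fraction to lie
  inside it is equivalent to requiring the fraction from either end to do
  so; one field suffices.
* **Variant base quality** is the mean Phred quality of variant-supporting
  base calls (the common convention of both callers).
* **"Next to a germline mutation"** waives only the normal-context
  criterion, and means within 2 bp of a germline variant (from the
  resource or the paired normal at VAF > 95%); a phased germline allele on
  the same reads legitimately breaks the sequence context. The window is
  configurable.
* **Union merging**: when both callers report a key, the first caller's
  per-read summaries are kept and the second's are preserved under
  `provenance["secondary"]`. Deterministic and auditable; no element-wise
  mixing of summaries. The union is commutative on keys and caller sets.
* **Missing annotations fail closed**: a record lacking a summary needed by
  some criterion receives MISSING_ANNOTATION rather than passing by
  default. A sidecar TSV keyed on (sample, position, ref, alt) can supply
  summaries a caller's VCF lacks.
* **Indels** are represented minimally; `is_indel` is derived from the
  allele lengths, so records sharing a (position, ref, alt) key can never
  disagree about it.

## Germline removal and the noise model

A call is germline when its (position, allele) matches a cohort-normal or
external-panel entry at VAF > 95%, a population-database entry at frequency
> 1%, or the sample's own paired normal at VAF > 95%.

The panel-of-normals noise level at a position is mean + 3 SD of the
non-reference allele fraction across all panel normals (samples without
signal contribute 0; the SD is the n−1 sample SD, defined as 0 for a
single-normal panel), clamped below by a floor of 0.005. The mean + 3 SD
form is the minimal parametric upper bound on background noise; the floor
keeps positions with no observed signal from passing raw sequencing error.
Both are configurable. Tumour calls with VAF strictly below the position's
level are removed (BELOW_NOISE).

## Classification

Passing tumour variants are labelled **somatic** when the paired normal
shows essentially no signal (VAF < 1%) and **tumour-specific dysplastic**
when the normal carries the allele at 1–95% but the tumour VAF exceeds the
normal VAF by at least 5 percentage points. Calls matching neither pattern
(near-fixed in the normal, or no real expansion) are dropped from classified
output with a log line. The 1% / 95% / 5-point thresholds are interpretive
defaults in `ClassifyConfig`, not published constants.

## Consequence annotation

The packaged gene model lists the 37 mitochondrial genes plus the control
region in rCRS coordinates (NC_012920.1). Protein genes are translated with
the vertebrate mitochondrial code (table 2: AGA/AGG stops, ATA Met, TGA
Trp); light-strand genes are reverse-complemented before codon lookup;
incomplete 3′ stop codons are padded with A, mirroring polyadenylation.
Overlapping genes (ATP8/ATP6, ND4L/ND4) are annotated against both and the
worst consequence is reported (frameshift > nonsense > missense > tRNA/rRNA
> synonymous > noncoding). In-frame indels are reported as missense
(protein-altering). tRNA/rRNA variants count as non-silent by default
(configurable). Codon-level calls require a reference sequence argument;
the package does not bundle the rCRS sequence itself, and synthetic cohorts
carry their own generated reference.

Pathogenicity is membership in a user-supplied allele list; no in-house
scoring is attempted.

## Group statistics

Summaries are per sample: the count of classified variants, the mean VAF of
classified variants (per-variant mean within the sample first, then compared
across samples), the pathogenic stratum of the same, and mtCN. Group means
are compared with Welch's unequal-variance two-sample *t*-test, two-sided,
with Welch–Satterthwaite degrees of freedom and no multiple-testing
correction. Degenerate comparisons (fewer than two defined values per group,
or zero variance in both) are reported as NaN rows rather than omitted.

## Synthetic cohorts: what they emulate — and what they do not

The generator produces paired tumour/normal call sets whose statistical
structure matches what the pipeline consumes. The default cohort mirrors
the study composition at desk scale: 10 BHD-ChRCC and 4 BHD-HOCT tumours
(higher mtCN range 500–2000 copies/cell, ~1 somatic variant per tumour) and
10 sporadic-ChRCC tumours standing in for a larger public cohort (mtCN
100–800, ~3 somatic variants per tumour), each with a paired normal, at
30× mean autosomal depth.

Mechanics: per-site depths are negative-binomial (shape 30) around an
expected chrM depth constructed by inverting the copy-number formula, so the
estimator is unbiased by design and its error reflects depth noise only;
variant read counts are binomial at the simulated depth; per-read summaries
are truncated normals centred at non-violating values for genuine variants
and at violating values for artifacts, each artifact violating exactly one
named criterion; germline haplogroup variants (30 per patient, plus shared
population polymorphisms) appear near-fixed (VAF ≈ 0.985) in both tissues;
panel-wide noisy positions carry sub-percent VAFs in normals, and tumour
noise calls are placed strictly below the resulting noise level. Two
emulated callers each emit 90% of records jointly and split the remainder,
with slightly jittered base qualities. One master seed fixes everything;
per-sample substreams are derived by counter so extending the cohort leaves
earlier samples untouched.

What the simulation does **not** model — and therefore what passing tests do
not demonstrate about real data: alignment and NUMT mis-mapping (artifacts
here are drawn at designed values, not produced by an aligner), caller-
specific biases and representation differences, contamination, oxidative
damage profiles, linked heteroplasmies, or a realistic site-frequency
spectrum of haplogroups. Recovery results certify the bookkeeping and the
decision boundaries of the pipeline, not caller or aligner behaviour.

## Problem sizes and numerical choices

The test suite exercises copy-number recovery on 100 simulated samples
(median relative error < 5%), somatic sensitivity on 250 injected
heteroplasmies (≥ 0.95 recovered) with 9 artifact classes at ~1 per tumour
(every artifact rejected with its designed reason), and Welch null
calibration on 10,000 replicates of n = 20 (type-I error 0.05 ± 0.01) —
sizes chosen so the full suite runs in seconds while estimates remain
stable. Noise-level ties pass (strict "below"); reason codes are emitted in
a fixed canonical order so reports are deterministic; VCF round trips
preserve annotations to float precision; all coordinates are 1-based
inclusive internally, with BED-dialect conversion at the I/O boundary.

## Known limitations

* Per-read summaries must arrive precomputed (VCF INFO or sidecar TSV);
  there is no BAM/pileup processing.
* Purity and ploidy are trusted inputs; no internal estimation or
  consistency check against the depth data.
* The somatic/dysplastic thresholds are interpretive defaults; analyses
  sensitive to them should sweep `ClassifyConfig`.
* No haplogroup calling, no heteroplasmy phasing, no liftover between
  mitochondrial reference versions.
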