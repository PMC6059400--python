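# Methods

## Scope and model

`cfsieve` analyses UMI-tagged, hybrid-capture sequencing of circulating
cell-free DNA (ccfDNA) with an emphasis on two coupled effects of physical
fragment-size selection:

1. **Variant enrichment.** Tumor-derived fragments are shorter than the bulk
   of plasma DNA. Wild-type inserts are modeled as a mononucleosome Gaussian
   (mean 166.9 bp, SD 2.5 bp) mixed with a dinucleosome component
   (334 ± 10 bp, weight 0.15); variant-bearing inserts as a shorter, wider
   Gaussian (151.8 ± 12.8 bp). Both are truncated below a 50 bp floor by
   resampling. Selecting a sub-mononucleosome window therefore raises the
   variant allele frequency (VAF).
2. **Error correction.** Size selection discards molecules, reducing library
   complexity. At a fixed read budget, fewer unique molecules means more PCR
   duplicates per molecule (larger UMI family sizes), and larger families
   support stricter in-silico consensus filtering, which suppresses PCR and
   sequencing errors.

All analysis-facing rules follow the standard single-strand UMI consensus
workflow: reads sharing a strand-aware unclipped alignment start are grouped
on molecular-barcode similarity strictly greater than 0.875; per column,
bases with quality ≥ Q20 vote and the predominant base is called only above
0.66 concordance (ties and empty columns give N); alleles are scored by a
100% match of an 11-bp string anchored at the assay coordinate; background
error rates are tabulated over 7-base windows with depth ≥ 100 Q20 bases, no
indels, and pooled non-reference AF ≤ 0.1, counting only window centres and
each centre once; per-allele AFs are binned (<0.1%, 0.1–1.0%, 1.0–2.0%,
lower and upper edges of the middle bin inclusive) and split into unique
versus shared (present in ≥ 3 control samples). Both similarity and
concordance thresholds are compared as exact rationals (a float threshold is
taken at its printed decimal value), so 7/8 never merges and 2/3 always
calls.

## The simulator

The generator emits everything downstream stages consume, so the whole
pipeline can be exercised without patient data.

* **Reference and panel.** A random single-contig reference laid out as
  flank/target/gap/…/flank; the capture panel (BED) is the set of target
  intervals (128 kb over 8 targets by default) and each target carries a
  designated assay locus with a recorded reference and alternative base.
  Reads are emitted pre-aligned at their true coordinates; alignment is not
  part of what the package studies, and omitting it keeps every read
  traceable to exactly one template molecule.
* **Molecules.** Assay-locus cohorts contain the full 11-bp assay window in
  every fragment and carry exactly `round(tumor_fraction · n)` variant
  molecules; panel-wide background molecules are wild type, with
  `1 − on_target_fraction` of them placed in off-panel territory.
  UMIs (8 bases) are drawn without replacement while the tag space allows;
  real libraries can collide, but collision-free tagging keeps molecule
  identity exact and library complexity is modeled through molecule counts,
  not tag saturation.
* **Amplification and sequencing.** Sequencer read pairs (2×125 bp, Phred
  Q30 flat profile) are sampled multinomially across molecules with
  per-molecule lognormal amplification weights
  (σ = 1.0, mean-one parameterisation). The lognormal overdispersion is
  essential and was fixed from a closed-form design calculation before any
  end-to-end testing: a pure multinomial model gives Poisson family sizes,
  which cannot simultaneously provide singleton families (the dominant
  error channel at FS ≥ 1) and enough FS ≥ 20 families for the
  depth-100 eligibility rule. At mean duplication 10, σ = 1.0 yields ≈ 9%
  singleton families and ≈ 14% families of size ≥ 20.
* **Errors.** Three channels: (i) *first-copy* errors, introduced by the
  first synthesis off the original molecule and therefore shared by **all**
  duplicates — the classic blind spot of single-strand UMI consensus and the
  reason family filtering suppresses PCR errors only weakly; (ii) per-cycle
  doubling-tree errors (an error on a cycle-c copy reaches that copy's
  descendants, roughly a 2^−c fraction of the family); (iii) independent
  per-read sequencing errors. With `pcr_cycles = 0` the library is
  amplification-free: each molecule is sequenced exactly once, which is the
  mode used to verify exact VAF closure and estimator recovery.
* **ddPCR.** Input copies are scattered uniformly over droplets (Poisson
  occupancy in the large-n limit); false-positive droplets are added as
  Poisson(λ_fp) events on the variant channel.

### What the generator does not emulate

No indels, CNVs or rearrangements; no GC or capture bias; no duplex (two
strand) tags; no base-quality miscalibration (flat Q30); no alignment or
mapping artifacts. Passing tests therefore demonstrate the internal
consistency of the analysis under the stated stochastic model — not
robustness to mapping error, context-specific chemistry artifacts, or real
gel physics.

## Size selection

The gel is replaced by a retention-probability model over insert size:
probability 1 inside `[low, high]`, 0 below `low` (sharp lower edge), and
`exp(−(L − high)/leak_scale)` above (one-sided exponential leak,
`leak_scale` 5 bp by default) — longer fragments co-migrate into a shorter
target range but not the reverse. Default windows are short 100–160 bp,
medium 150–170 bp, long 160–200 bp, chosen so the short fraction's median
insert lands near 142 bp and the long fraction covers the 167 bp
mononucleosome peak; the physical extraction protocol reports only resulting
medians/peaks, so the boundaries are package choices. Selection is applied
to molecules *before* amplification (selecting a molecule selects all its
future duplicates), mirroring extraction of library molecules ahead of the
final PCR. Densitometry-style profiles smooth a 1-bp histogram with a
Gaussian kernel (3 bp bandwidth); on the library scale, 135 bp of
full-length adapter mass is added.

## Quantification choices

* Allele counting is per molecule: the forward- and reverse-strand families
  of one template (same chromosome, fragment span and UMI) contribute a
  single count, and conflicting strand calls give UNCLASSIFIED. Counting
  consensus reads instead would double-count molecules with both mates over
  the assay window, and the multiplicity differs between alleles because
  their insert-size laws differ.
* VAF is missing (not 0) on an empty denominator; a `variant_lost` flag
  marks thresholds where wild-type counts survive but variant counts do not.
* Insert-size summaries split at 250 bp to separate mono- from
  dinucleosome material.
* Consensus base quality is `min(40, round(−10·log10(1 − concordance +
  1e−4)))`; the source workflow does not state a formula, and this one maps
  full concordance to Q40 and anything at the 0.66 decision boundary well
  below the Q20 pileup filter.
* Reads whose CIGAR contains indels are excluded from consensus with a
  counted reason (columns would not be reference-aligned); indel consensus
  is out of scope.
* At eligibility time the non-reference AF of a column is pooled
  (depth − reference count)/depth; reported AFs are per allele.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; SAM output is 1-based per the
standard. All randomness flows from one seed through named
`numpy.random.default_rng([seed, stream])` streams, so identical
configuration and seed reproduce byte-identical artifacts. Ties for the
predominant base give N. Saturated droplet channels (no negative droplets)
are unquantifiable rather than infinite. Empty densitometry input is an
error; a single record peaks at its own length. The limit of blank is the
smallest k with Poisson CDF(k; λ) ≥ 0.95 with λ the sample mean (MLE), and
the 95% point of the empirical count distribution is reported alongside.

## Problem sizes

Library-scale computations in the test suite and the reproduction script use
a 2–8 kb panel, 4 000–10 000 molecules and 24 000–100 000 read pairs per
library, with 3–10 seeded replicates per comparison; fragment-level
Monte-Carlo checks use 10⁵ molecules. These sizes give ≥ 10⁶ quality
center-base observations for error-rate recovery and binomial confidence
intervals tight enough for every directional claim, and a full run completes
in a few minutes on one CPU.

## Known limitations

Family-size spectra are calibrated only qualitatively (overdispersed,
singleton-bearing); no attempt is made to match a particular instrument's
duplicate distribution. The error model has a single flat quality tier, so
quality-weighted consensus variants cannot be explored. The grouping
oracle-equivalence guarantee is for the stated seeding rule (descending
abundance, lexicographic ties); other seeding orders can yield different
partitions when tags sit exactly at the similarity boundary. On 8-base tags
the >0.875 similarity rule admits only identical tags, so sub-threshold
sensitivity analyses must lower the threshold explicitly.
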