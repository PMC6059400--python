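# cfsieve

Size selection and UMI-consensus error correction for circulating cell-free
DNA (ccfDNA) sequencing, with a built-in library simulator.

## The problem

Circulating tumor DNA (ctDNA) is a minor, *shorter-fragmented* subpopulation
of plasma cell-free DNA: bulk ccfDNA peaks at the ~167 bp mononucleosome,
while tumor-derived fragments centre nearer ~152 bp. Detecting variants below
1% allele frequency is limited less by depth than by PCR and sequencing
errors. Two levers interact:

* **physical size selection** — extracting a sub-mononucleosome fraction
  enriches the variant allele frequency (VAF);
* **UMI consensus** — reads sharing an unclipped alignment start and a
  molecular barcode (similarity > 0.875) collapse into one consensus read per
  family (per-base call at > 0.66 concordance among Q20 bases, else N).
  Discarding molecules by size also *reduces library complexity*, so a fixed
  read budget produces larger duplicate families, and filtering on family
  size (FS ≥ k) suppresses errors — at the price of consensus depth.

`cfsieve` implements the full analysis — UMI family grouping and consensus,
in-silico size selection with an asymmetric long-fragment leak,
11-bp-string allele classification and VAF across family-size thresholds,
background error-rate estimation over eligible 7-base panel windows, and
Poisson droplet-digital-PCR quantification with a limit-of-blank fit — plus a
simulator that generates the panel reference, nucleosome-mixture fragments,
UMI-tagged PCR-duplicated read pairs, spike-in dilution series and droplet
experiments that the analysis consumes. It is aimed at method developers who
want to reason quantitatively about size windows, family-size thresholds and
read budgets before touching patient material.

Key quantities, in the field's usual notation:

* `VAF = 100 · v / (v + w)` from per-molecule consensus counts;
* enrichment fold change `VAF_fraction / VAF_unselected`;
* absolute relative percent change `100 · |VAF_{FS≥k} − VAF_{FS≥1}| / VAF_{FS≥1}`;
* background error rate = non-reference / total Q20 centre-base observations
  over eligible 7-base windows (depth ≥ 100, no indels, AF ≤ 0.1);
* ddPCR copies `λ·n` with `λ = −ln(negative fraction)`; LOB = 95% Poisson
  quantile of false-positive droplets.

## Worked example

Simulate a 1% VAF library, extract the short fraction in silico, and compare
VAF stability at family size ≥ 20:

```python
import cfsieve as cf

cfg = cf.SimConfig(seed=1, panel_size_bp=8000, n_targets=2,
                   n_unique_molecules=4000, total_reads=40000,
                   tumor_fraction=0.01)
ref = cf.make_reference(cfg)
assay = cf.VariantAssay.from_reference(ref)
fragments = cf.simulate_fragments(cfg, ref, 4000)

def sequence(molecules, stream):
    reads = cf.amplify_and_sequence(molecules, cfg, rng=cfg.rng(stream))
    families, _ = cf.group_families(reads)
    return cf.consensus_reads(families)

unselected = sequence(fragments, 10)
short_molecules, report = cf.select_fraction(
    fragments, cf.SizeWindow("short", 100, 160, 5.0), seed=cfg.rng(11))
short = sequence(short_molecules, 12)

for label, lib in (("unselected", unselected), ("short", short)):
    c1, c20 = cf.vaf_at_fs(lib, assay, 1), cf.vaf_at_fs(lib, assay, 20)
    fs = sum(c.family_size for c in lib) / len(lib)
    print(f"{label:10s} molecules={len(lib)//2:5d} mean_family_size={fs:5.1f} "
          f"VAF(FS>=1)={c1.vaf_percent:.2f}% VAF(FS>=20)="
          f"{'lost' if c20.variant_lost else f'{c20.vaf_percent:.2f}%'}")
```

prints

```
unselected molecules= 3770 mean_family_size= 10.6 VAF(FS>=1)=0.99% VAF(FS>=20)=1.02%
short      molecules=  957 mean_family_size= 41.8 VAF(FS>=1)=3.34% VAF(FS>=20)=3.83%
```

Selection kept about a quarter of the molecules, so the same 40 000 read
pairs produced four-fold larger families (41.8 vs 10.6), and the short
fraction carries a 3.4-fold enriched VAF that stays stable at FS ≥ 20.
In lower-VAF or lower-complexity settings the unselected library frequently
*loses* the variant entirely at FS ≥ 20 while the short fraction retains it.

The same workflow is available as a CLI over a YAML config:

```
cfsieve all --config run.yaml --seed 1 --out my_run
```

writing FASTA/BED/TSV/JSON artifacts (reference, panel, VAF-by-family-size
tables, error-rate tables, non-reference-AF BED, droplet metrics, comparative
statistics) into the run directory.

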