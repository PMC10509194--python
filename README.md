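# svorigin

Stratify structural variants (SVs) in a bovine cohort by evolutionary
origin: natural selection in wild yaks, artificial selection during
domestication, or introgression from cattle.

Domestic yaks carry structural variation shaped by three processes that
leave different genomic signatures.  Given phased SNP and SV genotypes and
a sample-to-population map, this package implements the analyses needed to
tell them apart:

- **Divergence scans** — per-variant Weir–Cockerham θ and AMOVA Φ_ST
  between populations, with the fixed-difference outlier rule (θ = 1) for
  sweep candidates and the θ > 0.3 rule for SNP scans; LD r² on phased
  haplotypes; the frequency-based ABBA–BABA D statistic
  `D = Σ[(1−p1)p2p3 − p1(1−p2)p3] / Σ[(1−p1)p2p3 + p1(1−p2)p3]`
  with block-jackknife errors.
- **Haplotype-tree origin classification** — for each SV, SNPs within
  50 kb in strong LD (r² ≥ 0.45) with the SV allele are used to build a
  neighbour-joining tree of phased haplotypes; a haplotype nesting inside
  the other species' reference clade (≥ 3 reference leaves, ≥ 90% pure)
  is called introgressed, yielding per-SV directions
  cattle→yak / yak→cattle / mutual / none.
- **Domestication contrast** — Fisher's exact wild-vs-domestic allele
  frequency test with Benjamini–Hochberg FDR (α = 0.05), then exclusion
  of SVs whose trees show cattle introgression.
- **Copy-number genotyping** — integer CN of named segments from read
  depth, `CN = round(2·depth/baseline)`, matched against a composite
  genotype rule table (the serial-translocation / coat-colour analysis).
- **Pangenome statistics** — core / near-core / variable occupancy
  classes, pan/core saturation curves, pairwise presence/absence counts.
- **Variant I/O** — phased VCF and population-map loading, call-rate /
  MAF / depth filters (0.7 / 0.05 / 1⁄3–3×), bubble→SV extraction from
  explicit-path GFA, and coding/regulatory/intergenic SV annotation
  against GFF3 (CDS vs introns ± 5 kb flanks).

A synthetic-cohort generator (`svorigin.synthetic`) produces phased
haplotypes along the species topology
`(outgroup,(cattle,(wild_yak,domestic_yak)))` with controllable
introgression events and ground-truth labels, so every stage is testable
without external sequencing data.  See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_divergence_scan.py
python analysis/03_classify_introgression.py
python analysis/04_domestication_scan.py
python analysis/05_cn_genotypes.py
python analysis/06_pangenome.py
```

Script 01 simulates the default cohort (20 wild yaks, 30 domestic yaks,
20 cattle, 2 outgroup; 100 SV windows of 50 kb) and plants cattle→yak
introgression at 30% of loci.  Script 03 then prints:

```
introgressed-haplotype recall: 1.000
native-haplotype false-call rate: 0.0000
per-SV direction agreement with truth: 1.000
fraction of yaks carrying a cattle-derived haplotype: 0.600
```

i.e. every planted cattle-derived haplotype is recovered from its tree,
no native haplotype is miscalled, all 30 event SVs get the correct
direction, and 60% of the simulated yaks carry at least one cattle-derived
haplotype.  Script 02 reports the divergence side:

```
wild-vs-cattle theta = 1 outliers: 100 of 100 SVs (species-diagnostic by construction)
wild-vs-domestic theta/Phi_ST concordance over 30 polymorphic SVs: Pearson r = 0.998 (p = 3.5e-34)
D statistic (wild, domestic; cattle | outgroup) = 1.000 over 100 polarized SVs
```

and script 04 the domestication bookkeeping at the study's group sizes
(18 wild vs 215 domestic): 103 SVs significant at FDR < 0.05, of which 30
are excluded as cattle-introgressed and 73 retained as candidates.

Equivalently, `svorigin.pipeline.run_pipeline(RunConfig(...))` runs all
stages end to end and writes a manifest with a SHA-256 digest per output;
identical (config, seed) runs are bit-identical.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch under the given seed — cohort
simulation, divergence scan, tree classification, domestication contrast,
copy-number calls, pangenome statistics — and writes the acceptance JSON
to `--out`.  Intermediate artifacts go to `scratch/`.
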