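# Methods

`svorigin` stratifies structural variants (SVs) segregating in a bovine
cohort — wild yaks, domestic yaks, cattle, and an outgroup — by the
evolutionary process that produced them: natural selection in the wild
ancestor, artificial selection during domestication, or introgression from
cattle.  This note documents the models, the parameters that matter, the
synthetic data the package is validated on, and the numerical choices made
where the procedure left room.

## 1. Synthetic cohort model (`svorigin.synthetic`)

Every downstream stage is exercised on simulated cohorts with known truth,
because the analyses it implements were designed for external datasets
(multi-assembly graph genomes and hundreds of resequenced individuals) that
are not reproducible at desk scale.

**Haplotype model.** Each SV locus carries a window of `n_snps_per_window`
candidate sites at distinct positions in `[1, window_bp]` (default 500
sites in 50 kb).  Haplotypes evolve along the fixed species topology
`(outgroup,(cattle,(wild_yak,domestic_yak)))`.  Each of the six branches
receives `Poisson(divergence_per_branch × n_sites)` mutations at uniformly
chosen distinct sites (infinite-sites within a branch), flipping the allele
in every haplotype of the descendant clade; each individual haplotype then
receives `Poisson(within_pop_diversity/2 × n_sites)` private flips, so the
expected within-population pairwise difference is `within_pop_diversity`
per site.  There is no recombination within a window: the flanking
haplotype travels with the SV allele, which is precisely the assumption the
tree classifier relies on.  Mutation rates are per *candidate site*, not
per bp.

**Defaults.** 20 wild yaks, 30 domestic yaks, 20 cattle, 2 outgroup
individuals; 100 SV windows; `divergence_per_branch = 0.02` and
`within_pop_diversity = 0.002`.  The 10:1 divergence/diversity ratio is not
estimated from real data (the source study does not report its regime); it
is chosen so that species clades separate cleanly, which is the stated
operating condition of the classifier.  A configuration warning fires when
divergence does not exceed diversity.

**SV allele.** The SV alternate allele is placed on the cattle branch:
cattle haplotypes carry it, yaks and the outgroup do not.  This makes every
locus species-diagnostic, which mirrors the situation in which the origin
question is well-posed.

**Introgression.** An event replaces a recipient haplotype's entire window
— all flanking SNP alleles plus the SV allele — with a copy of a uniformly
chosen donor-population haplotype.  All other entries are bit-identical
after injection (tested).  `random_cattle_to_yak_events` places events on a
configurable fraction of loci (default 30%) with 1–10 recipient
domestic-yak haplotypes each, emulating variable introgression frequency
across herds.

**Other generators.** SV genotype panels are binomial draws from
per-population allele frequencies; segment read depths are Poisson per
100-bp bin with mean `base_depth × CN/2`; gene-family presence matrices
make each family core with probability `core_fraction` and give accessory
families an occupancy `k ∈ 1..N−1` with probability ∝
`presence_decay^(N−1−k)` (most accessory families near-universal, a
geometric-like rare tail).

**PRNG contract.** Every operation seeds one `numpy.random.default_rng`
and draws in a fixed documented order; identical inputs give bit-identical
outputs, including the VCF text.

**What a green test does not establish.** The generator has no
recombination, no selection, no genotyping error, no coalescent variance
beyond the star-within-clade approximation, and mutation counts rather
than sequence context.  Recovery rates measured on it bound the
classifier's behaviour only under its own assumptions; robustness to
recombination inside the 50-kb window is untested here as it was in the
source analysis.

## 2. Variant I/O and filters (`svorigin.variant_io`)

VCF reading uses pysam; writing emits plain VCF 4.2 text.  Internal
coordinates are 0-based half-open, converted only at the VCF/GFF boundary.
Records with `SVTYPE` set and length < 50 bp are dropped at load (an SV is
defined as ≥ 50 bp).

**Filters.** Genotypes with depth outside `[1/3×, 3×]` of the sample's
mean depth are soft-filtered to missing (when depths are supplied); then
variants with call rate < 0.7 or minor allele frequency < 0.05 are removed,
with per-cause tallies.  MAF is computed over non-missing allele copies;
for multiallelic records it is `1 − max allele frequency` (the upstream
tool chain does not state its multiallelic convention).  Filtering is
idempotent.

**Bubbles.** `extract_bubbles` reimplements reference-anchored bubble
popping on explicit-path GFA 1.0: the reference path must exist and be all
forward-oriented (general bidirected superbubbles are declared unsupported
rather than half-implemented).  A bubble is a pair of reference nodes
between which some path's interior differs from the reference interior;
alleles are compared as oriented node sequences, allele length is the
summed segment length, and the reported position is the 1-based last base
of the source node (the VCF-style anchor).  Two distinct paths → biallelic,
more → multiallelic; an SV is emitted when the maximal allele-length
difference is ≥ 50 bp.  Output is invariant to S-/P-line order.  Real
graph pipelines derive allele paths from read or assembly mappings; the
P-line representation is an explicit simplification.

**Region annotation.** An SV is *coding* if it overlaps any CDS,
else *regulatory* if it overlaps an intron or the ±5 kb gene flanks, else
*intergenic*.  Deletions and divergent alleles occupy `[pos, pos+svlen)`
on the reference; insertions occupy their single anchor base.  Exonic
non-CDS (UTR) overlap without intron/flank overlap falls through to
intergenic — a deliberate literal reading of the region definition.

## 3. Divergence statistics (`svorigin.divergence`)

**Weir–Cockerham θ** is computed per variant from the 1984 variance
components a, b, c with r = 2 populations, summed over alleles (so
multiallelic records are handled uniformly); θ = Σa / Σ(a+b+c).  Fewer
than two complete diploids in either group gives NA; negative estimates
are reported raw, never clamped.  Missing data are handled listwise within
each variant.

**Φ_ST** is the AMOVA ratio σ²_among/(σ²_among+σ²_within) over allele
copies (two per diploid) with the allele-identity distance (0 if same
allele index, else 1); an allele-length distance for multiallelic SVs
would be a drop-in alternative but identity is the default.  All copies
identical → NA (zero total variance).

Both estimators are verified to 1e-10 against independent brute-force
implementations (scalar component sums for θ, explicit
sums-of-squared-distances for Φ_ST) on 1000 random cohorts, and both give
exactly 1 on fixed differences with no within-group variation.

**LD r²** on phased haplotypes is `(p_AB − p_A p_B)² / (p_A(1−p_A)
p_B(1−p_B))`, NA when either locus is monomorphic.

**D statistic.** Frequency-based ABBA–BABA:
`D = Σ[(1−p1)p2p3 − p1(1−p2)p3] / Σ[(1−p1)p2p3 + p1(1−p2)p3]` over sites
polarized by the outgroup (outgroup-polymorphic sites are skipped; where
the outgroup is fixed for the alternate allele, frequencies are flipped).
Since ABBA−BABA = p3(p2−p1) per site, D is exactly 0 when p1 = p2
everywhere.  A delete-one block jackknife over contiguous equal-size site
blocks provides SE and Z on request.

**Outlier rules.** `equals` mode selects θ within 1e-9 of the threshold
(the fixed-difference sweep rule at θ = 1, with float tolerance); `greater`
mode selects θ strictly above it (the SNP-scan rule at θ > 0.3).

## 4. Origin classification (`svorigin.introgression`)

The per-SV procedure:

1. **Panel.** Collect phased SNPs within 50 kb each side of the SV; tag
   each haplotype with its phased SV allele.  For deletions, SNPs inside
   the deleted span are set missing on deletion-carrying haplotypes.
2. **Tagging SNPs.** Keep SNPs with r²(SNP, SV allele) ≥ 0.45.  The LD
   threshold for "close LD" is not quantified in the source; 0.45 is its
   only printed strong-LD cutoff and is adopted here.  Fewer than 5
   surviving SNPs → the SV is flagged unclassifiable.
3. **Distances.** Normalized Hamming distance over pairwise-complete
   sites; pairs sharing < 50% of sites get NA and the SV is flagged.
4. **Tree.** Saitou–Nei neighbour joining with the Q criterion; ties
   broken by the smallest index pair (row-major argmin, internal nodes
   numbered after leaves); negative branch estimates clamped to 0.  The
   tree is rooted at the midpoint of the first outgroup leaf's pendant
   edge; no outgroup → error, since the nesting test is undefined
   unrooted.
5. **Nesting call.** Ascend from the query leaf to the first ancestor
   whose subtree holds ≥ k = 3 reference-panel leaves (wild yaks anchor
   the yak side, non-admixed cattle the cattle side; panel membership is
   declared, never inferred; the query itself is excluded).  If those
   references are ≥ τ = 0.9 pure for one species, the clade's species
   decides: yak query in a cattle clade → `cattle_derived`, cattle query
   in a yak clade → `yak_derived`, own species → `native`; otherwise
   `unclassified`.
6. **Direction.** Per SV: `cattle_to_yak` if any yak haplotype is
   cattle-derived and no cattle haplotype is yak-derived; `yak_to_cattle`
   symmetric; `mutual` if both; `none` otherwise.

k, τ and the minimum tagging-SNP count are artifact parameters (the source
describes the nesting qualitatively); all are exposed in
`ClassifierConfig` and echoed in output metadata.  One tree is built per
SV, matching the per-SV description of the original procedure.  Both
per-haplotype and per-SV granularities are reported, since the original
exclusion step is ambiguous between them.

On the seed-fixed default cohort the classifier attains 100% recall on
introgressed haplotypes, a 0% false-call rate on native haplotypes and
100% direction agreement (acceptance thresholds: ≥95%, ≤2%, ≥95%), and
calls no direction on any SV of an event-free cohort (threshold ≤1%).
These numbers are what the tests compute; they characterize the stated
synthetic regime, not real data.

## 5. Domestication contrast (`svorigin.domestication`)

Fisher's exact test contrasts allele counts (default) or carrier status
(dominance model, for the coat-colour case/control design) between two
groups.  The two-sided p sums hypergeometric probabilities ≤ the observed
table's probability — the classical definition, no mid-p — evaluated from
`scipy.stats.hypergeom` with a 1e-9 relative tie tolerance; it matches an
exact rational-arithmetic enumeration to 1e-12.  Whether the original
test used allele or genotype counts is unstated; allele counts are the
default.  Multiallelic variants are tested each-alt-vs-rest, FDR is
controlled jointly over all tests, and an SV is significant if any alt
survives.

FDR control is Benjamini–Hochberg (the original names neither its AF test
nor its FDR procedure; Fisher + BH are consistent with its case/control
methods and both are swappable).  Candidates are `q < 0.05` minus SVs
whose tree direction is `cattle_to_yak` or `mutual`; each exclusion
carries its reason.  At the study's group sizes (18 wild vs 215 domestic)
a simulated |ΔAF| = 0.8 contrast is detected with power ≥ 0.9 at empirical
FDR ≤ 0.08 (tested over 50 replicates).

## 6. Copy-number genotyping (`svorigin.cn`)

Integer copy number per named segment is `round(2 × mean_depth /
baseline)`, rounding half away from zero (ties at exactly .5 are
measure-zero under Poisson noise), capped at 8.  The baseline is a 10%
trimmed mean of genome-wide depth (the normalization used originally is
unstated).  Calls are exactly scale-invariant in (depth, baseline).  No GC
correction is applied.  Composite genotypes (e.g. the white-yak allele
carrying three copies of the translocated block) are exact-match lookups
in a user-supplied rule table: the published genotype definitions live in
supplementary material not reproduced here, so the shipped five-row table
is a clearly-labelled synthetic example.  Under the Poisson model at 20×
over ≥5 kb segments, ≥99% of CN ∈ {0..6} calls are correct (tested at
n = 1000 samples).

## 7. Pangenome statistics (`svorigin.pangenome`)

Occupancy classes: *core* = present in all N genomes, *near-core* =
missing at most `near_core_max_missing` (default 2, serving both the
22-genome gene-family preset and, with the same rule, the 47-genome
graph-node preset where near-core means present in 46 or 45), *variable* =
the rest.  Saturation curves average pan (union) and core (intersection)
sizes over genome orderings: all N! orderings when N! ≤ R (so small-N
results are exact), otherwise R = 100 seeded random orderings — whether
the original curves used random or fixed orderings is unstated.
Per-ordering monotonicity (pan non-decreasing, core non-increasing) is
asserted, not assumed.  `pairwise_absence[i, j]` counts entities present
in genome i and absent from j; it satisfies `(i,j) + |i∩j| = |i|`.

## 8. Pipeline (`svorigin.pipeline`)

`run_pipeline` executes simulate → divergence → introgression →
domestication (copy-number and pangenome stages independent), enforcing
the dependency that domestication exclusion requires origin calls.  Every
output begins with a header carrying tool version, configuration digest
and seed; the manifest records per-stage status and a SHA-256 digest of
every artifact, so identical (config, seed) runs are verifiably
bit-identical.  Per-stage seeds are the global seed plus fixed offsets.
The full default run takes well under a minute on one CPU.

## Known limitations

- The bubble finder handles forward-oriented reference backbones with
  explicit P-lines only; inversions and nested bidirected bubbles are out
  of scope.
- The classifier assumes the flanking haplotype is co-inherited with the
  SV; within-window recombination would erode tagging LD and is not
  modelled.
- Fisher p-values use float hypergeometric pmfs with a tie tolerance;
  pathological near-ties between distinct tables could in principle be
  resolved differently than exact arithmetic would, though none arise in
  the tested range.
- The Φ_ST distance for multiallelic SVs is allele identity; length-aware
  distances would change the statistic for multiallelic records.
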