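"""Synthetic four-group bovine cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: phased SNP haplotypes evolved along the fixed species topology
``(outgroup,(cattle,(wild_yak,domestic_yak)))``, an SV allele riding on the
cattle branch, controllable introgression events that copy whole donor
haplotypes (flanking SNPs plus SV allele) into recipients, binomially drawn
SV genotype panels, Poisson read depths over copy-number segments, and
gene-family presence/absence matrices.

Mutation model: each SV window carries ``n_snps_per_window`` candidate sites
at distinct positions in ``[1, window_bp]``.  A branch with expected
``divergence_per_branch`` substitutions per site receives a
Poisson(divergence * n_sites) number of mutations placed at uniformly chosen
distinct sites (infinite-sites within a branch), each flipping the allele in
every haplotype of the descendant clade.  Within-population diversity is
added as Poisson(diversity/2 * n_sites) private flips per haplotype, so the
expected pairwise difference within a population is ``diversity`` per site.
There is no recombination within a window: the flanking haplotype travels
with the SV allele, which is exactly the signal the tree classifier reads.

PRNG contract: every operation takes a seed (or a seeded config), constructs
a single ``numpy.random.default_rng`` once, and draws from it in a fixed
documented order; identical inputs give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

POPULATIONS = ("wild_yak", "domestic_yak", "cattle", "outgroup")

#: Fixed species topology; branch name -> populations descending from it.
BRANCH_CLADES = {
    "outgroup": ("outgroup",),
    "bovina": ("cattle", "wild_yak", "domestic_yak"),
    "cattle": ("cattle",),
    "yak": ("wild_yak", "domestic_yak"),
    "wild_yak": ("wild_yak",),
    "domestic_yak": ("domestic_yak",),
}

SPECIES_NEWICK = "(outgroup,(cattle,(wild_yak,domestic_yak)));"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated four-group cohort.

    Defaults follow the cohort used throughout the recovery tests: 20 wild
    yaks, 30 domestic yaks, 20 cattle and 2 outgroup individuals, 100 SV
    windows of 50 kb, and a divergence regime ten times the within-population
    diversity so species clades separate cleanly.
    """

    n_wild_yak: int = 20
    n_domestic_yak: int = 30
    n_cattle: int = 20
    n_outgroup: int = 2
    n_snps_per_window: int = 500
    window_bp: int = 50_000
    divergence_per_branch: float = 0.02
    within_pop_diversity: float = 0.002
    n_sv_loci: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_wild_yak": self.n_wild_yak,
            "n_domestic_yak": self.n_domestic_yak,
            "n_cattle": self.n_cattle,
            "n_outgroup": self.n_outgroup,
            "n_snps_per_window": self.n_snps_per_window,
            "n_sv_loci": self.n_sv_loci,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.window_bp < self.n_snps_per_window:
            raise ConfigurationError("window_bp must be >= n_snps_per_window (distinct sites)")
        if self.divergence_per_branch < 0 or self.within_pop_diversity < 0:
            raise ConfigurationError("mutation rates must be non-negative")
        if self.divergence_per_branch <= self.within_pop_diversity and self.divergence_per_branch > 0:
            warnings.warn(
                "divergence_per_branch <= within_pop_diversity: species clades "
                "may not separate",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.n_wild_yak + self.n_domestic_yak + self.n_cattle + self.n_outgroup


@dataclass(frozen=True)
class IntrogressionEvent:
    """One directed haplotype-replacement event at one SV locus."""

    sv_index: int
    direction: str  # "cattle_to_yak" | "yak_to_cattle"
    recipient_haplotypes: tuple  # of (sample_id, hap_index in {0,1})
    donor_population: str

    def __post_init__(self) -> None:
        if self.direction not in ("cattle_to_yak", "yak_to_cattle"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        for _, h in self.recipient_haplotypes:
            if h not in (0, 1):
                raise ConfigurationError("haplotype index must be 0 or 1")


@dataclass
class Window:
    """Phased SNP haplotypes flanking one SV locus."""

    sv_index: int
    positions: np.ndarray  # sorted 1-based site positions within the window
    haplotypes: np.ndarray  # (2 * n_samples, n_sites) uint8 allele indices
    sv_alleles: np.ndarray  # (2 * n_samples,) uint8 SV allele per haplotype


@dataclass
class SimulatedCohort:
    config: CohortConfig
    samples: list  # sample ids, population-blocked order
    populations: dict  # sample id -> population label
    windows: list  # one Window per SV locus

    def haplotype_population(self) -> np.ndarray:
        """Population label of each haplotype row (2 per sample)."""
        return np.repeat([self.populations[s] for s in self.samples], 2)

    def haplotype_carriers(self) -> list:
        """(sample, hap_index) of each haplotype row."""
        return [(s, h) for s in self.samples for h in (0, 1)]


def _sample_ids(config: CohortConfig) -> tuple:
    names, pops = [], {}
    for prefix, pop, n in (
        ("WY", "wild_yak", config.n_wild_yak),
        ("DY", "domestic_yak", config.n_domestic_yak),
        ("CT", "cattle", config.n_cattle),
        ("OG", "outgroup", config.n_outgroup),
    ):
        for i in range(n):
            name = f"{prefix}{i + 1:03d}"
            names.append(name)
            pops[name] = pop
    return names, pops


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Simulate phased SNP windows for every SV locus of a cohort.

    Per locus, in PRNG order: site positions; one Poisson mutation count and
    site set per species branch (fixed branch order); one Poisson private
    mutation count and site set per haplotype (sample-blocked order).
    The SV allele is placed on the cattle branch: cattle haplotypes carry
    allele 1, all others allele 0.
    """
    rng = np.random.default_rng(config.seed)
    samples, populations = _sample_ids(config)
    pop_of_hap = np.repeat([populations[s] for s in samples], 2)
    n_haps = 2 * config.n_samples
    n_sites = config.n_snps_per_window

    windows = []
    for locus in range(config.n_sv_loci):
        positions = np.sort(rng.choice(config.window_bp, size=n_sites, replace=False)) + 1
        haps = np.zeros((n_haps, n_sites), dtype=np.uint8)
        for branch, clade in BRANCH_CLADES.items():
            n_mut = min(rng.poisson(config.divergence_per_branch * n_sites), n_sites)
            sites = rng.choice(n_sites, size=n_mut, replace=False)
            rows = np.isin(pop_of_hap, clade)
            haps[np.ix_(rows, sites)] ^= 1
        rate = config.within_pop_diversity / 2.0 * n_sites
        for row in range(n_haps):
            n_mut = min(rng.poisson(rate), n_sites)
            sites = rng.choice(n_sites, size=n_mut, replace=False)
            haps[row, sites] ^= 1
        sv_alleles = (pop_of_hap == "cattle").astype(np.uint8)
        windows.append(Window(locus, positions, haps, sv_alleles))
    return SimulatedCohort(config, samples, populations, windows)


def inject_introgression(
    cohort: SimulatedCohort, events: list, seed: int = 0
) -> tuple:
    """Copy donor haplotypes into recipients and record the ground truth.

    For each event and recipient haplotype, the entire window (all flanking
    SNP alleles plus the SV allele) is replaced by a copy of one uniformly
    chosen donor-population haplotype.  Only targeted rows change; everything
    else is bit-identical to the input.  Returns ``(cohort, truth)`` where
    truth is a DataFrame with one row per (sv_index, sample, hap_index).
    """
    rng = np.random.default_rng(seed)
    hap_pops = cohort.haplotype_population()
    carriers = cohort.haplotype_carriers()
    row_of = {c: i for i, c in enumerate(carriers)}

    origin = {}
    direction_of_sv = {}
    for ev in events:
        if ev.sv_index < 0 or ev.sv_index >= len(cohort.windows):
            raise ConfigurationError(f"event references unknown SV locus {ev.sv_index}")
        recipient_species = "yak" if ev.direction == "cattle_to_yak" else "cattle"
        donor_rows = np.flatnonzero(hap_pops == ev.donor_population)
        if donor_rows.size == 0:
            raise ConfigurationError(f"no haplotypes in donor population {ev.donor_population!r}")
        win = cohort.windows[ev.sv_index]
        for sample, hap in ev.recipient_haplotypes:
            if (sample, hap) not in row_of:
                raise ConfigurationError(f"unknown recipient haplotype {(sample, hap)!r}")
            row = row_of[(sample, hap)]
            pop = cohort.populations[sample]
            is_yak = pop in ("wild_yak", "domestic_yak")
            if (recipient_species == "yak") != is_yak:
                raise ConfigurationError(
                    f"direction {ev.direction} inconsistent with recipient population {pop}"
                )
            donor = int(rng.choice(donor_rows))
            win.haplotypes[row] = win.haplotypes[donor].copy()
            win.sv_alleles[row] = win.sv_alleles[donor]
            origin[(ev.sv_index, sample, hap)] = ev.donor_population
        direction_of_sv.setdefault(ev.sv_index, set()).add(ev.direction)

    rows = []
    for sv_index in range(len(cohort.windows)):
        dirs = direction_of_sv.get(sv_index, set())
        if dirs == {"cattle_to_yak", "yak_to_cattle"}:
            true_dir = "mutual"
        elif dirs:
            true_dir = next(iter(dirs))
        else:
            true_dir = "none"
        for sample, hap in carriers:
            donor = origin.get((sv_index, sample, hap))
            rows.append(
                (
                    sv_index,
                    sample,
                    hap,
                    "introgressed" if donor else "native",
                    donor if donor else "",
                    true_dir,
                )
            )
    truth = pd.DataFrame(
        rows,
        columns=["sv_index", "sample", "hap_index", "origin", "donor_population", "direction"],
    )
    return cohort, truth


def random_cattle_to_yak_events(
    cohort: SimulatedCohort,
    sv_fraction: float = 0.3,
    max_recipients: int = 10,
    seed: int = 0,
) -> list:
    """Draw cattle->yak events on a random subset of SV loci.

    Recipients are domestic-yak haplotypes; each event SV receives between 1
    and ``max_recipients`` of them (uniform), mirroring the variable carrier
    frequency of introgressed haplotypes in real herds.
    """
    rng = np.random.default_rng(seed)
    n_events = int(round(sv_fraction * len(cohort.windows)))
    loci = np.sort(rng.choice(len(cohort.windows), size=n_events, replace=False))
    dy_haps = [
        (s, h)
        for s in cohort.samples
        if cohort.populations[s] == "domestic_yak"
        for h in (0, 1)
    ]
    events = []
    for locus in loci:
        k = int(rng.integers(1, max_recipients + 1))
        picks = rng.choice(len(dy_haps), size=min(k, len(dy_haps)), replace=False)
        events.append(
            IntrogressionEvent(
                sv_index=int(locus),
                direction="cattle_to_yak",
                recipient_haplotypes=tuple(dy_haps[i] for i in sorted(picks)),
                donor_population="cattle",
            )
        )
    return events


def simulate_sv_genotypes(
    af_spec: pd.DataFrame, n_per_population: dict, seed: int = 0
) -> tuple:
    """Draw diploid SV genotypes binomially from per-population allele freqs.

    ``af_spec`` is (n_sv x populations) of alt-allele frequencies in [0, 1];
    columns are population labels.  Returns ``(genotypes, samples, pops)``:
    genotypes is (n_sv, n_samples, 2) int8 with each allele an independent
    Bernoulli(af) draw, samples the generated ids, pops the id->label map.
    """
    if ((af_spec.to_numpy() < 0) | (af_spec.to_numpy() > 1)).any():
        raise ConfigurationError("allele frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sv = len(af_spec)
    samples, pops = [], {}
    blocks = []
    for pop in af_spec.columns:
        n = int(n_per_population[pop])
        af = af_spec[pop].to_numpy()[:, None, None]
        blocks.append((rng.random((n_sv, n, 2)) < af).astype(np.int8))
        for i in range(n):
            name = f"{pop}_{i + 1:03d}"
            samples.append(name)
            pops[name] = pop
    genotypes = np.concatenate(blocks, axis=1)
    return genotypes, samples, pops


def simulate_segment_depths(
    true_cn: pd.DataFrame,
    segment_lengths: dict,
    base_depth: float = 20.0,
    depth_window_bp: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate mean read depth per (sample, segment) from true copy numbers.

    Depth is profiled in non-overlapping ``depth_window_bp`` bins; each bin's
    depth is Poisson with mean ``base_depth * CN / 2`` and the reported value
    is the mean over bins.  ``true_cn`` is (samples x segments) of integers.
    """
    if base_depth <= 0:
        raise ConfigurationError("base_depth must be positive")
    if (true_cn.to_numpy() < 0).any():
        raise ConfigurationError("copy numbers must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in true_cn.index:
        for segment in true_cn.columns:
            cn = int(true_cn.loc[sample, segment])
            length = int(segment_lengths[segment])
            n_bins = max(1, length // depth_window_bp)
            mean_depth = float(rng.poisson(base_depth * cn / 2.0, size=n_bins).mean())
            rows.append((sample, segment, mean_depth, length, base_depth))
    return pd.DataFrame(
        rows, columns=["sample", "segment", "mean_depth", "length", "baseline"]
    )


def simulate_family_matrix(
    n_genomes: int,
    n_families: int,
    core_fraction: float = 0.5,
    presence_decay: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a gene-family presence/absence matrix.

    Each family is core (present in every genome) with probability
    ``core_fraction``; a non-core family is present in a uniformly chosen
    subset whose size k in 1..N-1 has probability proportional to
    ``presence_decay**(N-1-k)`` (most accessory families are near-universal,
    a geometric-like tail is rare, which matches observed occupancy spectra).
    Rows are family ids, columns genome ids, values 0/1; no empty rows.
    """
    if not 0 <= core_fraction <= 1:
        raise ConfigurationError("core_fraction must lie in [0, 1]")
    if n_genomes < 2:
        raise ConfigurationError("need at least 2 genomes")
    rng = np.random.default_rng(seed)
    sizes = np.arange(1, n_genomes)
    weights = presence_decay ** (n_genomes - 1 - sizes)
    weights = weights / weights.sum()
    mat = np.zeros((n_families, n_genomes), dtype=np.int8)
    is_core = rng.random(n_families) < core_fraction
    for fam in range(n_families):
        if is_core[fam]:
            mat[fam, :] = 1
        else:
            k = int(rng.choice(sizes, p=weights))
            cols = rng.choice(n_genomes, size=k, replace=False)
            mat[fam, cols] = 1
    return pd.DataFrame(
        mat,
        index=[f"fam{i + 1:05d}" for i in range(n_families)],
        columns=[f"g{j + 1:02d}" for j in range(n_genomes)],
    )


# ---------------------------------------------------------------------------
# Bridges to the variant-matrix containers used by the I/O and scan layers.

def locus_chrom(sv_index: int) -> str:
    """Contig name of an SV locus (one contig per window avoids cross-talk)."""
    return f"w{sv_index}"


def sv_position(config: CohortConfig) -> int:
    """1-based position of the SV within its window (the window centre)."""
    return config.window_bp // 2


def cohort_to_matrices(cohort: SimulatedCohort):
    """Convert a cohort to (snp GenotypeMatrix, sv GenotypeMatrix).

    SNP alleles are written as REF=A / ALT=T; SV records are 100 bp
    insertions anchored at the window centre.  All genotypes are phased.
    """
    from svorigin.variant_io import GenotypeMatrix

    cfg = cohort.config
    n_samples = cfg.n_samples
    snp_rows, snp_gts = [], []
    for win in cohort.windows:
        chrom = locus_chrom(win.sv_index)
        gt = win.haplotypes.reshape(n_samples, 2, -1).transpose(2, 0, 1)
        for j, pos in enumerate(win.positions):
            snp_rows.append((chrom, int(pos), f"{chrom}_snp{j}", "A", ("T",), "SNP", 1))
        snp_gts.append(gt.astype(np.int8))
    snp_variants = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "id", "ref", "alts", "svtype", "svlen"]
    )
    snp_matrix = GenotypeMatrix(
        samples=list(cohort.samples),
        variants=snp_variants,
        genotypes=np.concatenate(snp_gts, axis=0),
        phased=np.ones((len(snp_variants), n_samples), dtype=bool),
    )

    sv_rows, sv_gts = [], []
    pos = sv_position(cfg)
    for win in cohort.windows:
        chrom = locus_chrom(win.sv_index)
        sv_rows.append((chrom, pos, f"sv{win.sv_index}", "N", ("<INS>",), "INS", 100))
        sv_gts.append(win.sv_alleles.reshape(n_samples, 2).astype(np.int8))
    sv_variants = pd.DataFrame(
        sv_rows, columns=["chrom", "pos", "id", "ref", "alts", "svtype", "svlen"]
    )
    sv_matrix = GenotypeMatrix(
        samples=list(cohort.samples),
        variants=sv_variants,
        genotypes=np.stack(sv_gts, axis=0),
        phased=np.ones((len(sv_variants), n_samples), dtype=bool),
    )
    return snp_matrix, sv_matrix
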