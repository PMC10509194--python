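"""Flanking-haplotype tree classification of SV origin.

For each SV, the phased SNP haplotypes in a window around the variant are
restricted to SNPs in strong LD with the SV allele (the tagging SNPs), a
neighbour-joining tree is built from normalized Hamming distances between
haplotypes, and each query haplotype is assigned a species origin from where
it nests: a yak haplotype inside a cattle clade is cattle-derived, a cattle
haplotype inside a wild-yak clade is yak-derived, and a haplotype inside its
own species' clade is native.  Per-SV direction follows from the haplotype
calls: cattle->yak, yak->cattle, mutual (both), or none.

The nesting test ascends from the query leaf to the first ancestor whose
subtree holds at least ``min_ref_leaves`` reference-panel leaves and calls an
origin only if those references are at least ``purity_min`` pure for one
species.  Reference panels (wild yaks as the yak anchor, non-admixed cattle
as the cattle anchor) are declared by the caller, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from svorigin.divergence import ld_r2

DEFAULT_SPECIES_OF = {
    "wild_yak": "yak",
    "domestic_yak": "yak",
    "cattle": "cattle",
    "qtp_cattle": "cattle",
    "european_taurine": "cattle",
    "outgroup": "outgroup",
}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    window_bp: int = 50_000  # each side of the SV
    tag_r2_min: float = 0.45
    min_ref_leaves: int = 3
    purity_min: float = 0.9
    min_tag_snps: int = 5
    min_shared_frac: float = 0.5  # pairwise-complete distance floor
    outgroup_label: str = "outgroup"
    yak_reference_pops: tuple = ("wild_yak",)
    cattle_reference_pops: tuple = ("cattle", "european_taurine")
    species_of: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_OF))

    def __post_init__(self) -> None:
        if not (0 < self.purity_min <= 1):
            raise ClassificationError("purity_min must lie in (0, 1]")
        if self.min_ref_leaves < 1 or self.window_bp <= 0:
            raise ClassificationError("min_ref_leaves >= 1 and window_bp > 0 required")


@dataclass
class HaplotypePanel:
    """Per-SV window of phased SNP haplotypes, one row per haplotype."""

    sv_id: str
    positions: np.ndarray  # (n_sites,) 1-based, ascending
    sequences: np.ndarray  # (n_haps, n_sites) int8, -1 missing
    samples: list  # carrier sample per haplotype row
    hap_index: np.ndarray  # (n_haps,) 0/1
    populations: np.ndarray  # (n_haps,) object
    sv_alleles: np.ndarray  # (n_haps,) int8

    @property
    def n_haps(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_sites(self) -> int:
        return self.sequences.shape[1]

    def leaf_names(self) -> list:
        return [f"{s}|{h}" for s, h in zip(self.samples, self.hap_index)]


# ---------------------------------------------------------------------------
# Panel construction


def extract_flanking_haplotypes(
    snp_matrix,
    sv_record,
    sv_genotypes: np.ndarray,
    popmap: dict,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> HaplotypePanel:
    """Collect phased SNPs within ``window_bp`` of an SV into a panel.

    ``sv_record`` needs chrom, pos, id, svtype, svlen; ``sv_genotypes`` is
    the (n_samples, 2) phased SV allele array aligned with
    ``snp_matrix.samples``.  For deletions, SNPs inside the deleted span
    are set missing on deletion-carrying haplotypes.  Unphased genotypes in
    the window raise; a window without SNPs yields a zero-site panel.
    """
    chrom, pos = sv_record["chrom"], int(sv_record["pos"])
    on_chrom = snp_matrix.variants["chrom"] == chrom
    positions = snp_matrix.variants["pos"].to_numpy()
    in_window = (
        on_chrom
        & (positions >= pos - cfg.window_bp)
        & (positions <= pos + cfg.window_bp)
    ).to_numpy()
    idx = np.flatnonzero(in_window)
    if idx.size and not snp_matrix.phased[idx].all():
        raise ClassificationError(
            f"unphased SNP genotypes in the window of {sv_record['id']}"
        )
    n_samples = len(snp_matrix.samples)
    seqs = (
        snp_matrix.genotypes[idx]
        .transpose(1, 2, 0)
        .reshape(2 * n_samples, idx.size)
        .astype(np.int8)
    )
    sv_alleles = np.asarray(sv_genotypes, dtype=np.int8).reshape(2 * n_samples)
    site_pos = positions[idx]
    if sv_record.get("svtype") == "DEL" and idx.size:
        span_lo, span_hi = pos + 1, pos + int(sv_record["svlen"])
        inside = (site_pos >= span_lo) & (site_pos <= span_hi)
        carriers = sv_alleles > 0
        seqs[np.ix_(carriers, inside)] = -1
    return HaplotypePanel(
        sv_id=str(sv_record["id"]),
        positions=site_pos,
        sequences=seqs,
        samples=[s for s in snp_matrix.samples for _ in (0, 1)],
        hap_index=np.tile([0, 1], n_samples),
        populations=np.repeat([popmap[s] for s in snp_matrix.samples], 2),
        sv_alleles=sv_alleles,
    )


def panels_from_cohort(cohort) -> list:
    """Fast path: build one HaplotypePanel per simulated SV window."""
    panels = []
    pops = cohort.haplotype_population()
    samples = [s for s in cohort.samples for _ in (0, 1)]
    hap_index = np.tile([0, 1], len(cohort.samples))
    for win in cohort.windows:
        panels.append(
            HaplotypePanel(
                sv_id=f"sv{win.sv_index}",
                positions=win.positions,
                sequences=win.haplotypes.astype(np.int8),
                samples=samples,
                hap_index=hap_index,
                populations=pops,
                sv_alleles=win.sv_alleles.astype(np.int8),
            )
        )
    return panels


def select_tagging_snps(
    panel: HaplotypePanel, cfg: ClassifierConfig = ClassifierConfig()
) -> tuple:
    """Restrict a panel to SNPs with r2(SNP, SV allele) >= tag_r2_min.

    Returns ``(panel, kept_indices)``; the caller compares ``len(kept)``
    against ``min_tag_snps`` to decide classifiability.
    """
    carrier = (panel.sv_alleles > 0).astype(np.int8)
    kept = [
        j
        for j in range(panel.n_sites)
        if (r2 := ld_r2(panel.sequences[:, j], carrier)) == r2
        and r2 >= cfg.tag_r2_min
    ]
    kept = np.array(kept, dtype=int)
    restricted = HaplotypePanel(
        sv_id=panel.sv_id,
        positions=panel.positions[kept],
        sequences=panel.sequences[:, kept],
        samples=panel.samples,
        hap_index=panel.hap_index,
        populations=panel.populations,
        sv_alleles=panel.sv_alleles,
    )
    return restricted, kept


def hamming_distance_matrix(
    sequences: np.ndarray, min_shared_frac: float = 0.5
) -> np.ndarray:
    """Normalized Hamming distances over pairwise-complete sites.

    Pairs sharing fewer than ``min_shared_frac`` of the sites get NaN.
    """
    seqs = np.asarray(sequences)
    n, s = seqs.shape
    valid = seqs >= 0
    shared = (valid[:, None, :] & valid[None, :, :])
    n_shared = shared.sum(axis=2)
    neq = (seqs[:, None, :] != seqs[None, :, :]) & shared
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = neq.sum(axis=2) / n_shared
    dist[n_shared < min_shared_frac * max(s, 1)] = np.nan
    np.fill_diagonal(dist, 0.0)
    return dist


# ---------------------------------------------------------------------------
# Neighbour joining


class Clade:
    """Node of a phylogeny; leaves carry a name, edges a length to parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = float(length)
        self.children = list(children or [])
        self.parent = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Clade") -> None:
        child.parent = self
        self.children.append(child)

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> list:
        return [leaf.name for leaf in self.leaves()]

    def find_leaf(self, name: str) -> "Clade":
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    def to_newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def bipartitions(self) -> set:
        """Non-trivial splits as frozensets of leaf names (unrooted sense)."""
        all_leaves = frozenset(self.leaf_names())
        splits = set()

        def walk(node):
            names = frozenset(node.leaf_names())
            if 1 < len(names) < len(all_leaves) - 1:
                splits.add(min(names, all_leaves - names, key=sorted))
            for c in node.children:
                walk(c)

        for c in self.children:
            walk(c)
        return splits


def nj_tree(distances: np.ndarray, labels: list) -> Clade:
    """Saitou-Nei neighbour joining with the Q criterion.

    Ties in Q are broken by the smallest (row, column) index pair, with new
    internal nodes appended after the original leaf indices.  Negative
    branch-length estimates are clamped to zero.  The returned tree is the
    unrooted NJ topology arbitrarily rooted at the last internal node
    (degree 3); use :func:`root_on_outgroup` for a rooted view.
    """
    d0 = np.asarray(distances, dtype=float)
    n = d0.shape[0]
    if n < 3:
        raise ClassificationError("neighbour joining needs at least 3 leaves")
    if d0.shape != (n, n) or not np.allclose(d0, d0.T, equal_nan=True):
        raise ClassificationError("distance matrix must be square and symmetric")
    if np.isnan(d0).any():
        raise ClassificationError("distance matrix contains NaN")
    if len(labels) != n:
        raise ClassificationError("label count must match matrix size")

    size = 2 * n
    d = np.zeros((size, size))
    d[:n, :n] = d0
    nodes = {i: Clade(name=labels[i]) for i in range(n)}
    active = list(range(n))
    next_id = n

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major: smallest index pair on ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        ci, cj = nodes.pop(i), nodes.pop(j)
        ci.length = max(li, 0.0)
        cj.length = max(lj, 0.0)
        parent = Clade(children=[ci, cj])
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            d[next_id, k] = d[k, next_id] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    u, v = active
    cu, cv = nodes[u], nodes[v]
    duv = max(d[u, v], 0.0)
    if cv.is_leaf and not cu.is_leaf:
        cu, cv = cu, cv
    elif cu.is_leaf and not cv.is_leaf:
        cu, cv = cv, cu
    cv.length = duv
    cu.add(cv)
    cu.length = 0.0
    return cu


def root_on_outgroup(tree: Clade, outgroup_leaf_name: str) -> Clade:
    """Root a tree at the midpoint of an outgroup leaf's pendant edge."""
    edges = []

    def collect(node):
        for c in node.children:
            edges.append((node, c, c.length))
            collect(c)

    collect(tree)
    adjacency: dict = {}
    for a, b, length in edges:
        adjacency.setdefault(id(a), []).append((b, length))
        adjacency.setdefault(id(b), []).append((a, length))
    node_by_id = {id(tree): tree}
    for a, b, _ in edges:
        node_by_id[id(a)] = a
        node_by_id[id(b)] = b

    target = None
    for node in node_by_id.values():
        if node.is_leaf and node.name == outgroup_leaf_name:
            target = node
    if target is None:
        raise ClassificationError(f"outgroup leaf {outgroup_leaf_name!r} not in tree")
    (neighbor, pendant_len), = [
        (nb, ln) for nb, ln in adjacency[id(target)]
    ]

    def build(node, come_from, length):
        fresh = Clade(name=node.name, length=length)
        for nb, ln in adjacency[id(node)]:
            if id(nb) != id(come_from):
                fresh.add(build(nb, node, ln))
        return fresh

    half = pendant_len / 2.0
    root = Clade(children=[])
    root.add(build(target, neighbor, half))
    root.add(build(neighbor, target, half))
    return root


# ---------------------------------------------------------------------------
# Origin calls


@dataclass
class HaplotypeCall:
    sample: str
    hap_index: int
    population: str
    origin: str  # native | cattle_derived | yak_derived | unclassified
    n_ref_leaves: int
    purity: float


@dataclass
class SVOriginCall:
    sv_id: str
    direction: str  # none | cattle_to_yak | yak_to_cattle | mutual
    calls: list  # of HaplotypeCall
    n_tag_snps: int
    flag: str = ""  # "", "too_few_tag_snps", "sparse_distances", "no_snps"
    newick: str = ""

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.sv_id, c.sample, c.hap_index, c.population, c.origin,
                 c.n_ref_leaves, c.purity)
                for c in self.calls
            ],
            columns=["sv_id", "sample", "hap_index", "population", "origin",
                     "n_ref_leaves", "purity"],
        )


def classify_haplotype_origin(
    root: Clade,
    query_leaf_name: str,
    leaf_population: dict,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple:
    """Origin of one haplotype from its nesting in the rooted tree.

    Ascends from the query leaf to the first ancestor whose subtree holds at
    least ``min_ref_leaves`` reference-panel leaves (query excluded); if
    those references are ``purity_min``-pure for one species the clade's
    species decides the call, otherwise the haplotype is unclassified.
    Returns ``(origin, n_ref_leaves, purity)``.
    """
    ref_pops = set(cfg.yak_reference_pops) | set(cfg.cattle_reference_pops)
    query = root.find_leaf(query_leaf_name)
    query_species = cfg.species_of[leaf_population[query_leaf_name]]
    node = query.parent
    while node is not None:
        refs = [
            leaf
            for leaf in node.leaves()
            if leaf is not query and leaf_population[leaf.name] in ref_pops
        ]
        if len(refs) >= cfg.min_ref_leaves:
            species = [cfg.species_of[leaf_population[r.name]] for r in refs]
            counts = pd.Series(species).value_counts()
            purity = counts.iloc[0] / len(refs)
            if purity < cfg.purity_min:
                return "unclassified", len(refs), float(purity)
            clade_species = counts.index[0]
            if clade_species == query_species:
                return "native", len(refs), float(purity)
            if query_species == "yak" and clade_species == "cattle":
                return "cattle_derived", len(refs), float(purity)
            if query_species == "cattle" and clade_species == "yak":
                return "yak_derived", len(refs), float(purity)
            return "unclassified", len(refs), float(purity)
        node = node.parent
    return "unclassified", 0, float("nan")


def classify_sv_origin(calls: list, cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """Per-SV direction from per-haplotype origin calls."""
    yak_from_cattle = any(
        c.origin == "cattle_derived" and cfg.species_of[c.population] == "yak"
        for c in calls
    )
    cattle_from_yak = any(
        c.origin == "yak_derived" and cfg.species_of[c.population] == "cattle"
        for c in calls
    )
    if yak_from_cattle and cattle_from_yak:
        return "mutual"
    if yak_from_cattle:
        return "cattle_to_yak"
    if cattle_from_yak:
        return "yak_to_cattle"
    return "none"


def classify_panel(
    panel: HaplotypePanel,
    cfg: ClassifierConfig = ClassifierConfig(),
    keep_newick: bool = False,
) -> SVOriginCall:
    """Run the full per-SV procedure: tag SNPs, NJ tree, origin calls."""
    if panel.n_sites == 0:
        return SVOriginCall(panel.sv_id, "none", [], 0, flag="no_snps")
    tagged, kept = select_tagging_snps(panel, cfg)
    if len(kept) < cfg.min_tag_snps:
        return SVOriginCall(panel.sv_id, "none", [], len(kept), flag="too_few_tag_snps")
    dist = hamming_distance_matrix(tagged.sequences, cfg.min_shared_frac)
    if np.isnan(dist).any():
        return SVOriginCall(panel.sv_id, "none", [], len(kept), flag="sparse_distances")
    names = tagged.leaf_names()
    leaf_population = dict(zip(names, tagged.populations))
    outgroup_leaves = [
        n for n, p in leaf_population.items() if p == cfg.outgroup_label
    ]
    if not outgroup_leaves:
        raise ClassificationError("no outgroup leaves: rooting undefined")
    tree = nj_tree(dist, names)
    rooted = root_on_outgroup(tree, outgroup_leaves[0])

    calls = []
    for name in names:
        pop = leaf_population[name]
        if pop == cfg.outgroup_label:
            continue
        origin, n_ref, purity = classify_haplotype_origin(
            rooted, name, leaf_population, cfg
        )
        sample, hap = name.rsplit("|", 1)
        calls.append(HaplotypeCall(sample, int(hap), pop, origin, n_ref, purity))
    direction = classify_sv_origin(calls, cfg)
    return SVOriginCall(
        panel.sv_id,
        direction,
        calls,
        len(kept),
        newick=rooted.to_newick() if keep_newick else "",
    )


def cohort_introgression_summary(sv_calls: list, popmap: dict) -> tuple:
    """Per-sample introgressed-SV counts and the yak carrier fraction.

    Returns ``(per_sample, fraction)``: per_sample maps sample id to the
    number of SVs at which it carries at least one cattle-derived or
    yak-derived haplotype; fraction is the share of yak samples carrying at
    least one cattle-derived haplotype anywhere.
    """
    per_sample = {s: 0 for s in popmap}
    cattle_derived_carrier = set()
    for sv in sv_calls:
        seen = set()
        for c in sv.calls:
            if c.origin in ("cattle_derived", "yak_derived"):
                seen.add(c.sample)
            if c.origin == "cattle_derived":
                cattle_derived_carrier.add(c.sample)
        for s in seen:
            per_sample[s] = per_sample.get(s, 0) + 1
    yaks = [s for s, p in popmap.items() if p in ("wild_yak", "domestic_yak")]
    if not yaks:
        return per_sample, float("nan")
    fraction = sum(1 for s in yaks if s in cattle_derived_carrier) / len(yaks)
    return per_sample, float(fraction)
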