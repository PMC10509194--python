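"""Read/write the formats the pipeline touches and apply variant-level filters.

Covers the TSV population map, phased VCF genotype matrices (via pysam),
genotype-level and variant-level quality filters (call rate, minor allele
frequency, depth soft band), bubble/SV extraction from an explicit-path GFA,
and SV region annotation against a GFF3.

Internal coordinates are 0-based half-open; conversion to and from 1-based
happens only at the VCF/GFF boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

#: Minimum length for a record to count as a structural variant.
MIN_SV_LEN = 50

#: Default population vocabulary; extensible via read_population_map(extra=...).
POPULATION_VOCABULARY = frozenset(
    {
        "wild_yak",
        "domestic_yak",
        "cattle",
        "qtp_cattle",
        "european_taurine",
        "bison",
        "wisent",
        "gaur",
        "outgroup",
    }
)

SV_TYPES = ("INS", "DEL", "DIV", "MULTI")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid genotype matrix.

    genotypes: (n_variants, n_samples, 2) int8 allele indices, -1 = missing.
    phased: (n_variants, n_samples) bool, True where GT used '|'.
    variants: DataFrame with chrom, pos (1-based), id, ref, alts (tuple),
    svtype, svlen columns; positions strictly increasing within a chromosome.
    """

    samples: list
    variants: pd.DataFrame
    genotypes: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape[0] != len(self.variants):
            raise DataError("genotype/variant row mismatch")
        if self.genotypes.shape[1] != len(self.samples):
            raise DataError("genotype/sample column mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            phased=self.phased[idx],
        )

    def sample_columns(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise DataError(f"sample {exc.args[0]!r} absent from matrix") from None


@dataclass(frozen=True)
class FilterConfig:
    """Variant- and genotype-level quality thresholds.

    Genotypes with depth below ``depth_soft_filter_low`` or above
    ``depth_soft_filter_high`` times the sample's mean depth are soft-filtered
    (set missing); variants with call rate below ``min_call_rate`` or minor
    allele frequency below ``min_maf`` are then dropped.
    """

    min_call_rate: float = 0.7
    min_maf: float = 0.05
    depth_soft_filter_low: float = 1.0 / 3.0
    depth_soft_filter_high: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_call_rate <= 1 and 0 <= self.min_maf <= 1):
            raise DataError("min_call_rate and min_maf must lie in [0, 1]")


@dataclass(frozen=True)
class AnnotationConfig:
    flank_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise DataError("flank_bp must be >= 0")


def read_population_map(path, extra_labels=()) -> dict:
    """Read a two-column TSV (sample, population) into a validated dict."""
    vocabulary = POPULATION_VOCABULARY | set(extra_labels)
    mapping: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected at least 2 columns")
            sample, label = parts[0].strip(), parts[1].strip()
            if sample in mapping:
                raise DataError(f"{path}:{lineno}: duplicate sample {sample!r}")
            if label not in vocabulary:
                raise DataError(
                    f"{path}:{lineno}: unknown population {label!r}; "
                    f"known labels: {sorted(vocabulary)}"
                )
            mapping[sample] = label
    return mapping


def _parse_svtype(rec) -> tuple:
    """(svtype, svlen) of a pysam record; SNP for 1bp substitutions."""
    try:
        svtype = rec.info["SVTYPE"] if "SVTYPE" in rec.info else None
        svlen = rec.info["SVLEN"] if "SVLEN" in rec.info else None
    except (KeyError, ValueError):  # INFO keys absent from the header
        svtype = svlen = None
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0]
    if svtype is None:
        alt = rec.alts[0] if rec.alts else rec.ref
        if len(rec.ref) == 1 and all(len(a) == 1 for a in (rec.alts or "N")):
            return "SNP", 1
        diff = max(abs(len(a) - len(rec.ref)) for a in rec.alts) if rec.alts else 0
        svtype = "INS" if any(len(a) > len(rec.ref) for a in (rec.alts or ())) else "DEL"
        svlen = diff
        _ = alt
    return str(svtype), int(abs(svlen)) if svlen is not None else 0


def read_phased_vcf(path, require_phase: bool = False) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    '|' genotypes are marked phased, '/' unphased, missing alleles -1.
    With ``require_phase`` any unphased non-missing genotype raises a
    DataError naming the first offending record.  SV records (SVTYPE set)
    shorter than 50 bp are dropped at load.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows, gts, phases = [], [], []
    last_pos: dict = {}
    for rec in vcf:
        svtype, svlen = _parse_svtype(rec)
        if svtype in SV_TYPES and svlen < MIN_SV_LEN:
            continue
        prev = last_pos.get(rec.chrom)
        if prev is not None and rec.pos <= prev:
            raise DataError(
                f"positions not strictly increasing at {rec.chrom}:{rec.pos}"
            )
        last_pos[rec.chrom] = rec.pos
        gt_row = np.full((len(samples), 2), -1, dtype=np.int8)
        ph_row = np.zeros(len(samples), dtype=bool)
        for i, sample in enumerate(samples):
            call = rec.samples[sample]
            alleles = call.get("GT")
            phased = bool(call.phased)
            if alleles is None:
                alleles = (None, None)
            if len(alleles) == 1:
                alleles = (alleles[0], alleles[0])
            a, b = alleles
            gt_row[i, 0] = -1 if a is None else a
            gt_row[i, 1] = -1 if b is None else b
            ph_row[i] = phased
            if require_phase and not phased and (a is not None or b is not None):
                raise DataError(
                    f"unphased genotype for sample {sample} at "
                    f"{rec.chrom}:{rec.pos}"
                )
        rows.append(
            (
                rec.chrom,
                rec.pos,
                rec.id or f"{rec.chrom}:{rec.pos}",
                rec.ref,
                tuple(rec.alts or ()),
                svtype,
                svlen,
            )
        )
        gts.append(gt_row)
        phases.append(ph_row)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alts", "svtype", "svlen"]
    )
    genotypes = (
        np.stack(gts) if gts else np.zeros((0, len(samples), 2), dtype=np.int8)
    )
    phased = np.stack(phases) if phases else np.zeros((0, len(samples)), dtype=bool)
    return GenotypeMatrix(samples, variants, genotypes, phased)


def write_vcf(matrix: GenotypeMatrix, path, header_comment: str | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file."""
    contigs = list(dict.fromkeys(matrix.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header_comment:
            fh.write(f"##svorigin={header_comment}\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i, row in enumerate(matrix.variants.itertuples(index=False)):
            info = "."
            if row.svtype in SV_TYPES:
                info = f"SVTYPE={row.svtype};SVLEN={row.svlen}"
            fields = [
                row.chrom,
                str(row.pos),
                row.id,
                row.ref,
                ",".join(row.alts) if row.alts else ".",
                ".",
                "PASS",
                info,
                "GT",
            ]
            gt = matrix.genotypes[i]
            ph = matrix.phased[i]
            for j in range(len(matrix.samples)):
                sep = "|" if ph[j] else "/"
                a, b = gt[j]
                fields.append(
                    f"{'.' if a < 0 else a}{sep}{'.' if b < 0 else b}"
                )
            fh.write("\t".join(fields) + "\n")


def filter_variants(
    matrix: GenotypeMatrix,
    cfg: FilterConfig = FilterConfig(),
    genotype_depths: np.ndarray | None = None,
    mean_depths: np.ndarray | None = None,
) -> tuple:
    """Apply the genotype depth soft-filter, then call-rate and MAF filters.

    When ``genotype_depths`` (n_variants x n_samples) and per-sample
    ``mean_depths`` are supplied, genotypes whose depth lies outside
    [low x mean, high x mean] are set missing first.  Variants failing call
    rate are counted under "call_rate"; of the survivors, those failing MAF
    under "maf".  MAF is computed over non-missing alleles; for multiallelic
    records it is 1 minus the frequency of the most common allele.

    Returns ``(filtered_matrix, report)`` with per-cause removal tallies.
    """
    if matrix.n_variants == 0:
        raise DataError("cannot filter an empty matrix")
    genotypes = matrix.genotypes.copy()
    phased = matrix.phased.copy()
    n_depth_masked = 0
    if genotype_depths is not None:
        if mean_depths is None:
            raise DataError("mean_depths required with genotype_depths")
        mean = np.asarray(mean_depths, dtype=float)[None, :]
        bad = (genotype_depths < cfg.depth_soft_filter_low * mean) | (
            genotype_depths > cfg.depth_soft_filter_high * mean
        )
        n_depth_masked = int(bad.sum())
        genotypes[bad] = -1

    n_var, n_samp, _ = genotypes.shape
    called = (genotypes >= 0).all(axis=2)
    call_rate = called.sum(axis=1) / n_samp

    maf = np.zeros(n_var)
    for v in range(n_var):
        alleles = genotypes[v][genotypes[v] >= 0]
        if alleles.size == 0:
            maf[v] = 0.0
            continue
        counts = np.bincount(alleles)
        maf[v] = 1.0 - counts.max() / alleles.size

    fail_cr = call_rate < cfg.min_call_rate
    fail_maf = ~fail_cr & (maf < cfg.min_maf)
    keep = ~(fail_cr | fail_maf)
    report = {
        "n_input": n_var,
        "n_genotypes_depth_masked": n_depth_masked,
        "n_dropped_call_rate": int(fail_cr.sum()),
        "n_dropped_maf": int(fail_maf.sum()),
        "n_retained": int(keep.sum()),
    }
    out = GenotypeMatrix(
        samples=list(matrix.samples),
        variants=matrix.variants.iloc[np.flatnonzero(keep)].reset_index(drop=True),
        genotypes=genotypes[keep],
        phased=phased[keep],
    )
    return out, report


# ---------------------------------------------------------------------------
# GFA bubble extraction


@dataclass
class BubbleRecord:
    """A bubble between two reference-path nodes.

    ``alleles`` maps each distinct interior path (tuple of oriented node
    names, reference allele included) to its sequence length in bp.
    """

    chrom: str
    source: str
    sink: str
    pos: int  # 1-based position of the reference base before the bubble
    ref_allele: tuple
    alleles: dict
    svlen: int

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def allele_class(self) -> str:
        return "biallelic" if self.n_alleles == 2 else "multiallelic"

    @property
    def is_sv(self) -> bool:
        return self.svlen >= MIN_SV_LEN


def _parse_gfa(path) -> tuple:
    seg_len: dict = {}
    paths: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                name, seq = parts[1], parts[2]
                if seq == "*":
                    length = None
                    for tag in parts[3:]:
                        if tag.startswith("LN:i:"):
                            length = int(tag[5:])
                    if length is None:
                        raise DataError(f"segment {name} has no sequence and no LN tag")
                else:
                    length = len(seq)
                seg_len[name] = length
            elif parts[0] == "P":
                name = parts[1]
                steps = tuple(
                    (step[:-1], step[-1]) for step in parts[2].split(",") if step
                )
                paths[name] = steps
    return seg_len, paths


def extract_bubbles(gfa_path, reference_name: str) -> list:
    """Find bubbles against the reference path of an explicit-path GFA.

    A bubble is anchored by a pair of reference-path nodes (u, v) between
    which at least one path traverses an interior differing from the
    reference interior.  Interiors are compared as oriented node sequences;
    allele lengths are the summed segment lengths of the interior.  The
    reported position is the 1-based coordinate of the last base of u on the
    reference (the VCF-style anchor base before the bubble).  Output order
    and content are invariant to S- and P-line order.
    """
    seg_len, paths = _parse_gfa(gfa_path)
    if reference_name not in paths:
        raise DataError(f"reference path {reference_name!r} absent from GFA")
    ref_steps = paths[reference_name]
    if any(orient != "+" for _, orient in ref_steps):
        raise DataError("reverse-orientation reference segments are unsupported")
    ref_nodes = [node for node, _ in ref_steps]
    ref_index = {node: i for i, node in enumerate(ref_nodes)}
    if len(ref_index) != len(ref_nodes):
        raise DataError("reference path visits a node twice; unsupported")

    # 1-based coordinate of the last base of each reference node.
    end_coord = np.cumsum([seg_len[n] for n in ref_nodes])

    # anchored interiors per (u_index, v_index): set of interior step tuples
    interiors: dict = {}
    for name in sorted(paths):
        steps = paths[name]
        anchors = [
            (i, ref_index[node]) for i, (node, _) in enumerate(steps) if node in ref_index
        ]
        if not anchors:
            continue
        ref_positions = [r for _, r in anchors]
        if ref_positions != sorted(ref_positions):
            raise DataError(f"path {name!r} traverses reference nodes out of order")
        for (i_a, r_a), (i_b, r_b) in zip(anchors, anchors[1:]):
            interior = steps[i_a + 1 : i_b]
            interiors.setdefault((r_a, r_b), set()).add(interior)

    bubbles = []
    for (r_a, r_b), alleles in sorted(interiors.items()):
        ref_interior = tuple(ref_steps[r_a + 1 : r_b])
        alleles = set(alleles) | {ref_interior}
        if len(alleles) < 2:
            continue
        lengths = {
            allele: sum(seg_len[node] for node, _ in allele) for allele in alleles
        }
        span = max(lengths.values()) - min(lengths.values())
        bubbles.append(
            BubbleRecord(
                chrom=reference_name,
                source=ref_nodes[r_a],
                sink=ref_nodes[r_b],
                pos=int(end_coord[r_a]),
                ref_allele=ref_interior,
                alleles={k: lengths[k] for k in sorted(lengths)},
                svlen=int(span),
            )
        )
    bubbles.sort(key=lambda b: b.pos)
    return bubbles


# ---------------------------------------------------------------------------
# GFF3 region annotation


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataError(f"{path}:{lineno}: expected 9 GFF3 columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                (
                    parts[0],
                    parts[2].lower(),
                    start - 1,  # to 0-based half-open
                    end,
                    attrs.get("ID", ""),
                    attrs.get("Parent", ""),
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "feature", "start", "end", "id", "parent"]
    )


def _overlaps(start: int, end: int, intervals: np.ndarray) -> bool:
    if intervals.size == 0:
        return False
    return bool(((intervals[:, 0] < end) & (intervals[:, 1] > start)).any())


def annotate_sv_regions(
    svs: pd.DataFrame, gff_path, cfg: AnnotationConfig = AnnotationConfig()
) -> pd.Series:
    """Classify SVs as coding, regulatory, or intergenic against a GFF3.

    coding: overlaps any CDS interval.  regulatory: overlaps an intron
    (gene span minus its exons) or the +-flank_bp flanks of a gene.
    intergenic otherwise; precedence coding > regulatory > intergenic.
    ``svs`` needs chrom, pos (1-based), svtype and svlen columns; deletions
    and divergent alleles occupy [pos, pos+svlen) on the reference,
    insertions the single anchor base.
    """
    feats = _read_gff3(gff_path)
    cds: dict = {}
    regulatory: dict = {}
    for chrom, group in feats.groupby("chrom"):
        cds[chrom] = group.loc[group["feature"] == "cds", ["start", "end"]].to_numpy()
        reg_rows = []
        genes = group[group["feature"] == "gene"]
        exons = group[group["feature"] == "exon"]
        for gene in genes.itertuples(index=False):
            reg_rows.append((max(0, gene.start - cfg.flank_bp), gene.start))
            reg_rows.append((gene.end, gene.end + cfg.flank_bp))
            gene_exons = exons[
                (exons["start"] >= gene.start) & (exons["end"] <= gene.end)
            ].sort_values("start")
            prev_end = None
            for exon in gene_exons.itertuples(index=False):
                if prev_end is not None and exon.start > prev_end:
                    reg_rows.append((prev_end, exon.start))  # intron
                prev_end = exon.end if prev_end is None else max(prev_end, exon.end)
            if len(gene_exons) == 0:
                reg_rows.append((gene.start, gene.end))
        regulatory[chrom] = np.array(reg_rows, dtype=int).reshape(-1, 2)

    labels = []
    for sv in svs.itertuples(index=False):
        start = sv.pos - 1
        span = 1 if sv.svtype == "INS" else max(1, int(sv.svlen))
        end = start + span
        if _overlaps(start, end, cds.get(sv.chrom, np.empty((0, 2)))):
            labels.append("coding")
        elif _overlaps(start, end, regulatory.get(sv.chrom, np.empty((0, 2)))):
            labels.append("regulatory")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=svs.index, name="region_class")
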