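"""Per-variant population-differentiation statistics.

Implements the estimators used for the wild-yak adaptation scan:

- Weir & Cockerham (1984) theta from the variance components a, b, c
  (the quantity VCFtools reports per site), summed over alleles so
  multiallelic records are handled uniformly;
- AMOVA Phi_ST over allele copies with an allele-identity distance
  (the Arlequin-style decomposition);
- LD r2 on phased haplotypes;
- the frequency-based ABBA-BABA D statistic with an optional block
  jackknife;
- threshold outlier scans (theta == 1 for the fixed-difference sweep rule,
  theta > t for the SNP domestication scan).

Negative estimates are reported raw, never clamped.  Missing genotypes are
excluded listwise within each variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ScanConfig:
    """Outlier thresholds; 1.0 is the SV fixed-difference sweep rule and
    0.3 the SNP domestication rule.  ld_strong_r2 is the strong-LD cutoff
    used when tagging SNPs within ld_window_bp of a variant."""

    fst_outlier_threshold: float = 1.0
    ld_strong_r2: float = 0.45
    ld_window_bp: int = 50_000


def _allele_counts(gt: np.ndarray, n_alleles: int) -> np.ndarray:
    """Per-allele counts over the non-missing allele copies of each variant.

    gt: (n_variants, n_samples, 2).  Returns (n_variants, n_alleles).
    """
    n_var = gt.shape[0]
    out = np.zeros((n_var, n_alleles), dtype=int)
    for a in range(n_alleles):
        out[:, a] = (gt == a).sum(axis=(1, 2))
    return out


def fst_weir_cockerham(gt_a: np.ndarray, gt_b: np.ndarray) -> np.ndarray:
    """Weir-Cockerham theta per variant between two groups of diploids.

    ``gt_a``/``gt_b`` are (n_variants, n_i, 2) allele-index arrays with -1
    for missing.  An individual with any missing allele at a variant is
    excluded at that variant.  For each allele u the variance components

        a_u = (nbar/nc) [ s2 - (pbar qbar - s2 (r-1)/r - hbar/4) / (nbar-1) ]
        b_u = (nbar/(nbar-1)) [ pbar qbar - s2 (r-1)/r - hbar (2 nbar - 1)/(4 nbar) ]
        c_u = hbar / 2

    are evaluated with r = 2 populations and summed over alleles;
    theta = sum(a) / sum(a + b + c).  NaN where fewer than two complete
    diploids remain in either group or the denominator is zero.
    """
    n_var = gt_a.shape[0]
    max_allele = int(max(gt_a.max(initial=0), gt_b.max(initial=0)))
    theta = np.full(n_var, np.nan)
    for v in range(n_var):
        groups = []
        for gt in (gt_a, gt_b):
            g = gt[v]
            g = g[(g >= 0).all(axis=1)]
            groups.append(g)
        n = np.array([len(g) for g in groups], dtype=float)
        if (n < 2).any():
            continue
        r = 2.0
        nbar = n.mean()
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1.0)
        num = den = 0.0
        for u in range(max_allele + 1):
            p = np.array([(g == u).mean() for g in groups])
            h = np.array([((g == u).sum(axis=1) == 1).mean() for g in groups])
            pbar = (n * p).sum() / (r * nbar)
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1.0) * nbar)
            hbar = (n * h).sum() / (r * nbar)
            pq = pbar * (1.0 - pbar)
            a = (nbar / nc) * (
                s2 - (pq - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
            )
            b = (nbar / (nbar - 1.0)) * (
                pq - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
            )
            c = hbar / 2.0
            num += a
            den += a + b + c
        theta[v] = num / den if den != 0.0 else np.nan
    return theta


def phi_st(gt_a: np.ndarray, gt_b: np.ndarray) -> np.ndarray:
    """AMOVA Phi_ST per variant between two groups, allele-identity distance.

    The units are allele copies (two per complete diploid); the distance
    between two copies is 0 if they carry the same allele index, else 1.
    Phi_ST = sigma2_among / (sigma2_among + sigma2_within) from the standard
    mean-square decomposition.  NaN when all copies are identical (zero
    total variance) or a group has fewer than two copies.
    """
    n_var = gt_a.shape[0]
    out = np.full(n_var, np.nan)
    for v in range(n_var):
        copies = []
        for gt in (gt_a, gt_b):
            g = gt[v]
            g = g[(g >= 0).all(axis=1)]
            copies.append(g.ravel())
        n = np.array([len(c) for c in copies], dtype=float)
        if (n < 2).any():
            continue
        total = np.concatenate(copies)
        big_n = float(len(total))

        def unequal_pairs(x: np.ndarray) -> float:
            counts = np.bincount(x)
            return (len(x) ** 2 - (counts.astype(float) ** 2).sum()) / 2.0

        ssd_total = unequal_pairs(total) / big_n
        ssd_within = sum(unequal_pairs(c) / len(c) for c in copies)
        ssd_among = ssd_total - ssd_within
        r = 2.0
        df_among, df_within = r - 1.0, big_n - r
        if df_within <= 0:
            continue
        ms_among = ssd_among / df_among
        ms_within = ssd_within / df_within
        n0 = (big_n - (n**2).sum() / big_n) / (r - 1.0)
        sigma_within = ms_within
        sigma_among = (ms_among - ms_within) / n0
        denom = sigma_among + sigma_within
        out[v] = sigma_among / denom if denom != 0.0 else np.nan
    return out


def fst_phist_concordance(theta: np.ndarray, phist: np.ndarray) -> tuple:
    """Pearson r and two-sided p over variants where both statistics exist."""
    ok = np.isfinite(theta) & np.isfinite(phist)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    x, y = theta[ok], phist[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ld_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r2 between two biallelic loci on phased haplotypes (0/1 arrays).

    NaN if either locus is monomorphic over the jointly non-missing
    haplotypes (missing coded < 0).
    """
    hap_a = np.asarray(hap_a, dtype=float)
    hap_b = np.asarray(hap_b, dtype=float)
    ok = (hap_a >= 0) & (hap_b >= 0)
    a, b = hap_a[ok], hap_b[ok]
    if a.size == 0:
        return float("nan")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def polarize_by_outgroup(freqs: np.ndarray, outgroup_freqs: np.ndarray) -> tuple:
    """Polarize allele frequencies so the outgroup carries the ancestral state.

    Sites where the outgroup is polymorphic are skipped.  Where the outgroup
    is fixed for the alternate allele the frequencies are flipped so they
    count the derived allele.  Returns (derived_freqs, kept_site_mask);
    ``freqs`` has shape (n_sites, n_pops).
    """
    outgroup_freqs = np.asarray(outgroup_freqs, dtype=float)
    keep = (outgroup_freqs == 0.0) | (outgroup_freqs == 1.0)
    derived = np.asarray(freqs, dtype=float)[keep].copy()
    flip = outgroup_freqs[keep] == 1.0
    derived[flip] = 1.0 - derived[flip]
    return derived, keep


def d_statistic(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    n_blocks: int = 0,
) -> tuple:
    """Frequency-based ABBA-BABA D statistic over polarized sites.

    D = sum[(1-p1) p2 p3 - p1 (1-p2) p3] / sum[(1-p1) p2 p3 + p1 (1-p2) p3]
    with p_i the derived-allele frequency in population i.  With
    ``n_blocks`` > 1 a delete-one block jackknife over contiguous equal-size
    site blocks gives (D, SE, Z); otherwise (D, nan, nan).  D is NaN when
    the denominator is zero.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    abba = (1.0 - p1) * p2 * p3
    baba = p1 * (1.0 - p2) * p3
    num, den = (abba - baba).sum(), (abba + baba).sum()
    if den == 0.0:
        return float("nan"), float("nan"), float("nan")
    d = num / den
    if n_blocks <= 1 or len(p1) < n_blocks:
        return float(d), float("nan"), float("nan")
    bounds = np.linspace(0, len(p1), n_blocks + 1).astype(int)
    d_del = []
    for j in range(n_blocks):
        mask = np.ones(len(p1), dtype=bool)
        mask[bounds[j] : bounds[j + 1]] = False
        nj, dj = (abba - baba)[mask].sum(), (abba + baba)[mask].sum()
        if dj == 0.0:
            return float(d), float("nan"), float("nan")
        d_del.append(nj / dj)
    d_del = np.array(d_del)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((d_del - d_del.mean()) ** 2).sum()))
    z = d / se if se > 0 else float("nan")
    return float(d), se, float(z)


def outlier_scan(
    values: np.ndarray, threshold: float, mode: str = "equals", atol: float = 1e-9
) -> np.ndarray:
    """Indices of outlier variants.

    ``equals`` selects values within ``atol`` of the threshold (the theta = 1
    fixed-difference rule); ``greater`` selects values strictly above it
    (the theta > 0.3 rule).  NaN never qualifies.
    """
    values = np.asarray(values, dtype=float)
    if mode == "equals":
        mask = np.isfinite(values) & (np.abs(values - threshold) <= atol)
    elif mode == "greater":
        mask = np.isfinite(values) & (values > threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.flatnonzero(mask)


def group_genotypes(matrix, popmap: dict, population) -> np.ndarray:
    """Genotype slab (n_variants, n, 2) of one population (or several)."""
    wanted = {population} if isinstance(population, str) else set(population)
    ids = [s for s in matrix.samples if popmap.get(s) in wanted]
    if not ids:
        raise ValueError(f"no samples with population {sorted(wanted)}")
    return matrix.genotypes[:, matrix.sample_columns(ids), :]
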