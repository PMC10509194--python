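"""Wild-vs-domestic allele-frequency contrast with FDR control.

Candidate domestication SVs are those with a large allele-frequency
difference between wild and domestic yaks (Fisher's exact test,
Benjamini-Hochberg q < alpha) after removing SVs whose haplotype trees show
cattle introgression.  The same machinery, run in the dominance
(carrier-status) parameterization, serves the white-coat case/control
contrast.

The two-sided Fisher p is the sum of hypergeometric probabilities not
exceeding the observed table's probability, evaluated directly from the
hypergeometric pmf (the classical definition, no mid-p correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Relative tolerance when comparing pmf values to the observed table's
#: probability; absorbs float round-off on exact ties.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ContrastConfig:
    group_a: str = "wild_yak"
    group_b: str = "domestic_yak"
    model: str = "allelic"  # "allelic" (allele counts) or "dominance" (carrier status)
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.model not in ("allelic", "dominance"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of counts.

    Sums hypergeometric probabilities over all tables with the same margins
    whose probability is <= the observed table's (with a small relative
    tolerance for float ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        return 1.0
    k = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _contrast_tables(gt_a: np.ndarray, gt_b: np.ndarray, alt: int, model: str):
    """2x2 table (group x status) for one alt allele across variants.

    allelic: alt-allele copies vs all other non-missing copies.
    dominance: carriers (>= 1 copy of alt) vs non-carriers among complete
    diploids.
    """
    if model == "allelic":
        a_alt = (gt_a == alt).sum(axis=(1, 2))
        a_ref = ((gt_a >= 0) & (gt_a != alt)).sum(axis=(1, 2))
        b_alt = (gt_b == alt).sum(axis=(1, 2))
        b_ref = ((gt_b >= 0) & (gt_b != alt)).sum(axis=(1, 2))
    else:
        ok_a = (gt_a >= 0).all(axis=2)
        ok_b = (gt_b >= 0).all(axis=2)
        car_a = ((gt_a == alt).any(axis=2)) & ok_a
        car_b = ((gt_b == alt).any(axis=2)) & ok_b
        a_alt = car_a.sum(axis=1)
        a_ref = ok_a.sum(axis=1) - a_alt
        b_alt = car_b.sum(axis=1)
        b_ref = ok_b.sum(axis=1) - b_alt
    return a_alt, a_ref, b_alt, b_ref


def af_contrast_scan(
    matrix, popmap: dict, cfg: ContrastConfig = ContrastConfig()
) -> pd.DataFrame:
    """Per-variant (and per-alt-allele) Fisher contrast between two groups.

    Multiallelic variants are tested each-alt-vs-rest, one row per alt
    allele sharing the variant id.  BH q-values are computed jointly over
    all tests.  Columns: variant_id, alt, af_a, af_b, the 2x2 cells, p, q,
    candidate (q < alpha).
    """
    from svorigin.divergence import group_genotypes

    gt_a = group_genotypes(matrix, popmap, cfg.group_a)
    gt_b = group_genotypes(matrix, popmap, cfg.group_b)
    if gt_a.shape[1] == 0 or gt_b.shape[1] == 0:
        raise ValueError("both contrast groups must be non-empty")

    rows = []
    for v in range(matrix.n_variants):
        var_id = matrix.variants["id"].iloc[v]
        n_alts = max(1, len(matrix.variants["alts"].iloc[v]))
        for alt in range(1, n_alts + 1):
            a_alt, a_ref, b_alt, b_ref = (
                x[v] for x in _contrast_tables(gt_a, gt_b, alt, cfg.model)
            )
            tot_a, tot_b = a_alt + a_ref, b_alt + b_ref
            af_a = a_alt / tot_a if tot_a else np.nan
            af_b = b_alt / tot_b if tot_b else np.nan
            p = fisher_exact_two_sided(((a_alt, a_ref), (b_alt, b_ref)))
            rows.append((var_id, alt, af_a, af_b, a_alt, a_ref, b_alt, b_ref, p))
    result = pd.DataFrame(
        rows,
        columns=["variant_id", "alt", "af_a", "af_b",
                 "a_alt", "a_ref", "b_alt", "b_ref", "p"],
    )
    result["q"] = bh_fdr(result["p"].to_numpy())
    result["candidate"] = result["q"] < cfg.fdr_alpha
    return result


def select_candidates(
    contrast: pd.DataFrame,
    sv_directions: dict,
    cfg: ContrastConfig = ContrastConfig(),
) -> pd.DataFrame:
    """Final candidate set: significant contrasts minus introgressed SVs.

    ``sv_directions`` maps variant id to the tree-classifier direction; SVs
    with direction cattle_to_yak or mutual are excluded with reason
    "introgressed".  A multiallelic SV is a candidate if any of its alt
    tests survives FDR.  Returns one row per variant id with columns
    min_q, candidate, excluded, reason.
    """
    per_sv = (
        contrast.groupby("variant_id", sort=False)
        .agg(min_q=("q", "min"), any_significant=("candidate", "any"))
        .reset_index()
    )
    directions = per_sv["variant_id"].map(lambda s: sv_directions.get(s, "none"))
    introgressed = directions.isin(["cattle_to_yak", "mutual"])
    per_sv["direction"] = directions
    per_sv["excluded"] = per_sv["any_significant"] & introgressed
    per_sv["reason"] = np.where(per_sv["excluded"], "introgressed", "")
    per_sv["candidate"] = per_sv["any_significant"] & ~introgressed
    return per_sv.drop(columns=["any_significant"])
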