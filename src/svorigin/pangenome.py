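"""Pangenome presence/absence statistics.

Classifies entities (gene families or graph nodes) by occupancy into core
(present in all N genomes), near-core (missing at most
``near_core_max_missing`` genomes) and variable (the rest); computes
pan/core saturation curves over random genome orderings; and counts
pairwise presence/absence asymmetries.  The same parametrized thresholds
serve both the gene-family use (N=22, missing <= 2) and the graph-node use
(N=47, present in 46 or 45 genomes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FamilyConfig:
    near_core_max_missing: int = 2
    permutations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.near_core_max_missing < 1:
            raise ValueError("near_core_max_missing must be >= 1")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


def load_presence(path_or_frame) -> pd.DataFrame:
    """Load a presence matrix (entities x genomes of 0/1).

    Accepts a wide TSV (first column entity id) or a long TSV with columns
    entity, genome, present.  Entities present nowhere are rejected.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        mat = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, sep="\t")
        cols = [c.lower() for c in df.columns]
        if cols[:3] == ["entity", "genome", "present"]:
            mat = df.pivot(index=df.columns[0], columns=df.columns[1],
                           values=df.columns[2]).fillna(0)
        else:
            mat = df.set_index(df.columns[0])
    mat = mat.astype(int)
    if not mat.isin([0, 1]).to_numpy().all():
        raise ValueError("presence matrix must be 0/1")
    empty = mat.sum(axis=1) == 0
    if empty.any():
        raise ValueError(
            f"entities present in no genome: {list(mat.index[empty][:5])}"
        )
    return mat


def classify_presence(
    matrix: pd.DataFrame, cfg: FamilyConfig = FamilyConfig()
) -> tuple:
    """Occupancy class per entity and the class fractions.

    core: present in all N genomes; near_core: present in N-1 down to
    N - near_core_max_missing; variable: anything rarer.  For N too small
    to separate three classes only core/variable are emitted (with a
    warning in the fractions dict).
    """
    n = matrix.shape[1]
    occupancy = matrix.sum(axis=1)
    if n < cfg.near_core_max_missing + 2:
        classes = pd.Series(
            np.where(occupancy == n, "core", "variable"), index=matrix.index
        )
        fractions = classes.value_counts(normalize=True).to_dict()
        fractions["warning"] = "too few genomes for a near-core class"
        return classes, fractions
    classes = pd.Series("variable", index=matrix.index, dtype=object)
    classes[occupancy == n] = "core"
    near = (occupancy < n) & (occupancy >= n - cfg.near_core_max_missing)
    classes[near] = "near_core"
    fractions = {
        label: float((classes == label).mean())
        for label in ("core", "near_core", "variable")
    }
    return classes, fractions


def saturation_trajectories(
    matrix: pd.DataFrame, cfg: FamilyConfig = FamilyConfig()
) -> tuple:
    """Per-ordering pan(k) and core(k) trajectories.

    Uses all N! genome orderings when N! <= ``cfg.permutations``, otherwise
    ``cfg.permutations`` seeded random orderings.  Returns (pan, core),
    each (n_orderings, N) of entity counts.
    """
    presence = matrix.to_numpy(dtype=bool).T  # genomes x entities
    n = presence.shape[0]
    if math.factorial(n) <= cfg.permutations:
        orders = [np.array(p) for p in permutations(range(n))]
    else:
        rng = np.random.default_rng(cfg.seed)
        orders = [rng.permutation(n) for _ in range(cfg.permutations)]
    pan = np.empty((len(orders), n), dtype=int)
    core = np.empty((len(orders), n), dtype=int)
    for i, order in enumerate(orders):
        rolled = presence[order]
        pan[i] = np.logical_or.accumulate(rolled, axis=0).sum(axis=1)
        core[i] = np.logical_and.accumulate(rolled, axis=0).sum(axis=1)
    return pan, core


def saturation_curves(
    matrix: pd.DataFrame, cfg: FamilyConfig = FamilyConfig()
) -> pd.DataFrame:
    """Mean pan(k) and core(k) for k = 1..N over genome orderings."""
    pan, core = saturation_trajectories(matrix, cfg)
    n = matrix.shape[1]
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "pan_mean": pan.mean(axis=0),
            "core_mean": core.mean(axis=0),
        }
    )


def pairwise_absence(matrix: pd.DataFrame) -> pd.DataFrame:
    """N x N counts; cell (i, j) = entities present in genome i, absent in j.

    The diagonal is zero and the matrix is not generally symmetric;
    (i, j) + |i intersect j| = |i| for every pair.
    """
    p = matrix.to_numpy(dtype=np.int64).T  # genomes x entities
    counts = p @ (1 - p).T
    return pd.DataFrame(counts, index=matrix.columns, columns=matrix.columns)
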