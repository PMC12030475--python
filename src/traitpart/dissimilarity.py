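"""Jaccard community dissimilarity and the ANOSIM permutation test.

Plots are reduced to the species making up >= 90% of their cover, binarised
to presence/absence, and compared with the Jaccard dissimilarity
d = 1 - |intersection| / |union|.  ANOSIM (analysis of similarities) then
asks whether between-group dissimilarities are systematically larger than
within-group ones: all pairwise dissimilarities are ranked (mid-ranks for
ties) and

    R = (mean between-group rank - mean within-group rank) / (M / 2),

with M = n(n-1)/2 pairs; R = 1 means complete separation, R near 0 no group
structure.  Significance is one-sided by permuting group labels — exactly,
by enumerating all distinct label arrangements when there are at most 10,000
of them, otherwise by seeded random sampling.

The study design implies four tests: one grouping all plots by climate, and
one per climate grouping its plots by herbivore treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sympy.utilities.iterables import multiset_permutations

from .data_model import (
    AbundanceMatrix,
    CommonSpeciesFilter,
    PlotDesign,
    ValidationError,
)

EXACT_PERMUTATION_LIMIT = 10_000


def jaccard_matrix(
    ab: AbundanceMatrix, species_filter: CommonSpeciesFilter | None = None
) -> pd.DataFrame:
    """Plot x plot Jaccard dissimilarity on presence/absence after filtering."""
    if species_filter is not None:
        ab = species_filter.apply(ab)
    presence = (ab.matrix.to_numpy() > 0)
    if not presence.any(axis=1).all():
        empty = ab.matrix.index[~presence.any(axis=1)].tolist()
        raise ValidationError(f"plot(s) with empty retained species set: {empty}")
    D = squareform(pdist(presence, metric="jaccard"))
    return pd.DataFrame(D, index=ab.matrix.index, columns=ab.matrix.index)


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    method: str           # "exact" or "sampled"
    grouping: str
    seed: int | None

    def __post_init__(self) -> None:
        assert -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12
        assert 0.0 < self.p_value <= 1.0


def _n_distinct_label_permutations(labels: np.ndarray) -> int:
    n = len(labels)
    total = factorial(n)
    for _, count in zip(*np.unique(labels, return_counts=True)):
        total //= factorial(int(count))
    return total


def _r_statistic(rank_matrix: np.ndarray, codes: np.ndarray) -> float:
    same = codes[:, None] == codes[None, :]
    iu = np.triu_indices_from(rank_matrix, k=1)
    within = same[iu]
    ranks = rank_matrix[iu]
    m = len(ranks)
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def _r_statistics(rank_matrix: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Vectorised ANOSIM R for a (P, n) array of label permutations.

    Group sizes are identical across permutations, so the within-pair count
    is constant and only the within-group rank sum varies.
    """
    n = rank_matrix.shape[0]
    m = n * (n - 1) / 2.0
    total = rank_matrix.sum() / 2.0
    _, counts = np.unique(perms[0], return_counts=True)
    n_within = float((counts * (counts - 1) // 2).sum())
    same = perms[:, :, None] == perms[:, None, :]
    within_sum = np.einsum("pij,ij->p", same, rank_matrix) / 2.0
    rw = within_sum / n_within
    rb = (total - within_sum) / (m - n_within)
    return (rb - rw) / (m / 2.0)


def anosim(
    d: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int | None = 0,
    grouping_name: str = "",
) -> AnosimResult:
    """Rank-based one-sided ANOSIM test of group separation.

    ``d`` is a symmetric dissimilarity matrix, ``groups`` the group label per
    plot (aligned on the matrix index).  All distinct label permutations are
    enumerated when there are at most 10,000; otherwise ``n_permutations``
    random permutations are drawn from ``seed``.
    """
    groups = groups.loc[d.index]
    labels = groups.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        singles = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValidationError(f"singleton group(s): {singles}")
    Dm = d.to_numpy(dtype=float)
    if not np.allclose(Dm, Dm.T) or not np.allclose(np.diag(Dm), 0.0):
        raise ValidationError("dissimilarity matrix must be symmetric with zero diagonal")

    iu = np.triu_indices_from(Dm, k=1)
    vals = Dm[iu]
    if np.allclose(vals, vals[0]):
        warnings.warn("constant dissimilarities: ANOSIM R is 0 by construction")
    ranks = np.zeros_like(Dm)
    ranks[iu] = rankdata(vals)  # mid-ranks for ties
    ranks = ranks + ranks.T

    codes = np.searchsorted(uniq, labels)
    r_obs = _r_statistic(ranks, codes)

    n_exact = _n_distinct_label_permutations(codes)
    if n_exact <= EXACT_PERMUTATION_LIMIT:
        perms = np.array(list(multiset_permutations(sorted(codes))))
        r_perm = _r_statistics(ranks, perms)
        p = float(np.sum(r_perm >= r_obs - 1e-12) / n_exact)
        return AnosimResult(r_obs, p, n_exact, "exact", grouping_name, None)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    r_perm = _r_statistics(ranks, perms)
    exceed = int(np.sum(r_perm >= r_obs - 1e-12))
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return AnosimResult(r_obs, p, n_permutations, "sampled", grouping_name, seed)


def run_study_anosims(
    d: pd.DataFrame,
    design: PlotDesign,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, AnosimResult]:
    """The design's four tests: climate across all plots, then herbivore
    treatment within each climate."""
    table = design.table.loc[d.index]
    results = {
        "climate": anosim(
            d, table["climate"], n_permutations, seed, grouping_name="climate"
        )
    }
    for climate in sorted(table["climate"].unique()):
        ids = table.index[table["climate"] == climate]
        sub = d.loc[ids, ids]
        results[climate] = anosim(
            sub,
            table.loc[ids, "treatment"],
            n_permutations,
            seed,
            grouping_name=f"treatment within {climate}",
        )
    return results
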