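"""Analysis of similarity (ANOSIM).

ANOSIM tests whether between-group dissimilarities are larger than
within-group ones, on ranks. With M = n(n-1)/2 pairwise dissimilarities
ranked with mid-ranks for ties,

    R = (mean_rank_between - mean_rank_within) / (M / 2)

lies in [-1, 1]; R near 1 means all between-group pairs outrank all
within-group pairs. Significance is one-sided by label permutation with
the +1 convention, p = (1 + #{R_perm >= R_obs}) / (1 + n_perm); when the
number of distinct label assignments is small the permutation distribution
is enumerated exhaustively and p is an exact fraction over that count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .io import DistanceMatrix, SampleMetadata
from .diversity import bonferroni

# exhaustive enumeration is used when the number of distinct labelings is
# at most this AND at most the requested n_perm
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    exhaustive: bool
    groups: tuple[str, ...]
    seed: int | None = None


def _n_distinct_labelings(counts: list[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def _distinct_labelings(counts: list[int]):
    """Yield all distinct assignments of group indices to n positions.

    Generated recursively by choosing the position set of each group in
    turn, so the cost is the multinomial coefficient, not n!.
    """
    n = sum(counts)

    def rec(positions: tuple[int, ...], gi: int, acc: np.ndarray):
        if gi == len(counts):
            yield acc.copy()
            return
        for chosen in itertools.combinations(positions, counts[gi]):
            acc[list(chosen)] = gi
            remaining = tuple(p for p in positions if p not in chosen)
            yield from rec(remaining, gi + 1, acc)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def _anosim_r(ranks: np.ndarray, grouping: np.ndarray) -> float:
    """R from condensed-order ranks and an integer grouping vector."""
    n = grouping.size
    iu, ju = np.triu_indices(n, k=1)
    within = grouping[iu] == grouping[ju]
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    D: DistanceMatrix,
    meta: SampleMetadata,
    n_perm: int = 9999,
    seed: int | None = None,
) -> AnosimResult:
    """Global ANOSIM on a distance matrix with group labels.

    Requires >= 2 groups each with >= 2 samples. Exhaustive enumeration of
    the label permutations is selected automatically when their number is
    at most min(n_perm, 10,000); otherwise ``n_perm`` random relabelings
    drawn from ``seed`` are used.
    """
    labels = np.array(meta.labels_for(D.labels))
    group_names = tuple(sorted(set(labels)))
    if len(group_names) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    counts = []
    for g in group_names:
        c = int((labels == g).sum())
        if c < 2:
            raise ValidationError(f"group {g!r} has {c} sample(s); ANOSIM needs >= 2")
        counts.append(c)

    grouping = np.array([group_names.index(g) for g in labels])
    ranks = rankdata(D.condensed())  # mid-ranks for ties
    r_obs = _anosim_r(ranks, grouping)

    n_distinct = _n_distinct_labelings(counts)
    exhaustive = n_distinct <= min(n_perm, EXHAUSTIVE_LIMIT)
    if exhaustive:
        count = 0
        for lab in _distinct_labelings(counts):
            if _anosim_r(ranks, lab) >= r_obs - 1e-12:
                count += 1
        p = count / n_distinct
        return AnosimResult(r_obs, p, n_distinct, True, group_names, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(grouping)
        if _anosim_r(ranks, perm) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(r_obs, p, n_perm, False, group_names, seed)


def anosim_null_distribution(
    D: DistanceMatrix, meta: SampleMetadata, n_perm: int, seed: int | None = None
) -> np.ndarray:
    """R values under random relabeling (for calibration checks)."""
    labels = np.array(meta.labels_for(D.labels))
    group_names = sorted(set(labels))
    grouping = np.array([group_names.index(g) for g in labels])
    ranks = rankdata(D.condensed())
    rng = np.random.default_rng(seed)
    return np.array([
        _anosim_r(ranks, rng.permutation(grouping)) for _ in range(n_perm)
    ])


def pairwise_anosim(
    D: DistanceMatrix,
    meta: SampleMetadata,
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """ANOSIM for every unordered pair of groups, Bonferroni-corrected.

    Each pair is tested on the submatrix of its samples; raw p-values are
    multiplied by the number of pairs (capped at 1).
    """
    by_group = meta.by_group()
    names = sorted(by_group)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for k, (ga, gb) in enumerate(pairs):
        members = [s for s in D.labels if meta.group_of(s) in (ga, gb)]
        sub = D.submatrix(members)
        sub_meta = SampleMetadata({s: meta.group_of(s) for s in members})
        pair_seed = None if seed is None else seed + k
        res = anosim(sub, sub_meta, n_perm=n_perm, seed=pair_seed)
        rows.append({
            "group_a": ga, "group_b": gb,
            "R": res.R, "p": res.p,
            "n_permutations": res.n_permutations,
            "exhaustive": res.exhaustive,
        })
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy(), len(pairs))
    return out


def anosim_matrix(pairwise: pd.DataFrame, group_order: list[str]) -> pd.DataFrame:
    """Square layout: R in the lower-left triangle, corrected p upper-right."""
    M = pd.DataFrame(0.0, index=group_order, columns=group_order)
    for _, row in pairwise.iterrows():
        ga, gb = row["group_a"], row["group_b"]
        ia, ib = group_order.index(ga), group_order.index(gb)
        lo, hi = (ga, gb) if ia > ib else (gb, ga)
        M.loc[lo, hi] = row["R"]        # lower-left
        M.loc[hi, lo] = row["p_bonferroni"]  # upper-right
    return M
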