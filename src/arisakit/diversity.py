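"""Alpha- and beta-diversity statistics.

Alpha diversity is observed OTU richness and Shannon-Wiener H' (natural
log). Beta diversity is the Bray-Curtis index:

    dissimilarity(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y)

and its complement as similarity. Sequencing count tables are converted to
per-sample proportions before Bray-Curtis so the two method arms are
compared on the same relative-abundance scale; no rarefaction is applied.
On proportion vectors Bray-Curtis dissimilarity equals half the L1
distance.

The module also provides within-group similarity summaries, a Mantel-style
correlation between two methods' pairwise-similarity vectors, Welch's
t-test, and Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import JoinError, ValidationError
from .io import DistanceMatrix, OTUTable, RELATIVE_INTENSITY, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class TTestResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float


@dataclass
class CorrelationResult:
    """Pearson correlation between two pairwise-similarity vectors.

    ``p_parametric`` treats the n(n-1)/2 pairs as independent (they are
    not); ``p_permutation`` is the Mantel-style permutation p obtained by
    relabeling the samples of one matrix, which respects the dependence.
    """

    pearson_r: float
    r_squared: float
    p_parametric: float
    p_permutation: float | None
    n_pairs: int


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def observed_otus(table: OTUTable) -> pd.Series:
    """Per-sample count of OTUs with abundance > 0."""
    return (table.data > 0).sum(axis=1).rename("observed_otus")


def group_observed_otus(table: OTUTable, meta: SampleMetadata) -> pd.Series:
    """Per-group count of OTUs present in at least one sample of the group."""
    counts = {}
    for group, samples in meta.by_group().items():
        members = [s for s in samples if s in table.data.index]
        if not members:
            continue
        counts[group] = int(((table.data.loc[members] > 0).any(axis=0)).sum())
    return pd.Series(counts, name="group_otus")


def shannon(table: OTUTable) -> pd.Series:
    """Per-sample Shannon-Wiener H' in nats.

    H' = -sum p_i ln p_i over the positive proportions of each sample.
    """
    values = {}
    for sid, row in table.data.iterrows():
        v = row.to_numpy(dtype=float)
        v = v[v > 0]
        if v.size == 0:
            raise ValidationError(f"sample {sid!r} has no positive abundance")
        p = v / v.sum()
        values[sid] = float(-(p * np.log(p)).sum())
    return pd.Series(values, name="shannon_h")


def alpha_summary(table: OTUTable, meta: SampleMetadata) -> pd.DataFrame:
    """Per-group mean +/- SD of observed OTUs and Shannon H', plus group totals."""
    obs = observed_otus(table)
    h = shannon(table)
    rows = []
    for group, samples in meta.by_group().items():
        members = [s for s in samples if s in table.data.index]
        if not members:
            continue
        rows.append({
            "group": group,
            "n_samples": len(members),
            "otus_mean": float(obs[members].mean()),
            "otus_sd": float(obs[members].std(ddof=1)) if len(members) > 1 else 0.0,
            "shannon_mean": float(h[members].mean()),
            "shannon_sd": float(h[members].std(ddof=1)) if len(members) > 1 else 0.0,
        })
    out = pd.DataFrame(rows).set_index("group")
    out["group_total_otus"] = group_observed_otus(table, meta)
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Return (similarity, dissimilarity) between two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("abundance vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundance vectors must be non-negative")
    den = x.sum() + y.sum()
    if den == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    sim = 2.0 * np.minimum(x, y).sum() / den
    return float(sim), float(1.0 - sim)


def distance_matrix(table: OTUTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarity matrix.

    Count tables are converted to proportions first; relative-intensity
    tables are used as-is.
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    if table.abundance_kind != RELATIVE_INTENSITY:
        table = table.to_proportions()
    X = table.data.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    row_sums = X.sum(axis=1)
    for i in range(n):
        mins = np.minimum(X[i], X[i + 1:]).sum(axis=1)
        den = row_sums[i] + row_sums[i + 1:]
        if (den == 0).any():
            j = int(np.nonzero(den == 0)[0][0]) + i + 1
            raise ValidationError(
                f"Bray-Curtis undefined: samples {table.sample_ids[i]!r} and "
                f"{table.sample_ids[j]!r} are both all-zero"
            )
        d = 1.0 - 2.0 * mins / den
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    np.clip(D, 0.0, 1.0, out=D)
    return DistanceMatrix(table.sample_ids, D, "braycurtis")


def within_group_similarity(D: DistanceMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Mean +/- SD of within-group pairwise Bray-Curtis similarity.

    Groups with fewer than 2 samples are skipped with a warning. The SD of
    a group with a single pair is reported as 0.
    """
    rows = []
    for group, samples in meta.by_group().items():
        members = [s for s in samples if s in D.labels]
        if len(members) < 2:
            logger.warning("group %r has < 2 samples; skipped", group)
            continue
        sub = D.submatrix(members)
        sims = 1.0 - sub.condensed()
        sd = float(sims.std(ddof=1)) if sims.size > 1 else 0.0
        rows.append({
            "group": group,
            "n_pairs": sims.size,
            "similarity_mean": float(sims.mean()),
            "similarity_sd": sd,
        })
    return pd.DataFrame(rows).set_index("group")


def within_group_pairs(D: DistanceMatrix, meta: SampleMetadata) -> dict[str, np.ndarray]:
    """Within-group pair-level similarities, for cross-method comparisons."""
    out = {}
    for group, samples in meta.by_group().items():
        members = [s for s in samples if s in D.labels]
        if len(members) >= 2:
            out[group] = 1.0 - D.submatrix(members).condensed()
    return out


def compare_method_similarity(
    D1: DistanceMatrix, D2: DistanceMatrix, meta: SampleMetadata,
    name1: str = "method1", name2: str = "method2",
) -> pd.DataFrame:
    """Per-group Welch t-test of pair-level within-group similarities."""
    pairs1 = within_group_pairs(D1, meta)
    pairs2 = within_group_pairs(D2, meta)
    rows = []
    for group in pairs1:
        if group not in pairs2:
            continue
        if pairs1[group].size < 2 or pairs2[group].size < 2:
            logger.warning("group %r has a single pair; method comparison skipped", group)
            continue
        res = welch_t_test(pairs1[group], pairs2[group], name1, name2)
        rows.append({
            "group": group,
            f"{name1}_mean": float(pairs1[group].mean()),
            f"{name2}_mean": float(pairs2[group].mean()),
            "t": res.t,
            "df": res.df,
            "p": res.p,
        })
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# similarity-vector correlation (Mantel-style)
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        raise ValidationError("zero variance in a similarity vector")
    return float((a * b).sum() / den)


def correlate_similarity_vectors(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> CorrelationResult:
    """Pearson correlation between two matrices' pairwise similarities.

    Uses the n(n-1)/2 upper-triangle pairs. Because pairs sharing a sample
    are not independent, a Mantel permutation p is computed alongside the
    parametric one: the samples of the second matrix are relabeled
    ``n_perm`` times (exhaustively when n! <= n_perm) and the one-sided
    p-value for positive association is reported.
    """
    if D1.labels != D2.labels:
        raise JoinError("distance matrices have different sample labels")
    s1 = 1.0 - D1.condensed()
    s2 = 1.0 - D2.condensed()
    r = _pearson(s1, s2)
    n_pairs = s1.size
    # parametric two-sided p for Pearson r
    if n_pairs > 2:
        t = r * math.sqrt((n_pairs - 2) / max(1e-300, 1.0 - r * r))
        p_param = float(2 * stats.t.sf(abs(t), n_pairs - 2))
    else:
        p_param = 1.0

    n = D1.n
    if math.factorial(n) <= n_perm:
        perms = itertools.permutations(range(n))
        count = 0
        total = 0
        for perm in perms:
            P = D2.values[np.ix_(perm, perm)]
            s2p = 1.0 - P[np.triu_indices(n, k=1)]
            if _pearson(s1, s2p) >= r - 1e-12:
                count += 1
            total += 1
        p_perm = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            P = D2.values[np.ix_(perm, perm)]
            s2p = 1.0 - P[np.triu_indices(n, k=1)]
            if _pearson(s1, s2p) >= r - 1e-12:
                count += 1
        p_perm = (1 + count) / (1 + n_perm)
    return CorrelationResult(r, r * r, p_param, p_perm, n_pairs)


# ---------------------------------------------------------------------------
# group-mean tests
# ---------------------------------------------------------------------------

def welch_t_test(
    a: np.ndarray, b: np.ndarray, name_a: str = "a", name_b: str = "b"
) -> TTestResult:
    """Welch's unequal-variance two-sided t-test.

    When both groups have zero variance and equal means the comparison is
    degenerate and p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TTestResult(name_a, name_b, 0.0, float(a.size + b.size - 2), 1.0)
        return TTestResult(name_a, name_b, math.inf if a.mean() > b.mean() else -math.inf,
                           float(a.size + b.size - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return TTestResult(name_a, name_b, float(res.statistic), float(df), float(res.pvalue))


def pairwise_group_t_tests(values: pd.Series, meta: SampleMetadata) -> pd.DataFrame:
    """Welch t-tests for every unordered pair of groups on a per-sample statistic."""
    groups = meta.by_group()
    names = sorted(groups)
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        xa = values[[s for s in groups[ga] if s in values.index]].to_numpy()
        xb = values[[s for s in groups[gb] if s in values.index]].to_numpy()
        res = welch_t_test(xa, xb, ga, gb)
        rows.append({"group_a": ga, "group_b": gb, "t": res.t, "df": res.df, "p": res.p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = bonferroni(df["p"].to_numpy(), len(rows))
    return df


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValidationError("m must be >= 1")
    return np.minimum(1.0, m * p)
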