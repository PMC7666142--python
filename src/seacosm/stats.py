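"""Comparative statistics on rate and abundance tables.

Covers the campaign-level summaries: per-group min/max growth-rate ranges
and spreads, one-way ANOVA with Tukey HSD post hoc pairwise comparisons,
Ward hierarchical clustering of community profiles (euclidean or
Bray-Curtis), and one-way PERMANOVA with label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "round_half_up",
    "range_summary",
    "AnovaTukeyResult",
    "anova_tukey",
    "WardClustering",
    "ward_cluster",
    "PermanovaResult",
    "permanova",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at one decimal), as in printed tables.

    numpy/python banker's rounding rounds 0.25 to 0.2; published tables use
    conventional half-up rounding, so displayed spreads go through this.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def range_summary(ranges: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Overall growth-rate range and spread per group.

    Parameters
    ----------
    ranges
        One row per group per experiment with columns ``group``, ``k_min``
        and ``k_max`` (day^-1).  A single pre-computed overall range row per
        group is equally valid input: the spread is then computed directly
        from it.

    Returns
    -------
    DataFrame
        Per group: overall ``k_min`` (min of mins), ``k_max`` (max of
        maxes), exact ``spread`` = max − min, and a display ``spread_1dp``
        rounded half-up to ``decimals``.
    """
    required = {"group", "k_min", "k_max"}
    missing = required - set(ranges.columns)
    if missing:
        raise ValueError(f"range table missing columns: {sorted(missing)}")
    if not len(ranges):
        raise ValueError("range table is empty")
    bad = ranges["k_min"] > ranges["k_max"]
    if bad.any():
        rows = ranges.index[bad]
        raise ValueError(f"k_min > k_max at rows {list(rows[:5])}")
    out = (
        ranges.groupby("group", sort=False)
        .agg(k_min=("k_min", "min"), k_max=("k_max", "max"))
        .reset_index()
    )
    out["spread"] = out["k_max"] - out["k_min"]
    out["spread_1dp"] = out["spread"].map(lambda s: round_half_up(s, decimals))
    return out


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F and p plus the Tukey HSD pairwise table."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame | None  # group1, group2, meandiff, p_adj, lower, upper, reject
    alpha: float


def anova_tukey(
    values, labels, alpha: float = 0.05, *, include_tukey: bool = True
) -> AnovaTukeyResult:
    """One-way ANOVA across labelled groups with Tukey HSD post hoc pairs.

    Requires at least two groups with at least two observations each.  When
    the within-group variance is exactly zero but means differ (degenerate,
    e.g. constant replicates), the F statistic is infinite and p is
    reported as 0, with every unequal-mean pair flagged significant.
    ``include_tukey=False`` skips the post hoc table (it is much costlier
    than the omnibus test, which matters in simulation loops).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and the same length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups with fewer than 2 observations: {small.tolist()}")

    groups = [values[labels == g] for g in uniq]
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if within_ss == 0.0:
        if np.allclose(means, means[0]):
            raise ValueError("all observations identical; ANOVA undefined")
        rows = []
        for i in range(uniq.size):
            for j in range(i + 1, uniq.size):
                diff = means[j] - means[i]
                rows.append(
                    {
                        "group1": uniq[i],
                        "group2": uniq[j],
                        "meandiff": diff,
                        "p_adj": 0.0 if diff != 0 else 1.0,
                        "lower": diff,
                        "upper": diff,
                        "reject": diff != 0,
                    }
                )
        return AnovaTukeyResult(np.inf, 0.0, pd.DataFrame(rows), alpha)

    f_stat, p_val = sps.f_oneway(*groups)
    tukey = None
    if include_tukey:
        hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey = pd.DataFrame(
            hsd.summary().data[1:],
            columns=[
                "group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject",
            ],
        )
    return AnovaTukeyResult(float(f_stat), float(p_val), tukey, alpha)


@dataclass
class WardClustering:
    """Ward merge tree over samples.

    ``linkage`` is the (n-1, 4) merge matrix (children, height, cluster
    size) with non-decreasing heights; ``labels`` are the sample names in
    input order.
    """

    linkage: np.ndarray
    labels: list[str]
    distance: str

    def to_newick(self) -> str:
        """Nested-parentheses text export of the dendrogram with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            ldist = (node.dist - left.dist) / 2 if not left.is_leaf() else node.dist / 2
            rdist = (
                (node.dist - right.dist) / 2 if not right.is_leaf() else node.dist / 2
            )
            return f"({walk(left)}:{ldist:.6g},{walk(right)}:{rdist:.6g})"

        return walk(tree) + ";"


def ward_cluster(
    matrix, labels=None, distance: str = "euclidean"
) -> WardClustering:
    """Ward's-method hierarchical clustering of a samples × features matrix.

    ``distance="euclidean"`` is classical Ward; ``distance="bray-curtis"``
    applies the Ward (minimum-variance) update to Bray-Curtis
    dissimilarities, the conventional choice for community composition
    data.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains NaN or infinite features")
    if labels is None:
        labels = [f"S{i}" for i in range(x.shape[0])]
    if len(labels) != x.shape[0]:
        raise ValueError("labels length must match number of samples")
    if distance == "euclidean":
        z = hierarchy.linkage(x, method="ward")
    elif distance in ("bray-curtis", "braycurtis"):
        z = hierarchy.linkage(pdist(x, metric="braycurtis"), method="ward")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return WardClustering(linkage=z, labels=list(labels), distance=distance)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ss = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def permanova(
    distances, labels, n_perm: int = 999, seed: int | np.random.Generator = 0
) -> PermanovaResult:
    """One-way PERMANOVA: permutation test of location differences in distance space.

    The total sum of squared distances is partitioned into among- and
    within-group components; the pseudo-F statistic is the among/within
    mean-square ratio.  Significance is assessed by freely permuting the
    group labels: ``p = (count of permuted F >= observed F + 1) /
    (n_perm + 1)``.  Fixed seed, inputs and permutation count give a
    bit-identical p value.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per sample")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(
            f"groups with a single member: {uniq[counts < 2].tolist()}"
        )
    a = uniq.size
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_w = _ss_within(d2, lab, uniq)
        ss_a = ss_total - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(labels[rng.permutation(n)]) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        n_samples=n,
        n_groups=a,
    )
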