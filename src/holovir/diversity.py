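"""Jaccard beta diversity and permutational tests over grouping factors.

The community table is a samples x taxa presence/absence matrix.  Distances
are Jaccard: d(A, B) = 1 - |A n B| / |A u B| over presence sets.  Group
structure is tested with a one-factor PERMANOVA (the `adonis` model):

    SS_total = (1/n) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    SS_among = SS_total - SS_within
    R^2 = SS_among / SS_total
    F = (SS_among / (a - 1)) / (SS_within / (n - a))

with the permutation p-value (1 + #{F_perm >= F_obs}) / (1 + n_perm) under
random relabelling, or an exact p by full enumeration of distinct label
assignments for small n.  Homogeneity of multivariate dispersion
(`betadisper`) embeds the distance matrix by principal coordinates,
keeping axes of positive and negative eigenvalues separately; the squared
distance of a sample to its group centroid is the squared distance on the
positive axes minus that on the negative ("imaginary") axes, floored at 0,
and group differences in these distances are tested with a one-way ANOVA F
and a permutation p obtained by shuffling the per-sample distances across
groups (the convention of vegan's permutest).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _permutations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    r2: float
    f: float
    p: float
    n_perm: int
    seed: int | None
    method: str = "permutation"  # or "exact"


@dataclass(frozen=True)
class DispersionResult:
    factor: str
    group_mean_dist: dict = field(compare=False)
    f: float = math.nan
    p: float = 1.0
    n_perm: int = 0
    seed: int | None = None


def validate_presence_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence/absence matrix entries must be 0 or 1")
    empty = values.sum(axis=1) == 0
    if empty.any():
        bad = list(matrix.index[empty])
        raise ValueError(f"all-zero sample rows rejected: {bad}")
    return matrix.astype(int)


def jaccard_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric Jaccard distance matrix over sample rows."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.to_numpy().astype(bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2).astype(float)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2).astype(float)
    empty = union == 0
    if empty.any():
        warnings.warn("sample pair(s) with empty union; distance set to 0")
        union[empty] = 1.0
        inter[empty] = 1.0
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _check_groups(labels: np.ndarray, allow_singleton: bool = False):
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if not allow_singleton:
        small = uniq[counts < 2]
        if small.size:
            raise ValueError(f"singleton group(s): {list(small)}")
    return uniq


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq) -> float:
    ss = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, uniq):
    n = labels.size
    a = len(uniq)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = _ss_within(d2, labels, uniq)
    ss_among = ss_total - ss_within
    r2 = ss_among / ss_total if ss_total > 0 else math.nan
    if ss_within == 0:
        f = math.inf if ss_among > 0 else math.nan
    else:
        f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return r2, f


def permanova(dist: pd.DataFrame, labels, n_perm: int = 999,
              seed: int | None = None, factor: str = "group",
              exact: bool = False) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    With ``exact=True`` (small n only) the p-value is computed over the
    full enumeration of distinct group assignments, identity included.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    if d.shape[0] != d.shape[1] or d.shape[0] != labels.size:
        raise ValueError("distance matrix and labels are inconsistent")
    uniq = _check_groups(labels)
    d2 = d ** 2
    r2, f_obs = _permanova_stats(d2, labels, uniq)
    if exact:
        if labels.size > 10:
            raise ValueError("exact enumeration is limited to n <= 10")
        assignments = set(_permutations(labels))
        exceed = sum(1 for perm in assignments
                     if _permanova_stats(d2, np.asarray(perm), uniq)[1] >= f_obs)
        return PermanovaResult(factor, r2, f_obs, exceed / len(assignments),
                               len(assignments), seed, method="exact")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_stats(d2, perm, uniq)[1] >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(factor, r2, f_obs, p, n_perm, seed)


def _pcoa_centroid_distances(d: np.ndarray, labels: np.ndarray, uniq) -> np.ndarray:
    """Per-sample distance to its group centroid in the PCoA embedding."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    keep = np.abs(eigval) > 1e-9 * max(1.0, np.abs(eigval).max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 0
    dist2 = np.zeros(n)
    for gname in uniq:
        idx = np.flatnonzero(labels == gname)
        cent = coords[idx].mean(axis=0)
        delta2 = (coords[idx] - cent) ** 2
        dist2[idx] = delta2[:, pos].sum(axis=1) - delta2[:, ~pos].sum(axis=1)
    return np.sqrt(np.clip(dist2, 0.0, None))


def _anova_f(values: np.ndarray, labels: np.ndarray, uniq) -> float:
    grand = values.mean()
    ss_between = ss_within = 0.0
    for g in uniq:
        v = values[labels == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df1, df2 = len(uniq) - 1, values.size - len(uniq)
    if ss_within == 0:
        return math.inf if ss_between > 0 else math.nan
    return (ss_between / df1) / (ss_within / df2)


def beta_dispersion(dist: pd.DataFrame, labels, n_perm: int = 999,
                    seed: int | None = None, factor: str = "group") -> DispersionResult:
    """Test homogeneity of multivariate dispersion across groups."""
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    if d.shape[0] != labels.size:
        raise ValueError("distance matrix and labels are inconsistent")
    uniq = _check_groups(labels)
    zdist = _pcoa_centroid_distances(d, labels, uniq)
    group_means = {str(g): float(zdist[labels == g].mean()) for g in uniq}
    f_obs = _anova_f(zdist, labels, uniq)
    if math.isnan(f_obs):  # degenerate: every point at its centroid
        return DispersionResult(factor, group_means, math.nan, 1.0, n_perm, seed)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm = _anova_f(rng.permutation(zdist), labels, uniq)
        if not math.isnan(f_perm) and f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return DispersionResult(factor, group_means, f_obs, p, n_perm, seed)
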