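"""Read-fraction quantification and between-group enrichment tests.

Per-sample counts of host+symbiont, bacterial and viral reads are
normalised by either the quality-controlled (QC) read count or the
host/symbiont-filtered read count and expressed in percent.  Extraction
groups (e.g. size-fractionation enrichment vs bulk control) are compared
with a two-sample Student's t-test using the pooled-variance form, whose
degrees of freedom are n1 + n2 - 2 (Welch's form is available behind a
flag), and fold enrichment is the ratio of group means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("host_symbiont", "bacterial", "viral")
_DENOMS = {"qc": "n_qc_reads", "filtered": "n_filtered_reads"}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    denominator: str
    group_a: str
    group_b: str
    mean_a: float  # percent
    se_a: float
    mean_b: float
    se_b: float
    fold: float
    t: float
    df: float
    p: float


def compute_fractions(counts: pd.DataFrame, denominator: str = "qc") -> pd.DataFrame:
    """Per-sample category fractions in percent.

    `counts` needs columns sample_id, group, n_qc_reads, n_filtered_reads,
    n_host_symbiont, n_bacterial, n_viral.  Samples with a zero denominator
    are excluded with a warning rather than failing the run.
    """
    if denominator not in _DENOMS:
        raise ValueError(f"denominator must be one of {sorted(_DENOMS)}")
    denom_col = _DENOMS[denominator]
    df = counts.sort_values("sample_id").reset_index(drop=True)
    zero = df[denom_col] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} sample(s) with zero "
                      f"{denom_col}: {', '.join(df.loc[zero, 'sample_id'])}")
        df = df[~zero].reset_index(drop=True)
    out = df[["sample_id", "group"]].copy()
    for cat in CATEGORIES:
        frac = df[f"n_{cat}"] / df[denom_col]
        if (frac > 1).any() or (frac < 0).any():
            raise ValueError(f"category n_{cat} exceeds denominator {denom_col}")
        out[cat] = 100.0 * frac
    return out


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Mean and standard error (sd/sqrt(n)) per group; SE is NaN for n=1."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)})
    if df.empty:
        raise ValueError("empty input")
    g = df.groupby("group", sort=True)["value"]
    out = g.agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, ["sd", "se"]] = np.nan
    out.loc[(out["n"] > 1) & (out["sd"] == 0), "se"] = 0.0
    return out[["group", "n", "mean", "se"]]


def fold_enrichment(mean_a: float, mean_b: float) -> float:
    if mean_b == 0:
        raise ZeroDivisionError("fold enrichment undefined for zero reference mean")
    return mean_a / mean_b


def pooled_t_test(x, y, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test; pooled variance unless welch=True.

    Degenerate zero-variance inputs: equal means give (t=0, p=1); unequal
    means give an infinite-t marker with p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    if welch:
        res = stats.ttest_ind(x, y, equal_var=False)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0)
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def compare_groups(counts: pd.DataFrame, group_a: str, group_b: str,
                   denominator: str = "qc", welch: bool = False) -> list[EnrichmentResult]:
    """Full group comparison table over all read categories."""
    fr = compute_fractions(counts, denominator)
    known = set(fr["group"])
    for g in (group_a, group_b):
        if g not in known:
            raise ValueError(f"unknown group label: {g}")
    results = []
    for cat in CATEGORIES:
        summ = group_summary(fr[cat], fr["group"]).set_index("group")
        a, b = summ.loc[group_a], summ.loc[group_b]
        tt = pooled_t_test(fr.loc[fr["group"] == group_a, cat],
                           fr.loc[fr["group"] == group_b, cat], welch=welch)
        fold = fold_enrichment(a["mean"], b["mean"]) if b["mean"] > 0 else math.nan
        results.append(EnrichmentResult(cat, denominator, group_a, group_b,
                                        a["mean"], a["se"], b["mean"], b["se"],
                                        fold, tt.t, tt.df, tt.p))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
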