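"""Phage gene-repertoire statistics.

Alignment hits against a curated symbiosis/virulence gene database are
filtered at e-value <= 1e-5, identity >= 40% and alignment length >= 20
amino acids, with overlapping hits on the same query resolved to the best
e-value.  Gene frequencies per habitat (count of distinct phages encoding
each gene) feed Simpson's index of diversity, Pielou's evenness, the
number of genes needed to reach a cumulative share threshold, and
shared/unique gene partitions between habitats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AlignmentHit:
    query_virus: str
    gene_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    query_interval: tuple[int, int]  # 0-based half-open, amino acids

    def __post_init__(self):
        if self.query_interval[0] >= self.query_interval[1]:
            raise ValueError(f"malformed query interval on {self.query_virus}")
        if self.alignment_length < 1 or self.evalue < 0:
            raise ValueError("invalid alignment hit")


def filter_symbiosis_hits(hits: list[AlignmentHit], max_evalue: float = 1e-5,
                          min_identity: float = 40.0,
                          min_length: int = 20) -> list[AlignmentHit]:
    """Threshold filter plus best-hit resolution of overlapping placements.

    Among surviving hits on the same query whose intervals overlap by >=1
    aa, only the best is kept: minimum e-value, ties broken by higher
    identity, longer alignment, then lexicographic gene id.  The result is
    independent of input row order.
    """
    surviving = [h for h in hits
                 if h.evalue <= max_evalue and h.percent_identity >= min_identity
                 and h.alignment_length >= min_length]
    surviving.sort(key=lambda h: (h.query_virus, h.evalue, -h.percent_identity,
                                  -h.alignment_length, h.gene_id,
                                  h.query_interval))
    kept: list[AlignmentHit] = []
    kept_by_query: dict[str, list[tuple[int, int]]] = {}
    for h in surviving:
        s, e = h.query_interval
        if any(s < ke and ks < e for ks, ke in kept_by_query.get(h.query_virus, [])):
            continue
        kept.append(h)
        kept_by_query.setdefault(h.query_virus, []).append((s, e))
    kept.sort(key=lambda h: (h.query_virus, h.query_interval))
    return kept


def tabulate_gene_frequencies(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-habitat gene frequencies: distinct viruses encoding each gene.

    `annotations` needs columns virus_id, gene_id, habitat (category and
    pathway are carried through when present).  A virus encoding a gene
    more than once counts once; proportions are normalised per habitat.
    """
    required = {"virus_id", "gene_id", "habitat"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    extras = [c for c in ("category", "pathway") if c in annotations.columns]
    counts = (annotations.groupby(["habitat", "gene_id"], sort=True)["virus_id"]
              .nunique().rename("count").reset_index())
    counts["proportion"] = counts["count"] / counts.groupby("habitat")["count"].transform("sum")
    if extras:
        meta = annotations[["gene_id", *extras]].drop_duplicates("gene_id")
        counts = counts.merge(meta, on="gene_id", how="left")
    return counts


def _as_props(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportion")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        if total <= 0:
            raise ValueError("proportions sum to zero")
        p = p / total  # accept raw counts
    return p


def simpson_diversity(freqs, bias_corrected: bool = False) -> float:
    """Simpson's index of diversity, D = 1 - sum(p_i^2).

    With ``bias_corrected=True``, `freqs` are interpreted as counts and the
    finite-sample estimator 1 - sum(n_i (n_i - 1)) / (N (N - 1)) is used.
    """
    if bias_corrected:
        n = np.asarray(freqs, dtype=float)
        if (n < 0).any():
            raise ValueError("negative count")
        total = n.sum()
        if total < 2:
            raise ValueError("bias-corrected Simpson needs N >= 2")
        return float(1.0 - (n * (n - 1)).sum() / (total * (total - 1)))
    p = _as_props(freqs)
    return float(1.0 - (p ** 2).sum())


def shannon_entropy(freqs) -> float:
    p = _as_props(freqs)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def pielou_evenness(freqs) -> float:
    """Pielou's evenness E = H' / ln(S); defined as 0 when S = 1."""
    p = _as_props(freqs)
    s = int((p > 0).sum())
    if s == 0:
        raise ValueError("no nonzero proportions")
    if s == 1:
        return 0.0
    return shannon_entropy(p) / np.log(s)


def genes_to_threshold(freqs, threshold: float = 0.80) -> int:
    """Smallest k such that the k most frequent genes reach the threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    p = np.sort(_as_props(freqs))[::-1]
    p = p[p > 0]
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def shared_unique(genes_a, genes_b) -> tuple[int, int, int]:
    """(unique to A, shared, unique to B) counts of two gene sets."""
    a, b = set(genes_a), set(genes_b)
    return len(a - b), len(a & b), len(b - a)


def habitat_summary(freq_table: pd.DataFrame, threshold: float = 0.80) -> pd.DataFrame:
    """Richness, Simpson D, Shannon H', Pielou E and k-at-threshold per habitat."""
    rows = []
    for habitat, sub in freq_table.groupby("habitat", sort=True):
        p = sub["proportion"].to_numpy()
        rows.append({"habitat": habitat, "S": int((p > 0).sum()),
                     "simpson_D": simpson_diversity(p),
                     "shannon_H": shannon_entropy(p),
                     "pielou_E": pielou_evenness(p),
                     "k_at_threshold": genes_to_threshold(p, threshold)})
    return pd.DataFrame(rows)
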