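"""Provirus detection by exact embedding of viral genomes in host contigs.

A provirus call requires a gap-free, substitution-free occurrence of the
viral sequence (by default the whole virus, ``min_embed_frac=1.0``) inside
a bacterial contig, with host sequence flanking at least one side.  Host
genomes (bins) are pre-filtered on assembly quality: >=50% completeness and
<=10% contamination, boundaries inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from ._align import revcomp
from .crispr import HostLink


@dataclass(frozen=True)
class BinQuality:
    host_id: str
    completeness: float  # percent, 0-100
    contamination: float  # percent, >= 0

    def __post_init__(self):
        if not (0 <= self.completeness <= 100):
            raise ValueError(f"{self.host_id}: completeness outside [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"{self.host_id}: negative contamination")


@dataclass(frozen=True)
class EmbeddingMatch:
    virus_id: str
    host_contig: str
    host_interval: tuple[int, int]
    strand: str
    matched_len: int


@dataclass(frozen=True)
class ProvirusCall:
    embedding: EmbeddingMatch
    left_flank: int
    right_flank: int
    is_provirus: bool


def filter_host_bins(qualities: list[BinQuality], min_completeness: float = 50,
                     max_contamination: float = 10) -> list[str]:
    ids = [q.host_id for q in qualities]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate host ids in bin quality table")
    return [q.host_id for q in qualities
            if q.completeness >= min_completeness and q.contamination <= max_contamination]


def _exact_occurrences(needle: str, haystack: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _partial_embeddings(virus: str, host: str, min_len: int, seed_k: int):
    """Maximal exact shared segments >= min_len via seed-and-extend."""
    found = set()
    for q0 in range(0, max(1, len(virus) - seed_k + 1), seed_k):
        seed = virus[q0 : q0 + seed_k]
        if len(seed) < seed_k:
            break
        for h0 in _exact_occurrences(seed, host):
            # extend left
            qa, ha = q0, h0
            while qa > 0 and ha > 0 and virus[qa - 1] == host[ha - 1]:
                qa -= 1
                ha -= 1
            # extend right
            qb, hb = q0 + seed_k, h0 + seed_k
            while qb < len(virus) and hb < len(host) and virus[qb] == host[hb]:
                qb += 1
                hb += 1
            if qb - qa >= min_len:
                found.add((ha, hb))
    return sorted(found)


def find_exact_embeddings(virus_id: str, virus_seq: str, contig_id: str,
                          contig_seq: str, min_embed_frac: float = 1.0,
                          seed_k: int = 21) -> list[EmbeddingMatch]:
    """Every exact occurrence of the virus (or a long segment) in the contig.

    Both strands are searched.  At ``min_embed_frac=1.0`` this is a
    whole-virus exact substring search; below 1.0, any contiguous virus
    segment of at least ``min_embed_frac * len(virus)`` bases qualifies.
    """
    if not virus_seq or not contig_seq:
        raise ValueError("empty sequence")
    virus_seq, contig_seq = virus_seq.upper(), contig_seq.upper()
    vlen = len(virus_seq)
    min_len = max(1, math.ceil(min_embed_frac * vlen))
    out = []
    for strand, v in (("+", virus_seq), ("-", revcomp(virus_seq))):
        if min_len >= vlen:
            spans = [(i, i + vlen) for i in _exact_occurrences(v, contig_seq)]
        else:
            spans = _partial_embeddings(v, contig_seq, min_len, seed_k)
        for s, e in spans:
            out.append(EmbeddingMatch(virus_id, contig_id, (s, e), strand, e - s))
    out.sort(key=lambda m: (m.host_interval, m.strand))
    return out


def call_provirus(embedding: EmbeddingMatch, contig_length: int,
                  min_flank: int = 500) -> ProvirusCall:
    s, e = embedding.host_interval
    if not (0 <= s <= e <= contig_length):
        raise ValueError("embedding interval outside contig")
    left, right = s, contig_length - e
    return ProvirusCall(embedding, left, right, max(left, right) >= min_flank)


def link_hosts_by_provirus(viruses: dict[str, str], host_contigs: dict[str, str],
                           bin_membership: dict[str, str] | None = None,
                           min_flank: int = 500, min_embed_frac: float = 1.0,
                           seed_k: int = 21) -> list[HostLink]:
    """One provirus link per distinct (virus, host) pair, deterministic order."""
    bin_membership = bin_membership or {}
    best: dict[tuple[str, str], ProvirusCall] = {}
    for contig_id, contig_seq in host_contigs.items():
        host = bin_membership.get(contig_id)
        if host is None:
            if bin_membership:
                warnings.warn(f"contig {contig_id} has no bin membership; "
                              "treating it as its own host")
            host = contig_id
        for vid, vseq in viruses.items():
            if math.ceil(min_embed_frac * len(vseq)) > len(contig_seq):
                continue
            for emb in find_exact_embeddings(vid, vseq, contig_id, contig_seq,
                                             min_embed_frac, seed_k):
                call = call_provirus(emb, len(contig_seq), min_flank)
                if call.is_provirus and (vid, host) not in best:
                    best[(vid, host)] = call
    return [HostLink(vid, host, "provirus", best[(vid, host)])
            for vid, host in sorted(best)]
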