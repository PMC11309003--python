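"""CRISPR array detection, spacer extraction and spacer-to-virus matching.

Virus-host links are called when a spacer carried by a bacterial contig
aligns to a viral genome under stringent thresholds: the alignment must
cover the entire spacer (semi-global with free ends on the virus only),
total edits (substitutions + gaps) must not exceed ``max_edits`` (default
2), and the spacer must be at least 20 nt long.  Both strands of the virus
are searched.  Array detection follows the CRT family of tools: at least
three repeat copies of 19-38 bp separated by spacers of 19-48 bp, repeat
copies identical by default (a per-copy mismatch allowance is exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import leftmost_start, revcomp, semiglobal_end_scores

SEED_LEN = 19  # minimum repeat length doubles as the exact-seed width


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    host_contig: str
    sequence: str
    interval: tuple[int, int]  # 0-based half-open on the host contig

    def __post_init__(self):
        if len(self.sequence) != self.interval[1] - self.interval[0]:
            raise ValueError("spacer sequence length differs from its interval")


@dataclass
class CrisprArray:
    host_contig: str
    repeat_consensus: str
    repeat_positions: list[tuple[int, int]]
    spacers: list[Spacer]

    def __post_init__(self):
        if len(self.repeat_positions) != len(self.spacers) + 1:
            raise ValueError("an array with r spacers must have r+1 repeat copies")


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    virus_id: str
    strand: str  # '+' or '-'
    virus_interval: tuple[int, int]  # forward-strand coordinates
    edit_distance: int


@dataclass(frozen=True)
class HostLink:
    virus_id: str
    host_id: str
    evidence: str  # 'crispr' | 'provirus'
    detail: object = field(compare=False, default=None)


@dataclass
class CrisprParams:
    min_repeats: int = 3
    repeat_len_range: tuple[int, int] = (19, 38)
    spacer_len_range: tuple[int, int] = (19, 48)
    max_repeat_mismatch: int = 0  # per copy, vs the first copy
    max_ambiguous_frac: float = 0.1


def detect_crispr_arrays(contig_id: str, sequence: str,
                         params: CrisprParams | None = None) -> list[CrisprArray]:
    """Detect CRISPR arrays on the forward strand of one contig.

    Seed-and-chain scan: exact 19-mer seeds are chained when consecutive
    occurrences are separated by a plausible repeat+spacer period; the
    repeat is then extended to its maximal common length and the chain is
    validated against the repeat/spacer length windows and the minimum copy
    number.
    """
    params = params or CrisprParams()
    seq = sequence.upper()
    n = len(seq)
    non_acgt = sum(1 for c in seq if c not in "ACGT")
    if n and non_acgt / n > params.max_ambiguous_frac:
        raise ValueError(f"contig {contig_id}: too many non-ACGT characters "
                         f"({non_acgt}/{n})")
    rep_lo, rep_hi = params.repeat_len_range
    sp_lo, sp_hi = params.spacer_len_range
    k = SEED_LEN
    if n < params.min_repeats * rep_lo + (params.min_repeats - 1) * sp_lo:
        return []

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    gap_lo, gap_hi = k + sp_lo, rep_hi + sp_hi
    candidates: list[tuple[int, list[int], int]] = []  # (start, chain, rep_len)

    for i in range(n - k + 1):
        positions = index.get(seq[i : i + k], [])
        if len(positions) < 2:
            continue
        # chain greedily: nearest next occurrence within the period window
        chain = [i]
        while True:
            nxt = [p for p in positions
                   if gap_lo <= p - chain[-1] <= gap_hi]
            if not nxt:
                break
            chain.append(min(nxt))
        if len(chain) < params.min_repeats:
            continue
        gaps = [b - a for a, b in zip(chain, chain[1:])]
        # extend the repeat to its maximal shared length
        cap = min(rep_hi, min(gaps) - sp_lo, n - chain[-1])
        rep_len = k
        mismatches = [0] * len(chain)
        for ext in range(k, cap):
            ref = seq[chain[0] + ext]
            ok = True
            trial = list(mismatches)
            for ci, p in enumerate(chain[1:], start=1):
                if seq[p + ext] != ref:
                    trial[ci] += 1
                    if trial[ci] > params.max_repeat_mismatch:
                        ok = False
                        break
            if not ok:
                break
            mismatches = trial
            rep_len = ext + 1
        if not (rep_lo <= rep_len <= rep_hi):
            continue
        # trim the chain to the longest prefix with valid spacer lengths
        valid = [chain[0]]
        for a, b in zip(chain, chain[1:]):
            if sp_lo <= (b - a) - rep_len <= sp_hi:
                valid.append(b)
            else:
                break
        if len(valid) < params.min_repeats:
            continue
        candidates.append((valid[0], valid, rep_len))

    # Competing candidates (shifted seeds, chance partial chains) are
    # resolved by keeping maximal arrays: most repeat copies first, then
    # longest span, then leftmost; overlapping losers are discarded.
    candidates.sort(key=lambda c: (-len(c[1]), -(c[1][-1] + c[2] - c[0]), c[0]))
    arrays: list[CrisprArray] = []
    taken: list[tuple[int, int]] = []
    for start, chain, rep_len in candidates:
        end = chain[-1] + rep_len
        if any(start < te and ts < end for ts, te in taken):
            continue
        spacers = []
        for ordinal, (a, b) in enumerate(zip(chain, chain[1:])):
            s, e = a + rep_len, b
            spacers.append(Spacer(
                spacer_id=f"{contig_id}|arr{len(arrays)}|sp{ordinal}",
                host_contig=contig_id, sequence=seq[s:e], interval=(s, e)))
        arrays.append(CrisprArray(contig_id, seq[start : start + rep_len],
                                  [(p, p + rep_len) for p in chain], spacers))
        taken.append((start, end))
    arrays.sort(key=lambda a: a.repeat_positions[0])
    return arrays


def extract_spacers(arrays: list[CrisprArray]) -> list[Spacer]:
    """Flatten arrays to spacers in genomic order; ids are already stable."""
    out = []
    for arr in arrays:
        out.extend(arr.spacers)
    return out


def _collapse(candidates: list[tuple[int, int, int, str]]) -> list[tuple[int, int, int, str]]:
    """Collapse overlapping placements to the minimum-edit one.

    Candidates are (start, end, dist, strand) in forward virus coordinates.
    Overlap clusters are formed transitively; within a cluster the winner is
    minimum edit distance, ties broken by leftmost start, then '+' strand.
    """
    if not candidates:
        return []
    candidates = sorted(candidates)
    clusters: list[list[tuple[int, int, int, str]]] = [[candidates[0]]]
    cluster_end = candidates[0][1]
    for c in candidates[1:]:
        if c[0] < cluster_end:  # overlaps the running cluster
            clusters[-1].append(c)
            cluster_end = max(cluster_end, c[1])
        else:
            clusters.append([c])
            cluster_end = c[1]
    kept = []
    for cl in clusters:
        kept.append(min(cl, key=lambda c: (c[2], c[0], 0 if c[3] == "+" else 1)))
    return kept


def match_spacer(spacer: Spacer | str, virus_id: str, virus_seq: str,
                 max_edits: int = 2, min_spacer_len: int = 20) -> list[SpacerMatch]:
    """All non-redundant placements of a spacer on a virus, both strands.

    A placement qualifies when a semi-global alignment consuming the entire
    spacer has at most ``max_edits`` total edits.  Spacers shorter than
    ``min_spacer_len`` never match.  Overlapping placements (either strand)
    collapse to the minimum-edit one.
    """
    if isinstance(spacer, Spacer):
        seq, sid = spacer.sequence, spacer.spacer_id
    else:
        seq, sid = spacer, "spacer"
    if len(seq) < min_spacer_len:
        return []
    n = len(virus_seq)
    candidates = []
    for strand, target in (("+", virus_seq), ("-", revcomp(virus_seq))):
        row = semiglobal_end_scores(seq, target)
        for j in (row <= max_edits).nonzero()[0]:
            j = int(j)
            d = int(row[j])
            s = leftmost_start(seq, target, j, d)
            if strand == "+":
                candidates.append((s, j, d, "+"))
            else:
                candidates.append((n - j, n - s, d, "-"))
    return [SpacerMatch(sid, virus_id, strand, (s, e), d)
            for s, e, d, strand in _collapse(candidates)]


def link_hosts_by_crispr(spacers: list[Spacer], viruses: dict[str, str],
                         host_of: dict[str, str] | None = None,
                         max_edits: int = 2, min_spacer_len: int = 20) -> list[HostLink]:
    """One link per distinct (virus, host) pair with a qualifying spacer match.

    The retained detail is the best supporting match: minimum edit distance,
    then longest spacer.  ``host_of`` maps contigs to host (bin) ids;
    contigs without a mapping stand for themselves.
    """
    host_of = host_of or {}
    best: dict[tuple[str, str], tuple[int, int, SpacerMatch]] = {}
    for sp in spacers:
        host = host_of.get(sp.host_contig, sp.host_contig)
        for vid, vseq in viruses.items():
            for m in match_spacer(sp, vid, vseq, max_edits, min_spacer_len):
                key = (vid, host)
                rank = (m.edit_distance, -len(sp.sequence))
                if key not in best or rank < best[key][:2]:
                    best[key] = (*rank, m)
    return [HostLink(vid, host, "crispr", best[(vid, host)][2])
            for vid, host in sorted(best)]
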