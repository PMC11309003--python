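"""Synthetic holobiont datasets with planted ground truth.

Every downstream stage of the pipeline is testable without downloads: the
generator emits viral genomes, bacterial contigs carrying CRISPR arrays
whose spacers copy viral windows at controlled edit distances, exact
provirus insertions with host flanks, gene annotations drawn from a skewed
("coral-like") or even ("seawater-like") frequency profile, group-
structured read fractions, and group-structured presence/absence matrices.
All placements are recorded in a :class:`PlantedTruth` ledger that tests
re-verify independently.

Defaults mirror the study conditions the statistics are meant to
reproduce: extraction groups of 19 (enriched) and 6 (control) samples;
bacterial QC-read fraction means of 2.72% vs 0.30%, viral 0.74% vs 0.40%,
host+symbiont 36.39% vs 69.83%, with spreads back-derived from the
reported standard errors; and a coral-like gene profile whose four
dominant genes carry 60.35%, 14.32%, 3.29% and 1.57% of the mass.
Sequences are i.i.d. uniform ACGT, which avoids spurious repeat
detections.  Each generator stage draws from its own RNG stream seeded
from ``SynthConfig.seed`` plus a fixed offset, so stages are reproducible
when re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import levenshtein, revcomp, semiglobal_end_scores

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stage offsets for per-generator RNG streams
_STREAMS = {"viruses": 1, "arrays": 2, "provirus": 3, "genes": 4,
            "fractions": 5, "presence": 6}


@dataclass(frozen=True)
class GeneDef:
    gene_id: str
    category: str  # 'metabolic' | 'symbiosis'
    pathway: str


# A compact gene pool modelled on genes recurrent in coral/seawater phage
# annotations: DNA methyltransferases, formaldehyde/sulfur metabolism,
# queuosine biosynthesis, quorum sensing; ankyrin-motif and secretion-
# system symbiosis genes.
DEFAULT_GENE_POOL: tuple[GeneDef, ...] = (
    GeneDef("DNMT1_dcm", "metabolic", "DNA methylation"),
    GeneDef("DNMT3A", "metabolic", "DNA methylation"),
    GeneDef("frmA_ADH5_adhC", "metabolic", "Formaldehyde metabolism"),
    GeneDef("NAMPT", "metabolic", "Cofactors and vitamins"),
    GeneDef("cysH", "metabolic", "Sulfur metabolism"),
    GeneDef("mec", "metabolic", "Sulfur metabolism"),
    GeneDef("queD", "metabolic", "Queuosine biosynthesis"),
    GeneDef("queE", "metabolic", "Queuosine biosynthesis"),
    GeneDef("folE_GCH1", "metabolic", "Queuosine biosynthesis"),
    GeneDef("raiI", "metabolic", "Quorum sensing"),
    GeneDef("bjaR1", "metabolic", "Quorum sensing"),
    GeneDef("gcrA", "metabolic", "Cell cycle regulation"),
    GeneDef("ankY_legA9", "symbiosis", "Ankyrin repeat"),
    GeneDef("pipB2", "symbiosis", "Effector delivery"),
    GeneDef("icmE_dotG", "symbiosis", "Effector delivery"),
    GeneDef("csgG", "symbiosis", "Adherence"),
    GeneDef("zot", "symbiosis", "Exotoxin"),
    GeneDef("cylR2", "symbiosis", "Exotoxin"),
)

# Dominant-gene shares of the coral-like profile; the remaining mass is
# spread evenly over the rest of the pool.
_CORAL_TOP = {"DNMT1_dcm": 0.6035, "DNMT3A": 0.1432,
              "frmA_ADH5_adhC": 0.0329, "NAMPT": 0.0157}


@dataclass(frozen=True)
class FractionSpec:
    """Mean and standard deviation of a per-sample read fraction (0-1)."""
    mean: float
    sd: float

    def __post_init__(self):
        if not (0 < self.mean < 1):
            raise ValueError(f"fraction mean must be in (0, 1), got {self.mean}")
        if self.sd < 0 or self.sd ** 2 >= self.mean * (1 - self.mean):
            raise ValueError("sd incompatible with a Beta distribution")


def _default_group_fractions() -> dict:
    # means from the reported group summaries; sd = SE * sqrt(n)
    return {
        "VBE": {"host_symbiont": FractionSpec(0.3639, 0.0010 * np.sqrt(19)),
                "bacterial": FractionSpec(0.0272, 0.0033 * np.sqrt(19)),
                "viral": FractionSpec(0.0074, 0.0005 * np.sqrt(19))},
        "Control": {"host_symbiont": FractionSpec(0.6983, 0.0013 * np.sqrt(6)),
                    "bacterial": FractionSpec(0.0030, 0.0003 * np.sqrt(6)),
                    "viral": FractionSpec(0.0040, 0.0005 * np.sqrt(6))},
    }


@dataclass
class SynthConfig:
    seed: int = 0
    # sequences
    n_viruses: int = 12
    virus_len_range: tuple[int, int] = (5000, 8000)
    n_host_contigs: int = 10
    host_len_range: tuple[int, int] = (20000, 30000)
    # CRISPR arrays
    repeat_len: int = 28
    spacer_len_range: tuple[int, int] = (20, 48)
    spacers_per_array: tuple[int, int] = (3, 8)
    spacer_edit_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.4, 1: 0.3, 2: 0.3})
    # proviruses
    provirus_fraction: float = 0.5
    min_flank_planted: int = 1000
    # genes
    gene_pool: tuple[GeneDef, ...] = DEFAULT_GENE_POOL
    gene_freq_profile: str = "coral"  # 'coral' (skewed) | 'seawater' (even)
    genes_per_virus: tuple[int, int] = (0, 4)
    habitat: str | None = None  # defaults to the profile name
    # read fractions
    group_fractions: dict = field(default_factory=_default_group_fractions)
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"VBE": 19, "Control": 6})
    read_depth: int = 1_000_000
    # presence/absence matrix
    n_taxa: int = 120
    presence_groups: dict[str, int] = field(
        default_factory=lambda: {"regionA": 8, "regionB": 8})
    signal_fraction: float = 0.4
    signal_presence: float = 1.0
    background_rate: float = 0.25

    def __post_init__(self):
        for name, (lo, hi) in (("virus_len_range", self.virus_len_range),
                               ("host_len_range", self.host_len_range),
                               ("spacer_len_range", self.spacer_len_range),
                               ("spacers_per_array", self.spacers_per_array),
                               ("genes_per_virus", self.genes_per_virus)):
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if self.spacer_len_range[0] < 20:
            raise ValueError("spacer_len_range lower bound must be >= 20 so "
                             "planted positives pass the matcher length filter")
        probs = np.array(list(self.spacer_edit_distribution.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("spacer_edit_distribution must sum to 1")
        if any(k not in (0, 1, 2, 3) for k in self.spacer_edit_distribution):
            raise ValueError("spacer edit counts must be in {0, 1, 2, 3}")
        if not (0 <= self.provirus_fraction <= 1):
            raise ValueError("provirus_fraction must be in [0, 1]")
        if self.gene_freq_profile not in ("coral", "seawater"):
            raise ValueError("gene_freq_profile must be 'coral' or 'seawater'")
        for frac in (self.signal_fraction, self.signal_presence, self.background_rate):
            if not (0 <= frac <= 1):
                raise ValueError("presence-matrix rates must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def profile_vector(self) -> np.ndarray:
        """Gene-sampling probabilities over ``gene_pool``."""
        ids = [g.gene_id for g in self.gene_pool]
        if self.gene_freq_profile == "seawater":
            return np.full(len(ids), 1.0 / len(ids))
        p = np.zeros(len(ids))
        top_mass = 0.0
        for i, gid in enumerate(ids):
            if gid in _CORAL_TOP:
                p[i] = _CORAL_TOP[gid]
                top_mass += _CORAL_TOP[gid]
        rest = [i for i in range(len(ids)) if p[i] == 0]
        if rest:
            p[rest] = (1.0 - top_mass) / len(rest)
        else:
            p /= p.sum()
        return p


@dataclass(frozen=True)
class SpacerLink:
    host_contig: str
    spacer_id: str
    virus_id: str
    strand: str
    virus_window: tuple[int, int]
    planted_edits: int
    spacer_seq: str = ""  # the planted (edited) spacer, for re-verification


@dataclass(frozen=True)
class ProvirusPlacement:
    host_contig: str
    virus_id: str
    start: int
    end: int
    left_flank: int
    right_flank: int


@dataclass
class PlantedTruth:
    """Ledger of everything the generator planted; the test oracle."""
    spacer_links: list[SpacerLink] = field(default_factory=list)
    provirus_placements: list[ProvirusPlacement] = field(default_factory=list)
    gene_assignments: list[tuple[str, str]] = field(default_factory=list)
    sample_fractions: pd.DataFrame | None = None
    # generator bookkeeping: planted array spans per host contig, so later
    # insertions never split an array
    array_intervals: dict = field(default_factory=dict)

    def merge(self, other: "PlantedTruth") -> "PlantedTruth":
        merged_intervals = {**self.array_intervals}
        for contig, spans in other.array_intervals.items():
            merged_intervals.setdefault(contig, []).extend(spans)
        return PlantedTruth(
            self.spacer_links + other.spacer_links,
            self.provirus_placements + other.provirus_placements,
            self.gene_assignments + other.gene_assignments,
            other.sample_fractions if other.sample_fractions is not None
            else self.sample_fractions,
            merged_intervals)

    def expected_crispr_pairs(self, max_edits: int = 2) -> set[tuple[str, str]]:
        return {(l.virus_id, l.host_contig) for l in self.spacer_links
                if l.planted_edits <= max_edits}

    def expected_provirus_pairs(self) -> set[tuple[str, str]]:
        return {(p.virus_id, p.host_contig) for p in self.provirus_placements}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def synth_viral_genomes(config: SynthConfig) -> dict[str, str]:
    """n_viruses i.i.d. uniform-base genomes; deterministic given the seed."""
    if config.n_viruses < 1:
        raise ValueError("n_viruses must be >= 1")
    rng = config.rng("viruses")
    lo, hi = config.virus_len_range
    out = {}
    for i in range(config.n_viruses):
        length = int(rng.integers(lo, hi + 1))
        out[f"virus_{i:04d}"] = _random_seq(rng, length)
    return out


def _apply_edits(rng: np.random.Generator, seq: str, k: int) -> str:
    """Apply exactly k random unit edits: substitutions and single-base
    indels, equally likely, at uniformly random positions."""
    s = list(seq)
    for _ in range(k):
        op = rng.integers(0, 3)
        if op == 0 and s:  # substitution
            pos = int(rng.integers(0, len(s)))
            old = s[pos]
            choices = [b for b in "ACGT" if b != old]
            s[pos] = choices[int(rng.integers(0, 3))]
        elif op == 1:  # insertion
            pos = int(rng.integers(0, len(s) + 1))
            s.insert(pos, "ACGT"[int(rng.integers(0, 4))])
        elif s:  # deletion
            pos = int(rng.integers(0, len(s)))
            del s[pos]
    return "".join(s)


def _plant_spacer(rng: np.random.Generator, viruses: dict[str, str],
                  config: SynthConfig, k: int, max_tries: int = 200):
    """Draw a spacer copying a viral window with exactly k realised edits.

    Realised means the minimum semi-global edit distance of the spacer
    against the *whole* target virus (either strand) equals k, and the
    distance to every other virus stays above the matcher's reach, so the
    planted ledger maps one-to-one onto detectable links.
    """
    vids = sorted(viruses)
    lo, hi = config.spacer_len_range
    for _ in range(max_tries):
        vid = vids[int(rng.integers(0, len(vids)))]
        vseq = viruses[vid]
        wlen = int(rng.integers(lo + k, hi - k + 1))
        if wlen > len(vseq):
            raise ValueError(f"spacer window ({wlen} bp) longer than virus {vid}")
        ws = int(rng.integers(0, len(vseq) - wlen + 1))
        window = vseq[ws : ws + wlen]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        base = window if strand == "+" else revcomp(window)
        spacer = _apply_edits(rng, base, k)
        if not (lo <= len(spacer) <= hi):
            continue
        if levenshtein(spacer, base) != k:
            continue
        realised = min(int(semiglobal_end_scores(spacer, vseq).min()),
                       int(semiglobal_end_scores(spacer, revcomp(vseq)).min()))
        if realised != k:
            continue
        cross = min((min(int(semiglobal_end_scores(spacer, viruses[o]).min()),
                         int(semiglobal_end_scores(spacer, revcomp(viruses[o])).min()))
                     for o in vids if o != vid), default=99)
        if cross <= 3:
            continue
        return spacer, vid, strand, (ws, ws + wlen)
    raise RuntimeError("could not plant a spacer with the requested edit count")


def synth_hosts_with_arrays(config: SynthConfig,
                            viruses: dict[str, str]) -> tuple[dict[str, str], PlantedTruth]:
    """Host contigs, each carrying one CRISPR array targeting the viruses.

    Arrays alternate repeat and spacer (r spacers => r+1 repeat copies);
    each spacer copies a random virus window (either strand) with exactly k
    planted edits, k drawn from ``spacer_edit_distribution``.
    """
    if not viruses:
        raise ValueError("viruses must be nonempty")
    rng = config.rng("arrays")
    edits = sorted(config.spacer_edit_distribution)
    probs = np.array([config.spacer_edit_distribution[e] for e in edits])
    hosts = {}
    truth = PlantedTruth()
    lo, hi = config.host_len_range
    for h in range(config.n_host_contigs):
        contig_id = f"host_{h:04d}"
        background = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        repeat = _random_seq(rng, config.repeat_len)
        n_spacers = int(rng.integers(config.spacers_per_array[0],
                                     config.spacers_per_array[1] + 1))
        parts = [repeat]
        links = []
        for s in range(n_spacers):
            k = int(edits[int(rng.choice(len(edits), p=probs))])
            spacer, vid, strand, window = _plant_spacer(rng, viruses, config, k)
            # guard against chance repeat-boundary extension in detection:
            # spacer first/last characters must not all coincide
            if s == n_spacers - 1 and n_spacers > 1:
                tries = 0
                while (len({l[1][0] for l in links} | {spacer[0]}) == 1
                       or len({l[1][-1] for l in links} | {spacer[-1]}) == 1):
                    spacer, vid, strand, window = _plant_spacer(rng, viruses, config, k)
                    tries += 1
                    if tries > 50:
                        raise RuntimeError("could not diversify spacer boundaries")
            parts.append(spacer)
            parts.append(repeat)
            links.append((f"{contig_id}|planted_sp{s}", spacer, vid, strand, window, k))
        array = "".join(parts)
        pos = int(rng.integers(0, len(background) - len(array) + 1))
        hosts[contig_id] = background[:pos] + array + background[pos + len(array):]
        truth.array_intervals[contig_id] = [(pos, pos + len(array))]
        for sid, sp_seq, vid, strand, window, k in links:
            truth.spacer_links.append(
                SpacerLink(contig_id, sid, vid, strand, window, k, sp_seq))
    return hosts, truth


def synth_provirus_insertions(config: SynthConfig, viruses: dict[str, str],
                              hosts: dict[str, str],
                              avoid_intervals: dict | None = None
                              ) -> tuple[dict[str, str], PlantedTruth]:
    """Insert whole, unmodified viral genomes into a fraction of hosts.

    Each insertion leaves at least ``min_flank_planted`` bp of host
    sequence on both sides; coordinates and flank lengths are recorded.
    ``avoid_intervals`` (host contig -> list of spans, e.g. planted CRISPR
    arrays) keeps the insertion point outside those spans so earlier
    plantings stay intact.
    """
    rng = config.rng("provirus")
    avoid_intervals = avoid_intervals or {}
    truth = PlantedTruth()
    out = dict(hosts)
    host_ids = sorted(hosts)
    n_insert = int(round(config.provirus_fraction * len(host_ids)))
    chosen = [host_ids[i] for i in sorted(rng.permutation(len(host_ids))[:n_insert])]
    vids = sorted(viruses)
    for contig_id in chosen:
        hseq = out[contig_id]
        fitting = [v for v in vids
                   if len(hseq) >= len(viruses[v]) + 2 * config.min_flank_planted]
        if not fitting:
            raise RuntimeError(
                f"no virus short enough to insert into {contig_id} with "
                f"{config.min_flank_planted} bp flanks")
        vid = fitting[int(rng.integers(0, len(fitting)))]
        vseq = viruses[vid]
        avoid = avoid_intervals.get(contig_id, [])
        for _ in range(200):
            pos = int(rng.integers(config.min_flank_planted,
                                   len(hseq) - len(vseq) - config.min_flank_planted + 1))
            if not any(s < pos < e for s, e in avoid):
                break
        else:
            raise RuntimeError(f"no insertion point outside avoided spans in {contig_id}")
        out[contig_id] = hseq[:pos] + vseq + hseq[pos:]
        truth.provirus_placements.append(ProvirusPlacement(
            contig_id, vid, pos, pos + len(vseq), pos,
            len(out[contig_id]) - (pos + len(vseq))))
    return out, truth


def synth_gene_annotations(config: SynthConfig,
                           viruses: dict[str, str]) -> tuple[pd.DataFrame, PlantedTruth]:
    """Assign 0..m genes per virus by sampling the frequency profile."""
    rng = config.rng("genes")
    profile = config.profile_vector()
    pool = list(config.gene_pool)
    habitat = config.habitat or config.gene_freq_profile
    truth = PlantedTruth()
    rows = []
    for vid in sorted(viruses):
        m = int(rng.integers(config.genes_per_virus[0],
                             config.genes_per_virus[1] + 1))
        picked = sorted({int(i) for i in rng.choice(len(pool), size=m, p=profile)}) if m else []
        for gi in picked:
            g = pool[gi]
            rows.append({"virus_id": vid, "gene_id": g.gene_id,
                         "category": g.category, "pathway": g.pathway,
                         "habitat": habitat})
            truth.gene_assignments.append((vid, g.gene_id))
    columns = ["virus_id", "gene_id", "category", "pathway", "habitat"]
    return pd.DataFrame(rows, columns=columns), truth


def _beta_draw(rng: np.random.Generator, spec: FractionSpec, size: int) -> np.ndarray:
    if spec.sd == 0:
        return np.full(size, spec.mean)
    nu = spec.mean * (1 - spec.mean) / spec.sd ** 2 - 1
    return rng.beta(spec.mean * nu, (1 - spec.mean) * nu, size=size)


def synth_read_fractions(config: SynthConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Per-sample read-classification counts at a fixed depth.

    Fractions are Beta-distributed around the configured group means;
    integer counts derive from fraction x depth.  The filtered-read count
    is depth minus the host+symbiont count, so filtered-denominator
    fractions are emergent rather than separately configured.
    """
    rng = config.rng("fractions")
    rows = []
    true_rows = []
    depth = config.read_depth
    for group in sorted(config.n_samples_per_group):
        n = config.n_samples_per_group[group]
        specs = config.group_fractions[group]
        draws = {cat: _beta_draw(rng, spec, n) for cat, spec in sorted(specs.items())}
        for i in range(n):
            sample = f"{group}_{i:03d}"
            h = float(draws["host_symbiont"][i])
            b = float(draws["bacterial"][i])
            v = float(draws["viral"][i])
            n_host = int(round(h * depth))
            rows.append({"sample_id": sample, "group": group,
                         "n_qc_reads": depth,
                         "n_filtered_reads": depth - n_host,
                         "n_host_symbiont": n_host,
                         "n_bacterial": int(round(b * depth)),
                         "n_viral": int(round(v * depth))})
            true_rows.append({"sample_id": sample, "group": group,
                              "host_symbiont": h, "bacterial": b, "viral": v})
    counts = pd.DataFrame(rows)
    truth = PlantedTruth(sample_fractions=pd.DataFrame(true_rows))
    return counts, truth


def synth_presence_matrix(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-structured samples x taxa binary matrix plus metadata.

    A ``signal_fraction`` of taxa are group-specific (present in their
    group's samples with probability ``signal_presence``, absent
    elsewhere); the rest occur everywhere at ``background_rate``.
    """
    if config.n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    groups = sorted(config.presence_groups)
    if len(groups) < 2 or any(config.presence_groups[g] < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    rng = config.rng("presence")
    n_signal = int(round(config.signal_fraction * config.n_taxa))
    taxon_group = {}  # taxon index -> owning group (signal taxa only)
    for t in range(n_signal):
        taxon_group[t] = groups[t % len(groups)]
    samples, labels = [], []
    data = []
    for g in groups:
        for i in range(config.presence_groups[g]):
            row = np.zeros(config.n_taxa, dtype=int)
            for t in range(config.n_taxa):
                if t in taxon_group:
                    if taxon_group[t] == g and rng.random() < config.signal_presence:
                        row[t] = 1
                elif rng.random() < config.background_rate:
                    row[t] = 1
            if row.sum() == 0:  # keep the matrix loadable: no empty samples
                row[int(rng.integers(0, config.n_taxa))] = 1
            samples.append(f"{g}_s{i:02d}")
            labels.append(g)
            data.append(row)
    matrix = pd.DataFrame(data, index=samples,
                          columns=[f"taxon_{t:04d}" for t in range(config.n_taxa)])
    meta = pd.DataFrame({"sample_id": samples, "group": labels})
    return matrix, meta


@dataclass
class SyntheticDataset:
    config: SynthConfig
    viruses: dict[str, str]
    hosts: dict[str, str]
    annotations: pd.DataFrame
    read_counts: pd.DataFrame
    presence: pd.DataFrame
    presence_meta: pd.DataFrame
    truth: PlantedTruth


def generate_all(config: SynthConfig) -> SyntheticDataset:
    """Run every generator stage in order and merge the truth ledgers."""
    viruses = synth_viral_genomes(config)
    hosts, truth = synth_hosts_with_arrays(config, viruses)
    hosts, pv_truth = synth_provirus_insertions(config, viruses, hosts,
                                                avoid_intervals=truth.array_intervals)
    truth = truth.merge(pv_truth)
    annotations, gene_truth = synth_gene_annotations(config, viruses)
    truth = truth.merge(gene_truth)
    read_counts, frac_truth = synth_read_fractions(config)
    truth = truth.merge(frac_truth)
    presence, meta = synth_presence_matrix(config)
    return SyntheticDataset(config, viruses, hosts, annotations,
                            read_counts, presence, meta, truth)
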