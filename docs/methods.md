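# Methods

This note documents the models, algorithms and numerical conventions behind
`holovir`, the design choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Scope and data model

The package analyses coral holobiont virome data downstream of assembly and
classification: viral genomic sequences (FASTA), bacterial contigs/MAGs
(FASTA), gene-annotation tables (TSV), per-sample read-classification
counts (TSV), and presence/absence community matrices (TSV). It does not
run read QC, assembly, binning, viral identification or taxonomy assignment;
the outputs of those external tools are consumed as tables. Coordinates are
0-based half-open throughout, and FASTA ids are taken verbatim up to the
first whitespace.

## CRISPR-spacer phage–host linkage

**Array detection** is a CRT-style scan: exact 19-mer seeds are chained
when consecutive occurrences are separated by a plausible repeat+spacer
period, the repeat is extended to its maximal shared length, and a chain is
accepted when it has ≥3 repeat copies of 19–38 bp separated by spacers of
19–48 bp (all configurable; repeat copies exact by default, with a per-copy
mismatch allowance exposed). Competing candidates from shifted seeds or
chance partial chains are resolved by keeping maximal arrays — most copies,
then longest span, then leftmost — with overlapping losers discarded.
Detection operates on the forward strand of the contig as given.

**Spacer matching** treats "mismatches/gaps" as unit-cost edit distance
(substitution = 1, each inserted or deleted base = 1) with a total budget
of 2 by default — the strictest consistent reading of a BLAST-style
mismatch/gap threshold. "100% coverage to the spacer" means the alignment
must consume the entire spacer: the alignment is semi-global with free ends
on the virus only, so an internal gap costs an edit but does not break
coverage. Spacers shorter than 20 nt never match. Both virus strands are
searched (standard practice; the upstream protocol does not state it).
The matcher computes, for every end position in the virus, the minimum
edit count of a whole-spacer alignment ending there, using a dynamic
programme vectorised along the virus with a min-plus prefix scan for the
within-row gap dependency; start coordinates are recovered by checking the
few starts consistent with the reported distance. Overlapping placements
(either strand) collapse to the minimum-edit one; ties break to the
leftmost virus coordinate, then the + strand. Ambiguity codes (N) never
match anything, including another N, so N-containing windows can only align
by spending edits. Per distinct (virus, host) pair one link is emitted,
carrying the best supporting match (minimum edits, then longest spacer).

## Provirus linkage

A provirus call requires an exact, gap-free embedding of the viral
sequence in a bacterial contig. The default demands the whole virus
(`min_embed_frac = 1.0`); the upstream protocol kept 100%-identity
full-mapping-length alignments, which permits partial-virus matches, so a
partial mode is available behind `min_embed_frac` but is not the default —
it would require an arbitrary partial-length cutoff. Whole-virus search is
a direct substring scan; partial mode is seed-and-extend (21-mer seeds,
maximal extension, segments ≥ the configured fraction of the virus
length). Flanks are `left = start` and `right = contig_length − end`; a
call is a provirus when at least one flank is ≥ `min_flank` (default
500 bp — the flank-assessment rule of the upstream tool is not published,
so the threshold is explicit and configurable). Host bins are pre-filtered
at completeness ≥ 50% and contamination ≤ 10%, boundaries inclusive.

## Enrichment statistics

Per-sample category fractions (host+symbiont, bacterial, viral) are counts
divided by either the QC-read or the filtered-read denominator, reported in
percent at full precision (rounding only at presentation). Samples with a
zero denominator are excluded with a warning. Group comparison uses the
two-sample Student's t-test in its pooled-variance form with df = n₁+n₂−2
(the printed df of the study this mirrors, 23 = 19+6−2, identifies the
pooled form); Welch's form is available behind a flag. Zero pooled
variance with equal means yields t = 0, p = 1; with unequal means an
infinite-t marker with p = 0. Fold enrichment is the ratio of group means,
undefined for a zero reference mean.

## Gene-repertoire statistics

Alignment hits are kept at e-value ≤ 1e-5, identity ≥ 40% and alignment
length ≥ 20 aa. Among surviving hits on the same query whose query-coordinate
intervals overlap by ≥1 aa (no overlap fraction is imposed), only the best
survives: minimum e-value, then higher identity, longer alignment,
lexicographic gene id — a deterministic, order-independent resolution.
Gene frequencies per habitat count *distinct* phages encoding each gene.
Simpson's index of diversity is D = 1 − Σ p_i² (the bias-corrected
finite-sample estimator 1 − Σ n_i(n_i−1)/(N(N−1)) is behind a flag);
Shannon H′ uses natural log, so Pielou's evenness is E = H′/ln S with
E ≡ 0 when S = 1. The cumulative-threshold statistic returns the smallest
k whose k most frequent genes reach the threshold (default 80%). Gene
identity is the annotation id string; no synonym resolution.

## Beta diversity

Jaccard distance on presence sets: d(A,B) = 1 − |A∩B|/|A∪B|; a pair with
an empty union is assigned distance 0 with a warning, and all-zero sample
rows are rejected at load. One-factor PERMANOVA partitions squared
distances: SS_total = (1/n)Σ_{i<j}d²; SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²;
R² = SS_among/SS_total; F = (SS_among/(a−1))/(SS_within/(n−a)). The
permutation p uses the (1+exceedances)/(1+n_perm) estimator to avoid p = 0;
for small n an exact mode enumerates all distinct label assignments.
Factors are tested one at a time; multi-factor decomposition is out of
scope. Beta-dispersion embeds the distance matrix by principal
coordinates, retaining positive- and negative-eigenvalue axes separately;
a sample's squared distance to its group centroid (coordinate-wise mean)
is the squared distance on the real axes minus that on the imaginary axes,
floored at 0 before the square root. Group differences are tested by
one-way ANOVA F on these distances; the permutation p shuffles the
per-sample distances across groups with the embedding fixed — the
convention of the permutation test in the R package this mirrors
(`vegan::permutest.betadisper`), chosen because recomputing centroids
under relabelling changes the statistic being tested. The centroid is the
mean, not the spatial median — a simple, documented default.

## Tripartite network

Nodes are typed host/virus/gene; the graph is simple and undirected.
CRISPR and provirus evidence between the same host–virus pair merge into a
single edge carrying an evidence set, since links are counted per pair and
parallel edges would inflate degree. Genes may be nodes (virus–gene
`encodes` edges) or linkages (virus–virus `shared_gene` edges when two
viruses share ≥1 gene id; an edge-weight variant counting shared genes is
behind a flag but unweighted is the default). Metrics: degree k; closeness
cc = 1/(mean shortest-path length to nodes in the same component), 0 for
isolated nodes — the within-component form used by desktop network tools
that analyse components separately (the harmonic alternative is not used);
clustering clust = 2e_N/(k(k−1)), 0 for k < 2. Keystone viruses are ranked
per metric in descending order with fractional (mid) ranks for ties,
averaged across the three metrics, and sorted ascending by average rank
with ties broken by id; ranking covers virus nodes only. The full ranked
table is emitted rather than a fixed keystone cutoff. Link aggregation
produces class×family counts by evidence kind, per-class link shares with
classes below 2% collapsed into "others", and family×pathway counts;
unmapped taxa become "Unclassified".

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without downloads, and logs a planted-truth ledger
that tests re-verify by direct alignment and substring checks.

- **Sequences** are i.i.d. uniform ACGT — this avoids spurious repeat
  detections and makes false-positive rates analysable; it does not model
  GC skew, repeats or real genome structure.
- **CRISPR arrays**: one array per host contig, 3–8 spacers (r spacers ⇒
  r+1 identical repeat copies of 28 bp). Each spacer copies a random viral
  window (either strand) with exactly k edits, k ∈ {0,1,2,3} drawn from a
  configurable distribution (default 0.4/0.3/0.3 over 0/1/2). Edits are
  substitutions and single-base indels, equally likely, at uniform
  positions; the generator regenerates a spacer until the *realised*
  semi-global distance to the whole target virus equals k and the distance
  to every other virus exceeds 3, so the ledger maps one-to-one onto
  detectable links. Spacer boundary characters are diversified so a chance
  shared boundary base cannot extend the detected repeat into the spacers.
- **Proviruses**: a configurable fraction of hosts (default 0.5) receives
  one whole, unmodified virus inserted with ≥1,000 bp flanks on both
  sides, never splitting a planted array.
- **Gene annotations** sample a pool of 18 genes recurrent in coral and
  seawater phage annotations. The coral-like profile gives its four
  dominant genes 60.35/14.32/3.29/1.57% of the mass (the reported dominant
  gene frequencies) with the remainder spread evenly; the seawater-like
  profile is even. Per-virus gene counts are uniform on 0–4 — the
  per-virus count distribution is not reported anywhere, so it is exposed
  as configuration rather than asserted.
- **Read fractions** are Beta-distributed per group around the reported
  group means (bacterial 2.72% vs 0.30% of QC reads, viral 0.74% vs
  0.40%, host+symbiont 36.39% vs 69.83%) with standard deviations
  back-derived from the printed standard errors (sd = SE·√n at n = 19 and
  6); counts derive from fractions at a fixed depth of 10⁶ reads/sample —
  the real sequencing depths are irrelevant to the statistics under test.
  The filtered-read count is depth minus the host+symbiont count, so
  filtered-denominator fractions are emergent and internally consistent.
- **Presence matrices** assign a fraction of taxa (default 0.4) to single
  groups (present in their group with probability 1 by default, absent
  elsewhere) and the rest as background noise at rate 0.25.

Each stage draws from its own RNG stream derived from the global seed plus
a fixed offset, so stages are byte-reproducible when re-run independently.

What passing tests show: the algorithms are correct against independent
oracles (exhaustive scans, brute-force BFS, full permutation enumeration,
an external alignment library) and the statistics are calibrated under
their nulls. What they do not show: robustness to sequencing error,
misassembly, chimeric contigs, compositional bias, or diverged (rather
than exactly planted) proviruses — real-data behaviour depends on the
upstream tools this package deliberately does not replace.

## Problem sizes and determinism

Default test and demonstration problem sizes are modest by design — tens
of kilobase hosts, ~10 viruses, hundreds of permutations, 200–1,000
simulation replicates — chosen so the full suite and the acceptance script
each run in well under a minute while keeping Monte-Carlo error far below
the tested tolerances. All randomness flows through seeded NumPy
generators; identical configuration (including seed) gives byte-identical
outputs, and the pipeline manifest records versions, parameters, seeds,
input checksums and per-stage row counts.

## Known limitations

- No cas-gene detection, repeat-family classification or PAM analysis; a
  detected repeat-spacer structure is taken at face value.
- The provirus default requires the complete virus; genuinely partial or
  diverged prophages are out of reach of the default (partial mode helps
  but has no principled length cutoff).
- One-factor PERMANOVA only; confounded factors must be interpreted by the
  user, and non-homogeneous dispersion (tested separately) can inflate
  PERMANOVA significance.
- Closeness centrality on disconnected graphs compares nodes only within
  components; cross-component comparisons of cc are not meaningful.
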