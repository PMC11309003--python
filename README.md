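# holovir

Phage–host linkage and community analysis for coral holobiont viromes.

Reef-building corals host dense bacterial and viral communities, and the
bacteriophages among those viruses can rewire bacterial metabolism and
bacteria–coral symbioses. Connecting uncultivated phages to their
bacterial hosts, and both to the genes the phages carry, is the central
analytical problem once viral and bacterial genomes have been assembled
from coral metagenomes. `holovir` implements that downstream analysis as
a tested, reusable pipeline for microbial ecologists:

- **CRISPR-spacer linkage** — CRT-style repeat–spacer array detection in
  bacterial contigs, spacer extraction, and spacer-to-virus matching under
  stringent thresholds (whole-spacer coverage, ≤2 total edits, spacer
  length ≥20 nt, both strands).
- **Provirus linkage** — exact, gap-free embedding of viral genomes in
  host contigs with flank assessment, plus bin-quality filtering
  (completeness ≥50%, contamination ≤10%).
- **Enrichment statistics** — per-sample read fractions (percent of QC or
  host-filtered reads), group means ± SE, fold enrichment
  (fold = x̄₁/x̄₂), and Student's pooled two-sample t-test
  (df = n₁+n₂−2; Welch behind a flag).
- **Gene-repertoire statistics** — alignment-hit filtering (e ≤ 1e-5,
  identity ≥40%, ≥20 aa, best-hit overlap resolution), per-habitat gene
  frequencies, Simpson's D = 1 − Σp², Pielou's E = H′/ln S, genes-to-80%
  cumulative threshold, shared/unique gene partitions.
- **Beta diversity** — Jaccard distances (d = 1 − |A∩B|/|A∪B|), one-factor
  PERMANOVA (R², pseudo-F, permutation p; exact enumeration for small n)
  and beta-dispersion (PCoA with signed eigenvalue handling, ANOVA F,
  permutation p).
- **Tripartite network** — bacteria–phage–gene graph (genes as nodes or as
  shared-gene edges), node degree k, closeness centrality cc, clustering
  coefficient clust, average-rank keystone-virus identification, and
  class×family×gene aggregation tables.
- **Synthetic data** — a first-class generator that plants CRISPR spacers
  at controlled edit distances, exact provirus insertions, skewed or even
  gene-frequency profiles, group-structured read fractions and
  presence/absence matrices, with a ground-truth ledger used as the test
  oracle.

## Worked example

Generate a synthetic holobiont dataset and run two stages:

```sh
holovir synth --seed 7 --outdir demo --n-viruses 8 --n-hosts 6
holovir enrich --counts demo/read_counts.tsv --out demo/enrichment.tsv
holovir link crispr --viruses demo/viruses.fasta --hosts demo/hosts.fasta \
    --out demo/links.tsv
```

which prints:

```
host_symbiont: 36.78% vs 69.73% (fold 0.53, t(23)=-175.61, p=1.77e-37)
bacterial: 2.78% vs 0.28% (fold 10.02, t(23)=4.71, p=9.48e-05)
viral: 0.82% vs 0.52% (fold 1.58, t(23)=2.05, p=0.0517)
6 arrays, 32 spacers, 23 links
```

Reading the enrichment lines: each compares the 19 enriched-extraction
samples against the 6 bulk controls. The enriched group carries about
half the coral/symbiont read load, a ~10× higher bacterial read fraction
(2.78% vs 0.28% of QC reads, pooled t-test on 23 degrees of freedom), and
a modest viral gain. The linkage line reports that all six planted CRISPR
arrays were detected, their 32 spacers extracted, and 23 distinct
virus–host pairs linked — exactly the pairs the generator planted with ≤2
edits. The full pipeline (`holovir run --config examples/demo.yaml
--outdir out`) chains synthesis, both linkage stages, enrichment, gene
repertoire, beta diversity and the network, writing TSV/GraphML outputs
and a JSON manifest with seeds, parameters and row counts.

The same operations are available as a library:

```python
import holovir as hv

ds = hv.generate_all(hv.SynthConfig(seed=7))
arrays = [a for cid, seq in ds.hosts.items()
          for a in hv.detect_crispr_arrays(cid, seq)]
links = hv.link_hosts_by_crispr(hv.extract_spacers(arrays), ds.viruses)
graph = hv.build_graph(links, ds.annotations, mode="genes_as_nodes")
keystones = hv.keystone_rank(hv.node_metrics(graph))
```

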