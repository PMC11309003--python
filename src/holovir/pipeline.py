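"""End-to-end pipeline orchestration with plain-file handoff.

Stages run in a fixed order (synth -> crispr -> provirus -> enrich ->
genes -> betadiv -> network), each reading and writing TSV/FASTA files
under the output directory, and a JSON manifest records the version,
parameters, seed, input checksums and per-stage row counts.  Stage
dependencies are validated before anything executes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import read_fasta, read_tsv, write_fasta, write_tsv
from . import crispr as crispr_mod
from . import provirus as provirus_mod
from . import enrichment, repertoire, diversity, network as network_mod
from .synth import SynthConfig, generate_all

log = logging.getLogger("holovir")

STAGES = ("synth", "crispr", "provirus", "enrich", "genes", "betadiv", "network")


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "stages": {s: True for s in STAGES},
        "paths": {},  # external inputs when synth is disabled
        "synth": {},
        "crispr": {"max_edits": 2, "min_spacer_len": 20},
        "provirus": {"min_flank": 500, "min_embed_frac": 1.0, "seed_k": 21},
        "enrich": {"group_a": "VBE", "group_b": "Control", "denominator": "qc",
                   "welch": False},
        "genes": {"threshold": 0.80},
        "betadiv": {"n_perm": 999, "factor": "group"},
        "network": {"mode": "genes_as_nodes", "others_threshold": 0.02,
                    "weighted_shared_genes": False},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config(seed=user.get("seed", 0))
    for key, value in user.items():
        if isinstance(value, dict) and key in cfg:
            cfg[key] = {**cfg[key], **value}
        else:
            cfg[key] = value
    return cfg


def validate_config(config: dict) -> None:
    stages = config.get("stages", {})
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    paths = config.get("paths", {})
    synth_on = stages.get("synth", False)

    def need(stage, *keys):
        if not stages.get(stage):
            return
        if synth_on:
            return
        missing = [k for k in keys if k not in paths]
        if missing:
            raise ValueError(f"stage '{stage}' requires inputs {missing} "
                             "when synth is disabled")
        for k in keys:
            if not Path(paths[k]).exists():
                raise ValueError(f"input path for '{k}' does not exist: {paths[k]}")

    need("crispr", "viruses", "hosts")
    need("provirus", "viruses", "hosts")
    need("enrich", "read_counts")
    need("genes", "annotations")
    need("betadiv", "presence", "presence_meta")
    need("network", "annotations")
    if stages.get("network") and not (stages.get("crispr") or stages.get("provirus")):
        if "links" not in paths:
            raise ValueError("stage 'network' needs host links: enable the "
                             "linkage stages or provide paths.links")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    paths = dict(config.get("paths", {}))
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "config": config,
                "stages": {}, "inputs": {}, "created": time.strftime("%Y-%m-%dT%H:%M:%S")}
    for key, p in paths.items():
        if Path(p).exists():
            manifest["inputs"][key] = _sha256(p)

    truth = None
    if stages.get("synth"):
        log.info("stage synth")
        scfg = SynthConfig(seed=seed, **config.get("synth", {}))
        ds = generate_all(scfg)
        write_fasta(ds.viruses, outdir / "viruses.fasta")
        write_fasta(ds.hosts, outdir / "hosts.fasta")
        write_tsv(ds.annotations, outdir / "annotations.tsv")
        write_tsv(ds.read_counts, outdir / "read_counts.tsv")
        ds.presence.rename_axis("sample_id").reset_index().to_csv(
            outdir / "presence.tsv", sep="\t", index=False)
        write_tsv(ds.presence_meta, outdir / "presence_meta.tsv")
        write_tsv(pd.DataFrame([dataclasses.asdict(l) for l in truth_links(ds)]),
                  outdir / "truth_spacer_links.tsv")
        write_tsv(pd.DataFrame([dataclasses.asdict(p)
                                for p in ds.truth.provirus_placements]),
                  outdir / "truth_provirus.tsv")
        truth = ds.truth
        paths.update({"viruses": outdir / "viruses.fasta",
                      "hosts": outdir / "hosts.fasta",
                      "annotations": outdir / "annotations.tsv",
                      "read_counts": outdir / "read_counts.tsv",
                      "presence": outdir / "presence.tsv",
                      "presence_meta": outdir / "presence_meta.tsv"})
        manifest["stages"]["synth"] = {"n_viruses": len(ds.viruses),
                                       "n_hosts": len(ds.hosts),
                                       "n_spacer_links": len(truth.spacer_links),
                                       "n_provirus": len(truth.provirus_placements)}

    links_frames = []
    if stages.get("crispr"):
        log.info("stage crispr")
        viruses = read_fasta(paths["viruses"])
        hosts = read_fasta(paths["hosts"])
        pcfg = config.get("crispr", {})
        arrays = []
        for cid, seq in hosts.items():
            arrays.extend(crispr_mod.detect_crispr_arrays(cid, seq))
        spacers = crispr_mod.extract_spacers(arrays)
        links = crispr_mod.link_hosts_by_crispr(
            spacers, viruses, max_edits=pcfg.get("max_edits", 2),
            min_spacer_len=pcfg.get("min_spacer_len", 20))
        sp_df = pd.DataFrame([{"spacer_id": s.spacer_id, "host_contig": s.host_contig,
                               "start": s.interval[0], "end": s.interval[1],
                               "sequence": s.sequence} for s in spacers])
        write_tsv(sp_df, outdir / "spacers.tsv")
        ldf = pd.DataFrame([{"virus_id": l.virus_id, "host_id": l.host_id,
                             "evidence": l.evidence} for l in links])
        write_tsv(ldf, outdir / "links_crispr.tsv")
        links_frames.append(ldf)
        manifest["stages"]["crispr"] = {"n_arrays": len(arrays),
                                        "n_spacers": len(spacers),
                                        "n_links": len(links)}

    if stages.get("provirus"):
        log.info("stage provirus")
        viruses = read_fasta(paths["viruses"])
        hosts = read_fasta(paths["hosts"])
        pcfg = config.get("provirus", {})
        links = provirus_mod.link_hosts_by_provirus(
            viruses, hosts, min_flank=pcfg.get("min_flank", 500),
            min_embed_frac=pcfg.get("min_embed_frac", 1.0),
            seed_k=pcfg.get("seed_k", 21))
        ldf = pd.DataFrame([{"virus_id": l.virus_id, "host_id": l.host_id,
                             "evidence": l.evidence} for l in links])
        write_tsv(ldf, outdir / "links_provirus.tsv")
        links_frames.append(ldf)
        manifest["stages"]["provirus"] = {"n_links": len(links)}

    if stages.get("enrich"):
        log.info("stage enrich")
        counts = read_tsv(paths["read_counts"])
        ecfg = config.get("enrich", {})
        results = enrichment.compare_groups(
            counts, ecfg.get("group_a", "VBE"), ecfg.get("group_b", "Control"),
            denominator=ecfg.get("denominator", "qc"),
            welch=ecfg.get("welch", False))
        write_tsv(enrichment.results_frame(results), outdir / "enrichment.tsv")
        manifest["stages"]["enrich"] = {"n_comparisons": len(results)}

    if stages.get("genes"):
        log.info("stage genes")
        ann = read_tsv(paths["annotations"])
        gcfg = config.get("genes", {})
        freqs = repertoire.tabulate_gene_frequencies(ann)
        summary = repertoire.habitat_summary(freqs, gcfg.get("threshold", 0.80))
        write_tsv(freqs, outdir / "gene_frequencies.tsv")
        write_tsv(summary, outdir / "gene_summary.tsv")
        manifest["stages"]["genes"] = {"n_genes": int(freqs["gene_id"].nunique()),
                                       "n_habitats": len(summary)}

    if stages.get("betadiv"):
        log.info("stage betadiv")
        matrix = pd.read_csv(paths["presence"], sep="\t", index_col="sample_id")
        meta = read_tsv(paths["presence_meta"]).set_index("sample_id")
        matrix = diversity.validate_presence_matrix(matrix)
        labels = meta.loc[matrix.index, "group"].to_numpy()
        bcfg = config.get("betadiv", {})
        dist = diversity.jaccard_distances(matrix)
        perm = diversity.permanova(dist, labels, n_perm=bcfg.get("n_perm", 999),
                                   seed=seed, factor=bcfg.get("factor", "group"))
        disp = diversity.beta_dispersion(dist, labels,
                                         n_perm=bcfg.get("n_perm", 999), seed=seed,
                                         factor=bcfg.get("factor", "group"))
        res = pd.DataFrame([{"factor": perm.factor, "R2": perm.r2, "F": perm.f,
                             "p": perm.p, "n_perm": perm.n_perm, "seed": seed,
                             "dispersion_F": disp.f, "dispersion_p": disp.p}])
        write_tsv(res, outdir / "beta_diversity.tsv")
        manifest["stages"]["betadiv"] = {"R2": perm.r2, "p": perm.p,
                                         "dispersion_p": disp.p}

    if stages.get("network"):
        log.info("stage network")
        if links_frames:
            links = pd.concat(links_frames, ignore_index=True)
        else:
            links = read_tsv(paths["links"])
        ann = read_tsv(paths["annotations"])
        ncfg = config.get("network", {})
        graph = network_mod.build_graph(
            links, ann, mode=ncfg.get("mode", "genes_as_nodes"),
            weighted_shared_genes=ncfg.get("weighted_shared_genes", False))
        metrics = network_mod.node_metrics(graph)
        write_tsv(metrics, outdir / "node_metrics.tsv")
        if (metrics["kind"] == "virus").any():
            keystones = network_mod.keystone_rank(metrics)
            write_tsv(keystones, outdir / "keystones.tsv")
        tables = network_mod.aggregate_links(
            links, gene_annotations=ann,
            others_threshold=ncfg.get("others_threshold", 0.02))
        for name, df in tables.items():
            write_tsv(df, outdir / f"agg_{name}.tsv")
        network_mod.export_graph(graph, outdir / "network.graphml",
                                 "graphml", metrics)
        manifest["stages"]["network"] = {"n_nodes": graph.number_of_nodes(),
                                         "n_edges": graph.number_of_edges()}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def truth_links(ds):
    return ds.truth.spacer_links
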