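"""End-to-end orchestration: simulate -> classify -> context -> expression.

`run_pipeline` executes the full funnel on a synthetic dataset (or on
user-supplied input files), writes one artifact per stage into the output
directory, and returns a manifest recording the funnel counts, every
parameter, and the seed.  Re-running with the same config produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .classify import TranscriptRecord, classify_transcripts
from .comodules import (adjacency, cluster_modules, expression_filter,
                        module_profiles, term_enrichment, tom)
from .exprstats import (CountMatrix, de_overlap_clustering, de_table,
                        independence_filter, ish_candidates, normalize,
                        normalize_log, size_factors, stage_upregulated_sets)
from .genomecontext import (all_neighbor_pairs, intergenic_filter,
                            load_gene_models)
from .synthdata import (SimConfig, read_fasta, read_hits_tsv, simulate_counts,
                        simulate_genome, write_truth_tables)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every threshold of every stage, with the pipeline's defaults.

    Overriding any value is logged with the old and new settings.  Unknown
    keys in a config file are errors.
    """

    seed: int = 42
    # classification cascade
    min_orf: int = 300
    min_nc_len: int = 600
    evalue_blastx: float = 10.0
    evalue_pfam: float = 0.01
    evalue_blastp: float = 10.0
    cp_threshold: float = 1.0
    # independence filter
    rho_cut: float = 0.6
    alpha_independence: float = 0.05
    # differential expression
    alpha_de: float = 0.1
    # module detection
    min_count: float = 5.0
    min_samples: int = 3
    var_quantile: float = 0.25
    beta: int = 18
    min_module_size: int = 30
    # ISH candidate selection
    ish_min_count: float = 40.0
    ish_min_fold: float = 20.0
    # synthetic data (used when no input paths are given)
    sim: SimConfig | None = None
    # optional existing inputs (paths); when set, simulation is skipped
    transcripts_fa: str | None = None
    genes_gff3: str | None = None
    hits_blastx: str | None = None
    hits_pfam: str | None = None
    hits_blastp: str | None = None
    counts_tsv: str | None = None
    design_tsv: str | None = None
    annotation_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw and raw["sim"] is not None:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(raw["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: "
                                 f"{sorted(sim_unknown)}")
            if "stages" in raw["sim"]:
                raw["sim"]["stages"] = tuple(raw["sim"]["stages"])
            raw["sim"] = SimConfig(**raw["sim"])
        cfg = cls(**raw)
        defaults = cls()
        for f in dataclasses.fields(cls):
            if f.name == "sim":
                continue
            old, new = getattr(defaults, f.name), getattr(cfg, f.name)
            if old != new:
                log.info("config override: %s %r -> %r", f.name, old, new)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, params: dict[str, Any],
               index: bool = False, index_label: str | None = None) -> None:
    with path.open("w") as fh:
        fh.write("# spongelinc " + " ".join(f"{k}={v}" for k, v in
                                            params.items()) + "\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def run_pipeline(config: PipelineConfig, outdir: str | Path
                 ) -> dict[str, Any]:
    """Run the full funnel; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if f.name != "sim" and not f.name.endswith(("_fa", "_gff3",
                                                        "_tsv"))
            and not f.name.startswith("hits_")
        },
        "funnel": {},
    }
    funnel = manifest["funnel"]

    # ----- inputs: simulate or load -------------------------------------
    simulated = config.counts_tsv is None
    truth = None
    if simulated:
        sim = config.sim or SimConfig(seed=config.seed)
        manifest["parameters"]["sim"] = dataclasses.asdict(sim)
        dataset = simulate_genome(sim)
        cm = simulate_counts(dataset)
        truth = dataset.truth
        inputs = outdir / "inputs"
        dataset.write(inputs)
        cm.to_tsv(inputs / "counts.tsv", inputs / "design.tsv")
        write_truth_tables(truth, inputs)
        transcripts = dataset.transcripts
        models = dataset.models
        hits = dataset.hits
        log.info("simulated %d transcripts on %d scaffolds",
                 len(transcripts), sim.n_scaffolds)
    else:
        for key in ("transcripts_fa", "genes_gff3", "counts_tsv",
                    "design_tsv"):
            if getattr(config, key) is None:
                raise ValueError(f"input path {key} required when not "
                                 "simulating")
        seqs = read_fasta(config.transcripts_fa)
        models = load_gene_models(config.genes_gff3)
        tx_gene = {f"{m.gene_id}.t1": m.gene_id for m in models}
        transcripts = [
            TranscriptRecord(tid, tx_gene.get(tid, tid), seq)
            for tid, seq in seqs.items()
        ]
        hit_frames = []
        for path, source in ((config.hits_blastx, "blastx_refseq"),
                             (config.hits_pfam, "pfam_hmm"),
                             (config.hits_blastp, "blastp_refseq")):
            if path is not None:
                hit_frames.append(read_hits_tsv(path, source))
        hits = pd.concat(hit_frames, ignore_index=True) if hit_frames \
            else pd.DataFrame(columns=["query_id", "source", "evalue"])
        cm = CountMatrix.from_tsv(config.counts_tsv, config.design_tsv)
    funnel["n_input_transcripts"] = len(transcripts)

    # ----- classification cascade ---------------------------------------
    decisions = classify_transcripts(
        transcripts, hits, cp_threshold=config.cp_threshold,
        min_orf=config.min_orf, min_nc_len=config.min_nc_len,
        evalue_blastx=config.evalue_blastx, evalue_pfam=config.evalue_pfam,
        evalue_blastp=config.evalue_blastp,
    )
    _write_tsv(decisions, outdir / "decisions.tsv",
               {"stage": "classify", "min_orf": config.min_orf,
                "min_nc_len": config.min_nc_len,
                "cp_threshold": config.cp_threshold})
    funnel["n_coding"] = int((decisions["label"] == "coding").sum())
    funnel["n_lncRNA_candidates"] = int(
        (decisions["label"] == "lncRNA_candidate").sum())
    funnel["n_discarded"] = int((decisions["label"] == "discarded").sum())

    # ----- genomic context ----------------------------------------------
    candidate_genes = set(decisions.loc[
        decisions["label"] == "lncRNA_candidate", "gene_id"])
    model_of = {m.gene_id: m for m in models}
    candidate_models = [model_of[g] for g in decisions["gene_id"]
                        if g in candidate_genes and g in model_of]
    coding_models = [m for m in models if m.kind == "coding"]
    lincs, removed, evidence = intergenic_filter(candidate_models,
                                                 coding_models)
    linc_ids = [m.gene_id for m in lincs]
    _write_tsv(pd.DataFrame({"gene_id": linc_ids}), outdir / "lincRNAs.tsv",
               {"stage": "context"})
    _write_tsv(
        pd.DataFrame(
            [{"gene_id": e.gene_id, "coding_gene_id": e.coding_gene_id,
              "region": e.region, "overlap_bp": e.overlap_bp}
             for e in evidence]),
        outdir / "overlap_evidence.tsv", {"stage": "context"})
    funnel["n_lincRNA"] = len(lincs)

    pairs = all_neighbor_pairs(lincs, coding_models)

    # ----- expression ----------------------------------------------------
    factors = size_factors(cm.counts)
    cm.size_factors = factors
    _write_tsv(factors.to_frame(), outdir / "size_factors.tsv",
               {"stage": "normalize"}, index=True, index_label="library")
    norm = normalize(cm.counts, factors)
    lognorm = normalize_log(cm.counts, factors)

    independent, correlated, pair_table = independence_filter(
        pairs, lognorm, rho_cut=config.rho_cut,
        alpha=config.alpha_independence,
    )
    _write_tsv(pair_table, outdir / "neighbor_pairs.tsv",
               {"stage": "independence", "rho_cut": config.rho_cut,
                "alpha": config.alpha_independence})
    funnel["n_independent_lincRNA"] = len(independent)

    coding_ids = [m.gene_id for m in coding_models
                  if m.gene_id in cm.counts.index]
    test_genes = [g for g in coding_ids + independent
                  if g in cm.counts.index]
    de = de_table(cm, alpha_de=config.alpha_de, genes=test_genes)
    _write_tsv(de, outdir / "de_results.tsv",
               {"stage": "de", "alpha_de": config.alpha_de,
                "baseline": cm.stages[0]})

    linc_set = set(independent)
    de_linc = de[de["gene_id"].isin(linc_set)]
    summaries = stage_upregulated_sets(de_linc) if len(de_linc) else []
    up_lincs = set().union(*(s.upregulated for s in summaries)) \
        if summaries else set()
    funnel["n_upregulated_lincRNA"] = len(up_lincs)
    _write_tsv(
        pd.DataFrame([{"stage": s.stage, "n_upregulated": len(s.upregulated),
                       "unique_to_stage": s.unique_to_stage,
                       "shared_with_all": s.shared_with_all}
                      for s in summaries]),
        outdir / "stage_sets.tsv", {"stage": "de"})
    if len(summaries) >= 2:
        sets = {s.stage: s.upregulated for s in summaries}
        dist, _, newick = de_overlap_clustering(sets)
        _write_tsv(dist, outdir / "stage_distances.tsv",
                   {"stage": "de_overlap"}, index=True, index_label="stage")
        (outdir / "stage_dendrogram.nwk").write_text(newick + "\n")

    ish = ish_candidates(norm.loc[[g for g in independent
                                   if g in norm.index]],
                         cm.design, min_count=config.ish_min_count,
                         min_fold=config.ish_min_fold)
    _write_tsv(pd.DataFrame({"gene_id": ish}), outdir / "ish_candidates.tsv",
               {"stage": "ish", "min_count": config.ish_min_count,
                "min_fold": config.ish_min_fold})
    funnel["n_ish_candidates"] = len(ish)

    # ----- co-expression modules ----------------------------------------
    up_coding = set(de.loc[de["upregulated"] &
                           de["gene_id"].isin(coding_ids), "gene_id"])
    universe = [g for g in cm.counts.index
                if g in up_coding or g in linc_set]
    kept = expression_filter(norm.loc[universe], min_count=config.min_count,
                             min_samples=config.min_samples,
                             var_quantile=config.var_quantile)
    kept = [g for g in kept if lognorm.loc[g].std() > 0]
    funnel["n_module_universe"] = len(universe)
    funnel["n_module_input"] = len(kept)
    if len(kept) >= 3:
        adj = adjacency(lognorm.loc[kept], beta=config.beta)
        assignment = cluster_modules(tom(adj),
                                     min_module_size=config.min_module_size)
        profiles = module_profiles(assignment, norm, cm.design)
        _write_tsv(assignment.labels.rename("module").to_frame(),
                   outdir / "modules.tsv",
                   {"stage": "modules", "beta": config.beta,
                    "min_module_size": config.min_module_size},
                   index=True, index_label="gene_id")
        _write_tsv(profiles, outdir / "module_profiles.tsv",
                   {"stage": "modules"}, index=True, index_label="module")
        funnel["n_modules"] = int(len(assignment.sizes))
        funnel["n_genes_in_modules"] = int(assignment.sizes.sum())
    else:
        funnel["n_modules"] = 0
        funnel["n_genes_in_modules"] = 0

    # ----- optional term enrichment --------------------------------------
    if config.annotation_tsv is not None and funnel["n_modules"] > 0:
        ann = pd.read_csv(config.annotation_tsv, sep="\t", comment="#")
        background = set(kept)
        enr_frames = []
        for module in assignment.sizes.index:
            enr = term_enrichment(set(assignment.members(module)),
                                  background, ann)
            enr.insert(0, "module", module)
            enr_frames.append(enr)
        _write_tsv(pd.concat(enr_frames, ignore_index=True),
                   outdir / "enrichment.tsv", {"stage": "enrich"})

    log.info("pipeline finished in %.1f s; funnel: %s",
             time.monotonic() - t0, funnel)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
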