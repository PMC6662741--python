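"""End-to-end orchestration: generate -> filter -> quantify -> integrate.

A single YAML config drives the whole run.  Every stage logs its
input/output row counts (the identification funnel), and a manifest
records parameters, seeds, per-file SHA-256 checksums and package version
so that a re-run with the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cascade import build_2d_map, conformance_fraction, inverse_pairs
from .concordance import common_across_grades, match_transcript_trends, subcellular_fraction
from .design import CascadeParams, ChannelDesign
from .enrichment import GeneSetCollection, enrich_collection
from .io import read_psm_table, write_table
from .network import edge_enrichment_pvalue, hub_nodes, induced_subgraph, merge_tf_invasion, rank_bridging_tfs
from .psm_filters import apply_identification_filters
from .quant import call_de_table, curation_cascade
from .synthetic import (
    GeneratorParams,
    generate_mirna_pairs,
    generate_ppi,
    generate_psm_dataset,
    generate_transcriptome,
    write_dataset,
)

log = logging.getLogger("nucmap")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    In synthetic mode (``generator`` set) all inputs are generated under
    ``outdir/inputs``; otherwise ``psm_paths`` (two run-level TSVs) and the
    companion tables must be provided.
    """

    outdir: Path
    generator: GeneratorParams | None = None
    psm_paths: list[Path] = field(default_factory=list)
    transcript_path: Path | None = None
    mirna_pairs_path: Path | None = None
    mirna_dirs_path: Path | None = None
    edges_path: Path | None = None
    cascade_params: CascadeParams = field(default_factory=CascadeParams)
    fdr: float = 0.01
    sn_min: float = 1.5
    score_min: int = 400
    n_perm: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {"outdir": Path(data.pop("outdir", "nucmap_run"))}
        if "generator" in data:
            gen = data.pop("generator") or {}
            for name in ("true_fc_range_up", "true_fc_range_null",
                         "peptides_per_protein", "psms_per_peptide_per_run"):
                if name in gen:
                    gen[name] = tuple(gen[name])
            kwargs["generator"] = GeneratorParams(**gen)
        if "cascade_params" in data:
            kwargs["cascade_params"] = CascadeParams(**data.pop("cascade_params"))
        for key in ("psm_paths",):
            if key in data:
                kwargs[key] = [Path(p) for p in data.pop(key)]
        for key in ("transcript_path", "mirna_pairs_path", "mirna_dirs_path", "edges_path"):
            if key in data:
                kwargs[key] = Path(data.pop(key))
        kwargs.update(data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.generator is None:
            if len(self.psm_paths) != 2:
                raise ValueError(
                    "config error: synthetic mode is off and psm_paths does not "
                    "list exactly two run-level PSM tables"
                )
            for p in self.psm_paths:
                if not Path(p).exists():
                    raise ValueError(f"config error: input path does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the manifest dict.

    Outputs under ``config.outdir``: de_table.tsv, table1_summary.tsv,
    concordance.tsv, enrichment.tsv, network_stats.json, cascades.tsv and
    manifest.json (plus generated inputs in synthetic mode).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = ChannelDesign()
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "cascade": dataclasses.asdict(config.cascade_params),
            "fdr": config.fdr,
            "sn_min": config.sn_min,
            "score_min": config.score_min,
            "n_perm": config.n_perm,
        },
        "stages": {},
    }

    # ---- stage 0: inputs -------------------------------------------------
    truth = None
    if config.generator is not None:
        params = dataclasses.replace(config.generator, seed=config.seed)
        manifest["parameters"]["generator"] = dataclasses.asdict(params)
        indir = outdir / "inputs"
        runs, truth = generate_psm_dataset(params)
        psms = [p for run in runs.values() for p in run]
        tx = generate_transcriptome(truth, params.concordance_rate, params.seed + 2)
        pairs, mdirs = generate_mirna_pairs(truth, params.mirna_conformance_rate, params.seed + 3)
        ppi = generate_ppi(truth, params)
        write_dataset(indir, params)  # regenerate to files for the record (same seed)
        annotation = truth.compartments
        tf_nodes = set(truth.tf_nodes)
        invasion_nodes = _synthetic_invasion_set(truth, ppi)
        log.info("generated %d PSMs over %d runs", len(psms), len(runs))
    else:
        psms = []
        for p in config.psm_paths:
            psms.extend(read_psm_table(p))
        tx = pd.read_csv(config.transcript_path, sep="\t") if config.transcript_path else pd.DataFrame(
            columns=["gene", "grade", "log2fc", "direction"]
        )
        pairs = (
            pd.read_csv(config.mirna_pairs_path, sep="\t")
            if config.mirna_pairs_path
            else pd.DataFrame(columns=["mirna", "target_gene", "validated"])
        )
        mdirs = (
            pd.read_csv(config.mirna_dirs_path, sep="\t")
            if config.mirna_dirs_path
            else pd.DataFrame(columns=["mirna", "direction"])
        )
        from .network import read_edge_list

        ppi = read_edge_list(config.edges_path, config.score_min) if config.edges_path else None
        annotation = {}
        tf_nodes = set()
        invasion_nodes = set()

    # ---- stage 1: identification filters --------------------------------
    retained, counts = apply_identification_filters(
        psms, design, fdr=config.fdr, sn_min=config.sn_min
    )
    manifest["stages"]["identification"] = counts
    for stage, n in counts.items():
        log.info("identification funnel: %s = %d", stage, n)

    # ---- stage 2: quantitation cascade ----------------------------------
    quants = curation_cascade(retained, design, config.cascade_params)
    de_df, summary = call_de_table(quants, config.cascade_params)
    write_table(de_df, outdir / "de_table.tsv")
    write_table(summary, outdir / "table1_summary.tsv")
    manifest["stages"]["quantitation"] = {
        "proteins_quantified": len({(q.accession, q.grade) for q in quants}),
        "de_calls": len(de_df),
    }
    log.info("quantitation: %d (protein, grade) pairs -> %d DE calls", len(quants), len(de_df))

    # ---- stage 3: concordance -------------------------------------------
    labeled, rates = match_transcript_trends(de_df, tx)
    write_table(labeled, outdir / "concordance.tsv")
    common = common_across_grades(de_df)
    comp_frac = subcellular_fraction(de_df, annotation) if annotation else {}
    manifest["stages"]["concordance"] = {
        **rates,
        "common_across_grades": len(common),
        "subcellular_fraction": comp_frac,
    }

    # ---- stage 4: enrichment --------------------------------------------
    identified = sorted({a for p in psms if not p.is_decoy for a in p.proteins})
    de_proteins = sorted(set(de_df["accession"]))
    gene_sets: dict[str, set[str]] = {}
    if truth is not None:
        nuclear = {p for p, comps in annotation.items() if "nuclear" in comps}
        gene_sets = {"planted_module": set(truth.module_members), "nuclear": nuclear}
    if gene_sets:
        collection = GeneSetCollection.from_dict(gene_sets, identified)
        enr = enrich_collection(set(de_proteins) & collection.background, collection)
    else:
        enr = pd.DataFrame(columns=["set", "size", "overlap", "p", "q", "members"])
    write_table(enr, outdir / "enrichment.tsv")

    # ---- stage 5: network -------------------------------------------------
    network_stats: dict[str, Any] = {}
    if ppi is not None and tf_nodes:
        sub, n_edges, isolated = induced_subgraph(ppi, tf_nodes)
        enrich = edge_enrichment_pvalue(ppi, tf_nodes, n_perm=config.n_perm, seed=config.seed + 10)
        hubs = hub_nodes(sub, k=min(5, sub.number_of_nodes() or 1)) if sub.number_of_nodes() else []
        network_stats = {
            "query_nodes": len(tf_nodes),
            "connected_nodes": len(tf_nodes) - len(isolated),
            "edges": n_edges,
            "enrichment_p": enrich.p_value,
            "null_mean_edges": enrich.null_mean,
            "hubs": hubs,
        }
        if invasion_nodes:
            merged = merge_tf_invasion(ppi, tf_nodes, invasion_nodes)
            ranking = rank_bridging_tfs(merged)
            network_stats["bridging_tfs"] = ranking.to_dict(orient="records")
            network_stats["cross_edges"] = len(merged.cross)
    (outdir / "network_stats.json").write_text(json.dumps(network_stats, indent=2, default=str))
    manifest["stages"]["network"] = {
        k: network_stats.get(k) for k in ("edges", "enrichment_p", "connected_nodes")
    }

    # ---- stage 6: miRNA cascade map --------------------------------------
    de_iv = de_df[de_df["grade"] == "IV"]
    protein_dirs = dict(zip(de_iv["accession"], de_iv["direction"]))
    tx_iv = tx[tx["grade"] == "IV"] if len(tx) else tx
    transcript_dirs = dict(zip(tx_iv["gene"], tx_iv["direction"])) if len(tx_iv) else {}
    mirna_dirs = dict(zip(mdirs["mirna"], mdirs["direction"])) if len(mdirs) else {}
    cascades = build_2d_map(
        set(protein_dirs), pairs, protein_dirs, transcript_dirs, mirna_dirs
    )
    write_table(cascades, outdir / "cascades.tsv")
    if len(pairs):
        stats, _ = conformance_fraction(
            cascades, pairs["mirna"].unique(), candidate_entities=set(protein_dirs)
        )
    else:
        stats = {}
    manifest["stages"]["cascade_map"] = {"n_cascades": len(cascades), **stats}

    # ---- manifest ---------------------------------------------------------
    checksums = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            checksums[str(f.relative_to(outdir))] = _sha256(f)
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _synthetic_invasion_set(truth, ppi) -> set[str]:
    """Invasion-process stand-in: non-module graph nodes DE at grade IV."""
    de_iv = truth.de_set("IV")
    module = set(truth.module_members)
    return {n for n in ppi.nodes if n in de_iv and n not in module}
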