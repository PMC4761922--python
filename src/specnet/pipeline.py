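"""End-to-end orchestration: normalize -> differential -> volcano ->
abundance -> graph/MCL per direction -> enrichment -> cross-omics, with every
intermediate written to TSV and a versioned JSON run report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import crossomics as xo
from . import enrichment, io_tables, netclust, quant
from .synthetic_data import SimConfig, gen_annotations, gen_counts, gen_network, gen_transcripts

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    counts: str
    meta: str
    edges: str
    transcripts: str
    annotations: str
    groups: dict[str, str]
    outdir: str
    case_group: str = "injured"
    control_group: str = "control"
    alias: str | None = None
    epsilon: float = 0.5
    p_cut: float = 0.05
    threshold: float = 0.4
    inflation: float = 1.9
    prune: float = 1e-5
    tol: float = 1e-6
    max_iter: int = 100
    top_k: int = 8
    abundance_mode: str = "mean_all"
    welch: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.pop("inputs", {})
        params = raw.pop("params", {})
        cfg = cls(
            counts=inputs["counts"],
            meta=inputs["meta"],
            edges=inputs["edges"],
            transcripts=inputs["transcripts"],
            annotations=inputs["annotations"],
            alias=inputs.get("alias"),
            groups=raw["groups"],
            outdir=raw["outdir"],
            case_group=raw.get("case_group", "injured"),
            control_group=raw.get("control_group", "control"),
            log_level=raw.get("log_level", "INFO"),
            **params,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("counts", "meta", "edges", "transcripts", "annotations"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError(f"config: input path for {name!r} does not exist: {p}")
        if self.alias is not None and not Path(self.alias).exists():
            raise PipelineError(f"config: alias path does not exist: {self.alias}")
        if self.epsilon < 0:
            raise PipelineError("config: epsilon must be >= 0")
        if not 0 < self.p_cut <= 1:
            raise PipelineError("config: p_cut must be in (0, 1]")
        if not 0 <= self.threshold <= 1:
            raise PipelineError("config: threshold must be in [0, 1]")
        if self.inflation <= 1:
            raise PipelineError("config: inflation must be > 1")


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorate


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage, writing intermediates under ``config.outdir``.

    Returns the run report (also written as ``report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"schema_version": REPORT_SCHEMA_VERSION, "stages": {}}

    table = _stage("read_counts")(io_tables.read_count_table)(config.counts, config.groups)
    table.require_differential_design()
    meta = _stage("read_meta")(io_tables.read_protein_meta)(config.meta)
    alias_map = io_tables.read_alias_table(config.alias) if config.alias else None
    report["stages"]["input"] = {
        "proteins": len(table.protein_ids),
        "samples": len(table.sample_ids),
    }

    norm = _stage("normalize")(quant.normalize)(table)
    norm_out = norm.values.copy()
    norm_out.index.name = "accession"
    norm_out.to_csv(outdir / "normalized.tsv", sep="\t")

    de = _stage("differential")(quant.differential)(
        norm,
        case=config.case_group,
        control=config.control_group,
        unique_peptides=table.peptide_evidence(),
        epsilon=config.epsilon,
        welch=config.welch,
    )
    de.to_csv(outdir / "differential.tsv", sep="\t")
    n_filtered = int(de["passed_filter"].sum())
    sig = de[de["passed_filter"] & (de["p_value"] <= config.p_cut)]
    report["stages"]["differential"] = {
        "proteins_in": len(de),
        "passed_filter": n_filtered,
        "significant_p05": int((de["p_value"] <= 0.05).sum()),
        "significant_p01": int((de["p_value"] <= 0.01).sum()),
        "up": int(((sig["fold_change"] > 1)).sum()),
        "down": int(((sig["fold_change"] < 1)).sum()),
    }

    vol = _stage("volcano")(quant.volcano)(de)
    vol.to_csv(outdir / "volcano.tsv", sep="\t")

    if np.isfinite(meta["mass_kda"]).all():
        ab = _stage("abundance")(quant.abundance_index)(table, meta, mode=config.abundance_mode)
        ab.to_csv(outdir / "abundance.tsv", sep="\t")
        report["stages"]["abundance"] = {"proteins": len(ab)}
    else:
        logger.warning("abundance index skipped: molecular masses incomplete")
        report["stages"]["abundance"] = {"proteins": 0}

    edges = _stage("read_edges")(io_tables.read_edge_table)(config.edges)
    annotations = _stage("read_annotations")(io_tables.read_annotations)(config.annotations)
    gene_of = meta["gene_symbol"]
    universe = sorted(set(gene_of.reindex(de.index[de["passed_filter"]]).dropna()))

    for direction, mask in (
        ("up", sig["fold_change"] > 1),
        ("down", sig["fold_change"] < 1),
    ):
        nodes = sorted(set(gene_of.reindex(sig.index[mask]).dropna()))
        stage_report: dict[str, Any] = {"nodes": len(nodes)}
        if len(nodes) == 0:
            logger.warning("no %s-regulated nodes; skipping network stage", direction)
            report["stages"][f"network_{direction}"] = stage_report
            continue
        graph = _stage(f"build_graph_{direction}")(netclust.build_graph)(
            edges, nodes, threshold=config.threshold
        )
        cs = _stage(f"mcl_{direction}")(netclust.mcl)(
            graph,
            inflation=config.inflation,
            prune=config.prune,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        ranked = netclust.rank_clusters(cs, graph, top_k=config.top_k)
        cent = netclust.betweenness(graph)
        members_df = pd.DataFrame(
            [
                (node, r + 1, len(members), cent.get(node, 0.0))
                for r, members in enumerate(ranked)
                for node in members
            ],
            columns=["node", "cluster_rank", "cluster_size", "betweenness"],
        )
        members_df.to_csv(outdir / f"clusters_{direction}.tsv", sep="\t", index=False)
        enr = _stage(f"enrich_{direction}")(enrichment.enrich_clusters)(
            ranked, annotations, universe
        )
        enr.to_csv(outdir / f"enrichment_{direction}.tsv", sep="\t", index=False)
        dominant = {}
        for r in range(1, len(ranked) + 1):
            call = enrichment.dominant_call(enr[enr["cluster_rank"] == r])
            if call is not None:
                dominant[str(r)] = call["label"]
        stage_report.update(
            {
                "edges": graph.number_of_edges(),
                "clusters": len(cs.clusters),
                "dominant_terms": dominant,
            }
        )
        report["stages"][f"network_{direction}"] = stage_report

    transcripts = _stage("read_transcripts")(io_tables.read_transcript_table)(config.transcripts)
    prot_de = sig.join(gene_of).dropna(subset=["gene_symbol"])
    signature = _stage("crossomics")(xo.intersect_signatures)(
        prot_de,
        transcripts,
        alias_map=alias_map,
        p_cut=config.p_cut,
    )
    signature.shared_up.to_csv(outdir / "shared_signature_up.tsv", sep="\t", index=False)
    signature.shared_down.to_csv(outdir / "shared_signature_down.tsv", sep="\t", index=False)
    report["stages"]["crossomics"] = {
        "shared_up": len(signature.shared_up),
        "shared_down": len(signature.shared_down),
    }

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# Simulation materialization


def write_simulation(sim: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Generate all synthetic inputs, write them plus truth and a ready
    pipeline config; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, meta, truth = gen_counts(sim)
    edges = gen_network(sim, truth)
    annotations = gen_annotations(sim, truth)
    transcripts = gen_transcripts(sim, truth)

    paths = {name: str(outdir / f"{name}.tsv") for name in
             ("counts", "meta", "edges", "annotations", "transcripts", "truth")}
    io_tables.write_count_table(table, paths["counts"])
    io_tables.write_protein_meta(meta, paths["meta"])
    io_tables.write_edge_table(edges, paths["edges"])
    io_tables.write_annotations(annotations, paths["annotations"])
    io_tables.write_transcript_table(transcripts, paths["transcripts"])

    truth_df = pd.DataFrame(
        {
            "accession": list(truth.gene_of),
            "gene_symbol": [truth.gene_of[a] for a in truth.gene_of],
            "true_log2fc": [truth.de_log2fc.get(a, 0.0) for a in truth.gene_of],
            "module": [
                truth.module_labels.get(truth.gene_of[a], -1) for a in truth.gene_of
            ],
            "in_transcript_overlap": [
                truth.gene_of[a] in truth.transcript_overlap for a in truth.gene_of
            ],
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)

    config = {
        "inputs": {k: paths[k] for k in ("counts", "meta", "edges", "annotations", "transcripts")},
        "groups": dict(table.groups),
        "case_group": "injured",
        "control_group": "control",
        "outdir": str(outdir / "results"),
        "params": {},
    }
    config_path = outdir / "pipeline.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["config"] = str(config_path)
    return paths
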