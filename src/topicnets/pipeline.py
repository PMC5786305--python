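"""End-to-end orchestration: filter, corpus, fit, metrics, evaluation, networks.

A YAML config names the inputs and parameters; :func:`run` executes the
stages in order, writes per-stage artifacts under the output directory, and
records a manifest (stage status, seeds, artifact checksums) so a rerun with
the same config and seeds reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus as corpus_io
from . import lda, metrics, network, ontology
from .enrichment import read_gmt, enrich
from .metrics import AssociationSet

logger = logging.getLogger(__name__)

STAGES = ["filter", "corpus", "fit", "metrics", "ontology_eval", "networks", "enrichment"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    predications: str
    gene_symbols: str
    out_dir: str
    ontology: str | None = None
    annotations: str | None = None
    gold_associations: str | None = None
    gene_sets: str | None = None
    alpha: float = 0.1
    beta: float = 0.01
    n_topics: int = 10
    k_grid: list[int] | None = None
    iterations: int = 500
    seed: int = 0
    select_k_seeds: list[int] = field(default_factory=lambda: [0, 1, 2])
    algorithm: str = "cvb0"
    min_doc_tokens: int = 1
    dedupe: bool = False
    folds: int = 10
    levels: int = 3
    n_random: int = 1000
    min_count: int = 5
    alpha_p: float = 0.05
    alpha_adj: float = 0.01
    top_topics: int = 3
    membership_epsilon: float = 1e-6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": asdict(config)}

    def finish(stage: str, status: str, artifacts: list[Path] | None = None, **extra):
        entry = {"status": status, **extra}
        if artifacts:
            entry["artifacts"] = {p.name: _sha256(p) for p in artifacts}
        manifest["stages"][stage] = entry
        logger.info("stage %s: %s", stage, status)

    try:
        # -- filter -----------------------------------------------------
        records = corpus_io.read_predications(config.predications)
        symbols = corpus_io.read_gene_symbols(config.gene_symbols)
        associations = corpus_io.filter_associations(records, symbols, dedupe=config.dedupe)
        assoc_path = out / "associations.tsv"
        with open(assoc_path, "w") as fh:
            for a in associations:
                fh.write(f"{a.disease_id}\t{a.gene_symbol}\t{a.disease_semtype}\n")
        finish("filter", "ok", [assoc_path],
               n_predications=len(records), n_malformed=records.n_malformed,
               n_associations=len(associations))

        # -- corpus -----------------------------------------------------
        corp = corpus_io.build_corpus(associations, min_doc_tokens=config.min_doc_tokens)
        corp.to_dir(out / "corpus")
        corpus_files = sorted((out / "corpus").glob("*.tsv"))
        finish("corpus", "ok", corpus_files,
               n_documents=corp.n_documents, n_vocabulary=corp.n_vocabulary,
               n_tokens=corp.n_tokens)

        # -- fit (optionally with model selection) ----------------------
        n_topics = config.n_topics
        selection = None
        if config.k_grid:
            n_topics, scores = lda.select_topic_number(
                corp, config.k_grid, iterations=config.iterations,
                seeds=config.select_k_seeds, alpha=config.alpha, beta=config.beta,
                algorithm=config.algorithm,
            )
            selection = {str(k): v for k, v in scores.items()}
        model = lda.LatentTopicModel(
            n_topics=n_topics, alpha=config.alpha, beta=config.beta,
            iterations=config.iterations, seed=config.seed, algorithm=config.algorithm,
        ).fit(corp)
        trace_path = out / "trace.csv"
        pd.DataFrame(
            {"iteration": model.trace_.iterations,
             "log_likelihood": model.trace_.log_likelihood}
        ).to_csv(trace_path, index=False)
        ranking = lda.rank_topics(model)
        rank_path = out / "topic_ranking.csv"
        pd.DataFrame(ranking, columns=["topic", "posterior"]).to_csv(rank_path, index=False)
        finish("fit", "ok", [trace_path, rank_path], n_topics=n_topics,
               log_likelihood=lda.log_likelihood(model), selection=selection)

        # -- metrics ----------------------------------------------------
        sim, hist, edges = metrics.topic_similarity_matrix(model, level="gene")
        sim_path = out / "topic_similarity_gene.csv"
        pd.DataFrame(sim).to_csv(sim_path, index=False)
        hist_path = out / "topic_similarity_hist.csv"
        pd.DataFrame(
            {"bin_low": edges[:-1], "bin_high": edges[1:], "count": hist}
        ).to_csv(hist_path, index=False)
        finish("metrics", "ok", [sim_path, hist_path])

        # -- ontology evaluation (optional) ------------------------------
        if config.ontology and config.annotations:
            dag = ontology.read_ontology_tsv(config.ontology)
            dag.annotations.update(ontology.read_annotations(config.annotations))
            rows = []
            for topic, _mass in ranking[: config.top_topics]:
                diseases = [d for d, _ in metrics.top_entities(
                    model, topic, n=corp.n_documents, level="disease")]
                points = ontology.precision_recall(
                    diseases, dag, folds=config.folds, levels=config.levels)
                try:
                    a = ontology.auc(points)
                except ValueError:
                    a = None
                for p in points:
                    rows.append({"topic": topic, "fold": p.fold, "precision": p.precision,
                                 "recall": p.recall, "auc": a})
            pr_path = out / "ontology_pr.csv"
            pd.DataFrame(rows).to_csv(pr_path, index=False)
            finish("ontology_eval", "ok", [pr_path], mode="cumulative")
        else:
            finish("ontology_eval", "skipped", reason="no ontology/annotations configured")

        # -- networks and motifs ----------------------------------------
        if config.gold_associations:
            assoc_set = AssociationSet.from_tsv(config.gold_associations)
        else:
            assoc_set = AssociationSet(pairs=corp.association_set())
        net_rows, motif_rows = [], []
        net_artifacts = []
        for topic, _mass in ranking[: config.top_topics]:
            try:
                net = network.build_topic_network(
                    model, topic, assoc_set, membership_epsilon=config.membership_epsilon)
            except ValueError as exc:
                logger.warning("topic %d network skipped: %s", topic, exc)
                continue
            props = network.global_properties(net)
            net_rows.append({
                "topic": topic, "n_nodes": props["n_nodes"], "n_edges": props["n_edges"],
                "diameter": props["diameter"],
                "characteristic_path_length": props["characteristic_path_length"],
                "n_hubs": len(props["hubs"]), "connected": props["connected"],
            })
            edge_path = out / f"network_topic{topic}.tsv"
            net.to_tsv(edge_path)
            net_artifacts.append(edge_path)
            for res in network.motif_significance(
                net, n_random=config.n_random, min_count=config.min_count,
                alpha_p=config.alpha_p, seed=config.seed,
            ):
                motif_rows.append({"topic": topic, **asdict(res)})
        props_path = out / "network_properties.csv"
        pd.DataFrame(net_rows).to_csv(props_path, index=False)
        motif_path = out / "motifs.csv"
        pd.DataFrame(motif_rows).to_csv(motif_path, index=False)
        finish("networks", "ok", [props_path, motif_path, *net_artifacts],
               n_networks=len(net_rows))

        # -- enrichment (optional) --------------------------------------
        if config.gene_sets:
            collection = read_gmt(config.gene_sets)
            frames = []
            for topic, _mass in ranking[: config.top_topics]:
                genes = {g for g, _ in metrics.top_entities(
                    model, topic, n=corp.n_vocabulary, level="gene")
                    if g in collection.universe}
                if not genes:
                    continue
                table = enrich(genes, collection, alpha_adj=config.alpha_adj)
                table.insert(0, "topic", topic)
                frames.append(table)
            enr_path = out / "enrichment.csv"
            pd.concat(frames, ignore_index=True).to_csv(enr_path, index=False) if frames \
                else pd.DataFrame().to_csv(enr_path, index=False)
            finish("enrichment", "ok", [enr_path])
        else:
            finish("enrichment", "skipped", reason="no gene sets configured")
    except Exception as exc:
        stage = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        finish(stage, "failed", error=str(exc))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
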