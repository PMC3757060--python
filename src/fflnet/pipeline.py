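"""End-to-end pipeline: DE -> targets -> clustering -> motifs -> networks.

Each stage writes its result table under the output directory and logs the
thresholds applied and the counts surviving every filter, so a run is fully
reconstructable from its logs.  All randomness flows from ``config.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import clustering, diffexpr, enrichment, io, motifs, network, semsim
from .config import PipelineConfig
from .datatypes import InputBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    de_mirnas: pd.DataFrame
    de_genes: pd.DataFrame
    target_map: enrichment.TargetMap
    enrichment: pd.DataFrame
    retained_mirnas: set
    clustering: clustering.FuzzyClustering | None
    cluster_genes: dict                 # cluster id -> set of genes
    diagnostics: pd.DataFrame | None
    records: pd.DataFrame
    pair_table: pd.DataFrame
    coexpression: pd.DataFrame
    networks: dict                      # cluster id -> nx.Graph
    centralities: dict
    hubs: dict
    modules: dict                       # cluster id -> module table


STAGES = ("de", "targets", "cluster", "motifs", "network")


def run_pipeline(bundle: InputBundle, config: PipelineConfig | None = None,
                 outdir=None, stop_after: str = "network") -> PipelineResult:
    """Run the stages in order on a loaded input bundle.

    ``stop_after`` truncates the run after the named stage (stages are
    cumulative: each needs its predecessors).
    """
    cfg = config or PipelineConfig()
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    last = STAGES.index(stop_after)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(df: pd.DataFrame, name: str, index=True) -> None:
        if out is not None and df is not None:
            df.to_csv(out / f"{name}.tsv", sep="\t", index=index)

    tmap = enr = fz = diagnostics = None
    retained: set = set()
    cluster_genes: dict = {}
    records = pair_table = coexpr = pd.DataFrame()
    nets: dict = {}
    cents: dict = {}
    hubs: dict = {}
    modules: dict = {}

    stage = "differential_expression"
    try:
        de_mirnas, de_genes, mirna_table, gene_table = run_de(bundle, cfg)
        emit(mirna_table, "mirna_de_table")
        emit(gene_table, "mrna_de_table")
        emit(de_mirnas, "de_mirnas")
        emit(de_genes, "de_genes")
        if last < 1:
            return PipelineResult(de_mirnas, de_genes, None, None, set(), None,
                                  {}, None, records, pair_table, coexpr,
                                  {}, {}, {}, {})

        stage = "target_enrichment"
        tmap, enr, retained = run_targets(bundle, cfg, de_mirnas, de_genes)
        emit(enr, "mirna_enrichment")
        if not retained:
            logger.warning("no miRNA passed target enrichment; "
                           "stopping before the motif stage")
            return PipelineResult(de_mirnas, de_genes, tmap, enr, retained,
                                  None, {}, None, pd.DataFrame(), pd.DataFrame(),
                                  pd.DataFrame(), {}, {}, {}, {})
        tmap_kept = tmap.restrict(retained)
        if last < 2:
            return PipelineResult(de_mirnas, de_genes, tmap, enr, retained,
                                  None, {}, None, records, pair_table, coexpr,
                                  {}, {}, {}, {})

        stage = "go_clustering"
        fz, cluster_genes, diagnostics = run_clustering(bundle, cfg, tmap_kept)
        if fz is not None:
            emit(fz.membership, "cluster_membership")
            emit(diagnostics, "cluster_diagnostics", index=False)
        if last < 3:
            return PipelineResult(de_mirnas, de_genes, tmap, enr, retained, fz,
                                  cluster_genes, diagnostics, records,
                                  pair_table, coexpr, {}, {}, {}, {})

        stage = "ffl_motifs"
        records, pair_table, coexpr, tf_map = run_motifs(
            bundle, cfg, tmap_kept, de_genes, cluster_genes)
        emit(records, "ffl_records", index=False)
        emit(pair_table, "pair_tests", index=False)
        emit(motifs.summarize_pairs(records), "pair_summary", index=False)
        emit(coexpr, "coexpression", index=False)
        if last < 4:
            return PipelineResult(de_mirnas, de_genes, tmap, enr, retained, fz,
                                  cluster_genes, diagnostics, records,
                                  pair_table, coexpr, {}, {}, {}, {})

        stage = "network"
        nets, cents, hubs, modules = run_networks(
            bundle, cfg, records, tf_map, de_mirnas, de_genes)
        for cid, net in nets.items():
            emit(cents[cid], f"network_{cid}_centralities")
            emit(modules[cid], f"network_{cid}_modules")
            if out is not None:
                io.write_network(net, out / f"network_{cid}.graphml", "graphml")
                io.write_network(net, out / f"network_{cid}.sif", "sif")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return PipelineResult(de_mirnas, de_genes, tmap, enr, retained, fz,
                          cluster_genes, diagnostics, records, pair_table,
                          coexpr, nets, cents, hubs, modules)


# ---------------------------------------------------------------------------
# stages

def run_de(bundle: InputBundle, cfg: PipelineConfig):
    """miRNA DE (variance filter + FDR/lfc) and mRNA DE (loose raw-p filter)."""
    filtered = diffexpr.variance_filter(bundle.mirna_expr,
                                        cfg.variance_keep_fraction)
    mirna_table = diffexpr.moderated_t(filtered)
    de_mirnas = diffexpr.filter_de(mirna_table, "fdr", cfg.mirna_fdr,
                                   cfg.mirna_abs_lfc)
    gene_table = diffexpr.moderated_t(bundle.mrna_expr)
    de_genes = diffexpr.filter_de(gene_table, "raw", cfg.mrna_p,
                                  cfg.mrna_abs_lfc)
    return de_mirnas, de_genes, mirna_table, gene_table


def run_targets(bundle: InputBundle, cfg: PipelineConfig,
                de_mirnas: pd.DataFrame, de_genes: pd.DataFrame):
    universe = bundle.mrna_expr.feature_ids
    tmap = enrichment.assign_targets(de_mirnas, de_genes, bundle.predictions,
                                     cfg.context_score_max, universe=universe)
    enr = enrichment.hypergeom_enrichment(tmap, de_genes, universe,
                                          direction=cfg.enrichment_direction)
    if len(enr):
        perm = enrichment.permutation_es(tmap, universe, n_de=len(de_genes),
                                         B=cfg.n_permutations, seed=cfg.seed,
                                         observed=enr,
                                         direction=cfg.enrichment_direction)
        enr = enr.join(perm)
    retained = enrichment.select_mirnas(enr, cfg.enrich_fdr)
    return tmap, enr, retained


def run_clustering(bundle: InputBundle, cfg: PipelineConfig,
                   tmap: enrichment.TargetMap):
    """Similarity matrix over all functional targets, FANNY model selection."""
    targets = sorted(set().union(*tmap.functional.values())
                     if tmap.functional else set())
    annotated, excluded = semsim.annotated_subset(
        targets, bundle.go_annotations, bundle.go_dag)
    if len(annotated) <= max(cfg.k_grid):
        logger.warning("only %d annotated targets: clustering skipped, "
                       "single cluster used", len(annotated))
        return None, {"C1": set(targets)}, None
    resnik = semsim.ResnikSimilarity(bundle.go_annotations, bundle.go_dag,
                                     aggregation=cfg.similarity_aggregation)
    simmat = resnik.matrix(annotated)
    d = simmat.dissimilarity()
    r_star, k_star, diagnostics = clustering.select_parameters(
        d, cfg.fuzziness_grid, cfg.k_grid, seed=cfg.seed)
    fz = clustering.fanny(d, k=k_star, r=r_star, seed=cfg.seed)
    labels = fz.labels
    cluster_genes = {f"C{v + 1}": set(labels.index[labels == v])
                     for v in sorted(labels.unique())}
    return fz, cluster_genes, diagnostics


def run_motifs(bundle: InputBundle, cfg: PipelineConfig,
               tmap: enrichment.TargetMap, de_genes: pd.DataFrame,
               cluster_genes: dict):
    tf_map = motifs.map_tf_targets(bundle.tfbs, bundle.tss, bundle.mrna_expr,
                                   w=cfg.promoter_halfwidth,
                                   tf_expr_min=cfg.tf_expression_log2)
    records, pair_table = motifs.significant_pairs(
        tmap, tf_map, bundle.ppi, de_genes.index, cluster_genes,
        fdr_max=cfg.ffl_fdr)
    motifs.validate_records(records, tmap, tf_map, bundle.ppi, de_genes.index)
    coexpr = motifs.coexpression_eval(records, bundle.mrna_expr,
                                      B=cfg.n_permutations, seed=cfg.seed)
    return records, pair_table, coexpr, tf_map


def run_networks(bundle: InputBundle, cfg: PipelineConfig,
                 records: pd.DataFrame, tf_map, de_mirnas: pd.DataFrame,
                 de_genes: pd.DataFrame):
    de_table = pd.concat([de_mirnas, de_genes])
    sets = bundle.go_annotations.term_gene_sets(bundle.go_dag)
    nets, cents, hubs, modules = {}, {}, {}, {}
    for cid, sub in records.groupby("cluster"):
        net = network.merge_motifs(sub, tf_map=tf_map, de_table=de_table)
        if net.number_of_nodes() == 0:
            continue
        cent = network.centralities(net)
        hub_set = network.call_hubs(net, cfg.hub_fraction_mirna,
                                    cfg.hub_fraction_tf,
                                    cfg.hub_fraction_target, cent=cent)
        cent["hub"] = cent.index.isin(hub_set)
        part = network.walktrap_modules(net, steps=cfg.walktrap_steps)
        mods = network.annotate_modules(net, part, sets,
                                        enrich_fdr=cfg.enrich_fdr)
        nets[cid], cents[cid], hubs[cid], modules[cid] = net, cent, hub_set, mods
    return nets, cents, hubs, modules
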