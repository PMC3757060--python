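"""Feed-forward-loop (FFL) candidate enumeration and pair significance tests.

Two motif shapes are tested per miRNA-TF pair and per functional cluster:

* 3-node: the miRNA and the TF share a target gene.  The null asks whether
  the miRNA's *DE* (functional) targets carry the TF's binding site more
  often than expected given how often its *predicted* targets do:
  N = predicted targets, K = predicted targets with a TFBS, n = functional
  targets, k = functional targets with a TFBS.
* 4-node: the miRNA's target (primary) physically interacts with a TF-bound
  gene (secondary).  The null is over the 1st-neighbor interaction network
  of the miRNA's targets: N = neighbors, K = neighbors with a TFBS,
  n = DE neighbors, k = DE neighbors with a TFBS.

Pairs are BH-corrected within each (cluster x motif type) family and kept at
FDR < 0.2.  Significant pairs are materialized into FFL records and their
co-regulated genes evaluated for elevated coexpression against random gene
pairs with a one-sided two-sample KS test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, PPINetwork
from .diffexpr import bh_fdr
from .enrichment import TargetMap, hypergeom_pvalue

logger = logging.getLogger(__name__)

FFL_COLUMNS = ("cluster", "motif_type", "mirna", "tf", "primary_target",
               "secondary_target", "p", "fdr")


@dataclass
class TFTargetMap:
    """TF -> promoter-bound genes / miRNAs, restricted to expressed TFs."""

    gene_targets: dict    # tf -> set of gene ids
    mirna_targets: dict   # tf -> set of mirna ids
    expressed_tfs: set

    @property
    def tfs(self):
        return sorted(self.expressed_tfs)


def map_tf_targets(tfbs: pd.DataFrame, tss: pd.DataFrame,
                   expr: ExpressionMatrix, w: int = 2000,
                   tf_expr_min: float = 8.0) -> TFTargetMap:
    """Promoter-containment TF target mapping with the expressed-TF filter.

    A TFBS [s, e) counts for a feature iff tss - w <= s and e <= tss + w
    (complete containment in the symmetric promoter window).  TFs absent
    from the expression matrix are dropped; present TFs must reach
    ``tf_expr_min`` mean log2 intensity in at least one group.
    """
    if w <= 0:
        raise ValueError("promoter halfwidth must be positive")
    means = expr.group_means()
    expressed, dropped = set(), []
    for tf in sorted(tfbs["tf"].unique()):
        if tf not in means.index:
            dropped.append(tf)
        elif means.loc[tf].max() >= tf_expr_min:
            expressed.add(tf)
    if dropped:
        logger.info("map_tf_targets: %d TFs absent from expression matrix "
                    "dropped: %s", len(dropped), dropped[:10])
    logger.info("filter=tf_expressed before=%d after=%d min_log2=%s",
                tfbs["tf"].nunique(), len(expressed), tf_expr_min)

    gene_targets: dict = {tf: set() for tf in expressed}
    mirna_targets: dict = {tf: set() for tf in expressed}
    sub = tfbs[tfbs["tf"].isin(expressed)]
    for chrom, tss_chr in tss.groupby("chrom"):
        sites = sub[sub["chrom"] == chrom]
        if sites.empty:
            continue
        pos = tss_chr["tss"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        feats = tss_chr["feature"].to_numpy()[order]
        kinds = tss_chr["kind"].to_numpy()[order]
        starts = sites["start"].to_numpy()
        ends = sites["end"].to_numpy()
        tf_ids = sites["tf"].to_numpy()
        # containment <=> tss in [e - w, s + w]
        lo = np.searchsorted(pos_sorted, ends - w, side="left")
        hi = np.searchsorted(pos_sorted, starts + w, side="right")
        for s_i, e_i, tf, l, h in zip(starts, ends, tf_ids, lo, hi):
            for j in range(l, h):
                if kinds[j] == "mirna":
                    mirna_targets[tf].add(feats[j])
                else:
                    gene_targets[tf].add(feats[j])
    return TFTargetMap(gene_targets, mirna_targets, expressed)


# ---------------------------------------------------------------------------
# pair tests

def ffl3_test(mirna: str, tf: str, target_map: TargetMap,
              tf_map: TFTargetMap, cluster_genes=None) -> float:
    """3-node pair test; the null universe is the miRNA's predicted targets."""
    pred = set(target_map.predicted[mirna])
    func = set(target_map.functional.get(mirna, set()))
    if cluster_genes is not None:
        func &= set(cluster_genes)
    bound = tf_map.gene_targets.get(tf, set())
    N, K = len(pred), len(pred & bound)
    n, k = len(func), len(func & bound)
    if N == 0 or K == 0:
        return 1.0
    return hypergeom_pvalue(N, K, n, k)


def neighbor_network(target_map: TargetMap, ppi: PPINetwork,
                     cluster_genes=None) -> dict:
    """Per-miRNA 1st-neighbor network: functional targets plus PPI neighbors."""
    adj = ppi.adjacency()
    out = {}
    for m in target_map.mirnas:
        func = set(target_map.functional.get(m, set()))
        if cluster_genes is not None:
            func &= set(cluster_genes)
        nb = set(func)
        missing = 0
        for t in func:
            if t in adj:
                nb |= adj[t]
            else:
                missing += 1
        if missing:
            logger.debug("neighbor_network: %d targets of %s absent from PPI",
                         missing, m)
        out[m] = nb
    return out


def ffl4_test(mirna: str, tf: str, neighbors: dict, tf_map: TFTargetMap,
              de_genes) -> float:
    """4-node pair test over the miRNA's 1st-neighbor interaction network."""
    nb = neighbors.get(mirna, set())
    bound = tf_map.gene_targets.get(tf, set())
    de = set(de_genes)
    N, K = len(nb), len(nb & bound)
    n, k = len(nb & de), len(nb & bound & de)
    if N == 0 or K == 0:
        return 1.0
    return hypergeom_pvalue(N, K, n, k)


# ---------------------------------------------------------------------------
# significant pairs and record materialization

def significant_pairs(target_map: TargetMap, tf_map: TFTargetMap,
                      ppi: PPINetwork, de_genes, clusters: dict,
                      fdr_max: float = 0.2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every (miRNA, TF) pair per cluster and motif type; BH per family.

    ``clusters`` maps cluster id -> set of (primary target) genes.  Returns
    (records, pair_table): records holds one row per materialized FFL,
    pair_table one row per tested pair with p and family FDR.
    """
    de = set(de_genes)
    pair_rows = []
    for cluster_id, cgenes in sorted(clusters.items()):
        neighbors = neighbor_network(target_map, ppi, cgenes)
        if not ppi.edges:
            logger.warning("empty PPI network: 4-node stage skipped")
        for motif in ("ffl3", "ffl4"):
            if motif == "ffl4" and not ppi.edges:
                continue
            family = []
            for m in sorted(target_map.mirnas):
                for tf in tf_map.tfs:
                    if motif == "ffl3":
                        p = ffl3_test(m, tf, target_map, tf_map, cgenes)
                    else:
                        p = ffl4_test(m, tf, neighbors, tf_map, de)
                    family.append({"cluster": cluster_id, "motif_type": motif,
                                   "mirna": m, "tf": tf, "p": p})
            if family:
                fam = pd.DataFrame(family)
                fam["fdr"] = bh_fdr(fam["p"].to_numpy())
                pair_rows.append(fam)
    pair_table = (pd.concat(pair_rows, ignore_index=True) if pair_rows
                  else pd.DataFrame(columns=["cluster", "motif_type", "mirna",
                                             "tf", "p", "fdr"]))
    sig = pair_table[pair_table["fdr"] < fdr_max]
    logger.info("significant_pairs tested=%d significant=%d fdr<%s",
                len(pair_table), len(sig), fdr_max)

    records = _materialize_records(sig, target_map, tf_map, ppi, de, clusters)
    return records, pair_table


def _materialize_records(sig: pd.DataFrame, target_map: TargetMap,
                         tf_map: TFTargetMap, ppi: PPINetwork, de: set,
                         clusters: dict) -> pd.DataFrame:
    adj = ppi.adjacency()
    rows = []
    for row in sig.itertuples(index=False):
        cgenes = set(clusters[row.cluster])
        func = set(target_map.functional.get(row.mirna, set())) & cgenes
        bound = tf_map.gene_targets.get(row.tf, set())
        if row.motif_type == "ffl3":
            for g in sorted(func & bound):
                rows.append((row.cluster, "ffl3", row.mirna, row.tf, g, "",
                             row.p, row.fdr))
        else:
            for primary in sorted(func):
                for secondary in sorted(adj.get(primary, set()) & bound & de):
                    rows.append((row.cluster, "ffl4", row.mirna, row.tf,
                                 primary, secondary, row.p, row.fdr))
    return pd.DataFrame(rows, columns=FFL_COLUMNS)


def summarize_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate counts per cluster and motif type plus a per-cluster total."""
    rows = []
    for cluster_id, by_cluster in records.groupby("cluster"):
        groups = [(m, t) for m, t in by_cluster.groupby("motif_type")]
        groups.append(("total", by_cluster))
        for motif, sub in groups:
            sec = set(sub["secondary_target"]) - {""}
            rows.append({
                "cluster": cluster_id, "motif": motif,
                "n_mirnas": sub["mirna"].nunique(),
                "n_tfs": sub["tf"].nunique(),
                "n_primary_targets": sub["primary_target"].nunique(),
                "n_secondary_targets": len(sec),
                "n_pairs": sub[["mirna", "tf"]].drop_duplicates().shape[0],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structural re-verification

def validate_records(records: pd.DataFrame, target_map: TargetMap,
                     tf_map: TFTargetMap, ppi: PPINetwork, de_genes) -> None:
    """Re-check every emitted FFL record against the raw input tables."""
    de = set(de_genes)
    for row in records.itertuples(index=False):
        func = target_map.functional.get(row.mirna, set())
        bound = tf_map.gene_targets.get(row.tf, set())
        if row.primary_target not in func:
            raise AssertionError(f"{row}: primary not a functional miRNA target")
        if row.motif_type == "ffl3":
            if row.primary_target not in bound:
                raise AssertionError(f"{row}: common target lacks the TFBS")
        elif row.motif_type == "ffl4":
            if row.secondary_target not in bound:
                raise AssertionError(f"{row}: secondary lacks the TFBS")
            if row.secondary_target not in de:
                raise AssertionError(f"{row}: secondary target not DE")
            if not ppi.has_edge(row.primary_target, row.secondary_target):
                raise AssertionError(f"{row}: primary-secondary PPI edge missing")
        else:
            raise AssertionError(f"unknown motif type {row.motif_type}")


# ---------------------------------------------------------------------------
# coexpression evaluation

def coexpression_eval(records: pd.DataFrame, expr: ExpressionMatrix,
                      B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """KS comparison of co-regulated vs random gene-pair correlations.

    Per (cluster x motif type): the observed set holds the Pearson
    correlations across samples for every gene pair co-regulated by the same
    significant (miRNA, TF); the reference pools B draws of equally many
    random gene pairs from the expression matrix.  The one-sided two-sample
    KS test asks whether the observed correlations are shifted upward.
    """
    rng = np.random.default_rng(seed)
    values = expr.values
    variances = values.var(axis=1, ddof=1)
    usable = set(values.index[variances > 0])
    n_zero = len(values) - len(usable)
    if n_zero:
        logger.info("coexpression_eval: skipping %d zero-variance genes", n_zero)
    gene_list = sorted(usable)
    z = _standardized(values.loc[gene_list])
    gene_idx = {g: i for i, g in enumerate(gene_list)}
    nsmp = values.shape[1]

    out = []
    for (cluster_id, motif), sub in records.groupby(["cluster", "motif_type"]):
        pairs = set()
        for (_, _), ffls in sub.groupby(["mirna", "tf"]):
            coreg = set(ffls["primary_target"]) | (set(ffls["secondary_target"]) - {""})
            coreg = sorted(coreg & usable)
            pairs.update(itertools.combinations(coreg, 2))
        if not pairs:
            continue
        obs = np.array([z[gene_idx[a]] @ z[gene_idx[b]] / (nsmp - 1)
                        for a, b in sorted(pairs)])
        ref = []
        for _ in range(B):
            pick = rng.choice(len(gene_list), size=2 * len(pairs), replace=False) \
                if 2 * len(pairs) <= len(gene_list) else \
                rng.choice(len(gene_list), size=2 * len(pairs), replace=True)
            for a, b in pick.reshape(-1, 2):
                if a != b:
                    ref.append(z[a] @ z[b] / (nsmp - 1))
        ref = np.asarray(ref)
        ks = stats.ks_2samp(obs, ref, alternative="less")
        out.append({"cluster": cluster_id, "motif_type": motif,
                    "n_pairs": len(pairs), "ks_stat": float(ks.statistic),
                    "p": float(ks.pvalue), "mean_obs": float(obs.mean()),
                    "mean_ref": float(ref.mean())})
    return pd.DataFrame(out)


def _standardized(df: pd.DataFrame) -> np.ndarray:
    x = df.to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return x / sd
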