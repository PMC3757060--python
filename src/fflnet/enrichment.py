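"""Assignment of functional miRNA targets and target-gene enrichment.

A DE miRNA's *functional* targets are its predicted high-efficacy targets
(context score below the cutoff) that are differentially expressed in the
opposite direction — miRNAs repress, so a miRNA up in the high-proliferative
group should have its responsive targets down, and vice versa.

A miRNA is retained for motif analysis only if its predicted targets are
over-represented among the DE genes (upper-tail hypergeometric, BH across
miRNAs).  A permutation procedure recomputes the enrichment score
(ES = -log10 p) on randomly drawn "DE" sets of the same size to show that
enrichment is not an artifact of target-set size; it is reported alongside,
not used as an extra filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class TargetMap:
    """Predicted and functional target sets per miRNA.

    Invariant: functional[m] is a subset of predicted[m] intersected with the
    DE genes, with direction opposite to the miRNA's.
    """

    predicted: dict   # mirna -> set of genes (context-filtered, on-platform)
    functional: dict  # mirna -> set of inversely regulated DE target genes

    def __post_init__(self) -> None:
        for m, f in self.functional.items():
            if not f <= self.predicted.get(m, set()):
                raise ValueError(f"functional targets of {m} not within predicted set")

    @property
    def mirnas(self):
        return self.predicted.keys()

    def restrict(self, mirnas) -> "TargetMap":
        keep = set(mirnas)
        return TargetMap({m: s for m, s in self.predicted.items() if m in keep},
                         {m: s for m, s in self.functional.items() if m in keep})


def assign_targets(de_mirnas: pd.DataFrame, de_genes: pd.DataFrame,
                   predictions: pd.DataFrame, context_max: float = -0.1,
                   universe=None) -> TargetMap:
    """Build the per-miRNA predicted and functional (inverse DE) target sets.

    ``universe``, when given, restricts predicted targets to genes present on
    the mRNA platform.  ``de_mirnas``/``de_genes`` are DE tables indexed by
    feature with a ``direction`` column.
    """
    preds = predictions[predictions["context_score"] <= context_max]
    logger.info("filter=context_score before=%d after=%d cutoff=%s",
                len(predictions), len(preds), context_max)
    if universe is not None:
        universe = set(universe)
        n0 = len(preds)
        preds = preds[preds["gene"].isin(universe)]
        logger.info("filter=on_platform before=%d after=%d", n0, len(preds))

    gene_dir = de_genes["direction"].to_dict()
    predicted: dict = {}
    functional: dict = {}
    for m in de_mirnas.index:
        sub = preds[preds["mirna"] == m]
        predicted[m] = set(sub["gene"])
        mdir = de_mirnas.at[m, "direction"]
        want = "down" if mdir == "up" else "up"
        functional[m] = {g for g in predicted[m] if gene_dir.get(g) == want}
    return TargetMap(predicted, functional)


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k > min(K, n):
        raise ValueError(f"impossible overlap k={k} > min(K={K}, n={n})")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(tmap: TargetMap, de_genes: pd.DataFrame, universe,
                         direction: str = "inverse") -> pd.DataFrame:
    """Per-miRNA target-gene enrichment within the DE list.

    N = platform genes, K = DE genes, n = predicted targets, k = DE targets
    (inverse-direction functional targets by default; ``direction='any'``
    counts every DE predicted target).  Returns a table with p, BH FDR and
    ES = -log10 p.
    """
    universe = set(universe)
    de_set = set(de_genes.index) & universe
    if not de_set <= universe:
        raise ValueError("DE genes must be a subset of the universe")
    N, K = len(universe), len(de_set)
    rows = []
    for m in sorted(tmap.mirnas):
        pred = tmap.predicted[m] & universe
        if direction == "inverse":
            k = len(tmap.functional.get(m, set()) & universe)
        else:
            k = len(pred & de_set)
        p = hypergeom_pvalue(N, K, len(pred), k)
        rows.append({"mirna": m, "n_predicted": len(pred), "n_de_targets": k,
                     "p": p, "es": -np.log10(max(p, np.finfo(float).tiny))})
    result = pd.DataFrame(rows).set_index("mirna")
    result["fdr"] = bh_fdr(result["p"].to_numpy()) if len(result) else []
    return result


def permutation_es(tmap: TargetMap, universe, n_de: int, B: int = 1000,
                   seed: int = 0, observed: pd.DataFrame | None = None,
                   direction: str = "inverse") -> pd.DataFrame:
    """Permutation p-values for the per-miRNA enrichment scores.

    Each permutation draws ``n_de`` genes uniformly without replacement from
    the platform universe as a surrogate DE list, recomputes every miRNA's
    overlap k and its ES; the permutation p-value is
    (1 + #{ES_b >= ES_obs}) / (B + 1), so ties count as exceeding and p is
    bounded away from zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = sorted(set(universe))
    N = len(universe)
    if n_de > N:
        raise ValueError("n_de larger than the universe")
    idx = {g: i for i, g in enumerate(universe)}
    mirnas = sorted(tmap.mirnas)
    member = np.zeros((len(mirnas), N), dtype=np.int32)
    for r, m in enumerate(mirnas):
        for g in tmap.predicted[m]:
            if g in idx:
                member[r, idx[g]] = 1
    n_pred = member.sum(axis=1)

    if observed is None:
        raise ValueError("observed enrichment table required")
    es_obs = observed["es"].reindex(mirnas).to_numpy()

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(mirnas), dtype=np.int64)
    # one shared draw per permutation; k for all miRNAs via a mat-vec product
    for _ in range(B):
        draw = np.zeros(N, dtype=np.int32)
        draw[rng.choice(N, size=n_de, replace=False)] = 1
        k_b = member @ draw
        p_b = stats.hypergeom.sf(k_b - 1, N, n_de, n_pred)
        es_b = -np.log10(np.maximum(p_b, np.finfo(float).tiny))
        exceed += es_b >= es_obs - 1e-12
    perm_p = (1.0 + exceed) / (B + 1.0)
    return pd.DataFrame({"mirna": mirnas, "perm_p": perm_p}).set_index("mirna")


def select_mirnas(results: pd.DataFrame, fdr_max: float = 0.05) -> set:
    """Retain miRNAs with enrichment FDR strictly below the cutoff."""
    kept = set(results.index[results["fdr"] < fdr_max])
    logger.info("filter=mirna_enrichment before=%d after=%d fdr<%s",
                len(results), len(kept), fdr_max)
    return kept
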