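"""Resnik semantic similarity over a GO-style DAG.

The information content of a term is IC(t) = -ln p(t) with p(t) the fraction
of the annotated corpus carrying t or any of its descendants, so the root has
IC 0 and IC is non-decreasing from root to leaves.  Term-pair similarity is
the IC of the maximum-IC common ancestor (MICA); gene-pair similarity
aggregates term pairs either by the best-match average (default) or by the
maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GOAnnotationSet, GODag

logger = logging.getLogger(__name__)


def information_content(annot: GOAnnotationSet, dag: GODag) -> dict:
    """term -> IC (natural log) from annotation frequencies with propagation.

    Terms annotating no gene even after propagation have undefined IC and are
    dropped (logged).
    """
    annot.validate_against(dag)
    term_sets = annot.term_gene_sets(dag)
    corpus = set().union(*annot.propagated(dag).values()) if annot.direct else set()
    n_corpus = len({g for g in annot.genes})
    if n_corpus == 0:
        raise ValueError("no annotated genes; information content undefined")
    ic = {}
    dropped = 0
    for t, genes in term_sets.items():
        if not genes:
            dropped += 1
            continue
        ic[t] = -float(np.log(len(genes) / n_corpus))
    if dropped:
        logger.info("information_content: dropped %d unannotated terms", dropped)
    return ic


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene functional similarity with derived dissimilarity."""

    sim: pd.DataFrame

    @property
    def genes(self) -> list:
        return list(self.sim.index)

    def dissimilarity(self) -> pd.DataFrame:
        """max_sim - sim elementwise, diagonal forced to zero."""
        d = float(self.sim.to_numpy().max()) - self.sim
        np.fill_diagonal(d.values, 0.0)
        return d


class ResnikSimilarity:
    """Precomputes IC and ancestor sets for fast repeated gene comparisons."""

    def __init__(self, annot: GOAnnotationSet, dag: GODag,
                 aggregation: str = "bma"):
        if aggregation not in ("bma", "max"):
            raise ValueError("aggregation must be 'bma' or 'max'")
        self.dag = dag
        self.annot = annot
        self.aggregation = aggregation
        self.ic = information_content(annot, dag)
        self._anc = {t: dag.ancestors(t) for t in dag.terms}
        self._term_cache: dict = {}

    def term_similarity(self, t1: str, t2: str) -> float:
        """IC of the maximum-IC common ancestor of t1 and t2."""
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key not in self._term_cache:
            common = self._anc[t1] & self._anc[t2]
            self._term_cache[key] = max(
                (self.ic[t] for t in common if t in self.ic), default=0.0)
        return self._term_cache[key]

    def annotated_terms(self, gene) -> list:
        return [t for t in self.annot.terms_of(gene) if t in self.ic]

    def gene_similarity(self, g1, g2) -> float:
        """Aggregate term-pair Resnik similarity between two annotated genes."""
        ts1, ts2 = self.annotated_terms(g1), self.annotated_terms(g2)
        if not ts1 or not ts2:
            raise ValueError(f"gene without usable annotation: {g1 if not ts1 else g2}")
        m = np.array([[self.term_similarity(a, b) for b in ts2] for a in ts1])
        if self.aggregation == "max":
            return float(m.max())
        # best-match average, symmetrized over both directions
        return float((m.max(axis=1).mean() + m.max(axis=0).mean()) / 2.0)

    def matrix(self, genes) -> SimilarityMatrix:
        """Pairwise similarity for the given (annotated) genes."""
        genes = list(genes)
        unannotated = [g for g in genes if not self.annotated_terms(g)]
        if unannotated:
            raise ValueError(f"unannotated genes passed to matrix: {unannotated[:5]}")
        n = len(genes)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                s = self.gene_similarity(genes[i], genes[j])
                out[i, j] = out[j, i] = s
        return SimilarityMatrix(pd.DataFrame(out, index=genes, columns=genes))


def annotated_subset(genes, annot: GOAnnotationSet, dag: GODag) -> tuple[list, list]:
    """Split genes into (annotated, excluded-for-lack-of-annotation)."""
    ic = information_content(annot, dag)
    ann, excl = [], []
    for g in genes:
        if any(t in ic for t in annot.terms_of(g)):
            ann.append(g)
        else:
            excl.append(g)
    if excl:
        logger.info("excluded %d genes without usable GO annotation", len(excl))
    return ann, excl
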