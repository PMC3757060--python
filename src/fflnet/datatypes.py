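"""Core in-memory containers for the pipeline.

Tabular inputs (target predictions, TFBS intervals, TSS annotation) are plain
pandas DataFrames with documented column names, validated by the readers in
:mod:`fflnet.io`.  This module holds the containers that carry invariants of
their own: the two-group expression matrix, the protein-interaction edge set,
the GO DAG and its gene annotations.

Genomic coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("high", "low")

#: column contracts for the tabular inputs
PREDICTION_COLUMNS = ("mirna", "gene", "context_score")
TFBS_COLUMNS = ("tf", "chrom", "start", "end")
TSS_COLUMNS = ("feature", "kind", "chrom", "tss", "strand")


@dataclass
class ExpressionMatrix:
    """log2 intensities (features x samples) with a two-level group factor."""

    values: pd.DataFrame          # features x samples, float
    groups: pd.Series             # sample id -> "high" | "low"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without group assignment: {missing}")
        bad = set(self.groups.unique()) - set(GROUP_LEVELS)
        if bad:
            raise ValueError(f"unknown group levels {sorted(bad)}; expected {GROUP_LEVELS}")
        counts = self.groups.value_counts()
        for level in GROUP_LEVELS:
            if counts.get(level, 0) < 2:
                raise ValueError("each group needs >=2 samples "
                                 f"(got {counts.to_dict()})")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, level: str) -> list[str]:
        return list(self.groups.index[self.groups == level])

    def group_means(self) -> pd.DataFrame:
        """Per-feature mean log2 intensity per group (columns high, low)."""
        return pd.DataFrame({
            level: self.values[self.samples_of(level)].mean(axis=1)
            for level in GROUP_LEVELS
        })

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.groups)


@dataclass(frozen=True)
class PPINetwork:
    """Undirected, deduplicated, self-loop-free protein interaction edges."""

    edges: frozenset  # frozenset of frozenset({a, b}) pairs

    @classmethod
    def from_pairs(cls, pairs) -> "PPINetwork":
        edges = set()
        for a, b in pairs:
            if a == b:
                continue
            edges.add(frozenset((a, b)))
        return cls(frozenset(edges))

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, a, b) -> bool:
        return frozenset((a, b)) in self.edges

    def adjacency(self) -> dict:
        adj: dict = {}
        for e in self.edges:
            a, b = tuple(e)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def neighbors(self, node) -> set:
        out = set()
        for e in self.edges:
            if node in e:
                (out.update(e - {node}))
        return out

    def to_pairs(self) -> list[tuple]:
        return sorted(tuple(sorted(e)) for e in self.edges)


class GODag:
    """A GO-style DAG restricted to ``is_a`` edges, with a single root."""

    def __init__(self, parents: dict, namespace: str = "biological_process"):
        self.parents = {t: frozenset(ps) for t, ps in parents.items()}
        self.namespace = namespace
        for t, ps in self.parents.items():
            unknown = ps - self.parents.keys()
            if unknown:
                raise ValueError(f"term {t} has unknown parents {sorted(unknown)}")
        roots = [t for t, ps in self.parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {sorted(roots)}")
        self.root = roots[0]
        self._children: dict = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                self._children[p].add(t)
        self._check_acyclic()
        self._anc_cache: dict = {}

    def _check_acyclic(self) -> None:
        state: dict = {}

        def visit(t, stack):
            if t in stack:
                raise ValueError(f"cycle involving term {t}")
            if state.get(t):
                return
            stack.add(t)
            for p in self.parents[t]:
                visit(p, stack)
            stack.remove(t)
            state[t] = True

        for t in self.parents:
            visit(t, set())

    def __contains__(self, term) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    @property
    def terms(self):
        return self.parents.keys()

    def ancestors(self, term, include_self: bool = True) -> frozenset:
        """All terms reachable by following is_a links (cached)."""
        if term not in self._anc_cache:
            out = set()
            todo = list(self.parents[term])
            while todo:
                t = todo.pop()
                if t not in out:
                    out.add(t)
                    todo.extend(self.parents[t])
            self._anc_cache[term] = frozenset(out)
        anc = self._anc_cache[term]
        return anc | {term} if include_self else anc

    def descendants(self, term, include_self: bool = True) -> frozenset:
        out = set()
        todo = [term]
        while todo:
            t = todo.pop()
            if t not in out:
                out.add(t)
                todo.extend(self._children[t])
        return frozenset(out) if include_self else frozenset(out - {term})


@dataclass
class GOAnnotationSet:
    """gene -> directly annotated GO term ids (one namespace).

    Ancestor propagation happens on demand via :meth:`propagated`; the stored
    annotation always remains the direct one.
    """

    direct: dict  # gene -> frozenset of term ids

    def __post_init__(self) -> None:
        self.direct = {g: frozenset(ts) for g, ts in self.direct.items() if ts}

    def validate_against(self, dag: GODag) -> None:
        for g, ts in self.direct.items():
            unknown = ts - set(dag.terms)
            if unknown:
                raise ValueError(f"gene {g} annotated with unknown terms {sorted(unknown)}")

    @property
    def genes(self):
        return self.direct.keys()

    def terms_of(self, gene) -> frozenset:
        return self.direct.get(gene, frozenset())

    def propagated(self, dag: GODag) -> dict:
        """gene -> annotation closed under is_a ancestors (computed, not stored)."""
        return {
            g: frozenset().union(*(dag.ancestors(t) for t in ts))
            for g, ts in self.direct.items()
        }

    def term_gene_sets(self, dag: GODag) -> dict:
        """term -> set of genes annotated to the term or any descendant."""
        sets: dict = {t: set() for t in dag.terms}
        for g, ts in self.propagated(dag).items():
            for t in ts:
                sets[t].add(g)
        return sets


@dataclass
class InputBundle:
    """Everything the pipeline consumes, already validated."""

    mirna_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    predictions: pd.DataFrame      # PREDICTION_COLUMNS
    tfbs: pd.DataFrame             # TFBS_COLUMNS
    tss: pd.DataFrame              # TSS_COLUMNS
    ppi: PPINetwork
    go_dag: GODag
    go_annotations: GOAnnotationSet
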