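"""Readers and writers for the pipeline's text formats.

All inputs are TSV (or OBO/GMT for the ontology); all coordinates are kept
0-based half-open internally.  Readers enforce the type invariants, reject
offending rows and log one structured line per filter with before/after
counts, so every count surviving a filter is traceable in the log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .config import PipelineConfig
from .datatypes import (PREDICTION_COLUMNS, TFBS_COLUMNS, TSS_COLUMNS,
                        ExpressionMatrix, GOAnnotationSet, GODag, InputBundle,
                        PPINetwork)

logger = logging.getLogger(__name__)


def _log_filter(name: str, before: int, after: int, reason: str) -> None:
    logger.info("filter=%s before=%d after=%d rejected=%d reason=%s",
                name, before, after, before - after, reason)


# ---------------------------------------------------------------------------
# expression

def read_expression(matrix_path, groups_path) -> ExpressionMatrix:
    """Read a features x samples log2 TSV plus a two-column sample->group TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    groups = pd.read_csv(groups_path, sep="\t", index_col=0, header=None).iloc[:, 0]
    groups.index = groups.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, groups)


def write_expression(mat: ExpressionMatrix, matrix_path, groups_path) -> None:
    mat.values.to_csv(matrix_path, sep="\t")
    mat.groups.to_csv(groups_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# target predictions

def read_predictions(path) -> pd.DataFrame:
    """miRNA->gene context-score table; duplicate pairs keep the minimum score.

    The minimum (most negative) context score is the most-repressive-site
    reading of duplicated predictions.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=PREDICTION_COLUMNS,
                     dtype={"mirna": str, "gene": str},
                     float_precision="round_trip")
    if df["context_score"].isna().any() or not _all_finite(df["context_score"]):
        bad = df.index[~df["context_score"].apply(_is_finite)][0]
        raise ValueError(f"{path}: non-finite context score at line {bad + 1}")
    n0 = len(df)
    df = (df.sort_values(["mirna", "gene", "context_score"])
            .drop_duplicates(["mirna", "gene"], keep="first")
            .reset_index(drop=True))
    _log_filter("prediction_dedup", n0, len(df), "duplicate (mirna,gene) keep min score")
    return df


def _is_finite(x) -> bool:
    try:
        return pd.notna(x) and abs(float(x)) != float("inf")
    except (TypeError, ValueError):
        return False


def _all_finite(s: pd.Series) -> bool:
    return bool(s.apply(_is_finite).all())


# ---------------------------------------------------------------------------
# TFBS / TSS

def read_tfbs(path, one_based: bool = False) -> pd.DataFrame:
    """4-column BED-like TSV (tf, chrom, start, end), 0-based half-open.

    ``one_based=True`` converts 1-based closed intervals [a, b] to [a-1, b).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=TFBS_COLUMNS,
                     dtype={"tf": str, "chrom": str})
    if one_based:
        df["start"] = df["start"] - 1
    n0 = len(df)
    bad = (df["start"] >= df["end"]) | (df["start"] < 0)
    for i in df.index[bad][:20]:
        logger.warning("rejected TFBS row %d: invalid interval [%s,%s)",
                       i + 1, df.at[i, "start"], df.at[i, "end"])
    df = df[~bad].reset_index(drop=True)
    _log_filter("tfbs_intervals", n0, len(df), "start<end and start>=0 required")
    return df


def read_tss(path) -> pd.DataFrame:
    """5-column TSV (feature, kind, chrom, tss, strand); first TSS per feature wins."""
    df = pd.read_csv(path, sep="\t", header=None, names=TSS_COLUMNS,
                     dtype={"feature": str, "kind": str, "chrom": str, "strand": str})
    bad_kind = ~df["kind"].isin(("gene", "mirna"))
    bad_strand = ~df["strand"].isin(("+", "-"))
    if bad_kind.any() or bad_strand.any():
        i = int(df.index[bad_kind | bad_strand][0])
        raise ValueError(f"{path}: invalid kind/strand at line {i + 1}")
    n0 = len(df)
    df = df.drop_duplicates("feature", keep="first").reset_index(drop=True)
    _log_filter("tss_multi", n0, len(df), "one TSS per feature, first listed wins")
    return df


# ---------------------------------------------------------------------------
# PPI

def read_ppi(path) -> PPINetwork:
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    net = PPINetwork.from_pairs(df.itertuples(index=False))
    _log_filter("ppi_edges", len(df), len(net), "dedup undirected, drop self-loops")
    return net


def write_ppi(net: PPINetwork, path) -> None:
    pd.DataFrame(net.to_pairs()).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GO

def read_obo(path) -> GODag:
    """Read an OBO subset (id, is_a, namespace) into a :class:`GODag`."""
    graph = obonet.read_obo(path)
    parents: dict = {}
    namespaces = set()
    for term, data in graph.nodes(data=True):
        parents[term] = set(graph.successors(term))  # obonet: term -> parent
        if "namespace" in data:
            namespaces.add(data["namespace"])
    ns = namespaces.pop() if len(namespaces) == 1 else "biological_process"
    return GODag(parents, namespace=ns)


def write_obo(dag: GODag, path) -> None:
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.terms):
        lines += [f"[Term]", f"id: {term}", f"name: {term}",
                  f"namespace: {dag.namespace}"]
        lines += [f"is_a: {p} ! {p}" for p in sorted(dag.parents[term])]
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_gaf_lite(path, dag: GODag | None = None) -> GOAnnotationSet:
    """3-column TSV: gene, term, namespace (namespace column may be empty)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["gene", "term"], dtype=str)
    direct: dict = {}
    n_rej = 0
    for gene, term in df.itertuples(index=False):
        if dag is not None and term not in dag:
            n_rej += 1
            continue
        direct.setdefault(gene, set()).add(term)
    annot = GOAnnotationSet(direct)
    _log_filter("go_annotations", len(df), len(df) - n_rej, "term must exist in DAG")
    if dag is not None:
        annot.validate_against(dag)
    return annot


def write_gaf_lite(annot: GOAnnotationSet, path, namespace="biological_process") -> None:
    rows = [(g, t, namespace)
            for g in sorted(annot.genes) for t in sorted(annot.terms_of(g))]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene... -> {name: set}."""
    sets: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need >=3 columns")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path) -> None:
    lines = ["\t".join([name, name] + sorted(genes))
             for name, genes in sorted(sets.items())]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# networks

NETWORK_FORMATS = ("graphml", "sif", "tsv")


def write_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Serialize a typed co-regulatory network; round-trips exactly via graphml/tsv."""
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {NETWORK_FORMATS}")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "sif":
        lines = []
        for u, v, data in sorted(net.edges(data=True)):
            for kind in sorted(str(data.get("kind", "edge")).split(";")):
                lines.append(f"{u}\t{kind}\t{v}")
        lines += [str(n) for n in sorted(net.nodes) if net.degree(n) == 0]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:  # tsv: node table + edge table
        nodes = pd.DataFrame(
            [{"node": n, **d} for n, d in sorted(net.nodes(data=True))])
        edges = pd.DataFrame(
            [{"source": u, "target": v, **d} for u, v, d in sorted(net.edges(data=True))])
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
        edges.to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        g = nx.Graph()
        for raw in Path(path).read_text().splitlines():
            parts = raw.split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) == 3:
                u, kind, v = parts
                if g.has_edge(u, v):
                    kinds = set(g[u][v]["kind"].split(";")) | {kind}
                    g[u][v]["kind"] = ";".join(sorted(kinds))
                else:
                    g.add_edge(u, v, kind=kind)
        return g
    raise ValueError(f"unknown format {fmt!r}; supported: graphml, sif")


# ---------------------------------------------------------------------------
# bundle

BUNDLE_FILES = {
    "mirna_matrix": "mirna_expression.tsv",
    "mrna_matrix": "mrna_expression.tsv",
    "groups": "sample_groups.tsv",
    "predictions": "target_predictions.tsv",
    "tfbs": "tfbs.tsv",
    "tss": "tss.tsv",
    "ppi": "ppi.tsv",
    "go_dag": "go.obo",
    "go_annotations": "go_annotations.tsv",
}


def load_inputs(indir, config: PipelineConfig | None = None) -> InputBundle:
    """Load and validate the full input bundle from a directory."""
    indir = Path(indir)
    paths = {k: indir / v for k, v in BUNDLE_FILES.items()}
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input file for {k}: {p}")
    dag = read_obo(paths["go_dag"])
    return InputBundle(
        mirna_expr=read_expression(paths["mirna_matrix"], paths["groups"]),
        mrna_expr=read_expression(paths["mrna_matrix"], paths["groups"]),
        predictions=read_predictions(paths["predictions"]),
        tfbs=read_tfbs(paths["tfbs"]),
        tss=read_tss(paths["tss"]),
        ppi=read_ppi(paths["ppi"]),
        go_dag=dag,
        go_annotations=read_gaf_lite(paths["go_annotations"], dag),
    )


def write_inputs(bundle: InputBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = {k: outdir / v for k, v in BUNDLE_FILES.items()}
    write_expression(bundle.mirna_expr, p["mirna_matrix"], p["groups"])
    bundle.mrna_expr.values.to_csv(p["mrna_matrix"], sep="\t")
    bundle.predictions.to_csv(p["predictions"], sep="\t", header=False, index=False)
    bundle.tfbs.to_csv(p["tfbs"], sep="\t", header=False, index=False)
    bundle.tss.to_csv(p["tss"], sep="\t", header=False, index=False)
    write_ppi(bundle.ppi, p["ppi"])
    write_obo(bundle.go_dag, p["go_dag"])
    write_gaf_lite(bundle.go_annotations, p["go_annotations"],
                   namespace=bundle.go_dag.namespace)
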