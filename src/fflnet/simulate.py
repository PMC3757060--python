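"""Synthetic input bundles with planted ground truth.

The generator emulates the data layout of the osteosarcoma proliferation
study design: seven cell-line samples (4 high- vs 3 low-proliferative),
log2-scale expression with i.i.d. Gaussian noise, 17 planted DE miRNAs
(9 down, 8 up in the high group) of which 12 carry inversely regulated DE
target genes, TargetScan-like context-score predictions, conserved-TFBS-like
promoter intervals, a BioGRID-like PPI edge list, and a toy GO DAG whose two
branches ("metabolic-like" vs "signaling-like") define the planted functional
clusters.  3-node FFLs are planted by placing a TF's binding site fully
inside the promoters of a miRNA's functional targets; 4-node FFLs by wiring
DE, TF-bound secondary genes to primary targets through PPI edges.

Every planted fact is recorded in :class:`GroundTruth` and is re-derivable by
scanning the emitted files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (ExpressionMatrix, GOAnnotationSet, GODag, InputBundle,
                        PPINetwork)

logger = logging.getLogger(__name__)

GO_ROOT = "GO:0000001"
GO_BRANCH = {"A": "GO:0000010", "B": "GO:0000020"}
GO_LEAF_BASE = {"A": 10, "B": 20}

#: genomic layout: one chromosome, TSSs spaced far enough apart that
#: +/- 2 kb promoter windows never overlap
TSS_SPACING = 10_000
TFBS_LEN = 10


@dataclass
class SimulationParams:
    """Study-design parameters; the defaults are the emulated conditions."""

    n_samples_high: int = 4
    n_samples_low: int = 3
    n_mirnas: int = 60
    n_genes: int = 2000           # includes the TF genes
    n_tfs: int = 12
    n_de_mirnas: int = 17
    n_de_down: int = 9            # remainder are up-regulated in "high"
    n_enriched_mirnas: int = 12   # DE miRNAs given functional (inverse DE) targets
    de_lfc_mean: float = 2.0      # log2 units
    de_lfc_sd: float = 0.2
    target_lfc_mean: float = 1.5
    target_lfc_sd: float = 0.2
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.5
    targets_per_mirna: int = 30
    fraction_functional: float = 0.5
    n_planted_ffl3: int = 8
    n_planted_ffl4: int = 6
    ffl4_secondaries: int = 10    # planted DE secondary genes per 4-node pair
    tf_bind_rate: float = 0.02    # background promoter-binding probability
    ppi_edge_prob: float = 0.004
    go_leaves_per_branch: int = 6
    go_annotations_min: int = 2
    go_annotations_max: int = 3
    go_noise: float = 0.05        # probability a gene gets an off-branch term
    go_unannotated_fraction: float = 0.1
    n_background_annotated: int = 150
    n_decoy_tfbs: int = 40        # sites straddling a promoter boundary
    n_unexpressed_tfs: int = 1
    promoter_halfwidth: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_functional", "tf_bind_rate", "ppi_edge_prob",
                     "go_noise", "go_unannotated_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_samples_high", "n_samples_low", "n_mirnas", "n_genes",
                     "n_tfs", "targets_per_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_de_mirnas > self.n_mirnas:
            raise ValueError("n_de_mirnas cannot exceed n_mirnas")
        if self.n_de_down > self.n_de_mirnas:
            raise ValueError("n_de_down cannot exceed n_de_mirnas")
        if self.n_enriched_mirnas > self.n_de_mirnas:
            raise ValueError("n_enriched_mirnas cannot exceed n_de_mirnas")

    @property
    def n_functional_per_mirna(self) -> int:
        return int(round(self.fraction_functional * self.targets_per_mirna))


@dataclass
class GroundTruth:
    """Everything that was planted, keyed by the emitted identifiers."""

    de_mirnas: dict                  # mirna -> signed planted log2FC
    enriched_mirnas: list
    functional_pairs: list           # (mirna, gene)
    target_lfc: dict                 # gene -> signed planted log2FC
    branch: dict                     # functional target gene -> "A" | "B"
    ffl3: list                       # (mirna, tf, gene)
    ffl4: list                       # (mirna, tf, primary, secondary)
    ffl3_pairs: list                 # (mirna, tf, branch)
    ffl4_pairs: list                 # (mirna, tf, branch)
    secondaries: list

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        for key in ("functional_pairs", "ffl3", "ffl4", "ffl3_pairs", "ffl4_pairs"):
            raw[key] = [tuple(x) for x in raw[key]]
        return cls(**raw)


def _ids(params: SimulationParams):
    tfs = [f"TF{i + 1:02d}" for i in range(params.n_tfs)]
    genes = tfs + [f"G{i + 1:04d}" for i in range(params.n_genes - params.n_tfs)]
    mirnas = [f"miR-{i + 1:03d}" for i in range(params.n_mirnas)]
    return tfs, genes, mirnas


def generate(params: SimulationParams) -> tuple[InputBundle, GroundTruth]:
    """Generate a full input bundle and the matching ground truth."""
    p = params
    rng = np.random.default_rng(p.seed)
    tfs, genes, mirnas = _ids(p)
    non_tf_genes = [g for g in genes if g not in tfs]

    # ---- plan the planted structure -----------------------------------
    n_func = p.n_functional_per_mirna
    de_order = [f"down{i}" for i in range(p.n_de_down)] + \
               [f"up{i}" for i in range(p.n_de_mirnas - p.n_de_down)]
    # interleave down/up so both directions appear among the enriched miRNAs
    interleaved: list[str] = []
    downs = iter(m for m in de_order if m.startswith("down"))
    ups = iter(m for m in de_order if m.startswith("up"))
    for i in range(p.n_de_mirnas):
        tag = next(downs if i % 2 == 0 else ups, None) or \
              next(ups if i % 2 == 0 else downs)
        interleaved.append(tag)
    de_mirna_ids = mirnas[:p.n_de_mirnas]
    de_sign = {m: (-1 if tag.startswith("down") else +1)
               for m, tag in zip(de_mirna_ids, interleaved)}
    enriched = de_mirna_ids[:p.n_enriched_mirnas]

    n_secondary = p.n_planted_ffl4 * p.ffl4_secondaries
    need = len(enriched) * n_func + n_secondary
    if need > len(non_tf_genes):
        raise ValueError(f"infeasible parameters: need {need} plantable genes "
                         f"but only {len(non_tf_genes)} are available")
    pool = list(non_tf_genes)
    functional: dict = {}
    branch: dict = {}
    for m in enriched:
        functional[m] = pool[:n_func]
        pool = pool[n_func:]
        for j, g in enumerate(functional[m]):
            branch[g] = "A" if j % 2 == 0 else "B"
    secondary_pool = pool[:n_secondary]
    background_genes = pool[n_secondary:]

    expressed_tfs = tfs[:p.n_tfs - p.n_unexpressed_tfs]
    if p.n_planted_ffl3 and (not enriched or not expressed_tfs):
        raise ValueError("cannot plant FFLs without enriched miRNAs and expressed TFs")
    if p.n_planted_ffl3 > len(enriched) * len(expressed_tfs):
        raise ValueError("more planted 3-node FFL pairs than available pairs")
    if p.n_planted_ffl4 > len(enriched) * len(expressed_tfs):
        raise ValueError("more planted 4-node FFL pairs than available pairs")

    ffl3_pairs = [(enriched[i % len(enriched)],
                   expressed_tfs[i % len(expressed_tfs)],
                   "A" if i % 2 == 0 else "B")
                  for i in range(p.n_planted_ffl3)]
    ffl4_pairs = [(enriched[i % len(enriched)],
                   expressed_tfs[(i + 3) % len(expressed_tfs)],
                   "A" if i % 2 == 1 else "B")
                  for i in range(p.n_planted_ffl4)]

    # ---- expression ----------------------------------------------------
    samples = [f"H{i + 1}" for i in range(p.n_samples_high)] + \
              [f"L{i + 1}" for i in range(p.n_samples_low)]
    groups = pd.Series(["high"] * p.n_samples_high + ["low"] * p.n_samples_low,
                       index=samples)
    is_high = np.array([g == "high" for g in groups], dtype=float)

    de_mirna_lfc = {m: de_sign[m] * max(rng.normal(p.de_lfc_mean, p.de_lfc_sd), 0.0)
                    for m in de_mirna_ids}
    target_lfc: dict = {}
    for m in enriched:
        for g in functional[m]:
            target_lfc[g] = -de_sign[m] * max(
                rng.normal(p.target_lfc_mean, p.target_lfc_sd), 0.0)
    for g in secondary_pool:
        target_lfc[g] = rng.choice([-1.0, 1.0]) * max(
            rng.normal(p.target_lfc_mean, p.target_lfc_sd), 0.0)

    def expr_matrix(features, baselines, lfcs) -> ExpressionMatrix:
        base = np.asarray(baselines)[:, None]
        effect = np.array([lfcs.get(f, 0.0) for f in features])[:, None] * is_high
        noise = rng.normal(0.0, p.noise_sd, size=(len(features), len(samples)))
        vals = pd.DataFrame(base + effect + noise, index=features, columns=samples)
        return ExpressionMatrix(vals, groups)

    mirna_base = rng.normal(p.baseline_mean, p.baseline_sd, size=p.n_mirnas)
    gene_base = rng.normal(p.baseline_mean, p.baseline_sd, size=p.n_genes)
    for i, g in enumerate(genes):          # TFs: clearly expressed or clearly not
        if g in tfs:
            gene_base[i] = 6.0 if g not in expressed_tfs else \
                max(rng.normal(9.5, 0.3), 8.5)
    mirna_expr = expr_matrix(mirnas, mirna_base, de_mirna_lfc)
    mrna_expr = expr_matrix(genes, gene_base, target_lfc)

    # ---- target predictions -------------------------------------------
    pred_rows = []

    def strong_score() -> float:
        return float(rng.uniform(-0.5, -0.15))

    n_decoy_targets = p.targets_per_mirna - n_func
    for m in mirnas:
        if m in enriched:
            for g in functional[m]:
                pred_rows.append((m, g, strong_score()))
            decoys = rng.choice(background_genes, size=n_decoy_targets, replace=False)
        else:
            decoys = rng.choice(background_genes, size=p.targets_per_mirna,
                                replace=False)
        for g in decoys:
            pred_rows.append((m, str(g), strong_score()))
        # a few weak sites that the context-score filter must remove
        for g in rng.choice(background_genes, size=2, replace=False):
            pred_rows.append((m, str(g), float(rng.uniform(-0.09, -0.01))))
    predictions = pd.DataFrame(pred_rows, columns=["mirna", "gene", "context_score"])

    # ---- genome layout and TFBS ----------------------------------------
    w = p.promoter_halfwidth
    features = list(genes) + list(mirnas)
    tss_pos = {f: w + 1000 + i * TSS_SPACING for i, f in enumerate(features)}
    tss = pd.DataFrame({
        "feature": features,
        "kind": ["gene"] * len(genes) + ["mirna"] * len(mirnas),
        "chrom": "chr1",
        "tss": [tss_pos[f] for f in features],
        "strand": ["+" if i % 2 == 0 else "-" for i in range(len(features))],
    })

    tfbs_rows = []

    def plant_site(tf, feature):
        offset = int(rng.integers(-w, w - TFBS_LEN))
        s = tss_pos[feature] + offset
        tfbs_rows.append((tf, "chr1", s, s + TFBS_LEN))

    ffl3_triples = []
    for m, tf, b in ffl3_pairs:
        for g in functional[m]:
            if branch[g] == b:
                plant_site(tf, g)
                ffl3_triples.append((m, tf, g))
        plant_site(tf, m)      # the TF also drives the miRNA: full FFL

    ppi_pairs = set()
    ffl4_quads = []
    sec_iter = iter(secondary_pool)
    secondaries_used = []
    for m, tf, b in ffl4_pairs:
        primaries = [g for g in functional[m] if branch[g] == b]
        if not primaries:
            raise ValueError(f"no branch-{b} functional targets available "
                             f"for the planted 4-node pair ({m}, {tf})")
        for j in range(p.ffl4_secondaries):
            s = next(sec_iter)
            secondaries_used.append(s)
            plant_site(tf, s)
            # two interaction partners per secondary: the neighborhood
            # survives the loss of any single primary target
            for shift in (0, 1):
                prim = primaries[(j + shift) % len(primaries)]
                ppi_pairs.add((prim, s))
                ffl4_quads.append((m, tf, prim, s))
        plant_site(tf, m)

    # background binding: each TF binds a random sprinkling of promoters
    for tf in tfs:
        n_bg = rng.binomial(len(genes), p.tf_bind_rate)
        for g in rng.choice(genes, size=n_bg, replace=False):
            plant_site(tf, str(g))
        for m in rng.choice(mirnas, size=rng.binomial(len(mirnas), p.tf_bind_rate),
                            replace=False):
            plant_site(tf, str(m))
    # decoys straddling a promoter edge: must NOT count as hits
    for _ in range(p.n_decoy_tfbs):
        tf = str(rng.choice(tfs))
        f = str(rng.choice(features))
        s = tss_pos[f] + w - TFBS_LEN // 2
        tfbs_rows.append((tf, "chr1", s, s + TFBS_LEN))
    tfbs = pd.DataFrame(tfbs_rows, columns=["tf", "chrom", "start", "end"]
                        ).drop_duplicates().reset_index(drop=True)

    # ---- PPI ------------------------------------------------------------
    n_bg_edges = rng.binomial(len(genes) * (len(genes) - 1) // 2, p.ppi_edge_prob)
    idx_pairs = rng.integers(0, len(genes), size=(n_bg_edges, 2))
    for a, b in idx_pairs:
        if a != b:
            ppi_pairs.add((genes[a], genes[b]))
    ppi = PPINetwork.from_pairs(ppi_pairs)

    # ---- GO --------------------------------------------------------------
    parents = {GO_ROOT: set()}
    leaves = {"A": [], "B": []}
    for b, broot in GO_BRANCH.items():
        parents[broot] = {GO_ROOT}
        for j in range(p.go_leaves_per_branch):
            leaf = f"GO:{GO_LEAF_BASE[b] * 100000 + j + 1:07d}"
            parents[leaf] = {broot}
            leaves[b].append(leaf)
    dag = GODag(parents, namespace="biological_process")

    direct: dict = {}

    def annotate(gene, b):
        n_terms = int(rng.integers(p.go_annotations_min, p.go_annotations_max + 1))
        terms = set(rng.choice(leaves[b], size=min(n_terms, len(leaves[b])),
                               replace=False))
        if rng.random() < p.go_noise:
            other = "B" if b == "A" else "A"
            terms.add(str(rng.choice(leaves[other])))
        direct[gene] = {str(t) for t in terms}

    functional_all = [g for m in enriched for g in functional[m]]
    n_unann = int(round(p.go_unannotated_fraction * len(functional_all)))
    unannotated = set(rng.choice(functional_all, size=n_unann, replace=False)) \
        if n_unann else set()
    for g in functional_all:
        if g not in unannotated:
            annotate(g, branch[g])
    n_bg_ann = min(p.n_background_annotated, len(background_genes))
    for g in background_genes[:n_bg_ann]:
        annotate(str(g), str(rng.choice(["A", "B"])))
    for tf in tfs:
        annotate(tf, str(rng.choice(["A", "B"])))
    annot = GOAnnotationSet(direct)

    bundle = InputBundle(mirna_expr=mirna_expr, mrna_expr=mrna_expr,
                         predictions=predictions, tfbs=tfbs, tss=tss, ppi=ppi,
                         go_dag=dag, go_annotations=annot)
    truth = GroundTruth(
        de_mirnas=de_mirna_lfc,
        enriched_mirnas=list(enriched),
        functional_pairs=[(m, g) for m in enriched for g in functional[m]],
        target_lfc=target_lfc,
        branch={g: branch[g] for g in functional_all},
        ffl3=sorted(set(ffl3_triples)),
        ffl4=sorted(set(ffl4_quads)),
        ffl3_pairs=[(m, tf, b) for m, tf, b in ffl3_pairs],
        ffl4_pairs=[(m, tf, b) for m, tf, b in ffl4_pairs],
        secondaries=sorted(set(secondaries_used)),
    )
    logger.info("generated bundle: %d miRNAs, %d genes, %d predictions, "
                "%d TFBS, %d PPI edges", p.n_mirnas, p.n_genes,
                len(predictions), len(tfbs), len(ppi))
    return bundle, truth


def null_dataset(params: SimulationParams) -> tuple[InputBundle, GroundTruth]:
    """The same structural bundle with zero planted effects anywhere."""
    null_params = dataclasses.replace(
        params, n_de_mirnas=0, n_de_down=0, n_enriched_mirnas=0,
        n_planted_ffl3=0, n_planted_ffl4=0,
        de_lfc_mean=0.0, de_lfc_sd=0.0, target_lfc_mean=0.0, target_lfc_sd=0.0)
    return generate(null_params)
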