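"""Pipeline configuration: every filtering threshold in one place.

The defaults encode the analysis conditions of the osteosarcoma proliferation
study design this pipeline implements: strict BH-FDR + fold-change filtering
for miRNAs, a loose uncorrected filter for mRNAs (miRNA-driven expression
shifts are subtle), a TargetScan-style context-score cutoff for predicted
target sites, symmetric +/-2 kb promoter windows, and an FDR of 0.2 for the
feed-forward-loop pair tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence


@dataclass
class PipelineConfig:
    #: miRNA differential expression: BH-FDR < mirna_fdr and |log2FC| >= mirna_abs_lfc
    mirna_fdr: float = 0.05
    mirna_abs_lfc: float = 1.0
    #: mRNA differential expression: raw p < mrna_p and |log2FC| >= mrna_abs_lfc
    mrna_p: float = 0.05
    mrna_abs_lfc: float = 0.7
    #: keep predicted target sites with context score <= context_score_max
    context_score_max: float = -0.1
    #: fraction of highest-variance miRNA probes kept before testing
    variance_keep_fraction: float = 0.75
    #: a TF counts as expressed if its mean log2 intensity reaches this in >=1 group
    tf_expression_log2: float = 8.0
    #: promoter = [tss - w, tss + w], w in nucleotides
    promoter_halfwidth: int = 2000
    #: BH-FDR cutoff for miRNA-TF pair tests (per cluster x motif-type family)
    ffl_fdr: float = 0.2
    #: BH-FDR cutoff for GO / gene-set over-representation
    enrich_fdr: float = 0.05
    #: permutations for the enrichment-score and coexpression null distributions
    n_permutations: int = 1000
    #: hub calling: top fraction by degree within each node type
    hub_fraction_mirna: float = 0.25
    hub_fraction_tf: float = 0.25
    hub_fraction_target: float = 0.05
    #: FANNY model-selection grids
    fuzziness_grid: Sequence[float] = (1.1, 1.2, 1.3, 1.4, 1.5)
    k_grid: Sequence[int] = tuple(range(2, 16))
    #: whether enrichment counts only inverse-direction DE targets ("inverse")
    #: or any DE predicted target ("any")
    enrichment_direction: str = "inverse"
    #: GO similarity aggregation across a gene pair's term sets
    similarity_aggregation: str = "bma"
    #: random-walk length for walktrap community detection
    walktrap_steps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("variance_keep_fraction", "hub_fraction_mirna",
                     "hub_fraction_tf", "hub_fraction_target"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.fuzziness_grid = tuple(float(r) for r in self.fuzziness_grid)
        self.k_grid = tuple(int(k) for k in self.k_grid)
        if not self.fuzziness_grid or not self.k_grid:
            raise ValueError("fuzziness_grid and k_grid must be non-empty")
        if any(r <= 1 for r in self.fuzziness_grid):
            raise ValueError("fuzziness exponents must be > 1")
        if any(k < 2 for k in self.k_grid):
            raise ValueError("cluster numbers must be >= 2")
        if self.enrichment_direction not in ("inverse", "any"):
            raise ValueError("enrichment_direction must be 'inverse' or 'any'")
        if self.similarity_aggregation not in ("bma", "max"):
            raise ValueError("similarity_aggregation must be 'bma' or 'max'")
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be positive")

    # -- flat key=value config files ------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` text file; unknown keys are an error."""
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_value(key, val)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(key: str, val: str):
    if key in ("fuzziness_grid", "k_grid"):
        parts = [p for p in val.split(",") if p.strip()]
        return tuple(float(p) if "." in p else int(p) for p in parts)
    if key in ("enrichment_direction", "similarity_aggregation"):
        return val
    if key in ("promoter_halfwidth", "n_permutations", "seed", "walktrap_steps"):
        return int(val)
    return float(val)
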