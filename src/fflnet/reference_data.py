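"""Published differential-expression results used as a worked example.

The table below lists the 17 miRNAs reported as differentially expressed
between high- and low-proliferative osteosarcoma cell lines (log2 fold
change, high minus low, and BH-FDR), together with the downstream summary
counts of that analysis: which five miRNAs failed the target-gene enrichment
screen, and how the 474 target genes of the remaining twelve miRNAs split
into the two functional clusters (plus the targets without usable GO
biological-process annotation).

These printed numbers serve as inputs for exercising the pipeline's filter
logic on real reported values; they are not recomputed from raw data here.
"""

from __future__ import annotations

import pandas as pd

from . import diffexpr

_DE_ROWS = [
    ("miR-181a", -2.28, 0.000013),
    ("miR-9-3p", -2.01, 0.00443),
    ("miR-181d", -1.82, 0.000028),
    ("miR-138", -1.81, 0.03828),
    ("miR-214", -1.59, 0.03083),
    ("miR-9-5p", -1.44, 0.00525),
    ("miR-181b", -1.17, 0.000028),
    ("let-7f", -1.09, 0.00211),
    ("miR-92b", -1.06, 0.000149),
    ("miR-130a", 2.77, 0.00698),
    ("miR-21-5p", 2.31, 0.03760),
    ("miR-155", 2.05, 0.00382),
    ("miR-222", 1.87, 0.00698),
    ("miR-221", 1.45, 0.00823),
    ("miR-100", 1.26, 0.03827),
    ("miR-21-3p", 1.23, 0.03760),
    ("miR-151-5p", 1.00, 0.00698),
]

#: miRNAs whose predicted targets were not enriched among the DE genes
ENRICHMENT_EXCLUDED = ("miR-92b", "let-7f", "miR-9-3p", "miR-151-5p", "miR-100")

#: functional-cluster sizes of the retained miRNAs' target genes
CLUSTER_SIZES = {"C1": 172, "C2": 212}
UNANNOTATED_TARGETS = 90


def de_mirna_table() -> pd.DataFrame:
    """The published DE miRNA table as a DE-table DataFrame (fdr + log2fc)."""
    df = pd.DataFrame(_DE_ROWS, columns=["feature", "log2fc", "fdr"])
    df["direction"] = df["log2fc"].map(lambda x: "up" if x >= 0 else "down")
    return df.set_index("feature")


def de_summary(fdr_max: float = 0.05, abs_lfc_min: float = 1.0) -> dict:
    """Recompute the headline counts from the printed table via filter_de."""
    table = de_mirna_table()
    de = diffexpr.filter_de(table.assign(p=table["fdr"]), "fdr",
                            fdr_max, abs_lfc_min)
    retained = [m for m in de.index if m not in ENRICHMENT_EXCLUDED]
    return {
        "n_de": len(de),
        "n_down": int((de["direction"] == "down").sum()),
        "n_up": int((de["direction"] == "up").sum()),
        "n_retained": len(retained),
        "n_excluded": len(de) - len(retained),
        "n_target_genes": sum(CLUSTER_SIZES.values()) + UNANNOTATED_TARGETS,
    }
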