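"""External-knowledge overlay: pathway-grouped correlation matrices with a
direct-reaction mask, and mutation/CNV cross-referencing of outlier pairs.

The overlay arranges the screened robust correlations as a gene-by-compound
matrix whose rows and columns are grouped by pathway (the top pathways by
gene count), with a boolean mask marking cells where a curated reaction
directly couples the gene and the compound. Comparing the two answers how
many of the high robust correlations correspond to annotated direct
reactions versus candidate indirect relationships.

Cross-referencing matches each outlier-driven pair against mutation and
copy-number tables: a hit requires the same gene AND a flagged cell line,
i.e. the genomic event sits in exactly the sample that manufactured the
inflated Pearson correlation.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["overlay_matrix", "crossref_structural", "annotation_coverage",
           "top_pathways_by_genes"]


def top_pathways_by_genes(annotation: pd.DataFrame, k: int) -> list[str]:
    """The ``k`` pathway names with the most distinct annotated genes,
    largest first; ties break by pathway name."""
    counts = (annotation.groupby("pathway_name")["gene_id"].nunique()
              .reset_index(name="n_genes")
              .sort_values(["n_genes", "pathway_name"], ascending=[False, True]))
    return counts["pathway_name"].head(k).tolist()


def overlay_matrix(records: pd.DataFrame, annotation: pd.DataFrame,
                   top_pathways: int = 9
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pathway-grouped PQC matrix plus direct-reaction mask.

    Rows are (pathway, gene) and columns (pathway, compound) for the top
    ``top_pathways`` pathways ordered by number of distinct genes; features
    annotated to several pathways are duplicated per pathway block. Matrix
    cells carry the screened PQC (NaN where undefined or unscreened); mask
    cells are True where any annotation entry couples the row gene and the
    column compound. Returns ``(matrix, mask, orderings)``.
    """
    genes_seen = set(records["gene_id"])
    mets_seen = set(records["metabolite_id"])
    ann = annotation[annotation["gene_id"].isin(genes_seen)
                     & annotation["compound_id"].isin(mets_seen)]
    if ann.empty:
        warnings.warn("annotation and screened records share no gene/compound ids; "
                      "overlay matrix is empty")
        empty = pd.DataFrame()
        return empty, empty, {"pathways": [], "rows": [], "cols": []}

    pathways = top_pathways_by_genes(ann, top_pathways)
    ann = ann[ann["pathway_name"].isin(pathways)]
    rank = {p: i for i, p in enumerate(pathways)}

    rows = sorted({(p, g) for p, g in zip(ann["pathway_name"], ann["gene_id"])},
                  key=lambda t: (rank[t[0]], t[1]))
    cols = sorted({(p, c) for p, c in zip(ann["pathway_name"], ann["compound_id"])},
                  key=lambda t: (rank[t[0]], t[1]))
    row_index = pd.MultiIndex.from_tuples(rows, names=["pathway", "gene_id"])
    col_index = pd.MultiIndex.from_tuples(cols, names=["pathway", "compound_id"])

    pqc = records.set_index(["gene_id", "metabolite_id"])["pqc"]
    pqc = pqc[~pqc.index.duplicated()]
    matrix = pd.DataFrame(
        [[pqc.get((g, c), np.nan) for _, c in cols] for _, g in rows],
        index=row_index, columns=col_index, dtype=float)

    # only entries naming a specific reaction are masked; entries with an
    # empty reaction id contribute pathway membership (row/column placement)
    reacting = ann[ann["reaction_id"].fillna("").astype(str) != ""]
    linked = set(zip(reacting["gene_id"], reacting["compound_id"]))
    mask = pd.DataFrame(
        [[(g, c) in linked for _, c in cols] for _, g in rows],
        index=row_index, columns=col_index, dtype=bool)
    return matrix, mask, {"pathways": pathways, "rows": rows, "cols": cols}


def crossref_structural(records: pd.DataFrame, flags: pd.DataFrame,
                        mutations: pd.DataFrame,
                        cnv: pd.DataFrame) -> pd.DataFrame:
    """Match outlier-driven pairs to mutation/CNV rows on gene + flagged line.

    ``flags`` is the long-format outlier table (``gene_id, metabolite_id,
    sample_id, flagged``). One output row per (pair, knowledge row) match,
    columns ``gene_id, metabolite_id, cell_line, source, copy_number, pcc``,
    ordered by the pair's PCC descending.
    """
    out_cols = ["gene_id", "metabolite_id", "cell_line", "source",
                "copy_number", "pcc"]
    called = records[records["category"] == "outlier_driven"]
    if called.empty or flags.empty:
        return pd.DataFrame(columns=out_cols)
    flagged = flags[flags["flagged"].astype(int) == 1]
    flagged_of: dict[tuple[str, str], set] = {}
    for g, m, s in zip(flagged["gene_id"], flagged["metabolite_id"],
                       flagged["sample_id"]):
        flagged_of.setdefault((g, m), set()).add(s)

    rows = []
    for rec in called.itertuples(index=False):
        key = (rec.gene_id, rec.metabolite_id)
        lines = flagged_of.get(key, set())
        if not lines:
            continue
        if len(mutations):
            hits = mutations[(mutations["gene_id"] == rec.gene_id)
                             & (mutations["cell_line"].isin(lines))]
            for h in hits.itertuples(index=False):
                rows.append({"gene_id": rec.gene_id,
                             "metabolite_id": rec.metabolite_id,
                             "cell_line": h.cell_line, "source": "mutation",
                             "copy_number": np.nan, "pcc": rec.pcc})
        if len(cnv):
            hits = cnv[(cnv["gene_id"] == rec.gene_id)
                       & (cnv["cell_line"].isin(lines))]
            for h in hits.itertuples(index=False):
                rows.append({"gene_id": rec.gene_id,
                             "metabolite_id": rec.metabolite_id,
                             "cell_line": h.cell_line, "source": "cnv",
                             "copy_number": float(h.copy_number), "pcc": rec.pcc})
    out = pd.DataFrame(rows, columns=out_cols)
    return out.sort_values(["pcc", "gene_id", "metabolite_id", "cell_line"],
                           ascending=[False, True, True, True], kind="mergesort",
                           na_position="last", ignore_index=True)


def annotation_coverage(records: pd.DataFrame, annotation: pd.DataFrame,
                        pqc_high: float = 0.5) -> dict:
    """How many annotated direct pairs reach a high robust correlation, and
    how many high-PQC pairs lack any annotation (indirect candidates)."""
    direct = set(zip(annotation["gene_id"], annotation["compound_id"]))
    keyed = records.set_index(["gene_id", "metabolite_id"])
    present = [p for p in direct if p in keyed.index]
    pqc = keyed["pqc"]
    defined = [p for p in present if not pd.isna(pqc.get(p))]
    high_annotated = [p for p in defined if pqc.get(p) >= pqc_high]
    with np.errstate(invalid="ignore"):
        high_all = records[records["pqc"].to_numpy(dtype=float) >= pqc_high]
    high_pairs = set(zip(high_all["gene_id"], high_all["metabolite_id"]))
    return {
        "n_direct_annotated": len(present),
        "n_direct_defined": len(defined),
        "n_direct_high_pqc": len(high_annotated),
        "n_high_pqc_total": len(high_pairs),
        "n_high_pqc_unannotated": len(high_pairs - direct),
    }
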