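"""Decision rules separating steady-state associations from outlier-driven pairs.

A pair is *outlier-driven* when its Pearson correlation is high while the
robust quadrant correlation is near zero, fewer than three multidimensional
outliers were found, and the Pearson correlation collapses once they are
removed: the high PCC is then an artifact of one or two extreme cell lines,
the screening signature of a cell-line-specific genomic event. A pair is a
*robust association* when both estimators are high, indicating a
steady-state gene-metabolite coupling shared across the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["DecisionThresholds", "classify_pair", "classify_table",
           "rank_candidates", "screen_report", "CATEGORIES"]

CATEGORIES = ("robust_association", "outlier_driven", "none", "insufficient_n")


@dataclass(frozen=True)
class DecisionThresholds:
    """Rule cutoffs; the outlier rule is PCC > 0.6, PQC < 0.3, outliers < 3,
    post-removal PCC < 0.3. Inequalities are strict: boundary values fall
    through to the next rule."""

    pcc_outlier_min: float = 0.6
    pqc_outlier_max: float = 0.3
    max_outliers: int = 3          # exclusive bound: "smaller than 3"
    pqc_assoc_min: float = 0.5
    pcc_assoc_min: float = 0.3
    pcc_rm_max: float = 0.3

    def validate(self) -> None:
        for name in ("pcc_outlier_min", "pqc_outlier_max", "pqc_assoc_min",
                     "pcc_assoc_min", "pcc_rm_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pqc_outlier_max >= self.pqc_assoc_min:
            raise ValueError("pqc_outlier_max must be below pqc_assoc_min")
        if self.max_outliers < 0:
            raise ValueError("max_outliers must be >= 0")


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v)


def classify_pair(rec: Mapping, th: DecisionThresholds = DecisionThresholds()) -> str:
    """Assign one category to a pair record (mapping or DataFrame row).

    ``insufficient_n`` passes through unchanged. A rule whose operands are
    undefined is not satisfied (the reason is logged at debug level); the
    pair then falls through toward ``none`` rather than being coerced.
    """
    if rec.get("category", "") == "insufficient_n":
        return "insufficient_n"
    pcc, pqc = rec.get("pcc"), rec.get("pqc")
    n_out, pcc_rm = rec.get("n_outliers"), rec.get("pcc_rm")

    outlier_ops = (pcc, pqc, n_out, pcc_rm)
    if any(_is_na(v) for v in outlier_ops):
        if not _is_na(pcc) and not _is_na(pqc) and \
                pcc > th.pcc_outlier_min and pqc < th.pqc_outlier_max:
            log.debug("pair %s~%s: outlier rule operands undefined, not applied",
                      rec.get("gene_id"), rec.get("metabolite_id"))
    elif (pcc > th.pcc_outlier_min and pqc < th.pqc_outlier_max
          and int(n_out) < th.max_outliers and pcc_rm < th.pcc_rm_max):
        return "outlier_driven"

    if not _is_na(pcc) and not _is_na(pqc) and \
            pqc >= th.pqc_assoc_min and pcc >= th.pcc_assoc_min:
        return "robust_association"
    return "none"


def classify_table(records: pd.DataFrame,
                   th: DecisionThresholds = DecisionThresholds()) -> pd.DataFrame:
    """Vectorized :func:`classify_pair` over a pair-statistics table."""
    th.validate()
    pcc = records["pcc"].to_numpy(dtype=float)
    pqc = records["pqc"].to_numpy(dtype=float)
    n_out = records["n_outliers"].to_numpy(dtype=float)
    pcc_rm = records["pcc_rm"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        outlier = ((pcc > th.pcc_outlier_min) & (pqc < th.pqc_outlier_max)
                   & (n_out < th.max_outliers) & (pcc_rm < th.pcc_rm_max))
        robust = (pqc >= th.pqc_assoc_min) & (pcc >= th.pcc_assoc_min)
    outlier &= ~(np.isnan(pcc) | np.isnan(pqc) | np.isnan(n_out) | np.isnan(pcc_rm))
    robust &= ~(np.isnan(pcc) | np.isnan(pqc))

    category = np.where(outlier, "outlier_driven",
                        np.where(robust, "robust_association", "none"))
    insufficient = records["category"].astype(str).to_numpy() == "insufficient_n"
    category = np.where(insufficient, "insufficient_n", category)
    out = records.copy()
    out["category"] = category
    return out


def rank_candidates(records: pd.DataFrame,
                    gene_subset: Iterable[str] | None = None,
                    by: str = "pcc") -> pd.DataFrame:
    """Stable descending sort by ``pcc`` or ``pqc``, optionally restricted to
    a gene subset (e.g. the genes carrying known mutations); ties break by
    ``(gene_id, metabolite_id)``, undefined statistics sort last."""
    if by not in ("pcc", "pqc"):
        raise ValueError("by must be 'pcc' or 'pqc'")
    sub = records
    if gene_subset is not None:
        sub = sub[sub["gene_id"].isin(set(gene_subset))]
    return sub.sort_values([by, "gene_id", "metabolite_id"],
                           ascending=[False, True, True], kind="mergesort",
                           na_position="last", ignore_index=True)


def _precision_recall(called: set, planted: set) -> tuple[float, float]:
    tp = len(called & planted)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return precision, recall


def screen_report(records: pd.DataFrame, truth=None) -> dict:
    """Per-category counts, plus precision/recall against planted truth.

    ``truth`` is a :class:`~gmscreen.synthdata.PanelTruth`; outlier-driven
    calls are scored against the planted outlier pairs and robust
    associations against the planted true pairs.
    """
    counts = {cat: int((records["category"] == cat).sum()) for cat in CATEGORIES}
    report: dict = {"counts": counts, "n_pairs": int(len(records))}
    if truth is not None:
        pairs_of = lambda df: set(zip(df["gene_id"], df["metabolite_id"]))
        called_out = pairs_of(records[records["category"] == "outlier_driven"])
        called_rob = pairs_of(records[records["category"] == "robust_association"])
        p, r = _precision_recall(called_out, pairs_of(truth.outlier_pairs))
        report["outlier_driven_precision"] = p
        report["outlier_driven_recall"] = r
        p, r = _precision_recall(called_rob, pairs_of(truth.true_pairs))
        report["robust_association_precision"] = p
        report["robust_association_recall"] = r
    return report
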