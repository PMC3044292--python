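"""Classical and robust correlation of gene-metabolite pairs.

Two estimators are screened side by side over pairwise-complete samples:

* PCC — the Pearson correlation coefficient, efficient but inflated by a
  single extreme cell line;
* PQC — the pairwise quadrant correlation. With medians ``mx = med(x)`` and
  ``my = med(y)`` over the complete pairs, the raw statistic is

      q = (1/n) * sum_i sign(x_i - mx) * sign(y_i - my)

  (values exactly at the median contribute zero) and the reported value is
  ``sin(pi * q / 2)``, which makes the quadrant statistic a consistent
  estimate of the correlation at the bivariate normal model and hence
  directly comparable in magnitude to the PCC.

A pair with high PCC but near-zero PQC is the screening signature of a
correlation manufactured by one or two extreme samples; a pair high on both
reflects a steady-state association shared across the panel.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["pearson", "quadrant_correlation", "screen_pairs"]

MIN_N = 3  # below this, any correlation is reported as undefined


def _complete(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask], int(mask.sum())


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Pearson correlation over pairwise-complete entries.

    Returns ``(r, n_complete)``; ``r`` is NaN when fewer than three complete
    pairs remain or either complete sub-vector is constant. Undefined values
    are propagated as missing, never coerced to zero.
    """
    xs, ys, n = _complete(x, y)
    if n < MIN_N:
        return float("nan"), n
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    sx = np.sqrt(np.dot(xs, xs))
    sy = np.sqrt(np.dot(ys, ys))
    if sx == 0.0 or sy == 0.0:
        return float("nan"), n
    return float(np.clip(np.dot(xs, ys) / (sx * sy), -1.0, 1.0)), n


def quadrant_correlation(x: Sequence[float], y: Sequence[float],
                         sine_transform: bool = True) -> tuple[float, int]:
    """Pairwise quadrant correlation over pairwise-complete entries.

    Returns ``(r, n_complete)`` with ``r = sin(pi*q/2)`` by default, or the
    raw sign statistic ``q`` when ``sine_transform`` is false; NaN when fewer
    than three complete pairs remain.
    """
    xs, ys, n = _complete(x, y)
    if n < MIN_N:
        return float("nan"), n
    u = np.sign(xs - np.median(xs))
    v = np.sign(ys - np.median(ys))
    q = float(np.dot(u, v)) / n
    r = float(np.sin(np.pi * q / 2.0)) if sine_transform else q
    return r, n


def _screen_one_metabolite(genes: np.ndarray, y: np.ndarray,
                           sine_transform: bool) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized PCC and PQC of every (complete) gene row against one
    metabolite vector; the metabolite's missing samples are dropped for all
    genes at once. Assumes the gene matrix itself has no missing values."""
    mask = ~np.isnan(y)
    n = int(mask.sum())
    p = genes.shape[0]
    if n < MIN_N:
        return np.full(p, np.nan), np.full(p, np.nan), n
    g = genes[:, mask]
    ys = y[mask]

    gc = g - g.mean(axis=1, keepdims=True)
    yc = ys - ys.mean()
    sg = np.sqrt(np.einsum("ij,ij->i", gc, gc))
    sy = np.sqrt(np.dot(yc, yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where((sg > 0) & (sy > 0), gc @ yc / (sg * sy), np.nan)
    pcc = np.clip(pcc, -1.0, 1.0)

    u = np.sign(g - np.median(g, axis=1, keepdims=True))
    v = np.sign(ys - np.median(ys))
    q = (u @ v) / n
    pqc = np.sin(np.pi * q / 2.0) if sine_transform else q
    return pcc, pqc, n


def screen_pairs(genes: pd.DataFrame, metabolites: pd.DataFrame,
                 min_complete: int = 10,
                 pair_list: Iterable[tuple[str, str]] | None = None,
                 sine_transform: bool = True) -> pd.DataFrame:
    """Compute PCC and PQC for gene x metabolite pairs of two aligned
    feature-by-sample matrices.

    Parameters
    ----------
    genes, metabolites
        Feature-by-sample matrices sharing the sample (column) axis.
    min_complete
        Pairs with fewer pairwise-complete samples are categorized
        ``insufficient_n`` (their statistics, where defined, are still
        reported).
    pair_list
        Optional explicit ``(gene_id, metabolite_id)`` subset to bound cost
        on large panels; default is the full cross product.

    Returns one row per pair ordered by ``(gene_id, metabolite_id)`` with
    columns ``gene_id, metabolite_id, n_complete, pcc, pqc, n_outliers,
    pcc_rm, pqc_rm, category``; the outlier columns are filled by the
    outliers stage and are NaN here.
    """
    if genes.empty or metabolites.empty:
        raise ValueError("empty input matrix")
    if list(genes.columns) != list(metabolites.columns):
        common = [c for c in genes.columns if c in set(metabolites.columns)]
        if not common:
            raise ValueError("gene and metabolite matrices share no samples")
        genes = genes[common]
        metabolites = metabolites[common]

    if pair_list is not None:
        pairs = sorted(set(pair_list))
        gene_ids = sorted({g for g, _ in pairs})
        met_ids = sorted({m for _, m in pairs})
        wanted = set(pairs)
    else:
        gene_ids = list(genes.index)
        met_ids = list(metabolites.index)
        wanted = None

    gmat = genes.loc[gene_ids].to_numpy(dtype=float)
    gene_has_nan = np.isnan(gmat).any()

    rows: list[dict] = []
    for mid in met_ids:
        y = metabolites.loc[mid].to_numpy(dtype=float)
        if not gene_has_nan:
            pcc, pqc, n = _screen_one_metabolite(gmat, y, sine_transform)
            n_arr = np.full(len(gene_ids), n)
        else:  # per-pair masks differ: fall back to the scalar kernels
            pcc = np.empty(len(gene_ids))
            pqc = np.empty(len(gene_ids))
            n_arr = np.empty(len(gene_ids), dtype=int)
            for i, gid in enumerate(gene_ids):
                pcc[i], n_arr[i] = pearson(gmat[i], y)
                pqc[i], _ = quadrant_correlation(gmat[i], y, sine_transform)
        for i, gid in enumerate(gene_ids):
            if wanted is not None and (gid, mid) not in wanted:
                continue
            rows.append({"gene_id": gid, "metabolite_id": mid,
                         "n_complete": int(n_arr[i]),
                         "pcc": float(pcc[i]), "pqc": float(pqc[i])})

    out = pd.DataFrame(rows, columns=["gene_id", "metabolite_id", "n_complete",
                                      "pcc", "pqc"])
    out = out.sort_values(["gene_id", "metabolite_id"], kind="mergesort",
                          ignore_index=True)
    out["n_outliers"] = np.nan
    out["pcc_rm"] = np.nan
    out["pqc_rm"] = np.nan
    out["category"] = np.where(out["n_complete"] < min_complete,
                               "insufficient_n", "")
    return out
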