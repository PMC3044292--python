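"""Synthetic cell-line panel generator with known ground truth.

Emulates the statistical structure of a public cancer cell-line panel carrying
both a microarray-based transcriptome matrix and a much noisier metabolome
matrix: ~57 samples in ~9 tissue-of-origin classes (one with only two
samples), thousands of gene features, a few hundred metabolite features split
into known (KEGG-style compound ids) and unknown ("X-####") compounds,
per-cell missingness in the metabolite matrix, planted linear gene-metabolite
couplings, planted single-sample extreme outlier pairs with a matching
mutation or copy-number record, and one or more high-heterogeneity classes.

Every random draw descends from one global seed through a fixed hierarchy of
named substreams, so a given seed yields bit-identical panels across runs and
adding a new component does not perturb the draws of earlier ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as gio

__all__ = ["PanelConfig", "OmicsPanel", "PanelTruth", "generate_panel",
           "write_panel", "read_panel"]

# fixed substream labels: order is part of the on-disk contract
_STREAMS = ("names", "genes", "metabolites", "pairs", "outliers",
            "missing", "annotation", "structural")

_DEFAULT_CLASS_NAMES = ("leukemia", "nsclc", "colon", "cns", "melanoma",
                        "ovarian", "renal", "breast", "prostate")


@dataclass(frozen=True)
class PanelConfig:
    """Generator settings; defaults mirror the reference panel's structure.

    ``gene_noise_sd`` < ``metabolite_noise_sd`` encodes the noise asymmetry
    between array-based transcriptome data and metabolite profiles.
    ``outlier_magnitude_sd`` is the displacement of the spiked sample in
    units of the residual (noise) SD of each coordinate.
    Classes listed in ``heterogeneous_classes`` have no stable
    tissue-of-origin signature: each of their samples borrows most of its
    class signature (mixing weight ``1 - 1/heterogeneity_factor``) from a
    randomly chosen donor class, leaving measurement noise untouched.
    """

    n_samples: int = 57
    class_sizes: tuple[int, ...] = (9, 8, 7, 7, 6, 6, 6, 6, 2)
    class_names: tuple[str, ...] = _DEFAULT_CLASS_NAMES
    n_genes: int = 10000
    n_metabolites_known: int = 124
    n_metabolites_unknown: int = 218
    gene_noise_sd: float = 0.5
    metabolite_noise_sd: float = 1.5
    missing_rate: float = 0.15
    n_true_pairs: int = 20
    true_pair_slope_range: tuple[float, float] = (0.8, 2.0)
    n_outlier_pairs: int = 10
    # exemplar outlier pairs in real panels reach PCC ~0.9 at n ~ 22-26,
    # which a single displaced sample only produces at >= ~12 residual SD
    outlier_magnitude_sd: float = 12.0
    spike_gene: bool = True
    heterogeneous_classes: tuple[int, ...] = (3, 5, 7)  # cns, ovarian, breast
    heterogeneity_factor: float = 4.0
    informative_gene_fraction: float = 0.1
    class_effect_sd: float = 1.0
    gene_baseline_mean: float = 8.0
    gene_baseline_sd: float = 1.5
    metabolite_baseline_mean: float = 10.0
    metabolite_baseline_sd: float = 2.0
    n_pathways: int = 12
    n_annotation_background: int = 50
    seed: int = 0

    @property
    def n_metabolites(self) -> int:
        return self.n_metabolites_known + self.n_metabolites_unknown

    def validate(self) -> None:
        if sum(self.class_sizes) != self.n_samples:
            raise ValueError(
                f"class_sizes sum to {sum(self.class_sizes)}, expected n_samples={self.n_samples}")
        if len(self.class_names) < len(self.class_sizes):
            raise ValueError("need at least one class name per class")
        if any(s <= 0 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("n_genes", "n_metabolites_known", "n_metabolites_unknown",
                     "n_true_pairs", "n_outlier_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gene_noise_sd < 0 or self.metabolite_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.outlier_magnitude_sd <= 0:
            raise ValueError("outlier_magnitude_sd must be > 0")
        if self.n_true_pairs + self.n_outlier_pairs > self.n_genes:
            raise ValueError("not enough genes to assign disjoint planted pairs")
        if self.n_true_pairs + self.n_outlier_pairs > self.n_metabolites:
            raise ValueError("not enough metabolites to assign disjoint planted pairs")
        if any(c < 0 or c >= len(self.class_sizes) for c in self.heterogeneous_classes):
            raise ValueError("heterogeneous_classes indices out of range")
        lo, hi = self.true_pair_slope_range
        if hi < lo:
            raise ValueError("true_pair_slope_range must be (lo, hi) with lo <= hi")

    def with_seed(self, seed: int) -> "PanelConfig":
        return replace(self, seed=seed)


@dataclass
class OmicsPanel:
    """Two feature-by-sample matrices plus sample and feature metadata."""

    genes: pd.DataFrame            # n_genes x n_samples, complete
    metabolites: pd.DataFrame      # n_metabolites x n_samples, NaN allowed
    samples: pd.DataFrame          # index sample_id, column 'class'
    metabolite_meta: pd.DataFrame  # index metabolite_id: known (bool), compound_id
    annotation: pd.DataFrame       # gene_id, compound_id, reaction_id, pathway_name

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def class_labels(self) -> pd.Series:
        return self.samples["class"]


@dataclass
class PanelTruth:
    """Planted ground truth used to score downstream recovery."""

    true_pairs: pd.DataFrame     # gene_id, metabolite_id, slope
    outlier_pairs: pd.DataFrame  # gene_id, metabolite_id, spiked_sample
    mutations: pd.DataFrame      # gene_id, cell_line
    cnv: pd.DataFrame            # gene_id, cell_line, copy_number
    class_labels: pd.Series


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


def generate_panel(config: PanelConfig) -> tuple[OmicsPanel, PanelTruth]:
    """Generate one panel and its ground truth; deterministic in config.seed."""
    config.validate()
    rngs = _substreams(config.seed)
    n, n_classes = config.n_samples, len(config.class_sizes)

    # --- sample ids and class labels (block layout, one block per class)
    class_of_sample = np.repeat(np.arange(n_classes), config.class_sizes)
    names = [config.class_names[k] for k in range(n_classes)]
    sample_ids = []
    for k, size in enumerate(config.class_sizes):
        sample_ids.extend(f"{names[k].upper()}_{j + 1}" for j in range(size))
    samples = pd.DataFrame({"class": [names[k] for k in class_of_sample]},
                           index=pd.Index(sample_ids, name="sample_id"))

    # heterogeneity = unstable class signature: each sample of a
    # heterogeneous class largely borrows the signature of another class
    # (mixing weight 1 - 1/heterogeneity_factor, a distinct donor per
    # sample), so the class has no consistent tissue signature of its own.
    # Measurement noise is NOT inflated: pairwise scatters stay clean and
    # heterogeneity shows up where it does in real panels - as poor
    # classifiability.
    het_sample = np.isin(class_of_sample, list(config.heterogeneous_classes))
    het_weight = max(0.0, 1.0 - 1.0 / config.heterogeneity_factor)

    # --- metabolite identifiers (known KEGG-style, unknown "X-####")
    rng = rngs["names"]
    known_ids = [f"C{i:05d}" for i in np.sort(
        rng.choice(np.arange(1, 100000), size=config.n_metabolites_known, replace=False))]
    unknown_ids = [f"X-{i}" for i in np.sort(
        rng.choice(np.arange(1000, 10000), size=config.n_metabolites_unknown, replace=False))]
    metabolite_ids = known_ids + unknown_ids
    gene_ids = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]

    # --- gene expression: baseline + class effects (informative genes) + noise
    rng = rngs["genes"]
    baseline = rng.normal(config.gene_baseline_mean, config.gene_baseline_sd,
                          size=config.n_genes)
    n_informative = int(round(config.informative_gene_fraction * config.n_genes))
    informative = np.sort(rng.choice(config.n_genes, size=n_informative, replace=False))
    effects = np.zeros((config.n_genes, n_classes))
    if n_informative:
        effects[informative] = rng.normal(0.0, config.class_effect_sd,
                                          size=(n_informative, n_classes))
    signature = effects[:, class_of_sample]
    if n_informative and het_sample.any() and het_weight > 0 and n_classes > 1:
        for k in config.heterogeneous_classes:
            members = np.flatnonzero(class_of_sample == k)
            others = np.array([c for c in range(n_classes) if c != k])
            # distinct donors per sample where possible, so borrowed
            # signatures do not form recognisable sub-clusters
            donors = rng.choice(others, size=len(members),
                                replace=len(others) < len(members))
            for j, donor in zip(members, donors):
                signature[informative, j] = (
                    (1.0 - het_weight) * effects[informative, k]
                    + het_weight * effects[informative, int(donor)])
    expr = (baseline[:, None] + signature
            + rng.normal(0.0, 1.0, size=(config.n_genes, n)) * config.gene_noise_sd)

    # --- planted pair layout: disjoint genes and metabolites
    rng = rngs["pairs"]
    n_planted = config.n_true_pairs + config.n_outlier_pairs
    # couple true pairs to informative genes when available so metabolite
    # features inherit class structure, as enzyme-linked metabolites would
    pool = informative if n_informative >= config.n_true_pairs else np.arange(config.n_genes)
    true_genes = rng.choice(pool, size=config.n_true_pairs, replace=False)
    # outlier-pair genes avoid class-informative genes when possible so the
    # planted spike sits on a background free of class structure
    rest = np.setdiff1d(np.arange(config.n_genes),
                        np.concatenate([true_genes, informative]))
    if len(rest) < config.n_outlier_pairs:
        rest = np.setdiff1d(np.arange(config.n_genes), true_genes)
    outlier_genes = rng.choice(rest, size=config.n_outlier_pairs, replace=False)
    planted_mets = rng.choice(config.n_metabolites, size=n_planted, replace=False)
    true_mets, outlier_mets = planted_mets[:config.n_true_pairs], planted_mets[config.n_true_pairs:]
    lo, hi = config.true_pair_slope_range
    slopes = rng.uniform(lo, hi, size=config.n_true_pairs)

    # --- metabolite matrix: independent noise, then planted couplings
    rng = rngs["metabolites"]
    met_baseline = rng.normal(config.metabolite_baseline_mean,
                              config.metabolite_baseline_sd, size=config.n_metabolites)
    met = (met_baseline[:, None]
           + rng.normal(0.0, 1.0, size=(config.n_metabolites, n))
           * config.metabolite_noise_sd)
    for g, m, s in zip(true_genes, true_mets, slopes):
        centered = expr[g] - expr[g].mean()
        met[m] = met_baseline[m] + s * centered + (met[m] - met_baseline[m])

    # --- outlier pairs: background-uncorrelated rows with one spiked sample
    rng = rngs["outliers"]
    # distinct spiked samples (when possible): a cell-line-specific genomic
    # event hits one line, and shared spikes would couple unrelated pairs
    if config.n_outlier_pairs <= n:
        spiked = rng.choice(n, size=config.n_outlier_pairs, replace=False)
    else:
        spiked = rng.integers(0, n, size=config.n_outlier_pairs)
    for g, m, s_idx in zip(outlier_genes, outlier_mets, spiked):
        met[m, s_idx] += config.outlier_magnitude_sd * config.metabolite_noise_sd
        if config.spike_gene:
            expr[g, s_idx] += config.outlier_magnitude_sd * config.gene_noise_sd

    # --- missingness: MCAR per metabolite cell, spiked cells exempt
    rng = rngs["missing"]
    if config.missing_rate > 0.0:
        mask = rng.random(size=met.shape) < config.missing_rate
        mask[outlier_mets, spiked] = False
        met = np.where(mask, np.nan, met)

    genes_df = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids)
    mets_df = pd.DataFrame(met, index=pd.Index(metabolite_ids, name="metabolite_id"),
                           columns=sample_ids)
    meta = pd.DataFrame(
        {"known": [i < config.n_metabolites_known for i in range(config.n_metabolites)],
         "compound_id": metabolite_ids},
        index=pd.Index(metabolite_ids, name="metabolite_id"))

    # --- annotation: pathway membership per gene + direct-reaction entries
    rng = rngs["annotation"]
    weights = 1.0 / np.arange(1, config.n_pathways + 1)
    pathway_of_gene = rng.choice(config.n_pathways, size=config.n_genes,
                                 p=weights / weights.sum())
    pathway_names = [f"pathway_{k + 1:02d}" for k in range(config.n_pathways)]
    entries: list[dict] = []
    for g, m in zip(true_genes, true_mets):
        if m < config.n_metabolites_known:  # unknown compounds are never annotatable
            entries.append({"gene_id": gene_ids[g],
                            "compound_id": metabolite_ids[m],
                            "reaction_id": f"R{rng.integers(10000, 99999)}",
                            "pathway_name": pathway_names[pathway_of_gene[g]]})
    if config.n_annotation_background and config.n_metabolites_known:
        bg_genes = rng.integers(0, config.n_genes, size=config.n_annotation_background)
        bg_mets = rng.integers(0, config.n_metabolites_known,
                               size=config.n_annotation_background)
        for g, m in zip(bg_genes, bg_mets):
            entries.append({"gene_id": gene_ids[g],
                            "compound_id": metabolite_ids[m],
                            "reaction_id": f"R{rng.integers(10000, 99999)}",
                            "pathway_name": pathway_names[pathway_of_gene[g]]})
    annotation = pd.DataFrame(entries,
                              columns=["gene_id", "compound_id", "reaction_id",
                                       "pathway_name"]).drop_duplicates(
        subset=["gene_id", "compound_id", "reaction_id"], ignore_index=True)

    # --- structural truth: each outlier pair gets exactly one mutation OR CNV row
    rng = rngs["structural"]
    mut_rows, cnv_rows = [], []
    for j, (g, m, s_idx) in enumerate(zip(outlier_genes, outlier_mets, spiked)):
        if j % 2 == 0:
            mut_rows.append({"gene_id": gene_ids[g], "cell_line": sample_ids[s_idx]})
        else:
            cnv_rows.append({"gene_id": gene_ids[g], "cell_line": sample_ids[s_idx],
                             "copy_number": float(np.round(rng.uniform(4.0, 16.0), 2))})
    truth = PanelTruth(
        true_pairs=pd.DataFrame(
            {"gene_id": [gene_ids[g] for g in true_genes],
             "metabolite_id": [metabolite_ids[m] for m in true_mets],
             "slope": slopes}),
        outlier_pairs=pd.DataFrame(
            {"gene_id": [gene_ids[g] for g in outlier_genes],
             "metabolite_id": [metabolite_ids[m] for m in outlier_mets],
             "spiked_sample": [sample_ids[s] for s in spiked]}),
        mutations=pd.DataFrame(mut_rows, columns=["gene_id", "cell_line"]),
        cnv=pd.DataFrame(cnv_rows, columns=["gene_id", "cell_line", "copy_number"]),
        class_labels=samples["class"].copy(),
    )
    panel = OmicsPanel(genes=genes_df, metabolites=mets_df, samples=samples,
                       metabolite_meta=meta, annotation=annotation)
    return panel, truth


def write_panel(panel: OmicsPanel, truth: PanelTruth | None, directory: str) -> list[str]:
    """Write the panel (and optional truth) as the standard TSV file set."""
    os.makedirs(directory, exist_ok=True)
    paths = []

    def _p(name: str) -> str:
        path = os.path.join(directory, name)
        paths.append(path)
        return path

    gio.write_matrix(panel.genes, _p("genes.tsv"), index_label="gene_id")
    gio.write_matrix(panel.metabolites, _p("metabolites.tsv"), index_label="metabolite_id")
    gio.write_samples(panel.samples, _p("samples.tsv"))
    panel.metabolite_meta.to_csv(_p("metabolite_meta.tsv"), sep="\t",
                                 index_label="metabolite_id")
    gio.write_table(panel.annotation, _p("annotation.tsv"))
    if truth is not None:
        gio.write_table(truth.mutations, _p("mutations.tsv"))
        gio.write_table(truth.cnv, _p("cnv.tsv"))
        tp = truth.true_pairs.assign(kind="true", spiked_sample="")
        op = truth.outlier_pairs.assign(kind="outlier", slope=np.nan)
        all_pairs = pd.concat([tp, op], ignore_index=True)[
            ["gene_id", "metabolite_id", "kind", "slope", "spiked_sample"]]
        gio.write_table(all_pairs, _p("truth_pairs.tsv"))
    return paths


def read_panel(directory: str) -> tuple[OmicsPanel, PanelTruth | None]:
    """Read a panel written by :func:`write_panel` (truth files optional)."""
    genes = gio.read_matrix(os.path.join(directory, "genes.tsv"))
    mets = gio.read_matrix(os.path.join(directory, "metabolites.tsv"))
    samples = gio.read_samples(os.path.join(directory, "samples.tsv"))
    meta_path = os.path.join(directory, "metabolite_meta.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta["known"] = meta["known"].astype(bool)
    else:
        meta = pd.DataFrame({"known": [not str(i).startswith("X-") for i in mets.index],
                             "compound_id": mets.index}, index=mets.index)
    ann_path = os.path.join(directory, "annotation.tsv")
    if os.path.exists(ann_path):
        annotation = gio.read_table(ann_path)
    else:
        annotation = pd.DataFrame(columns=["gene_id", "compound_id", "reaction_id",
                                           "pathway_name"])
    panel = OmicsPanel(genes=genes, metabolites=mets, samples=samples,
                       metabolite_meta=meta, annotation=annotation)

    truth = None
    tp_path = os.path.join(directory, "truth_pairs.tsv")
    if os.path.exists(tp_path):
        tp = gio.read_table(tp_path)
        tp["spiked_sample"] = tp.get("spiked_sample", "").fillna("")
        mut_path = os.path.join(directory, "mutations.tsv")
        cnv_path = os.path.join(directory, "cnv.tsv")
        mutations = gio.read_table(mut_path) if os.path.exists(mut_path) else \
            pd.DataFrame(columns=["gene_id", "cell_line"])
        cnv = gio.read_table(cnv_path) if os.path.exists(cnv_path) else \
            pd.DataFrame(columns=["gene_id", "cell_line", "copy_number"])
        truth = PanelTruth(
            true_pairs=tp.loc[tp["kind"] == "true",
                              ["gene_id", "metabolite_id", "slope"]].reset_index(drop=True),
            outlier_pairs=tp.loc[tp["kind"] == "outlier",
                                 ["gene_id", "metabolite_id", "spiked_sample"]]
            .reset_index(drop=True),
            mutations=mutations, cnv=cnv, class_labels=samples["class"].copy())
    return panel, truth
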