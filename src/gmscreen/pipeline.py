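"""End-to-end orchestration of the screening pipeline.

Stages (mirrored 1:1 by the CLI subcommands):

    simulate -> correlate -> outliers -> screen -> classify -> annotate

Every stage reads and writes plain TSV in one run directory, so any stage
can be re-run or replaced by externally produced files with the same
columns. All stochastic stages are driven by the single configured seed
through named substreams; re-running with the same inputs and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from . import __version__
from .annotation import annotation_coverage, crossref_structural, overlay_matrix
from .classremoval import (backward_select, median_impute, progressive_removal,
                           random_removal_null)
from .correlation import screen_pairs
from .outliers import flag_outliers, recompute_after_removal, SingularScatterError
from .pairscreen import DecisionThresholds, classify_table, screen_report
from .synthdata import PanelConfig, generate_panel, read_panel, write_panel

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "correlate", "outliers", "screen", "classify", "annotate")


@dataclass
class PipelineConfig:
    outdir: str = "gmscreen_run"
    seed: int = 0
    min_complete: int = 10
    outlier_quantile: float = 0.975
    sine_transform: bool = True
    # which pairs get the (costly) MCD step: "candidates" restricts to pairs
    # already satisfying the high-PCC/low-PQC premise of the outlier rule
    outlier_scope: str = "candidates"
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)
    n_trees: int = 1000
    n_removal_steps: int = 3
    null_reps: int = 500
    drop_fraction: float = 0.2
    se_rule: float = 1.0
    top_pathways: int = 9
    synth: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # optional per-file path overrides

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        th = raw.pop("thresholds", {}) or {}
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if th:
            cfg.thresholds = DecisionThresholds(**th)
        return cfg

    def path(self, name: str) -> str:
        if name in self.inputs:
            return self.inputs[name]
        return os.path.join(self.outdir, name)

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, sort_keys=True, default=str))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (file locations excluded)."""
        d = self.canonical()
        d.pop("outdir", None)
        d.pop("inputs", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(cfg: PipelineConfig) -> None:
    synth = dict(cfg.synth)
    synth.setdefault("seed", cfg.seed)
    pconf = PanelConfig(**synth)
    panel, truth = generate_panel(pconf)
    write_panel(panel, truth, cfg.outdir)
    log.info("simulated panel: %d genes x %d samples, %d metabolites",
             len(panel.genes), len(panel.samples), len(panel.metabolites))


def _read_matrices(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = gio.read_matrix(cfg.path("genes.tsv"))
    mets = gio.read_matrix(cfg.path("metabolites.tsv"))
    return genes, mets


def stage_correlate(cfg: PipelineConfig) -> None:
    genes, mets = _read_matrices(cfg)
    records = screen_pairs(genes, mets, min_complete=cfg.min_complete,
                           sine_transform=cfg.sine_transform)
    gio.write_pairs(records, cfg.path("pairs.tsv"))
    log.info("correlate: %d pairs screened (min_complete=%d)",
             len(records), cfg.min_complete)


def stage_outliers(cfg: PipelineConfig) -> None:
    genes, mets = _read_matrices(cfg)
    records = gio.read_pairs(cfg.path("pairs.tsv"))
    th = cfg.thresholds
    if cfg.outlier_scope == "candidates":
        with np.errstate(invalid="ignore"):
            cand = ((records["pcc"].to_numpy(float) > th.pcc_outlier_min)
                    & (records["pqc"].to_numpy(float) < th.pqc_outlier_max)
                    & (records["category"].astype(str) != "insufficient_n"))
    elif cfg.outlier_scope == "all":
        cand = (records["category"].astype(str) != "insufficient_n").to_numpy()
    else:
        raise ValueError(f"unknown outlier_scope {cfg.outlier_scope!r}")
    sample_ids = list(genes.columns)

    flag_rows = []
    n_out = records["n_outliers"].copy()
    pcc_rm = records["pcc_rm"].copy()
    pqc_rm = records["pqc_rm"].copy()
    for i in np.flatnonzero(cand):
        gid = records.at[i, "gene_id"]
        mid = records.at[i, "metabolite_id"]
        if gid not in genes.index or mid not in mets.index:
            continue
        x = genes.loc[gid].to_numpy(float)
        y = mets.loc[mid].to_numpy(float)
        pair_seed = int(np.random.SeedSequence((cfg.seed, 11, int(i)))
                        .generate_state(1)[0] % (2 ** 31))
        try:
            flag = flag_outliers(x, y, quantile=cfg.outlier_quantile,
                                 min_complete=cfg.min_complete, seed=pair_seed,
                                 sample_ids=sample_ids, gene_id=gid,
                                 metabolite_id=mid)
        except SingularScatterError:
            log.warning("outliers: degenerate scatter for %s~%s, skipped", gid, mid)
            continue
        if flag is None:
            continue
        n_out.iloc[i] = len(flag.flagged_samples)
        rm = recompute_after_removal(x, y, flag, sample_ids=sample_ids,
                                     sine_transform=cfg.sine_transform)
        pcc_rm.iloc[i], pqc_rm.iloc[i] = rm
        for sid, dist in zip(flag.sample_ids, flag.robust_distance):
            flag_rows.append({"gene_id": gid, "metabolite_id": mid,
                              "sample_id": sid, "robust_distance": dist,
                              "cutoff": flag.cutoff,
                              "flagged": int(sid in set(flag.flagged_samples))})
    records["n_outliers"] = n_out
    records["pcc_rm"] = pcc_rm
    records["pqc_rm"] = pqc_rm
    gio.write_pairs(records, cfg.path("pairs.tsv"))
    flags = pd.DataFrame(flag_rows, columns=["gene_id", "metabolite_id",
                                             "sample_id", "robust_distance",
                                             "cutoff", "flagged"])
    gio.write_table(flags, cfg.path("outliers.tsv"), float_format="%.6g")
    log.info("outliers: MCD fit on %d candidate pairs (quantile=%.3f)",
             int(cand.sum()), cfg.outlier_quantile)


def stage_screen(cfg: PipelineConfig) -> None:
    records = gio.read_pairs(cfg.path("pairs.tsv"))
    cfg.thresholds.validate()
    log.info("screen: thresholds %s", cfg.thresholds)
    records = classify_table(records, cfg.thresholds)
    gio.write_pairs(records, cfg.path("pairs.tsv"))
    truth = None
    if os.path.exists(cfg.path("truth_pairs.tsv")):
        _, truth = read_panel(cfg.outdir)
    _write_json(screen_report(records, truth), cfg.path("screen_report.json"))


def stage_classify(cfg: PipelineConfig) -> None:
    _, mets = _read_matrices(cfg)
    samples = gio.read_samples(cfg.path("samples.tsv"))
    labels = samples.loc[list(mets.columns), "class"].to_numpy()
    x = median_impute(mets.to_numpy(float).T)  # samples x features

    n_classes = len(np.unique(labels))
    n_steps = min(cfg.n_removal_steps, n_classes - 2)
    traces = progressive_removal(x, labels, n_steps=n_steps,
                                 n_trees=cfg.n_trees, seed=cfg.seed)
    null = random_removal_null(x, labels, n_steps=n_steps, reps=cfg.null_reps,
                               n_trees=cfg.n_trees, seed=cfg.seed)
    rows = []
    for t, (null_mean, reps) in zip(traces, null):
        rows.append({"step": t.step,
                     "removed_class": t.removed_class or "",
                     "oob_error": t.oob_error,
                     "null_mean_oob": null_mean,
                     "null_reps": reps})
    gio.write_table(pd.DataFrame(rows), cfg.path("removal_trace.tsv"),
                    float_format="%.6g")

    selected, strace = backward_select(x, labels, drop_fraction=cfg.drop_fraction,
                                       se_rule=cfg.se_rule, n_trees=cfg.n_trees,
                                       seed=cfg.seed,
                                       feature_ids=list(mets.index))
    sel = pd.DataFrame({"feature_id": list(mets.index)})
    sel["selected"] = sel["feature_id"].isin(set(selected)).astype(int)
    gio.write_table(sel, cfg.path("selection.tsv"))
    gio.write_table(strace, cfg.path("selection_trace.tsv"), float_format="%.6g")
    log.info("classify: %d-step removal, %d features selected of %d",
             n_steps, len(selected), len(mets))


def stage_annotate(cfg: PipelineConfig) -> None:
    records = gio.read_pairs(cfg.path("pairs.tsv"))
    annotation = gio.read_table(cfg.path("annotation.tsv"),
                                required=["gene_id", "compound_id"])
    matrix, mask, _ = overlay_matrix(records, annotation,
                                     top_pathways=cfg.top_pathways)
    matrix.to_csv(cfg.path("matrix.tsv"), sep="\t", na_rep=gio.NA_TOKEN,
                  float_format="%.6g")
    mask.astype(int).to_csv(cfg.path("mask.tsv"), sep="\t")

    flags_path = cfg.path("outliers.tsv")
    flags = gio.read_table(flags_path) if os.path.exists(flags_path) else \
        pd.DataFrame(columns=["gene_id", "metabolite_id", "sample_id", "flagged"])
    mut_path, cnv_path = cfg.path("mutations.tsv"), cfg.path("cnv.tsv")
    mutations = gio.read_table(mut_path) if os.path.exists(mut_path) else \
        pd.DataFrame(columns=["gene_id", "cell_line"])
    cnv = gio.read_table(cnv_path) if os.path.exists(cnv_path) else \
        pd.DataFrame(columns=["gene_id", "cell_line", "copy_number"])
    matches = crossref_structural(records, flags, mutations, cnv)
    gio.write_table(matches, cfg.path("matches.tsv"), float_format="%.6g")
    _write_json(annotation_coverage(records, annotation,
                                    pqc_high=cfg.thresholds.pqc_assoc_min),
                cfg.path("coverage.json"))
    log.info("annotate: %d structural matches, overlay %s", len(matches),
             "x".join(map(str, matrix.shape)))


_STAGE_FN = {"simulate": stage_simulate, "correlate": stage_correlate,
             "outliers": stage_outliers, "screen": stage_screen,
             "classify": stage_classify, "annotate": stage_annotate}


def run_stage(name: str, cfg: PipelineConfig) -> None:
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}")
    os.makedirs(cfg.outdir, exist_ok=True)
    _STAGE_FN[name](cfg)


def run_all(cfg: PipelineConfig) -> None:
    os.makedirs(cfg.outdir, exist_ok=True)
    for name in STAGES:
        run_stage(name, cfg)
    _write_json({"tool": "gmscreen", "version": __version__,
                 "seed": cfg.seed, "config_hash": cfg.config_hash(),
                 "stages": list(STAGES)},
                os.path.join(cfg.outdir, "manifest.json"))
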