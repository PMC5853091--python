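"""End-to-end orchestration: simulate -> quantify -> QC -> regulon score ->
cluster -> markers -> scores, as one configured, logged, reproducible run.

A run is driven by a :class:`RunConfig` (YAML round-trippable).  One master
seed is fanned out deterministically to every stochastic stage, so re-running
an identical config reproduces byte-identical outputs; a ``manifest.json``
records parameters, seeds and a SHA-256 checksum of every stage output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, markers, qc, regulons as regmod, scores, strt, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "qc", "regulon_score",
          "cluster", "markers", "score")


@dataclass
class RunConfig:
    """All stage toggles and parameters of one pipeline run.

    Defaults follow the study thresholds where the study states them
    (min_genes 2000, min_cells 3, expressed >= 1, HVG mean > 1 and
    dispersion > 1, vote gates 0.6/0.55, 100 x 10-fold CV, power >= 0.4,
    log2 fold change >= 1, cell-cycle and hybrid thresholds 2, saturation
    fractions 10-90%).
    """

    seed: int = 0
    outdir: str = "run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulate: dict = field(default_factory=lambda: {
        "n_cells": 60, "n_genes": 200, "n_groups": 4,
        "markers_per_group": 6, "regulons_per_group": 2,
        "targets_per_regulon": 8, "mean_library_size": 800.0,
        "error_rate": 0.0, "duplicate_rate": 0.0,
    })
    quantify: dict = field(default_factory=lambda: {"k": 21, "hamming1_rescue": False})
    qc: dict = field(default_factory=lambda: {
        "min_genes_per_cell": 2000, "min_cells_per_gene": 3,
        "expressed_threshold": 1.0,
    })
    regulon_score: dict = field(default_factory=lambda: {"top_fraction": 0.05})
    cluster: dict = field(default_factory=lambda: {
        "mode": "binary", "train_gate": 0.6, "keep_gate": 0.55,
        "cv_runs": 100, "cv_folds": 10, "n_estimators": 500,
        "min_leaf": 10, "max_depth": 6, "split_quality_gate": 0.9,
    })
    markers: dict = field(default_factory=lambda: {
        "min_log2_diff": 1.0, "min_power": 0.4,
    })
    score: dict = field(default_factory=lambda: {
        "quiescent_threshold": 2.0, "hybrid_threshold": 2.0,
    })
    inputs: dict = field(default_factory=dict)  # paths for externally supplied data

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        for key, value in payload.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg


class DependencyError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(STAGES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Raises :class:`DependencyError` when a stage's upstream output is
    neither produced in this run nor supplied via ``config.inputs``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"seed": config.seed, "stage_seeds": seeds,
                "config": dataclasses.asdict(config), "outputs": {}}
    on = {s: config.stages.get(s, True) for s in STAGES}

    state: dict = {}

    def record(stage: str, paths: dict) -> None:
        manifest["outputs"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in paths.items()}

    if on["simulate"]:
        p = dict(config.simulate)
        gen_cfg = synthetic.GeneratorConfig(
            markers_per_group=p.get("markers_per_group", 6),
            regulons_per_group=p.get("regulons_per_group", 2),
            targets_per_regulon=p.get("targets_per_regulon", 8),
            mean_library_size=p.get("mean_library_size", 800.0))
        truth = synthetic.generate_truth_model(
            n_cells=p["n_cells"], n_genes=p["n_genes"],
            n_groups=p["n_groups"], config=gen_cfg, seed=seeds["simulate"])
        counts = synthetic.simulate_counts(truth, seed=seeds["simulate"] + 1)
        reference = synthetic.generate_reference(truth.gene_ids,
                                                 seed=seeds["simulate"] + 2)
        r1, r2 = outdir / "reads_R1.fastq", outdir / "reads_R2.fastq"
        whitelist = synthetic.simulate_fastq(
            truth, counts, reference, r1, r2,
            error_rate=p.get("error_rate", 0.0),
            duplicate_rate=p.get("duplicate_rate", 0.0),
            seed=seeds["simulate"] + 3)
        io.write_reference_fasta(reference, outdir / "reference.fasta")
        io.write_whitelist(whitelist, outdir / "whitelist.txt")
        io.write_regulons_tsv(truth.regulons, outdir / "regulons.tsv")
        synthetic.truth_labels_frame(truth).to_csv(outdir / "truth_labels.tsv",
                                                   sep="\t", index=False)
        paths = io.write_mtx(counts, outdir, prefix="truth_")
        paths.update({"r1": r1, "r2": r2,
                      "reference": outdir / "reference.fasta",
                      "whitelist": outdir / "whitelist.txt",
                      "regulons": outdir / "regulons.tsv",
                      "truth_labels": outdir / "truth_labels.tsv"})
        record("simulate", paths)
        state.update(truth=truth, reference=reference, whitelist=whitelist,
                     r1=r1, r2=r2, regulons=truth.regulons)

    if on["quantify"]:
        if "r1" not in state:
            if "r1" in config.inputs:
                state["r1"] = Path(config.inputs["r1"])
                state["r2"] = Path(config.inputs["r2"])
                state["reference"] = io.read_reference_fasta(config.inputs["reference"])
                state["whitelist"] = io.read_whitelist(config.inputs["whitelist"])
            else:
                raise DependencyError("quantify needs FASTQ from the simulate "
                                      "stage or config.inputs")
        counts, log = strt.quantify(state["r1"], state["r2"],
                                    state["whitelist"], state["reference"],
                                    **config.quantify)
        paths = io.write_mtx(counts, outdir, prefix="counts_")
        log_path = outdir / "quantify_log.json"
        log_path.write_text(json.dumps(log, indent=1))
        paths["log"] = log_path
        record("quantify", paths)
        state["counts"] = counts

    if on["qc"]:
        if "counts" not in state:
            if "counts_dir" in config.inputs:
                state["counts"] = io.read_mtx(config.inputs["counts_dir"],
                                              prefix=config.inputs.get("counts_prefix", ""))
            else:
                raise DependencyError("qc needs a count matrix from quantify "
                                      "or config.inputs")
        counts = state["counts"]
        nonzero = counts.sum(axis=0) > 0
        counts = counts.loc[:, nonzero]
        expr = qc.normalize(counts)
        expr_f, counts_f, report = qc.filter_cells_genes(expr, counts,
                                                         **config.qc)
        paths = io.write_mtx(expr_f, outdir, prefix="expr_")
        report_path = outdir / "qc_report.json"
        report_path.write_text(json.dumps(report, indent=1))
        paths["report"] = report_path
        record("qc", paths)
        state.update(expr=expr_f, counts_filtered=counts_f)

    if on["regulon_score"]:
        if "expr" not in state:
            raise DependencyError("regulon_score needs the qc stage output")
        if "regulons" not in state:
            if "regulons" in config.inputs:
                state["regulons"] = io.read_regulons_tsv(config.inputs["regulons"])
            else:
                raise DependencyError("regulon_score needs regulon definitions")
        usable = [r for r in state["regulons"]
                  if any(g in state["expr"].index for g in r.targets)]
        auc = regmod.auc_matrix(state["expr"], usable, **config.regulon_score)
        binary, thresholds = regmod.binarize(auc, random_state=seeds["regulon_score"])
        auc.to_csv(outdir / "regulon_auc.tsv", sep="\t")
        binary.to_csv(outdir / "regulon_binary.tsv", sep="\t")
        thresholds.to_csv(outdir / "regulon_thresholds.tsv", sep="\t")
        record("regulon_score", {"auc": outdir / "regulon_auc.tsv",
                                 "binary": outdir / "regulon_binary.tsv",
                                 "thresholds": outdir / "regulon_thresholds.tsv"})
        state["binary"] = binary

    if on["cluster"]:
        from .cluster import RecursiveRandomForestClusterer, leaf_assignment_frame
        p = dict(config.cluster)
        mode = p.pop("mode", "binary")
        if mode == "binary":
            if "binary" not in state:
                raise DependencyError("cluster (binary mode) needs regulon_score")
            matrix = state["binary"].T
        else:
            if "expr" not in state:
                raise DependencyError("cluster (expression mode) needs qc")
            matrix = state["expr"].T
        est = RecursiveRandomForestClusterer(mode=mode,
                                             random_state=seeds["cluster"], **p)
        est.fit(matrix)
        leaf_assignment_frame(est).to_csv(outdir / "leaves.tsv", sep="\t",
                                          index=False)
        tree_path = outdir / "cluster_tree.json"
        tree_path.write_text(json.dumps(est.tree_, indent=1, default=str))
        record("cluster", {"leaves": outdir / "leaves.tsv", "tree": tree_path})
        state["leaf_labels"] = pd.Series(est.labels_, index=matrix.index)

    if on["markers"]:
        if "leaf_labels" not in state or "expr" not in state:
            raise DependencyError("markers needs cluster and qc outputs")
        labels = state["leaf_labels"].reindex(state["expr"].columns)
        if labels.nunique() - (1 if (labels == -1).any() else 0) >= 2:
            table = markers.find_all_markers(state["expr"], labels,
                                             **config.markers)
        else:
            table = pd.DataFrame(columns=["gene", "cluster", "auc", "power",
                                          "log2_mean_diff", "direction"])
        table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        record("markers", {"markers": outdir / "markers.tsv"})

    if on["score"]:
        if "expr" not in state:
            raise DependencyError("score needs the qc stage output")
        if "panels" in config.inputs:
            panels = io.read_panels_tsv(config.inputs["panels"])
        elif "truth" in state and state["truth"].gradient_genes:
            panels = {name: scores.ScorePanel(name, tuple(genes))
                      for name, (genes, _) in state["truth"].gradient_genes.items()}
        else:
            panels = scores.load_default_panels()
        usable = {n: p for n, p in panels.items()
                  if any(g in state["expr"].index for g in p.genes)}
        table = scores.score_table(state["expr"], usable, **config.score)
        table.to_csv(outdir / "scores.tsv", sep="\t")
        record("score", {"scores": outdir / "scores.tsv"})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
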