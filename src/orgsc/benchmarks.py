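"""Synthetic-truth validation benchmarks used by the test suite and the
reproduction script.

Each function generates data with planted structure through
:mod:`orgsc.synthetic`, runs the relevant pipeline stage, and measures
recovery of the planted truth.  Run sizes (cells, genes, read counts, CV
repetitions, forest sizes) are desk-scale choices documented in the
methods note; the library defaults used in production runs are larger.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import markers, qc, regulons as regmod, scores, strt, synthetic
from .cluster import RecursiveRandomForestClusterer


def roundtrip_benchmark(seed: int = 0, n_cells: int = 50, n_genes: int = 200,
                        mean_library_size: float = 1000.0) -> dict:
    """Simulate error-free FASTQ, quantify, compare to planted counts.

    Returns the number of matrix entries that disagree (0 = exact
    identity) plus the scale of the comparison.
    """
    cfg = synthetic.GeneratorConfig(markers_per_group=6, regulons_per_group=2,
                                    targets_per_regulon=8,
                                    mean_library_size=mean_library_size)
    truth = synthetic.generate_truth_model(n_cells=n_cells, n_genes=n_genes,
                                           n_groups=4, config=cfg, seed=seed)
    counts = synthetic.simulate_counts(truth, seed=seed + 1)
    reference = synthetic.generate_reference(truth.gene_ids, seed=seed + 2)
    with tempfile.TemporaryDirectory() as tmp:
        r1, r2 = Path(tmp) / "r1.fq", Path(tmp) / "r2.fq"
        wl = synthetic.simulate_fastq(truth, counts, reference, r1, r2,
                                      error_rate=0.0, seed=seed + 3)
        recovered, log = strt.quantify(r1, r2, wl, reference)
    recovered.columns = counts.columns  # whitelist order == cell order
    recovered = recovered.loc[counts.index]
    return {
        "mismatched_entries": int((recovered.to_numpy()
                                   != counts.to_numpy()).sum()),
        "read_pairs": int(log["input_pairs"]),
        "planted_umis": int(counts.to_numpy().sum()),
    }


def dedup_oracle_benchmark(seed: int = 0, n_triples: int = 10_000) -> dict:
    """count_umis vs an independent set-cardinality oracle on random triples."""
    rng = np.random.default_rng(seed)
    triples = [(f"c{rng.integers(10)}", f"g{rng.integers(20)}",
                f"U{rng.integers(50)}") for _ in range(n_triples)]
    counted = strt.count_umis(triples)
    frame = pd.DataFrame(triples, columns=["cell", "gene", "umi"])
    oracle = (frame.drop_duplicates()
              .groupby(["gene", "cell"]).size().unstack(fill_value=0))
    oracle = oracle.reindex(index=counted.index, columns=counted.columns,
                            fill_value=0)
    return {
        "disagreements": int((counted.to_numpy() != oracle.to_numpy()).sum()),
        "n_triples": n_triples,
    }


def auc_oracle_benchmark(seed: int = 0, n_instances: int = 100) -> dict:
    """regulon_auc vs brute-force recovery-curve summation."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(50, 201))
        genes = [f"g{i}" for i in range(n)]
        expr = pd.Series(rng.random(n), index=genes)
        m = int(rng.integers(1, 15))
        members = list(rng.choice(genes, size=m, replace=False))
        reg = synthetic.Regulon("r", members[0], tuple(members))
        window = max(1, int(np.ceil(0.05 * n)))
        order = sorted(range(n), key=lambda i: (-expr.iloc[i], i))
        member_set = set(members)
        hits = area = 0
        for i in range(window):
            if genes[order[i]] in member_set:
                hits += 1
            area += hits
        best = sum(min(i + 1, m) for i in range(window))
        max_err = max(max_err, abs(regmod.regulon_auc(expr, reg) - area / best))
    return {"max_abs_error": float(max_err), "n_instances": n_instances}


def roc_oracle_benchmark(seed: int = 0, n_instances: int = 50) -> dict:
    """roc_power vs all-pairs enumeration, plus label-swap symmetry."""
    rng = np.random.default_rng(seed)
    max_err = max_sym = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 201))
        values = rng.integers(0, 10, size=n).astype(float)
        mask = rng.random(n) < 0.4
        if mask.all() or not mask.any():
            mask[0] = not mask[0]
        inside, outside = values[mask], values[~mask]
        wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
                   for a in inside for b in outside)
        expected = wins / (len(inside) * len(outside))
        auc, power = markers.roc_power(values, mask)
        max_err = max(max_err, abs(auc - expected),
                      abs(power - 2 * abs(expected - 0.5)))
        _, power_sw = markers.roc_power(values, ~mask)
        max_sym = max(max_sym, abs(power - power_sw))
    return {"max_abs_error": float(max_err),
            "max_swap_asymmetry": float(max_sym), "n_instances": n_instances}


def clustering_benchmark(seeds=range(5), cv_runs: int = 20,
                         n_estimators: int = 50,
                         n_cells_per_group: int = 100) -> dict:
    """Leaf-count and ARI recovery on the 4-group regulon-matrix benchmark."""
    leaves, aris = [], []
    for seed in seeds:
        mat, labels = synthetic.simulate_binary_regulon_matrix(
            n_cells_per_group=n_cells_per_group, n_groups=4, seed=seed)
        est = RecursiveRandomForestClusterer(
            cv_runs=cv_runs, n_estimators=n_estimators,
            random_state=seed).fit(mat)
        keep = est.labels_ >= 0
        leaves.append(est.n_leaves_)
        aris.append(float(adjusted_rand_score(labels[keep], est.labels_[keep])))
    return {
        "n_seeds": len(leaves),
        "leaf_counts": leaves,
        "aris": aris,
        "seeds_with_4_leaves_and_ari_ge_095": int(sum(
            (l == 4) and (a >= 0.95) for l, a in zip(leaves, aris))),
        "median_ari": float(np.median(aris)),
    }


def null_clustering_benchmark(seeds=range(5), cv_runs: int = 20,
                              n_estimators: int = 50,
                              n_cells: int = 400) -> dict:
    """Leaf count on a homogeneous (structure-free) binary matrix."""
    leaves = []
    for seed in seeds:
        mat, _ = synthetic.simulate_binary_regulon_matrix(
            n_groups=1, n_cells_per_group=n_cells, n_shared_regulons=40,
            seed=seed)
        est = RecursiveRandomForestClusterer(
            cv_runs=cv_runs, n_estimators=n_estimators,
            random_state=seed).fit(mat)
        leaves.append(est.n_leaves_)
    return {"n_seeds": len(leaves), "leaf_counts": leaves,
            "seeds_with_single_leaf": int(sum(l == 1 for l in leaves))}


def marker_recovery_benchmark(seeds=range(5), n_cells: int = 400,
                              n_genes: int = 300) -> dict:
    """Sensitivity / false-discovery proportion for planted fold-8 markers.

    Sensitivity counts planted group markers re-detected as up-markers of
    their group.  The false-discovery proportion counts detected up-markers
    with no planted between-group effect at all (regulon targets and
    subcluster markers are genuinely differential, so they are not false).
    """
    sens, fdps = [], []
    for seed in seeds:
        truth = synthetic.generate_truth_model(n_cells=n_cells,
                                               n_genes=n_genes, n_groups=4,
                                               seed=seed)
        counts = synthetic.simulate_counts(truth, seed=seed + 100)
        expr = qc.normalize(counts)
        table = markers.find_all_markers(expr, truth.group_labels)
        up = table[table["direction"] == "up"]
        found_up = set(zip(up["gene"], up["cluster"]))
        planted = {(g, grp) for grp, d in truth.marker_genes.items() for g in d}
        sens.append(len(planted & found_up) / len(planted))
        diff = truth.group_differential_genes()
        false = [g for g in up["gene"] if g not in diff]
        fdps.append(len(false) / max(1, len(up)))
    return {"n_seeds": len(sens), "sensitivities": sens, "fdps": fdps,
            "min_sensitivity": float(min(sens)), "max_fdp": float(max(fdps))}


def gradient_benchmark(seeds=range(10), slope: float = -2.0,
                       n_cells: int = 400, n_genes: int = 300) -> dict:
    """Score-vs-PC1 Pearson r for planted E/M/S pseudotime gradients.

    With ``slope=0`` this is the null control: panels carry no time trend
    and correlations should be near zero.
    """
    rs = {"E": [], "M": [], "S": []}
    for seed in seeds:
        cfg = synthetic.config_with_panels(
            {"E": slope, "M": slope, "S": slope}, genes_per_panel=12,
            markers_per_group=4, regulons_per_group=1, targets_per_regulon=6)
        truth = synthetic.generate_truth_model(n_cells=n_cells,
                                               n_genes=n_genes, n_groups=2,
                                               config=cfg, seed=seed)
        counts = synthetic.simulate_counts(truth, seed=seed + 100)
        expr = qc.normalize(counts)
        sub = expr.loc[:, truth.group_labels == "grp0"]
        panels = {name: scores.ScorePanel(name, tuple(genes))
                  for name, (genes, _) in truth.gradient_genes.items()}
        _, corr = scores.score_pseudotime_correlation(sub, panels)
        for name in rs:
            rs[name].append(float(corr[name]))
    out = {"n_seeds": len(next(iter(rs.values()))), "correlations": rs}
    if slope < 0:
        out["seeds_with_sign_and_magnitude"] = {
            name: int(sum(r <= -0.8 for r in values))
            for name, values in rs.items()}
    else:
        out["seeds_within_null_band"] = {
            name: int(sum(abs(r) <= 0.2 for r in values))
            for name, values in rs.items()}
    return out


def saturation_benchmark(seed: int = 0) -> dict:
    """Monotonicity and endpoint identity of the nested downsampling curve."""
    cfg = synthetic.GeneratorConfig(markers_per_group=4, regulons_per_group=1,
                                    targets_per_regulon=6,
                                    mean_library_size=400.0)
    truth = synthetic.generate_truth_model(n_cells=30, n_genes=120,
                                           n_groups=2, config=cfg, seed=seed)
    counts = synthetic.simulate_counts(truth, seed=seed + 1)
    reference = synthetic.generate_reference(truth.gene_ids, seed=seed + 2)
    with tempfile.TemporaryDirectory() as tmp:
        r1, r2 = Path(tmp) / "r1.fq", Path(tmp) / "r2.fq"
        wl = synthetic.simulate_fastq(truth, counts, reference, r1, r2,
                                      seed=seed + 3)
        stream = list(strt.assignment_stream(r1, r2, wl, reference))
    curve = qc.saturation_curve(stream, seed=seed)
    detected = curve["genes_detected"].to_numpy()
    full = curve.loc[curve["fraction"] == 1.0, "genes_detected"].iloc[0]
    ref_genes = int(curve["reference_genes"].iloc[0])
    half = curve.loc[curve["fraction"] == 0.5, "genes_detected"].iloc[0]
    return {
        "monotone_violations": int((np.diff(detected) < 0).sum()),
        "full_equals_reference": bool(int(full) == ref_genes),
        "reference_genes": ref_genes,
        "detected_fraction_at_half_depth": float(half / ref_genes),
    }
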