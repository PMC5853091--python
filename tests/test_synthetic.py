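"""Generator contracts: planted structure, NB moments, determinism, FASTQ."""

import numpy as np
import pandas as pd
import pytest

from orgsc import synthetic


def test_truth_model_plants_requested_group_structure(small_truth):
    assert len(set(small_truth.group_labels)) == 4
    groups = set(small_truth.group_labels)
    active = set()
    for reg in small_truth.regulons:
        active |= small_truth.regulon_active_groups[reg.name]
        assert reg.tf in reg.targets
    assert active == groups  # every group has at least one active regulon
    assert np.all((small_truth.pseudotime >= 0) & (small_truth.pseudotime <= 1))
    assert np.all(small_truth.library_sizes >= 1)


def test_truth_model_deterministic_for_fixed_seed():
    a = synthetic.generate_truth_model(n_cells=50, n_genes=200, n_groups=3, seed=5)
    b = synthetic.generate_truth_model(n_cells=50, n_genes=200, n_groups=3, seed=5)
    assert np.array_equal(a.group_labels, b.group_labels)
    assert np.allclose(a.pseudotime, b.pseudotime)
    assert a.marker_genes == b.marker_genes
    assert [r.name for r in a.regulons] == [r.name for r in b.regulons]
    assert np.allclose(a.baseline_expression, b.baseline_expression)


def test_truth_model_sizing_error_when_gene_pool_too_small():
    cfg = synthetic.GeneratorConfig(markers_per_group=4)
    with pytest.raises(ValueError, match="special genes"):
        synthetic.generate_truth_model(n_cells=20, n_genes=10, n_groups=5,
                                       config=cfg, seed=0)


def test_counts_marker_fold_recovered_from_nb_moments():
    """Empirical group-mean ratio of a fold-8 marker lands in [6, 10].

    Monte-Carlo check against the NB mean structure, averaged over 20
    replicate simulations with >= 100 cells per group.
    """
    cfg = synthetic.GeneratorConfig(markers_per_group=2, marker_fold=8.0,
                                    regulons_per_group=1, targets_per_regulon=4,
                                    n_maturation_genes=0, dispersion=0.2)
    truth = synthetic.generate_truth_model(n_cells=220, n_genes=150,
                                           n_groups=2, config=cfg, seed=3)
    gene = next(iter(truth.marker_genes["grp0"]))
    in_grp = truth.group_labels == "grp0"
    ratios = []
    for rep in range(20):
        counts = synthetic.simulate_counts(truth, seed=100 + rep)
        # compare on the depth-normalized scale so library sizes cancel
        frac = counts.loc[gene].to_numpy() / counts.sum(axis=0).to_numpy()
        ratios.append(frac[in_grp].mean() / frac[~in_grp].mean())
    assert 6 <= np.mean(ratios) <= 10


def test_counts_symmetric_when_no_effects_planted():
    cfg = synthetic.GeneratorConfig(markers_per_group=0, regulons_per_group=0,
                                    n_maturation_genes=0, library_size_cv=0.0,
                                    library_pseudotime_log2_slope=0.0)
    truth = synthetic.generate_truth_model(n_cells=300, n_genes=50,
                                           n_groups=2, config=cfg, seed=4)
    counts = synthetic.simulate_counts(truth, seed=5)
    in_grp = truth.group_labels == "grp0"
    m_in = counts.loc[:, in_grp].mean(axis=1)
    m_out = counts.loc[:, ~in_grp].mean(axis=1)
    # pooled-standard-error z-scores: no gene should deviate grossly
    se = np.sqrt(counts.loc[:, in_grp].var(axis=1) / in_grp.sum()
                 + counts.loc[:, ~in_grp].var(axis=1) / (~in_grp).sum())
    z = ((m_in - m_out) / se).abs()
    assert (z < 5).mean() > 0.98


def test_counts_totals_match_planted_library_sizes():
    truth = synthetic.generate_truth_model(n_cells=200, n_genes=150,
                                           n_groups=2, seed=6)
    counts = synthetic.simulate_counts(truth, seed=7)
    ratio = counts.sum(axis=0).to_numpy() / truth.library_sizes
    se = ratio.std(ddof=1) / np.sqrt(len(ratio))
    assert abs(ratio.mean() - 1) <= 3 * se


def test_reference_kmers_unique_across_genes():
    ref = synthetic.generate_reference([f"G{i}" for i in range(30)],
                                       length=300, k=21, seed=8)
    seen = {}
    for g in ref.gene_ids:
        s = ref.sequences[g]
        for i in range(len(s) - 20):
            km = s[i:i + 21]
            assert seen.setdefault(km, g) == g
    assert all(len(ref.sequences[g]) >= 200 for g in ref.gene_ids)


def test_fastq_emits_one_distinct_umi_per_planted_molecule(tmp_path):
    truth = synthetic.generate_truth_model(n_cells=6, n_genes=30, n_groups=2,
                                           config=synthetic.GeneratorConfig(
                                               markers_per_group=2,
                                               regulons_per_group=1,
                                               targets_per_regulon=3,
                                               n_maturation_genes=0,
                                               mean_library_size=50.0),
                                           seed=9)
    counts = synthetic.simulate_counts(truth, seed=10)
    ref = synthetic.generate_reference(truth.gene_ids, seed=11)
    r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
    wl = synthetic.simulate_fastq(truth, counts, ref, r1, r2,
                                  duplicate_rate=0.5, seed=12)
    layout = synthetic.ReadLayout()
    umis = {}
    cell_of = {bc: c for bc, c in zip(wl, counts.columns)}
    lines = r2.read_text().splitlines()
    names = [l[1:].split("/")[0] for l in lines[0::4]]
    for name, seq in zip(names, lines[1::4]):
        gene = name.split(":")[2]
        bc = seq[:layout.barcode_length]
        umi = seq[layout.umi_start:layout.umi_start + layout.umi_length]
        umis.setdefault((gene, cell_of[bc]), set()).add(umi)
    for (gene, cell), s in umis.items():
        assert len(s) == counts.loc[gene, cell]  # duplicates reuse UMIs


def test_fastq_byte_identical_for_fixed_seed(tmp_path):
    truth = synthetic.generate_truth_model(
        n_cells=4, n_genes=25, n_groups=2,
        config=synthetic.GeneratorConfig(markers_per_group=2,
                                         regulons_per_group=1,
                                         targets_per_regulon=3,
                                         n_maturation_genes=0,
                                         mean_library_size=40.0),
        seed=1)
    counts = synthetic.simulate_counts(truth, seed=2)
    ref = synthetic.generate_reference(truth.gene_ids, seed=3)
    outs = []
    for tag in ("a", "b"):
        r1, r2 = tmp_path / f"{tag}1.fq", tmp_path / f"{tag}2.fq"
        synthetic.simulate_fastq(truth, counts, ref, r1, r2, seed=42)
        outs.append((r1.read_bytes(), r2.read_bytes()))
    assert outs[0] == outs[1]


def test_fastq_layout_whitelist_mismatch_is_an_error(tmp_path, small_truth,
                                                     small_counts):
    ref = synthetic.generate_reference(small_truth.gene_ids, seed=1)
    with pytest.raises(ValueError, match="barcode"):
        synthetic.simulate_fastq(small_truth, small_counts, ref,
                                 tmp_path / "r1.fq", tmp_path / "r2.fq",
                                 whitelist=["ACGTAC"] * len(small_counts.columns),
                                 seed=2)
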