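# orgsc

Single-cell RNA-seq analysis tools for STRT-style (pooled barcode + UMI)
libraries, built around the regulon-activity workflow used to chart cell
types in early mouse organogenesis. The package takes raw paired FASTQ to
biology in five stages, each usable on its own:

1. **Quantification** (`orgsc.strt`) — demultiplex read 2 by its 8-nt
   cell barcode, trim the TSO prefix and poly-A tail from read 1, assign
   reads to genes, and count **distinct UMIs** per gene per cell, so PCR
   duplicates collapse to single molecules.
2. **QC and normalization** (`orgsc.qc`) — `log2(TPM/10 + 1)` with TPM =
   UMIs per million per cell; remove cells with < 2000 detected genes and
   genes expressed (≥ 1) in < 3 cells; select highly variable genes
   (mean > 1, dispersion > 1); saturation curves by nested read
   downsampling.
3. **Regulon activity** (`orgsc.regulons`) — score each cell for each
   regulon (a TF with its target set) by the area under the recovery
   curve of the cell's expression ranking,
   `AUC = Σᵢ R(i) / Σᵢ min(i, m)` over the top-5% window; binarize
   per-regulon AUC distributions with a two-component Gaussian mixture;
   rank cluster-specific TFs by activity difference.
4. **Clustering** (`orgsc.cluster`) — recursive bipartition: hierarchical
   clustering on 1 − Pearson r, random-forest feature selection, a
   training set gated at held-out vote probability > 0.6, relabeling by
   the resulting classifier, and 100 × 10-fold CV discarding samples
   voting < 0.55 for their class; recursion into each child. Exposed as
   the sklearn-style estimator `RecursiveRandomForestClusterer`.
5. **Markers and scores** (`orgsc.markers`, `orgsc.scores`) — one-vs-rest
   markers by ROC classification power (`power = 2·|AUC − ½|`, gates
   power ≥ 0.4 and |log2FC| ≥ 1); epithelial/mesenchymal/stemness and
   cell-cycle panel scores with the threshold rules: quiescent iff both
   cycle scores < 2, G2/M iff G2/M > G1/S, and an E/M *hybrid* call when
   Epcam and Vim both exceed 2; PC1-based developmental ordering with
   per-panel Pearson correlations.

A synthetic-data generator (`orgsc.synthetic`) plants known structure —
negative-binomial counts with marker/regulon/gradient effects, read-level
FASTQ with configurable PCR duplicates and errors — so every stage is
validated against ground truth. `orgsc.pipeline` orchestrates full runs
from a YAML config with a manifest of seeds and checksums.

## Worked example

```python
from orgsc import synthetic, strt, qc, regulons, cluster, markers

truth = synthetic.generate_truth_model(n_cells=60, n_genes=200, n_groups=4,
                                       seed=1)
counts = synthetic.simulate_counts(truth, seed=2)
ref = synthetic.generate_reference(truth.gene_ids, seed=3)
wl = synthetic.simulate_fastq(truth, counts, ref, "r1.fq", "r2.fq", seed=4)

recovered, log = strt.quantify("r1.fq", "r2.fq", wl, ref)
print(log)                      # {'input_pairs': 16993, 'assigned': 16993}
recovered.columns = counts.columns
print(recovered.equals(counts)) # True  (error-free reads round-trip exactly)

expr = qc.normalize(counts)
auc = regulons.auc_matrix(expr, truth.regulons)
binary, thresholds = regulons.binarize(auc)

est = cluster.RecursiveRandomForestClusterer(cv_runs=20, n_estimators=50,
                                             random_state=0)
est.fit(binary.T)
print(est.n_leaves_)            # 4  (the planted group count)

table = markers.find_all_markers(expr, truth.group_labels)
print(table.head(3)[["gene", "cluster", "power", "log2_mean_diff"]])
```

At the defaults above the quantifier reports every read pair assigned and
the recovered matrix equal to the planted one; the clusterer returns one
leaf per planted group with near-perfect agreement (adjusted Rand index
≈ 1.0 on this benchmark), and the marker table's top rows are the planted
fold-8 group markers with power ≈ 1.

The same stages run from the shell:

```bash
orgsc run-all --config cfg.yaml --seed 1 --outdir run/
orgsc quantify --r1 r1.fq --r2 r2.fq --whitelist wl.txt --reference ref.fa
```

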