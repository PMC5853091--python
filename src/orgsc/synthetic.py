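"""Synthetic STRT-style single-cell data with planted, known structure.

Everything downstream of this module (quantification, QC, regulon scoring,
clustering, marker detection, E/M/S scoring) is validated against data whose
generative truth is known exactly: which genes are markers of which cell
group, which regulons are active where, and how gene-panel expression drifts
along a latent pseudotime.

The count model is a standard negative-binomial (gamma-Poisson) UMI model:

    counts[g, c] ~ NB(mean = L_c * p_gc,  dispersion = phi)

where ``L_c`` is the cell's expected library size (log-normal across cells)
and ``p_gc`` is the cell's relative abundance of gene ``g`` — a per-gene
baseline multiplied by the cell's marker / regulon / pseudotime-gradient
fold effects and renormalized to sum to one within the cell.

The FASTQ emitter writes read pairs in the sequenced orientation of the
barcode-RT primer: read 2 carries an 8-nt cell barcode, an 8-nt UMI and a
poly-T tail; read 1 carries a template-switch-oligo prefix, an 80-nt
transcript fragment and a poly-A tail.  UMIs are drawn without replacement
within each (gene, cell), so planted molecule counts survive deduplication
exactly and the round-trip through the quantifier is an identity at zero
error rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TSO_SEQUENCE = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadLayout:
    """Coordinates of barcode and UMI in read 2, and read geometry."""

    barcode_start: int = 0
    barcode_length: int = 8
    umi_start: int = 8
    umi_length: int = 8
    read2_length: int = 150
    read1_length: int = 150
    fragment_length: int = 80
    polya_length: int = 25

    def validate_whitelist(self, whitelist) -> None:
        lengths = {len(b) for b in whitelist}
        if lengths and lengths != {self.barcode_length}:
            raise ValueError(
                f"whitelist barcode lengths {sorted(lengths)} inconsistent with "
                f"layout barcode_length={self.barcode_length}"
            )


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its target gene set (TF included)."""

    name: str
    tf: str
    targets: tuple

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"regulon {self.name!r} has no targets")
        if self.tf not in self.targets:
            raise ValueError(f"regulon {self.name!r}: TF {self.tf!r} not in its target set")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.name!r} has duplicate targets")


@dataclass
class GeneratorConfig:
    """Knobs of the planted-structure generator.

    Fold effects are dimensionless multipliers on relative abundance;
    gradient slopes are log2-fold change per unit pseudotime.
    """

    markers_per_group: int = 10
    marker_fold: float = 8.0
    subclusters_per_group: int = 1
    subcluster_markers: int = 5
    subcluster_fold: float = 4.0
    regulons_per_group: int = 3
    targets_per_regulon: int = 10
    regulon_fold: float = 4.0
    # panel name -> (n_genes, slope); slope in log2 units per unit pseudotime
    gradient_panels: dict = field(default_factory=dict)
    # maturation program: genes switching on along pseudotime (low baseline,
    # strong positive slope).  They anchor the principal developmental axis
    # and make per-cell detection complexity rise with latent time, the way
    # differentiation programs activate over real developmental windows.
    n_maturation_genes: int = 20
    maturation_slope: float = 3.0
    maturation_baseline_factor: float = 0.15
    mean_library_size: float = 5000.0
    library_size_cv: float = 0.4
    # expected library size scales with pseudotime: later (more mature) cells
    # are transcriptionally more complex, so detected-gene count rises along
    # the latent time axis
    library_pseudotime_log2_slope: float = 0.5
    dispersion: float = 0.2
    baseline_lognorm_sigma: float = 0.5


@dataclass
class TruthModel:
    """Ground truth behind one synthetic dataset."""

    gene_ids: list
    cell_ids: list
    group_labels: np.ndarray          # major group per cell
    subcluster_labels: np.ndarray     # "<group>.<sub>" per cell
    pseudotime: np.ndarray            # in [0, 1], uniform within group
    regulons: list                    # of Regulon
    regulon_active_groups: dict       # regulon name -> set of groups
    marker_genes: dict                # group -> {gene: fold}
    subcluster_marker_genes: dict     # subcluster -> {gene: fold}
    gradient_genes: dict              # panel -> (gene list, slope)
    maturation_genes: list            # genes switching on along pseudotime
    library_sizes: np.ndarray         # expected UMIs per cell (>= 1)
    baseline_expression: np.ndarray   # per-gene relative abundance (> 0)
    config: GeneratorConfig

    def validate(self) -> None:
        if len(self.group_labels) != len(self.cell_ids):
            raise ValueError("group labels do not cover all cells")
        if np.any(self.library_sizes < 1):
            raise ValueError("library sizes must be >= 1")
        if np.any(self.baseline_expression <= 0):
            raise ValueError("baseline expression must be positive")
        for group, markers in self.marker_genes.items():
            if any(f <= 1 for f in markers.values()):
                raise ValueError(f"marker fold effects for {group} must exceed 1")

    @property
    def groups(self) -> list:
        return sorted(set(self.group_labels))

    def group_differential_genes(self) -> set:
        """Genes with any planted between-group effect.

        Covers group markers, subcluster markers (differential at group level
        because they are elevated in a subset of one group) and targets of
        regulons active in a strict subset of groups.
        """
        out = set()
        for markers in self.marker_genes.values():
            out.update(markers)
        for markers in self.subcluster_marker_genes.values():
            out.update(markers)
        n_groups = len(self.groups)
        for reg in self.regulons:
            if len(self.regulon_active_groups[reg.name]) < n_groups:
                out.update(reg.targets)
        return out


@dataclass
class ToyReference:
    """A toy transcriptome: one transcript per gene, unique assignment k-mers."""

    gene_ids: list
    sequences: dict  # gene id -> DNA string

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        short = [g for g in self.gene_ids if len(self.sequences[g]) < 200]
        if short:
            raise ValueError(f"transcripts shorter than 200 nt: {short[:5]}")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def generate_reference(gene_ids, length: int = 500, k: int = 21,
                       seed: int = 0, max_tries: int = 50) -> ToyReference:
    """Random transcripts whose k-mers never collide across genes.

    Cross-gene k-mer uniqueness makes the majority-vote gene assigner exact
    on error-free reads; offending sequences are resampled until the pooled
    k-mer sets are disjoint.
    """
    rng = np.random.default_rng(seed)
    sequences = {g: _random_dna(rng, length) for g in gene_ids}
    for _ in range(max_tries):
        owner: dict = {}
        bad = set()
        for g in gene_ids:
            s = sequences[g]
            kmers = {s[i:i + k] for i in range(len(s) - k + 1)}
            for km in kmers:
                if km in owner and owner[km] != g:
                    bad.add(g)
                    bad.add(owner[km])
                else:
                    owner[km] = g
        if not bad:
            return ToyReference(list(gene_ids), sequences)
        for g in bad:
            sequences[g] = _random_dna(rng, length)
    raise RuntimeError("could not generate a k-mer-unique reference; "
                       "increase transcript length or reduce gene count")


def generate_truth_model(n_cells: int = 400, n_genes: int = 300,
                         n_groups: int = 4,
                         config: GeneratorConfig | None = None,
                         seed: int = 0) -> TruthModel:
    """Plant a 4-way (by default) group structure with regulons and gradients.

    Marker, subcluster-marker, regulon-target and gradient-panel genes are
    drawn from disjoint blocks of the gene universe so every planted effect
    has an unambiguous ground truth.  Raises ``ValueError`` when the config
    demands more special genes than ``n_genes`` provides.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    n_sub = max(1, config.subclusters_per_group)
    need = (n_groups * config.markers_per_group
            + (n_groups * n_sub * config.subcluster_markers if n_sub > 1 else 0)
            + n_groups * config.regulons_per_group * config.targets_per_regulon
            + sum(n for n, _ in config.gradient_panels.values())
            + config.n_maturation_genes)
    if need > n_genes:
        raise ValueError(
            f"config requires {need} distinct special genes but only "
            f"{n_genes} genes are available"
        )

    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    cursor = 0

    def take(n: int) -> list:
        nonlocal cursor
        block = gene_ids[cursor:cursor + n]
        cursor += n
        return block

    groups = [f"grp{j}" for j in range(n_groups)]
    group_labels = np.array([groups[i % n_groups] for i in range(n_cells)])
    sub_labels = np.empty(n_cells, dtype=object)
    for g in groups:
        idx = np.flatnonzero(group_labels == g)
        subs = rng.integers(0, n_sub, size=idx.size) if n_sub > 1 else np.zeros(idx.size, int)
        sub_labels[idx] = [f"{g}.{s}" for s in subs]

    pseudotime = np.empty(n_cells)
    for g in groups:
        idx = np.flatnonzero(group_labels == g)
        pseudotime[idx] = rng.uniform(0.0, 1.0, size=idx.size)

    marker_genes = {
        g: {gene: config.marker_fold for gene in take(config.markers_per_group)}
        for g in groups
    }
    subcluster_marker_genes: dict = {}
    if n_sub > 1:
        for g in groups:
            for s in range(n_sub):
                subcluster_marker_genes[f"{g}.{s}"] = {
                    gene: config.subcluster_fold
                    for gene in take(config.subcluster_markers)
                }

    regulons, active_groups = [], {}
    for g in groups:
        for r in range(config.regulons_per_group):
            targets = take(config.targets_per_regulon)
            reg = Regulon(name=f"{g}_reg{r}", tf=targets[0], targets=tuple(targets))
            regulons.append(reg)
            active_groups[reg.name] = {g}

    gradient_genes = {
        panel: (take(n), slope)
        for panel, (n, slope) in config.gradient_panels.items()
    }
    maturation_genes = take(config.n_maturation_genes)

    mu = np.log(config.mean_library_size)
    sigma = np.sqrt(np.log(1 + config.library_size_cv ** 2))
    library = rng.lognormal(mu - sigma ** 2 / 2, sigma, size=n_cells)
    library = library * 2.0 ** (config.library_pseudotime_log2_slope * pseudotime)
    library = np.maximum(1, np.round(library)).astype(int)

    baseline = rng.lognormal(0.0, config.baseline_lognorm_sigma, size=n_genes)

    truth = TruthModel(
        gene_ids=gene_ids, cell_ids=cell_ids, group_labels=group_labels,
        subcluster_labels=sub_labels.astype(str), pseudotime=pseudotime,
        regulons=regulons, regulon_active_groups=active_groups,
        marker_genes=marker_genes, subcluster_marker_genes=subcluster_marker_genes,
        gradient_genes=gradient_genes, maturation_genes=maturation_genes,
        library_sizes=library,
        baseline_expression=baseline, config=config,
    )
    truth.validate()
    return truth


def relative_abundance(truth: TruthModel) -> pd.DataFrame:
    """Per-cell relative abundance p_gc (columns sum to 1), genes x cells."""
    n_genes, n_cells = len(truth.gene_ids), len(truth.cell_ids)
    gene_pos = {g: i for i, g in enumerate(truth.gene_ids)}
    ab = np.tile(truth.baseline_expression[:, None], (1, n_cells))

    for group, markers in truth.marker_genes.items():
        cols = truth.group_labels == group
        for gene, fold in markers.items():
            ab[gene_pos[gene], cols] *= fold
    for sub, markers in truth.subcluster_marker_genes.items():
        cols = truth.subcluster_labels == sub
        for gene, fold in markers.items():
            ab[gene_pos[gene], cols] *= fold
    for reg in truth.regulons:
        cols = np.isin(truth.group_labels, list(truth.regulon_active_groups[reg.name]))
        rows = [gene_pos[g] for g in reg.targets]
        ab[np.ix_(rows, cols)] *= truth.config.regulon_fold
    for genes, slope in truth.gradient_genes.values():
        rows = [gene_pos[g] for g in genes]
        ab[rows, :] *= 2.0 ** (slope * truth.pseudotime)[None, :]
    if truth.maturation_genes:
        rows = [gene_pos[g] for g in truth.maturation_genes]
        ab[rows, :] *= (truth.config.maturation_baseline_factor
                        * 2.0 ** (truth.config.maturation_slope
                                  * truth.pseudotime)[None, :])

    ab /= ab.sum(axis=0, keepdims=True)
    return pd.DataFrame(ab, index=truth.gene_ids, columns=truth.cell_ids)


def simulate_counts(truth: TruthModel, seed: int = 0) -> pd.DataFrame:
    """Draw the genes x cells UMI count matrix from the NB model."""
    truth.validate()
    rng = np.random.default_rng(seed)
    p = relative_abundance(truth).to_numpy()
    mean = p * truth.library_sizes[None, :]
    phi = truth.config.dispersion
    if phi <= 0:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / phi
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam)
    return pd.DataFrame(counts.astype(np.int64), index=truth.gene_ids,
                        columns=truth.cell_ids)


def _all_umis_for(rng: np.random.Generator, n: int, length: int = 8) -> list:
    """n distinct random UMI strings (sampling without replacement)."""
    seen: set = set()
    while len(seen) < n:
        seen.add("".join(_BASES[rng.integers(0, 4, size=length)]))
    return sorted(seen)


def generate_barcodes(n: int, length: int = 8, seed: int = 0,
                      min_distance: int = 3) -> list:
    """Distinct cell barcodes with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    barcodes: list = []
    arrs: list = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not generate a well-separated barcode set")
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= min_distance for a in arrs):
            arrs.append(cand)
            barcodes.append("".join(_BASES[cand]))
    return barcodes


def simulate_fastq(truth: TruthModel, counts: pd.DataFrame,
                   reference: ToyReference, r1_path, r2_path,
                   whitelist: list | None = None,
                   layout: ReadLayout | None = None,
                   error_rate: float = 0.0, duplicate_rate: float = 0.0,
                   n_flood_rate: float = 0.0, seed: int = 0) -> list:
    """Write paired FASTQ emulating the barcode-RT read structure.

    Each planted UMI of counts[g, c] yields one read pair; with probability
    ``duplicate_rate`` extra PCR-duplicate pairs re-use an existing UMI of the
    same (gene, cell).  ``error_rate`` is the per-base substitution
    probability in the read-1 fragment; ``n_flood_rate`` is the fraction of
    pairs whose read 1 is flooded with >10% N bases.  Returns the whitelist
    (barcode per cell, in cell order).  Deterministic for a fixed seed.
    """
    layout = layout or ReadLayout()
    rng = np.random.default_rng(seed)
    cells = list(counts.columns)
    if whitelist is None:
        whitelist = generate_barcodes(len(cells), layout.barcode_length,
                                      seed=int(rng.integers(2**31)))
    if len(whitelist) < len(cells):
        raise ValueError("whitelist smaller than the number of cells in counts")
    layout.validate_whitelist(whitelist)
    missing = [g for g in counts.index if g not in reference.sequences]
    if missing:
        raise ValueError(f"genes absent from reference: {missing[:5]}")

    barcode_of = dict(zip(cells, whitelist))
    qual1 = "I" * layout.read1_length
    qual2 = "I" * layout.read2_length
    polyt = "T" * (layout.read2_length - layout.umi_start - layout.umi_length)

    genes = list(counts.index)
    mat = counts.to_numpy()
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        serial = 0
        for ci, cell in enumerate(cells):
            bc = barcode_of[cell]
            for gi in np.flatnonzero(mat[:, ci] > 0):
                gene = genes[gi]
                n = int(mat[gi, ci])
                umis = _all_umis_for(rng, n, layout.umi_length)
                tx = reference.sequences[gene]
                emit = list(umis)
                if duplicate_rate > 0:
                    n_dup = rng.binomial(n, duplicate_rate)
                    if n_dup:
                        emit += list(rng.choice(umis, size=n_dup, replace=True))
                for umi in emit:
                    start = int(rng.integers(0, len(tx) - layout.fragment_length + 1))
                    frag = tx[start:start + layout.fragment_length]
                    if error_rate > 0:
                        frag = _substitute(rng, frag, error_rate)
                    if n_flood_rate > 0 and rng.random() < n_flood_rate:
                        frag = _flood_n(rng, frag, 0.2)
                    r1 = (TSO_SEQUENCE + frag + "A" * layout.polya_length)[:layout.read1_length]
                    r2 = (bc + umi + polyt)[:layout.read2_length]
                    name = f"read{serial}:{cell}:{gene}"
                    serial += 1
                    f1.write(f"@{name}/1\n{r1}\n+\n{qual1[:len(r1)]}\n")
                    f2.write(f"@{name}/2\n{r2}\n+\n{qual2[:len(r2)]}\n")
    return whitelist


def _substitute(rng, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _flood_n(rng, seq: str, frac: float) -> str:
    arr = np.array(list(seq))
    k = max(1, int(np.ceil(frac * arr.size)))
    idx = rng.choice(arr.size, size=k, replace=False)
    arr[idx] = "N"
    return "".join(arr)


def simulate_binary_regulon_matrix(n_cells_per_group: int = 100,
                                   n_groups: int = 4,
                                   regulons_per_group: int = 8,
                                   n_shared_regulons: int = 8,
                                   p_active: float = 0.9,
                                   p_inactive: float = 0.1,
                                   p_shared: float = 0.3,
                                   seed: int = 0):
    """Cells x regulons binary activity matrix with planted group structure.

    With ``n_groups=1`` all regulons fire at ``p_shared`` everywhere — a
    homogeneous null with no structure to find.  Returns
    ``(DataFrame cells x regulons, labels array)``.
    """
    rng = np.random.default_rng(seed)
    groups = [f"grp{j}" for j in range(n_groups)]
    labels = np.repeat(groups, n_cells_per_group)
    n_cells = labels.size
    cols, data = [], []
    if n_groups > 1:
        for g in groups:
            mask = labels == g
            for r in range(regulons_per_group):
                p = np.where(mask, p_active, p_inactive)
                data.append(rng.random(n_cells) < p)
                cols.append(f"{g}_reg{r}")
    for r in range(n_shared_regulons):
        data.append(rng.random(n_cells) < p_shared)
        cols.append(f"shared_reg{r}")
    mat = pd.DataFrame(np.array(data, dtype=int).T,
                       index=[f"C{i:04d}" for i in range(n_cells)], columns=cols)
    return mat, labels


def truth_labels_frame(truth: TruthModel) -> pd.DataFrame:
    """Truth labels as the TSV-ready table (cell_id, group, subcluster, pseudotime)."""
    return pd.DataFrame({
        "cell_id": truth.cell_ids,
        "group": truth.group_labels,
        "subcluster": truth.subcluster_labels,
        "pseudotime": truth.pseudotime,
    })


def config_with_panels(slopes: dict, genes_per_panel: int = 12,
                       **kwargs) -> GeneratorConfig:
    """Convenience: a GeneratorConfig with gradient panels for given slopes."""
    panels = {name: (genes_per_panel, slope) for name, slope in slopes.items()}
    return GeneratorConfig(gradient_panels=panels, **kwargs)
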