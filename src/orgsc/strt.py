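"""Paired FASTQ -> genes x cells distinct-UMI count matrix.

The STRT-style library puts the cell identity in read 2: an 8-nt cell
barcode followed by an 8-nt UMI and a poly-T stretch.  Read 1 carries the
cDNA with a template-switch-oligo (TSO) prefix and a poly-A tail.  The
pipeline is:

1. demultiplex each pair by the read-2 barcode against a whitelist
   (exact match by default; optional unique Hamming-1 rescue),
2. trim the TSO prefix and trailing poly-A from read 1 and discard reads
   with >10% N bases, adapter contamination, or too little sequence left,
3. assign the trimmed read to a gene by majority vote of its k-mers
   against a unique-k-mer index of the toy reference,
4. count distinct UMIs per (gene, cell): reads sharing a UMI within one
   gene of one cell are PCR duplicates of a single transcript and are
   collapsed, so the matrix entry is a molecule count.

UMI deduplication is exact-string: no directional or network collapsing of
near-miss UMIs is attempted.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .synthetic import ReadLayout, ToyReference, TSO_SEQUENCE

# Oligos from the library-construction chemistry, used as the default
# adapter-contamination screen.
ISPCR_OLIGO = "AAGCAGTGGTATCAACGCAGAGT"
QP2_PRIMER = "CAAGCAGAAGACGGCATACGA"
DEFAULT_ADAPTERS = (QP2_PRIMER,)

REJECT_TOO_SHORT = "too_short"
REJECT_NO_BARCODE = "barcode_unmatched"
REJECT_AMBIGUOUS_BARCODE = "barcode_ambiguous"
REJECT_LOW_QUALITY = "low_quality"
REJECT_ADAPTER = "adapter"
REJECT_SHORT_INSERT = "short_after_trim"
REJECT_UNASSIGNED = "gene_unassigned"


@dataclass(frozen=True)
class Rejection:
    reason: str

    def __bool__(self):  # rejections are falsy so `if result:` reads naturally
        return False


def _hamming1_neighbors(barcode: str, whitelist: set) -> list:
    hits = []
    for i, base in enumerate(barcode):
        for alt in "ACGT":
            if alt != base:
                cand = barcode[:i] + alt + barcode[i + 1:]
                if cand in whitelist:
                    hits.append(cand)
    return hits


def extract_barcode_umi(read2_seq: str, layout: ReadLayout, whitelist,
                        hamming1_rescue: bool = False):
    """Pull (cell_barcode, umi) out of read 2, or a Rejection.

    The barcode must match the whitelist exactly; with
    ``hamming1_rescue=True`` a barcode at Hamming distance 1 from exactly
    one whitelist entry is rescued to that entry, and a tie between two
    entries is rejected as ambiguous.
    """
    span = max(layout.barcode_start + layout.barcode_length,
               layout.umi_start + layout.umi_length)
    if len(read2_seq) < span:
        return Rejection(REJECT_TOO_SHORT)
    barcode = read2_seq[layout.barcode_start:layout.barcode_start + layout.barcode_length]
    umi = read2_seq[layout.umi_start:layout.umi_start + layout.umi_length]
    wl = whitelist if isinstance(whitelist, (set, frozenset)) else set(whitelist)
    if barcode in wl:
        return barcode, umi
    if hamming1_rescue:
        hits = _hamming1_neighbors(barcode, wl)
        if len(hits) == 1:
            return hits[0], umi
        if len(hits) > 1:
            return Rejection(REJECT_AMBIGUOUS_BARCODE)
    return Rejection(REJECT_NO_BARCODE)


def _trim_tso(seq: str, tso: str, min_overlap: int) -> str:
    max_l = min(len(tso), len(seq))
    for l in range(max_l, min_overlap - 1, -1):
        if seq.startswith(tso[-l:]):
            return seq[l:]
    return seq


def _trim_polya(seq: str, min_run: int, max_mismatch: int = 1) -> str:
    """Remove a trailing poly-A run of >= min_run, tolerating one mismatch.

    The removed suffix always starts at an A: the mismatch allowance covers
    a non-A base inside the tail, never an insert base at the boundary.
    """
    mismatches = 0
    i = len(seq) - 1
    while i >= 0:
        if seq[i] != "A":
            mismatches += 1
            if mismatches > max_mismatch:
                break
        i -= 1
    cut = i + 1
    while cut < len(seq) and seq[cut] != "A":
        cut += 1
    if len(seq) - cut >= min_run:
        return seq[:cut]
    return seq


def trim_and_filter_read1(read1_seq: str, read1_qual: str | None = None,
                          tso: str = TSO_SEQUENCE,
                          adapters=DEFAULT_ADAPTERS,
                          max_n_frac: float = 0.10, min_len: int = 30,
                          min_tso_overlap: int = 10,
                          polya_min_run: int = 10):
    """Trim TSO prefix and poly-A tail; reject low-quality/contaminated reads.

    Returns the trimmed sequence, or a Rejection with reason
    ``low_quality`` (N fraction > max_n_frac), ``adapter`` (a configured
    adapter oligo occurs in the insert) or ``short_after_trim``.
    """
    seq = _trim_tso(read1_seq, tso, min_tso_overlap)
    seq = _trim_polya(seq, polya_min_run)
    if len(seq) == 0:
        return Rejection(REJECT_SHORT_INSERT)
    if seq.count("N") / len(seq) > max_n_frac:
        return Rejection(REJECT_LOW_QUALITY)
    for adapter in adapters:
        if adapter and adapter in seq:
            return Rejection(REJECT_ADAPTER)
    if len(seq) < min_len:
        return Rejection(REJECT_SHORT_INSERT)
    return seq


class KmerGeneIndex:
    """Unique-k-mer index over a toy reference for majority-vote assignment.

    k-mers occurring in more than one transcript are dropped from the index,
    so every indexed k-mer votes for exactly one gene.
    """

    def __init__(self, reference: ToyReference, k: int = 21):
        if not reference.gene_ids:
            raise ValueError("empty reference")
        self.k = k
        owner: dict = {}
        shared: set = set()
        for gene in reference.gene_ids:
            seq = reference.sequences[gene]
            for i in range(len(seq) - k + 1):
                km = seq[i:i + k]
                if km in owner and owner[km] != gene:
                    shared.add(km)
                else:
                    owner[km] = gene
        for km in shared:
            owner.pop(km, None)
        self._owner = owner

    def assign(self, seq: str):
        """Gene id winning the k-mer majority vote, or None (tie / no hits)."""
        k = self.k
        if len(seq) < k:
            return None
        votes = Counter()
        owner = self._owner
        for i in range(len(seq) - k + 1):
            gene = owner.get(seq[i:i + k])
            if gene is not None:
                votes[gene] += 1
        if not votes:
            return None
        ranked = votes.most_common(2)
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return None
        return ranked[0][0]


def assign_gene(trimmed_seq: str, index: KmerGeneIndex):
    return index.assign(trimmed_seq)


def count_umis(assignments, gene_ids=None, cell_barcodes=None) -> pd.DataFrame:
    """Distinct-UMI counts per (gene, cell) from (barcode, gene, umi) triples.

    Duplicated transcripts — identical UMI strings within one gene of one
    cell — collapse to a single molecule; the same UMI on two different
    genes counts once for each.  Optional ``gene_ids`` / ``cell_barcodes``
    fix the output axes (zero-filled where nothing was observed).
    """
    umis = defaultdict(set)
    for barcode, gene, umi in assignments:
        umis[(gene, barcode)].add(umi)
    genes_seen = sorted({g for g, _ in umis})
    cells_seen = sorted({c for _, c in umis})
    genes = list(gene_ids) if gene_ids is not None else genes_seen
    cells = list(cell_barcodes) if cell_barcodes is not None else cells_seen
    mat = pd.DataFrame(0, index=genes, columns=cells, dtype=np.int64)
    for (gene, barcode), s in umis.items():
        if gene in mat.index and barcode in mat.columns:
            mat.loc[gene, barcode] = len(s)
    return mat


def iterate_read_pairs(r1_path, r2_path):
    """Yield (read1_seq, read1_qual, read2_seq) from paired FASTQ files."""
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2):
        qual = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        yield str(rec1.seq), qual, str(rec2.seq)


def assignment_stream(r1_path, r2_path, whitelist, reference: ToyReference,
                      layout: ReadLayout | None = None, k: int = 21,
                      hamming1_rescue: bool = False,
                      trim_kwargs: dict | None = None):
    """Run demultiplex/trim/assign; yield (barcode, gene, umi) per surviving read.

    Returns a generator; per-stage rejection tallies are accumulated on the
    generator's ``log`` attribute (a Counter), complete once exhausted.
    """
    layout = layout or ReadLayout()
    index = KmerGeneIndex(reference, k=k)
    trim_kwargs = trim_kwargs or {}
    wl = set(whitelist)
    log = Counter()

    def gen():
        for r1_seq, r1_qual, r2_seq in iterate_read_pairs(r1_path, r2_path):
            log["input_pairs"] += 1
            demux = extract_barcode_umi(r2_seq, layout, wl, hamming1_rescue)
            if isinstance(demux, Rejection):
                log[demux.reason] += 1
                continue
            barcode, umi = demux
            trimmed = trim_and_filter_read1(r1_seq, r1_qual, **trim_kwargs)
            if isinstance(trimmed, Rejection):
                log[trimmed.reason] += 1
                continue
            gene = index.assign(trimmed)
            if gene is None:
                log[REJECT_UNASSIGNED] += 1
                continue
            log["assigned"] += 1
            yield barcode, gene, umi

    g = gen()
    g = _LoggedGenerator(g, log)
    return g


class _LoggedGenerator:
    """Generator wrapper exposing the rejection log."""

    def __init__(self, gen, log):
        self._gen = gen
        self.log = log

    def __iter__(self):
        return self._gen


def quantify(r1_path, r2_path, whitelist, reference: ToyReference,
             layout: ReadLayout | None = None, k: int = 21,
             hamming1_rescue: bool = False,
             trim_kwargs: dict | None = None):
    """Full FASTQ -> UMI count matrix run.

    Returns ``(counts genes x cells DataFrame, rejection log dict)``.  Axes
    cover the whole reference and whitelist so planted zeros round-trip.
    """
    stream = assignment_stream(r1_path, r2_path, whitelist, reference,
                               layout=layout, k=k,
                               hamming1_rescue=hamming1_rescue,
                               trim_kwargs=trim_kwargs)
    counts = count_umis(stream, gene_ids=reference.gene_ids,
                        cell_barcodes=list(whitelist))
    return counts, dict(stream.log)
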