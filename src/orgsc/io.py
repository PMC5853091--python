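"""Readers and writers for the on-disk formats the pipeline exchanges.

Count matrices travel as MatrixMarket MTX plus row (genes.tsv) and column
(barcodes.tsv) label files, or as plain TSV; regulons as TSV
(regulon_name, tf, target) or JSON; score panels as TSV (panel, gene);
references as FASTA; whitelists as one-barcode-per-line text.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scores import ScorePanel
from .synthetic import Regulon, ToyReference


def write_mtx(matrix: pd.DataFrame, outdir, prefix: str = "") -> dict:
    """Write a genes x cells matrix as MTX + genes.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "genes": outdir / f"{prefix}genes.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
    }
    mmwrite(str(paths["matrix"]), sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.index).to_csv(paths["genes"], index=False, header=False)
    pd.Series(matrix.columns).to_csv(paths["barcodes"], index=False, header=False)
    return paths


def read_mtx(outdir, prefix: str = "") -> pd.DataFrame:
    outdir = Path(outdir)
    mat = mmread(str(outdir / f"{prefix}matrix.mtx")).toarray()
    genes = pd.read_csv(outdir / f"{prefix}genes.tsv", header=None)[0].tolist()
    cells = pd.read_csv(outdir / f"{prefix}barcodes.tsv", header=None)[0].tolist()
    return pd.DataFrame(mat, index=genes, columns=cells)


def write_reference_fasta(reference: ToyReference, path) -> None:
    records = [SeqRecord(Seq(reference.sequences[g]), id=g, description="")
               for g in reference.gene_ids]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path) -> ToyReference:
    records = list(SeqIO.parse(str(path), "fasta"))
    return ToyReference([r.id for r in records],
                        {r.id: str(r.seq) for r in records})


def write_whitelist(barcodes, path) -> None:
    Path(path).write_text("\n".join(barcodes) + "\n")


def read_whitelist(path) -> list:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_regulons_tsv(regulons, path) -> None:
    rows = [(r.name, r.tf, t) for r in regulons for t in r.targets]
    pd.DataFrame(rows, columns=["regulon_name", "tf", "target"]).to_csv(
        path, sep="\t", index=False)


def read_regulons_tsv(path) -> list:
    table = pd.read_csv(path, sep="\t")
    out = []
    for name, sub in table.groupby("regulon_name", sort=False):
        tfs = sub["tf"].unique()
        if len(tfs) != 1:
            raise ValueError(f"regulon {name!r} lists multiple TFs: {tfs.tolist()}")
        out.append(Regulon(name=name, tf=tfs[0], targets=tuple(sub["target"])))
    return out


def write_regulons_json(regulons, path) -> None:
    payload = [{"name": r.name, "tf": r.tf, "targets": list(r.targets)}
               for r in regulons]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_regulons_json(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [Regulon(name=d["name"], tf=d["tf"], targets=tuple(d["targets"]))
            for d in payload]


def write_panels_tsv(panels: dict, path) -> None:
    rows = [(p.name, g) for p in panels.values() for g in p.genes]
    pd.DataFrame(rows, columns=["panel", "gene"]).to_csv(path, sep="\t", index=False)


def read_panels_tsv(path) -> dict:
    table = pd.read_csv(path, sep="\t")
    return {name: ScorePanel(name, tuple(sub["gene"]))
            for name, sub in table.groupby("panel", sort=False)}
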