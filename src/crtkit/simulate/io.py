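"""File export for synthetic datasets: FASTA, BED, TSV, MTX, metadata."""

from __future__ import annotations

import json
from pathlib import Path

import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta",
    "write_bed",
    "write_mtx",
    "write_run_metadata",
    "export_reference",
    "export_screen",
]


def write_fasta(sequences: dict, path):
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(df, path, name_col=None):
    """0-based half-open BED; optional 4th column from ``name_col``."""
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_mtx(matrix, row_names, col_names, prefix):
    """MatrixMarket matrix plus sidecar row/column name files."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(matrix))
    Path(str(prefix) + ".rows.txt").write_text("\n".join(map(str, row_names)) + "\n")
    Path(str(prefix) + ".cols.txt").write_text("\n".join(map(str, col_names)) + "\n")


def write_run_metadata(params: dict, path):
    Path(path).write_text(json.dumps(params, indent=2, default=str) + "\n")


def export_reference(ref, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ref.sequences, outdir / "genome.fa")
    gm = ref.gene_models
    write_bed(gm.genes, outdir / "genes.bed", name_col="gene")
    write_bed(gm.exons, outdir / "exons.bed", name_col="gene")
    gm.tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    ref.mutation_rates.to_csv(outdir / "mutation_rates.tsv", sep="\t")
    ref.cage.to_csv(outdir / "cage.tsv", sep="\t", index=False)


def export_screen(data, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx(data.gene_umis, data.cell_ids, data.gene_ids, outdir / "gene_umis")
    write_mtx(data.guide_umis, data.cell_ids, data.guide_ids, outdir / "guide_umis")
    data.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
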