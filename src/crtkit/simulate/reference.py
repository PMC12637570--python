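"""Synthetic reference genome, gene models, mutation rates and CAGE.

The genome is i.i.d. uniform over ACGT, so NGG PAM availability arises
naturally at about 1/16 per strand-position.  Genes are placed
non-overlapping on a slot grid; each gene has one or two transcription
start sites, a handful of exons, per-class de novo mutation
probabilities (per haploid genome per generation), and a unimodal
pseudo-CAGE 5' tag profile peaked at each TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..harmonize import GeneModels

__all__ = ["SyntheticReference", "gen_reference"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticReference:
    chromosomes: dict  # name -> length (bp)
    sequences: dict  # name -> str
    gene_models: GeneModels
    mutation_rates: pd.DataFrame  # index gene; columns lof, missense, synonymous
    cage: pd.DataFrame  # columns gene, chrom, pos, count


def gen_reference(
    seed: int,
    n_chromosomes: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 20,
    gene_length: int = 6_000,
    gene_spacing: int = 24_000,
) -> SyntheticReference:
    """Deterministic synthetic reference with non-overlapping genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be at least 10,000 bp")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chromosomes = {c: int(chrom_length) for c in chrom_names}
    sequences = {
        c: rng.choice(_BASES, size=chrom_length).tobytes().decode()
        for c in chrom_names
    }
    slot = gene_length + gene_spacing
    slots_per_chrom = max(0, (chrom_length - gene_spacing) // slot)
    if n_genes > slots_per_chrom * n_chromosomes:
        raise ValueError(
            f"cannot place {n_genes} non-overlapping genes of {gene_length} bp "
            f"on {n_chromosomes} x {chrom_length} bp"
        )
    genes, tss_rows, exon_rows, cage_rows = [], [], [], []
    for g in range(n_genes):
        chrom = chrom_names[g % n_chromosomes]
        slot_i = g // n_chromosomes
        start = gene_spacing + slot_i * slot
        end = start + gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{g:03d}"
        coding = bool(rng.random() < 0.9)
        genes.append(
            {"gene": name, "chrom": chrom, "strand": strand,
             "start": start, "end": end, "coding": coding}
        )
        primary = start if strand == "+" else end - 1
        tss_list = [primary]
        if rng.random() < 0.5:  # alternative TSS inside the gene body
            shift = int(rng.integers(500, gene_length // 2))
            tss_list.append(primary + shift if strand == "+" else primary - shift)
        for pos in tss_list:
            tss_rows.append({"gene": name, "chrom": chrom, "strand": strand,
                             "pos": int(pos)})
            # sigma of 8 bp keeps the rounded profile strictly peaked at
            # the TSS (no flat top), so the CAGE mode is well defined
            offs = np.arange(-40, 41)
            counts = np.rint(120 * np.exp(-(offs**2) / (2 * 8.0**2))).astype(int)
            keep = counts > 0
            for o, cnt in zip(offs[keep], counts[keep]):
                cage_rows.append({"gene": name, "chrom": chrom,
                                  "pos": int(pos + o), "count": int(cnt)})
        n_exons = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(
            np.arange(start + 50, end - 50), size=2 * n_exons, replace=False))
        for k in range(n_exons):
            exon_rows.append({"gene": name, "chrom": chrom,
                              "start": int(bounds[2 * k]),
                              "end": int(bounds[2 * k + 1])})
    gene_models = GeneModels(
        genes=pd.DataFrame(genes),
        tss=pd.DataFrame(tss_rows),
        exons=pd.DataFrame(exon_rows),
        chromosomes=chromosomes,
    )
    # per-gene per-class mutation probabilities, log-normal around typical
    # human per-gene rates, capped below 1e-3
    mu_lof = np.minimum(np.exp(rng.normal(np.log(1e-5), 0.5, n_genes)), 9e-4)
    rates = pd.DataFrame(
        {
            "lof": mu_lof,
            "missense": np.minimum(3.0 * mu_lof, 9.9e-4),
            "synonymous": np.minimum(1.2 * mu_lof, 9.9e-4),
        },
        index=pd.Index([g["gene"] for g in genes], name="gene"),
    )
    return SyntheticReference(
        chromosomes=chromosomes,
        sequences=sequences,
        gene_models=gene_models,
        mutation_rates=rates,
        cage=pd.DataFrame(cage_rows),
    )
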