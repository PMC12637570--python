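"""Ready-made scaled study conditions for the synthetic screen.

The study profiled ~200k neurons with ~10.3 gRNAs per cell and ~131
cells per gRNA.  :func:`scaled_screen` keeps the per-guide cell count
and multiplicity at study values while scaling the cell total down, by
sizing the guide pool as n_cells * moi / cells_per_guide.  Intended
target genes sit at a ~1 UMI baseline (typical for the risk genes);
background genes are brighter so cells clear the 900-UMI QC threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screen import gen_screen

__all__ = ["scaled_screen"]


def scaled_screen(
    n_cells: int = 6_000,
    n_genes: int = 80,
    n_target_genes: int = 15,
    cells_per_guide: float = 130.0,
    planted: dict | None = None,
    seed: int = 0,
    mean_guides_per_cell: float = 10.3,
    ntc_fraction: float = 0.10,
):
    """Build (ScreenData, guide_meta, truth, gene_table) at study-like
    per-guide coverage.  Targeting guides cycle over the target genes;
    gene TSSs are spaced 200 kb apart on one chromosome so every guide
    has cis neighbours within 1 Mb."""
    rng = np.random.default_rng(seed + 77)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    base = np.r_[
        np.full(n_target_genes, 1.0),
        rng.lognormal(3.6, 0.5, n_genes - n_target_genes),
    ]
    gene_table = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chr1",
            "tss": np.arange(n_genes) * 200_000,
            "base_mean": base,
        }
    )
    n_pool = max(
        n_target_genes, int(n_cells * mean_guides_per_cell / cells_per_guide)
    )
    n_targeting = int(round(n_pool * (1.0 - ntc_fraction)))
    tgene = np.resize(genes[:n_target_genes], n_targeting)
    tss_of = dict(zip(gene_table["gene"], gene_table["tss"]))
    starts = np.array([tss_of[g] for g in tgene]) + 100
    targets = pd.DataFrame(
        {
            "guide_id": [f"gd{i:04d}" for i in range(n_targeting)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + 20,
            "target_gene": tgene,
            "kind": "promoter",
        }
    )
    data, meta, truth = gen_screen(
        targets,
        gene_table,
        n_cells=n_cells,
        mean_guides_per_cell=mean_guides_per_cell,
        planted_effects=planted,
        ntc_fraction=ntc_fraction,
        seed=seed,
    )
    return data, meta, truth, gene_table
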