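"""Synthetic multiplexed single-cell CRISPRa screen with planted effects.

Each cell integrates a truncated-Poisson number of gRNAs (high MOI,
emulating ~10 distinct gRNAs per cell).  gRNA UMI counts for present
guides are negative binomial around a capture mean of 20; absent guides
see sparse background (mean 0.1), so the assignment threshold of 5 UMIs
is separative but imperfect.  Gene UMIs are negative binomial with
log-normal cell size factors, lane effects, and a Beta mitochondrial
fraction pushing ~5% of cells past the 20% QC cut; cells carrying an
effective gRNA have that target gene's mean multiplied by its planted
fold-change.  Non-targeting controls never carry effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..screen import ScreenData

__all__ = ["gen_screen"]


def _nb(rng, mean, alpha):
    r = 1.0 / alpha
    p = r / (r + np.maximum(np.asarray(mean, dtype=float), 1e-12))
    return rng.negative_binomial(r, p)


def gen_screen(
    targets: pd.DataFrame,
    gene_table: pd.DataFrame,
    n_cells: int,
    mean_guides_per_cell: float = 10.3,
    planted_effects: dict | None = None,
    ntc_fraction: float = 0.10,
    seed: int = 0,
    n_lanes: int = 4,
    nb_dispersion: float = 0.2,
    guide_umi_mean: float = 20.0,
    background_umi_mean: float = 0.1,
):
    """Cell x gene and cell x gRNA UMI matrices with planted upregulation.

    targets: targeting guides (guide_id, chrom, start, end, target_gene,
    kind).  gene_table: expressed genes (gene, chrom, tss, base_mean in
    UMIs per typical cell).  planted_effects maps guide_id ->
    fold-change (> 0) on its target gene.  NTC guides are appended so
    they make up ``ntc_fraction`` of the final pool.

    Returns (ScreenData, guide_meta, truth).
    """
    planted_effects = dict(planted_effects or {})
    if any(f <= 0 for f in planted_effects.values()):
        raise ValueError("fold-changes must be positive")
    if not 0 <= ntc_fraction < 1:
        raise ValueError("ntc_fraction must be in [0, 1)")
    unknown = set(planted_effects) - set(targets["guide_id"])
    if unknown:
        raise KeyError(f"planted guides not in targets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    n_targeting = len(targets)
    n_ntc = int(round(ntc_fraction / (1.0 - ntc_fraction) * n_targeting))
    guide_meta = targets.copy()
    guide_meta["is_ntc"] = False
    if n_ntc:
        ntc = pd.DataFrame(
            {
                "guide_id": [f"ntc_{i:04d}" for i in range(n_ntc)],
                "chrom": pd.NA,
                "start": pd.NA,
                "end": pd.NA,
                "target_gene": pd.NA,
                "kind": "ntc",
                "is_ntc": True,
            }
        )
        guide_meta = pd.concat([guide_meta, ntc], ignore_index=True)
    guide_ids = guide_meta["guide_id"].to_numpy()
    n_guides = len(guide_ids)
    genes = gene_table["gene"].to_numpy()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # multiplicity per cell: Poisson truncated at >= 1
    k = rng.poisson(mean_guides_per_cell, size=n_cells)
    while (k == 0).any():
        z = k == 0
        k[z] = rng.poisson(mean_guides_per_cell, size=int(z.sum()))
    k = np.minimum(k, n_guides)
    # Gumbel top-k sampling of distinct guides per cell with a skewed
    # library abundance
    logw = np.log(rng.lognormal(0.0, 0.3, size=n_guides))
    gumbel = rng.gumbel(size=(n_cells, n_guides))
    order = np.argsort(-(logw[None, :] + gumbel), axis=1, kind="stable")
    present = np.zeros((n_cells, n_guides), dtype=bool)
    rows = np.repeat(np.arange(n_cells), k)
    cols = np.concatenate([order[i, : k[i]] for i in range(n_cells)])
    present[rows, cols] = True

    # gRNA UMIs: NB capture for present guides, sparse Poisson background
    capture = rng.lognormal(0.0, 0.3, size=n_cells)
    guide_umis = rng.poisson(background_umi_mean, size=(n_cells, n_guides))
    pm = _nb(rng, guide_umi_mean * capture[rows], nb_dispersion)
    guide_umis[rows, cols] = pm

    # cell technical structure
    size = rng.lognormal(0.0, 0.3, size=n_cells)
    low_quality = rng.random(n_cells) < 0.03
    size[low_quality] *= 0.15
    lane = rng.integers(1, n_lanes + 1, size=n_cells)
    lane_mult = rng.lognormal(0.0, 0.1, size=n_lanes)[lane - 1]
    high_mito = rng.random(n_cells) < 0.05
    mito = np.where(
        high_mito, rng.beta(10.0, 20.0, size=n_cells), rng.beta(2.0, 38.0, size=n_cells)
    )

    effect = np.ones((n_cells, n_genes))
    for gid, fold in planted_effects.items():
        j = int(np.flatnonzero(guide_ids == gid)[0])
        target = guide_meta.loc[guide_meta["guide_id"] == gid, "target_gene"].iloc[0]
        effect[present[:, j], gene_idx[target]] *= fold
    base = gene_table["base_mean"].to_numpy(dtype=float)
    mean = (size * lane_mult)[:, None] * base[None, :] * effect
    gene_umis = _nb(rng, mean, nb_dispersion)

    cell_ids = np.array([f"cell_{i:06d}" for i in range(n_cells)])
    covariates = pd.DataFrame(
        {"lane": lane, "mito_frac": mito}, index=pd.Index(cell_ids, name="cell_id")
    )
    data = ScreenData(
        gene_umis=sp.csr_matrix(gene_umis),
        guide_umis=sp.csr_matrix(guide_umis),
        cell_ids=cell_ids,
        gene_ids=genes,
        guide_ids=guide_ids,
        covariates=covariates,
    )
    truth = pd.DataFrame(
        [
            {
                "guide_id": gid,
                "target_gene": guide_meta.loc[
                    guide_meta["guide_id"] == gid, "target_gene"
                ].iloc[0],
                "fold_change": fold,
            }
            for gid, fold in sorted(planted_effects.items())
        ],
        columns=["guide_id", "target_gene", "fold_change"],
    )
    return data, guide_meta, truth
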