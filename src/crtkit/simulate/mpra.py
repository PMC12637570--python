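"""Synthetic MPRA barcode-count tables with planted active tiles.

DNA counts follow a negative binomial around each barcode's plasmid
abundance; RNA counts around abundance x tile activity multiplier x
library size factor, so a planted multiplier m shows up as an expected
log2(RNA/DNA) of log2(m) after normalization.  Scrambled control tiles
always carry multiplier 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gen_mpra_counts"]


def _nb(rng, mean, alpha):
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / alpha
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def gen_mpra_counts(
    tiles: pd.DataFrame,
    barcodes_per_tile: float = 30.0,
    planted_active: dict | None = None,
    nb_dispersion: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    mean_depth: float = 60.0,
):
    """Barcode association plus long-format DNA/RNA count tables.

    tiles: DataFrame with tile_id and tile_class ('test' | 'scrambled' |
    'external_control').  planted_active maps tile_id -> activity
    multiplier (> 0); scrambled tiles may not carry one.  Barcode counts
    per tile are Poisson(barcodes_per_tile).

    Returns (association, counts, truth).
    """
    planted_active = dict(planted_active or {})
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if any(m <= 0 for m in planted_active.values()):
        raise ValueError("activity multipliers must be positive")
    scrambled = set(tiles.loc[tiles["tile_class"] == "scrambled", "tile_id"])
    bad = scrambled & set(planted_active)
    if bad:
        raise ValueError(f"scrambled tiles cannot be planted active: {sorted(bad)}")
    unknown = set(planted_active) - set(tiles["tile_id"])
    if unknown:
        raise KeyError(f"planted tiles not in design: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    tile_ids = tiles["tile_id"].to_numpy()
    n_bc = rng.poisson(barcodes_per_tile, size=len(tile_ids))
    tile_of_bc = np.repeat(np.arange(len(tile_ids)), n_bc)
    barcodes = np.array([f"bc{i:07d}" for i in range(tile_of_bc.size)])
    association = pd.DataFrame(
        {"barcode": barcodes, "tile_id": tile_ids[tile_of_bc]}
    )
    abundance = rng.lognormal(0.0, 0.5, size=tile_of_bc.size)
    mult = np.ones(len(tile_ids))
    for t, m in planted_active.items():
        mult[np.flatnonzero(tile_ids == t)[0]] = m
    bc_mult = mult[tile_of_bc]

    # replicate -> sequencing batch (first half A, rest B) with a shared
    # batch depth multiplier, plus per-library size factors
    batches = {
        r: ("batchA" if r <= (n_replicates + 1) // 2 else "batchB")
        for r in range(1, n_replicates + 1)
    }
    batch_mult = {b: rng.lognormal(0.0, 0.15) for b in sorted(set(batches.values()))}
    frames = []
    for rep in range(1, n_replicates + 1):
        for modality in ("dna", "rna"):
            sf = rng.lognormal(0.0, 0.2) * batch_mult[batches[rep]]
            mean = mean_depth * abundance * sf
            if modality == "rna":
                mean = mean * bc_mult
            frames.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "modality": modality,
                        "replicate": rep,
                        "batch": batches[rep],
                        "count": _nb(rng, mean, nb_dispersion),
                    }
                )
            )
    counts = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        sorted(planted_active.items()), columns=["tile_id", "multiplier"]
    )
    return association, counts, truth
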