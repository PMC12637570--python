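"""Trio-cohort de novo variant counts under the Poisson rate model."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..prioritize import VARIANT_CLASSES

__all__ = ["gen_denovo_cohort"]


def gen_denovo_cohort(
    ref,
    n_trios: int,
    risk_genes=(),
    lof_inflation: float = 1.0,
    seed: int = 0,
):
    """Observed de novo counts per gene and class, Poisson with mean
    2 * n_trios * mu; the LoF mean of planted risk genes is multiplied by
    ``lof_inflation``.

    Returns (counts DataFrame indexed by gene, truth DataFrame with one
    row per planted risk gene).
    """
    if lof_inflation < 1:
        raise ValueError("lof_inflation must be >= 1")
    risk_genes = set(risk_genes)
    unknown = risk_genes - set(ref.mutation_rates.index)
    if unknown:
        raise KeyError(f"risk genes not in reference: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mu = ref.mutation_rates[list(VARIANT_CLASSES)]
    mean = 2.0 * n_trios * mu
    infl = np.where(mu.index.isin(risk_genes), lof_inflation, 1.0)
    mean = mean.copy()
    mean["lof"] = mean["lof"] * infl
    counts = pd.DataFrame(
        rng.poisson(mean.to_numpy()),
        index=mu.index,
        columns=list(VARIANT_CLASSES),
    )
    truth = pd.DataFrame(
        {"gene": sorted(risk_genes), "lof_inflation": lof_inflation}
    )
    return counts, truth
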