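"""Published study design tables and the arithmetic over them.

The source study's library compositions and headline discovery counts
are reproducible by arithmetic from its printed component counts; this
module records those components as input data and derives the totals and
percentages from them.  Everything here is bookkeeping over published
tables, not measurement.
"""

from __future__ import annotations

__all__ = [
    "MPRA_LIBRARY",
    "GRNA_LIBRARY",
    "SCREEN_COUNTS",
    "mpra_library_size",
    "grna_library_size",
    "effective_cells",
    "headline_percentages",
]

# MPRA design composition: dense 270-bp tiling of the candidate
# enhancers plus external controls and base-shuffled negatives
MPRA_LIBRARY = {
    "ccre_tiles": 44_312,
    "npc_active_controls": 100,
    "npc_inactive_controls": 99,
    "har_active_controls": 729,
    "har_inactive_controls": 600,
    "shuffled_negatives": 500,
}

# CRISPRa gRNA library composition
GRNA_LIBRARY = {
    "enhancer_targeting": 9_685,
    "tss_targeting": 4_458,
    "non_targeting": 1_500,
}

# headline component counts from the discovery screens
SCREEN_COUNTS = {
    "n_ccres": 5_425,
    "n_ccres_mpra_validated": 2_422,
    "n_ccres_multi_source": 744,
    "n_risk_genes": 337,
    "n_genes_upregulated": 200,
    "n_genes_with_validated_enhancer": 309,
    "n_activating_grnas": 509,
    "n_grnas_therapeutic_window": 162,  # 1.5- to 2.5-fold upregulation
    "n_enhancer_pairs_responsive": 91,
    "n_viral_validations": 7,
    "n_viral_attempts": 8,
    "mean_guides_per_cell": 10.3,
    "n_cells_profiled": 200_513,
}


def mpra_library_size() -> int:
    return sum(MPRA_LIBRARY.values())


def grna_library_size() -> int:
    return sum(GRNA_LIBRARY.values())


def effective_cells() -> float:
    """Multiplexing power: mean assigned gRNAs per cell x cells profiled."""
    c = SCREEN_COUNTS
    return c["mean_guides_per_cell"] * c["n_cells_profiled"]


def headline_percentages() -> dict:
    """Ratio-of-counts percentages for the screen's headline figures."""
    c = SCREEN_COUNTS
    return {
        "pct_ccres_mpra_validated": 100.0 * c["n_ccres_mpra_validated"] / c["n_ccres"],
        "pct_genes_upregulated": 100.0 * c["n_genes_upregulated"] / c["n_risk_genes"],
        "pct_grnas_therapeutic_window": 100.0
        * c["n_grnas_therapeutic_window"]
        / c["n_activating_grnas"],
        "pct_viral_validations": 100.0
        * c["n_viral_validations"]
        / c["n_viral_attempts"],
        "pct_ccres_multi_source": 100.0 * c["n_ccres_multi_source"] / c["n_ccres"],
        "pct_enhancers_responsive": 100.0
        * c["n_enhancer_pairs_responsive"]
        / c["n_ccres_mpra_validated"],
        "pct_genes_with_validated_enhancer": 100.0
        * c["n_genes_with_validated_enhancer"]
        / c["n_risk_genes"],
    }
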