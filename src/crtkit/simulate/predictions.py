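"""Multi-source enhancer-gene prediction tables with planted truth.

True elements are placed in intergenic space, clear of promoters and
exons so they survive the harmonization filters.  Each prediction source
reports each true element with probability 1 - dropout, with boundaries
jittered; later sources also add decoy intervals, emulating the partial
overlap of independent enhancer-mapping datasets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gen_cre_predictions"]

_MARGIN = 3_000  # distance kept from gene bodies (covers 2 kb promoters)
_ANCHOR_SPACING = 2_000


def _anchors(ref):
    """Candidate (chrom, position, nearest-gene) placement anchors."""
    genes = ref.gene_models.genes
    rows = []
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = [0] + list(sub["end"])
        ends = list(sub["start"]) + [ref.chromosomes[chrom]]
        flank_genes = list(sub["gene"])
        for i, (lo, hi) in enumerate(zip(starts, ends)):
            zone_lo, zone_hi = lo + _MARGIN, hi - _MARGIN
            left = flank_genes[i - 1] if i > 0 else None
            right = flank_genes[i] if i < len(flank_genes) else None
            for a in range(zone_lo, zone_hi - 800, _ANCHOR_SPACING):
                # link to the nearer flanking gene
                gene = right if right is not None else left
                if left is not None and right is not None:
                    gene = left if (a - lo) < (hi - a) else right
                rows.append((chrom, a, gene))
    return rows


def gen_cre_predictions(
    ref,
    n_sources: int = 5,
    n_true_elements: int = 40,
    jitter_sd: float = 30.0,
    dropout: float = 0.2,
    seed: int = 0,
    decoy_rate: float = 0.15,
):
    """Per-source prediction tables plus the planted-truth table.

    Returns (predictions, truth): predictions maps source name ->
    DataFrame(chrom, start, end, gene); truth has one row per planted
    element (element_id, chrom, start, end, gene).
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must be a probability")
    rng = np.random.default_rng(seed)
    anchors = _anchors(ref)
    if n_true_elements > len(anchors):
        raise ValueError(
            f"cannot place {n_true_elements} elements; only {len(anchors)} slots"
        )
    picked = rng.choice(len(anchors), size=n_true_elements, replace=False)
    truth_rows = []
    for k, ai in enumerate(sorted(picked)):
        chrom, a, gene = anchors[ai]
        length = int(rng.integers(200, 700))
        truth_rows.append(
            {"element_id": f"elem_{k:03d}", "chrom": chrom,
             "start": int(a), "end": int(a + length), "gene": gene}
        )
    truth = pd.DataFrame(truth_rows)
    spare = [anchors[i] for i in range(len(anchors)) if i not in set(picked)]
    predictions = {}
    for s in range(n_sources):
        rows = []
        for el in truth_rows:
            if rng.random() < dropout:
                continue
            js = int(np.rint(rng.normal(0, jitter_sd)))
            je = int(np.rint(rng.normal(0, jitter_sd)))
            start = max(0, el["start"] + js)
            end = max(start + 50, el["end"] + je)
            rows.append({"chrom": el["chrom"], "start": start, "end": end,
                         "gene": el["gene"]})
        # decoys are predictions too and share the per-source dropout
        if s >= n_sources // 2 and spare and decoy_rate > 0:
            n_decoys = min(
                len(spare),
                rng.poisson(decoy_rate * n_true_elements * (1.0 - dropout)),
            )
            for di in rng.choice(len(spare), size=n_decoys, replace=False):
                chrom, a, gene = spare[di]
                length = int(rng.integers(200, 700))
                rows.append({"chrom": chrom, "start": int(a),
                             "end": int(a + length), "gene": gene})
        predictions[f"source{s + 1}"] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gene"]
        )
    return predictions, truth
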