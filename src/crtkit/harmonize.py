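"""Harmonization of multi-source enhancer-gene predictions.

Candidate cis-regulatory elements (cCREs) predicted by several datasets
and enhancer-gene mapping strategies are consolidated into one
non-redundant set: each interval is first extended from its center to a
minimum width, overlapping intervals are merged across sources (union of
source labels and gene links), and any merged element overlapping a
promoter or a protein-coding exon is removed.

All coordinates are 0-based half-open (BED convention); "overlap" means
an intersection of at least 1 bp, so bookended intervals do not merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModels",
    "merge_intervals",
    "overlaps_any",
    "define_promoters",
    "extend_to_min_width",
    "harmonize",
    "support_summary",
]


@dataclass
class GeneModels:
    """Gene annotation: gene table, TSS table and exon intervals.

    genes: columns gene, chrom, strand, start, end, coding (bool)
    tss:   columns gene, chrom, strand, pos       (>=1 row per gene)
    exons: columns gene, chrom, start, end
    """

    genes: pd.DataFrame
    tss: pd.DataFrame
    exons: pd.DataFrame
    chromosomes: dict = field(default_factory=dict)  # name -> length (bp)

    def __post_init__(self):
        if self.tss.groupby("gene").size().min() < 1:
            raise ValueError("every gene needs at least one TSS")


def _check_intervals(df):
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("intervals must satisfy 0 <= start < end")


def merge_intervals(df: pd.DataFrame, collect: dict | None = None) -> pd.DataFrame:
    """Single-linkage merge of overlapping (>=1 bp) intervals per chromosome.

    ``collect`` maps output column -> input column; for each merged
    interval the output column holds the sorted tuple of the distinct
    values contributed by its constituents.
    """
    _check_intervals(df)
    collect = collect or {}
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_start, cur_end = starts[0], ends[0]
        members = [0]
        groups = []
        for i in range(1, len(sub)):
            if starts[i] < cur_end:  # strict: bookended intervals stay apart
                cur_end = max(cur_end, ends[i])
                members.append(i)
            else:
                groups.append((cur_start, cur_end, members))
                cur_start, cur_end, members = starts[i], ends[i], [i]
        groups.append((cur_start, cur_end, members))
        for s, e, idx in groups:
            row = {"chrom": chrom, "start": int(s), "end": int(e)}
            for out_col, in_col in collect.items():
                vals = set()
                for v in sub[in_col].iloc[idx]:
                    vals.update(v if isinstance(v, (tuple, list, set, frozenset)) else [v])
                row[out_col] = tuple(sorted(vals))
            out.append(row)
    return pd.DataFrame(out)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it overlap (>=1 bp) any subject?"""
    hit = np.zeros(len(query), dtype=bool)
    if subject.empty or query.empty:
        return hit
    for chrom, sub in subject.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy()[:, None]
        qe = query.loc[mask, "end"].to_numpy()[:, None]
        ss = sub["start"].to_numpy()[None, :]
        se = sub["end"].to_numpy()[None, :]
        hit[mask] |= ((qs < se) & (qe > ss)).any(axis=1)
    return hit


def define_promoters(gene_models: GeneModels, width: int = 2000) -> pd.DataFrame:
    """Strand-aware promoter intervals of ``width`` bp upstream of each TSS.

    Overlapping isoform promoters are merged; intervals running off the
    left chromosome edge are clipped at 0 with a warning.
    """
    if width <= 0:
        raise ValueError("promoter width must be positive")
    tss = gene_models.tss
    plus = tss["strand"] == "+"
    starts = np.where(plus, tss["pos"] - width, tss["pos"])
    ends = np.where(plus, tss["pos"], tss["pos"] + width)
    if (starts < 0).any():
        warnings.warn("promoter interval clipped at chromosome start")
        starts = np.maximum(starts, 0)
    prom = pd.DataFrame({"chrom": tss["chrom"], "start": starts, "end": ends})
    return merge_intervals(prom)


def extend_to_min_width(start: int, end: int, min_width: int = 500,
                        chrom_length: int | None = None) -> tuple[int, int]:
    """Center-extend an interval to at least ``min_width`` bp.

    Center is the floor midpoint; extension past the chromosome start is
    clipped at 0 and padded on the right to preserve the width (and
    symmetrically at the right end when a chromosome length is given).
    """
    if not 0 <= start < end:
        raise ValueError("invalid interval")
    if end - start >= min_width:
        return int(start), int(end)
    center = (start + end) // 2
    half = min_width // 2
    new_start = center - half
    new_end = new_start + min_width
    if new_start < 0:
        warnings.warn("extension clipped at chromosome start")
        new_start, new_end = 0, min_width
    if chrom_length is not None and new_end > chrom_length:
        warnings.warn("extension clipped at chromosome end")
        new_end = chrom_length
        new_start = max(0, chrom_length - min_width)
    return int(new_start), int(new_end)


def harmonize(
    per_source_predictions: dict[str, pd.DataFrame],
    gene_models: GeneModels,
    promoter_width: int = 2000,
    min_width: int = 500,
) -> pd.DataFrame:
    """Merge per-source (interval, linked gene) predictions into cCREs.

    per_source_predictions maps source name -> DataFrame with columns
    chrom, start, end, gene.  Returns a DataFrame with columns chrom,
    start, end, ccre_id, sources, genes, support, sorted by position.
    """
    known_chroms = set(gene_models.chromosomes) or set(gene_models.genes["chrom"])
    known_genes = set(gene_models.genes["gene"])
    frames = []
    for source, preds in per_source_predictions.items():
        if preds.empty:
            continue
        bad_chrom = set(preds["chrom"]) - known_chroms
        if bad_chrom:
            raise ValueError(f"unknown chromosome(s) in source {source!r}: {sorted(bad_chrom)}")
        bad_gene = set(preds["gene"]) - known_genes
        if bad_gene:
            raise ValueError(f"unknown gene(s) in source {source!r}: {sorted(bad_gene)}")
        ext = [
            extend_to_min_width(s, e, min_width, gene_models.chromosomes.get(c))
            for c, s, e in zip(preds["chrom"], preds["start"], preds["end"])
        ]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": preds["chrom"].to_numpy(),
                    "start": [s for s, _ in ext],
                    "end": [e for _, e in ext],
                    "source": source,
                    "gene": preds["gene"].to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "ccre_id", "sources", "genes", "support"]
        )
    merged = merge_intervals(
        pd.concat(frames, ignore_index=True),
        collect={"sources": "source", "genes": "gene"},
    )
    promoters = define_promoters(gene_models, promoter_width)
    coding_exons = gene_models.exons[
        gene_models.exons["gene"].isin(
            gene_models.genes.loc[gene_models.genes["coding"], "gene"]
        )
    ]
    drop = overlaps_any(merged, promoters) | overlaps_any(merged, coding_exons)
    merged = merged.loc[~drop].reset_index(drop=True)
    merged["support"] = merged["sources"].map(len)
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)
    merged["ccre_id"] = [f"ccre_{i:05d}" for i in range(len(merged))]
    return merged[["chrom", "start", "end", "ccre_id", "sources", "genes", "support"]]


def support_summary(merged: pd.DataFrame) -> pd.DataFrame:
    """Histogram of source support plus cumulative fraction at >= k sources."""
    if merged.empty:
        raise ValueError("empty cCRE set")
    support = merged["support"].to_numpy()
    levels = np.arange(1, support.max() + 1)
    counts = np.array([(support == k).sum() for k in levels])
    frac_ge = np.array([(support >= k).mean() for k in levels])
    return pd.DataFrame({"support": levels, "n_ccres": counts, "fraction_ge": frac_ge})
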