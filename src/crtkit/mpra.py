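"""Massively parallel reporter assay design and activity calling.

Candidate elements are densely tiled with fixed-length oligos (270 bp,
90 bp overlap).  Activity of each tile is the RNA/DNA barcode-count
ratio, tested with a negative-binomial log-link regression of summed
barcode counts on modality (RNA vs DNA) plus sequencing batch, with
median-of-ratios size factors as offsets and a Wald test on the modality
coefficient.  A tile is called active when its BH-adjusted p-value and
log2 fold-change clear compound thresholds (default q < 0.01 and
log2FC > 1), and the empirical false-discovery rate of that rule is
estimated from scrambled negative-control tiles subjected to the same
thresholds.  Element-level validation asks whether any tile of an
element scores in the top fraction (default 10%) of all scored tiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import batched_glm, bh_adjust, fisher_odds_ratio, pearson_nb_dispersion

__all__ = [
    "design_tiles",
    "tile_sequences",
    "activity_test",
    "empirical_fdr",
    "validate_ccres",
    "enrichment_odds_ratio",
]

TILE_LEN = 270
TILE_OVERLAP = 90


def design_tiles(
    ccres: pd.DataFrame,
    tile_len: int = TILE_LEN,
    overlap: int = TILE_OVERLAP,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Tile each element with fixed-length oligos at a fixed step.

    Tiles start at offsets 0, step = tile_len - overlap.  If the last
    step-aligned tile stops short of the element end, one extra
    right-aligned tile [end - tile_len, end) is added.  Elements shorter
    than a tile get a single tile centered on the element, with flanking
    genomic sequence making up the width.
    """
    if not tile_len > overlap >= 0:
        raise ValueError("need tile_len > overlap >= 0")
    step = tile_len - overlap
    chrom_lengths = chrom_lengths or {}
    rows = []
    for ccre in ccres.itertuples(index=False):
        start, end = int(ccre.start), int(ccre.end)
        length = end - start
        clen = chrom_lengths.get(ccre.chrom)
        if length < tile_len:
            center = (start + end) // 2
            t0 = center - tile_len // 2
            if t0 < 0:
                t0 = 0
            if clen is not None and t0 + tile_len > clen:
                t0 = clen - tile_len
            tiles = [t0]
        else:
            tiles = list(range(start, end - tile_len + 1, step))
            if tiles[-1] + tile_len < end:
                tiles.append(end - tile_len)
        for k, t0 in enumerate(tiles):
            rows.append(
                {
                    "tile_id": f"{ccre.ccre_id}_t{k:02d}",
                    "ccre_id": ccre.ccre_id,
                    "chrom": ccre.chrom,
                    "start": t0,
                    "end": t0 + tile_len,
                    "offset_index": k,
                    "tile_class": "test",
                }
            )
    return pd.DataFrame(rows)


def tile_sequences(tiles: pd.DataFrame, genome: dict) -> pd.Series:
    """Extract tile sequences from a chrom -> sequence mapping."""
    seqs = []
    for t in tiles.itertuples(index=False):
        chrom_seq = genome.get(t.chrom)
        if chrom_seq is None or t.end > len(chrom_seq) or t.start < 0:
            raise KeyError(f"no reference sequence for tile {t.tile_id}")
        seqs.append(chrom_seq[t.start : t.end])
    return pd.Series(seqs, index=tiles["tile_id"].to_numpy(), name="sequence")


def _size_factors(Y: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors across libraries (columns)."""
    pos = (Y > 0).all(axis=1)
    if not pos.any():
        return np.ones(Y.shape[1])
    logY = np.log(Y[pos])
    ref = logY.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logY - ref, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def activity_test(
    counts: pd.DataFrame,
    association: pd.DataFrame,
    min_total: int = 10,
    fdr: float = 0.01,
    lfc: float = 1.0,
    dispersion_floor: float = 1e-4,
) -> pd.DataFrame:
    """Per-tile RNA-vs-DNA differential test.

    counts: long table with columns barcode, modality ('dna'|'rna'),
    replicate, batch, count.  association: columns barcode, tile_id
    (each barcode maps to exactly one tile).

    Returns a table with one row per tile: n_barcodes, total counts,
    log2fc, p, q, active, tested.  Tiles with no barcode or total count
    below ``min_total`` are kept in the table but excluded from testing.
    """
    dup = association["barcode"].duplicated()
    if dup.any():
        raise ValueError("barcodes mapping to more than one tile")
    merged = counts.merge(association, on="barcode", how="inner")
    lib_cols = ["modality", "replicate", "batch"]
    agg = (
        merged.groupby(["tile_id"] + lib_cols, observed=True)["count"]
        .sum()
        .reset_index()
    )
    libs = agg[lib_cols].drop_duplicates().sort_values(lib_cols).reset_index(drop=True)
    lib_key = libs.apply(tuple, axis=1)
    lib_index = {k: i for i, k in enumerate(lib_key)}
    tiles = np.sort(association["tile_id"].unique())
    tile_index = {t: i for i, t in enumerate(tiles)}
    Y = np.zeros((len(tiles), len(libs)))
    rows = agg["tile_id"].map(tile_index).to_numpy()
    cols = agg[lib_cols].apply(tuple, axis=1).map(lib_index).to_numpy()
    Y[rows, cols] = agg["count"].to_numpy()

    nbc = association.groupby("tile_id").size().reindex(tiles).fillna(0).astype(int)
    n_with_counts = (
        merged.groupby("tile_id")["barcode"].nunique().reindex(tiles).fillna(0)
    )
    total = Y.sum(axis=1)
    tested = (n_with_counts.to_numpy() > 0) & (total >= min_total)

    sf = _size_factors(Y)
    # design: intercept + RNA indicator + batch dummies (dropped when
    # confounded with modality or when only one batch is present)
    is_rna = (libs["modality"] == "rna").astype(float).to_numpy()
    X = [np.ones(len(libs)), is_rna]
    batches = sorted(libs["batch"].unique())
    for b in batches[1:]:
        col = (libs["batch"] == b).astype(float).to_numpy()
        trial = np.column_stack(X + [col])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            X.append(col)
    X = np.column_stack(X)

    # raw ratio score: mean log2 normalized RNA minus mean log2 normalized
    # DNA over libraries with positive counts; exactly invariant to
    # rescaling any single library (the constant moves every size factor
    # by the same amount and cancels in the RNA-DNA difference)
    with np.errstate(divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-zero sides -> NaN
        logn = np.log2(Y / sf)
        rna_cols = is_rna.astype(bool)
        pos = Y > 0
        rna_mean = np.nanmean(
            np.where(pos[:, rna_cols], logn[:, rna_cols], np.nan), axis=1
        )
        dna_mean = np.nanmean(
            np.where(pos[:, ~rna_cols], logn[:, ~rna_cols], np.nan), axis=1
        )
    raw = rna_mean - dna_mean

    log2fc = np.full(len(tiles), np.nan)
    pvals = np.full(len(tiles), np.nan)
    if tested.any():
        Yt = Y[tested]
        offset = np.log(sf)
        ddof = max(1, Y.shape[1] - X.shape[1])
        pois = batched_glm(X, Yt, family="poisson", offset=offset)
        # df-corrected Pearson dispersion: with ~6 library-level counts per
        # tile the naive moment estimator is biased low and the Wald test
        # becomes sharply anti-conservative
        alpha = pearson_nb_dispersion(
            Yt, pois["mu"], ddof, floor=dispersion_floor
        )
        fit = batched_glm(X, Yt, family="nb", alpha=alpha, offset=offset)
        beta = fit["beta"][:, 1]
        se = np.sqrt(fit["cov"][:, 1, 1])
        z = beta / se
        pvals[tested] = 2.0 * sps.t.sf(np.abs(z), df=ddof)
        log2fc[tested] = beta / np.log(2.0)
    qvals = np.full(len(tiles), np.nan)
    qvals[tested] = bh_adjust(pvals[tested])
    active = tested & (qvals < fdr) & (log2fc > lfc)
    return pd.DataFrame(
        {
            "tile_id": tiles,
            "n_barcodes": nbc.to_numpy(),
            "total_count": total,
            "raw_log2_ratio": raw,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "active": active,
            "tested": tested,
        }
    )


def empirical_fdr(test_active, scrambled_active) -> float:
    """Scrambled-control estimate of the false-discovery rate.

    eFDR = (scrambled pass rate x number of test tiles) / number of test
    tiles passing; 0 when no test tile passes.
    """
    test_active = np.asarray(test_active, dtype=bool)
    scrambled_active = np.asarray(scrambled_active, dtype=bool)
    if scrambled_active.size == 0:
        raise ValueError("need at least one scrambled control tile")
    n_pass = test_active.sum()
    if n_pass == 0:
        return 0.0
    expected_false = scrambled_active.mean() * test_active.size
    return float(expected_false / n_pass)


def validate_ccres(
    activities: pd.DataFrame,
    designs: pd.DataFrame,
    top_fraction: float = 0.10,
    universe: str = "all",
    score: str = "log2fc",
) -> pd.DataFrame:
    """Element-level validation: any tile in the top fraction of scores.

    The score threshold is the (1 - top_fraction) quantile of the score
    column (model estimate by default; ``score='raw_log2_ratio'`` for
    the plain normalized ratio) over scored tiles -- all of them by
    default, or test tiles only with ``universe='test'``.
    """
    scored = activities[activities["tested"]].copy()
    if len(scored) < 10:
        raise ValueError("need at least 10 scored tiles")
    if universe == "test":
        test_ids = designs.loc[designs["tile_class"] == "test", "tile_id"]
        pool = scored[scored["tile_id"].isin(set(test_ids))]
    else:
        pool = scored
    threshold = np.quantile(pool[score].to_numpy(), 1.0 - top_fraction)
    scored = scored.merge(designs[["tile_id", "ccre_id"]], on="tile_id")
    best = scored.groupby("ccre_id")[score].max()
    out = pd.DataFrame(
        {
            "ccre_id": best.index,
            "best_score": best.to_numpy(),
            "validated": best.to_numpy() >= threshold,
        }
    ).reset_index(drop=True)
    out.attrs["threshold"] = float(threshold)
    return out


def enrichment_odds_ratio(table):
    """2x2 odds ratio (Haldane-Anscombe corrected) and Fisher exact p."""
    return fisher_odds_ratio(table)
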