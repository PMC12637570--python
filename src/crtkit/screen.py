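"""Multiplex single-cell CRISPRa screen analysis.

Cells carry many gRNAs each (high multiplicity of integration); for every
gRNA the cells are partitioned into carriers vs. all other QC-passing
cells and tested for upregulation of candidate target genes with a
conditional randomization test (CRT): the carrier indicator is resampled
from its fitted logistic dependence on technical covariates, and the
one-sided p-value compares the observed negative-binomial score
statistic for the gene against the resampled null.  Non-targeting
control (NTC) gRNAs calibrate the test; Benjamini-Hochberg adjustment at
FDR < 0.1 defines the discovery set, and each hit gRNA is re-tested
against every gene within 1 Mb to classify specificity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .stats import batched_glm, bh_adjust, estimate_nb_dispersion

__all__ = [
    "ScreenData",
    "qc_and_assign",
    "cis_pairs",
    "ScreenTester",
    "calibrate_ntc",
    "call_hits_and_specificity",
    "gene_summary",
]


@dataclass
class ScreenData:
    """Cell x gene and cell x gRNA UMI matrices with cell covariates."""

    gene_umis: sp.csr_matrix
    guide_umis: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    guide_ids: np.ndarray
    covariates: pd.DataFrame  # index = cell_id; columns lane, mito_frac

    def __post_init__(self):
        n = len(self.cell_ids)
        if self.gene_umis.shape[0] != n or self.guide_umis.shape[0] != n:
            raise ValueError("matrices disagree on cell count")
        if not np.array_equal(
            np.asarray(self.covariates.index), np.asarray(self.cell_ids)
        ):
            raise ValueError("covariate table cell ids do not match matrices")


@dataclass
class GuideAssignments:
    matrix: sp.csr_matrix  # bool, QC-passing cells x guides
    cell_ids: np.ndarray
    guide_ids: np.ndarray
    summary: dict = field(default_factory=dict)

    def column(self, guide_id) -> np.ndarray:
        j = int(np.flatnonzero(self.guide_ids == guide_id)[0])
        return np.asarray(self.matrix[:, j].todense()).ravel().astype(bool)


def qc_and_assign(
    data: ScreenData,
    umi_threshold: int = 5,
    mito_max: float = 0.20,
    min_umis: int = 900,
):
    """Cell QC followed by gRNA assignment on the passing cells.

    A cell passes QC when its mitochondrial fraction is <= mito_max and
    its total gene UMIs >= min_umis (exclusion is strict: > 20% or
    < 900).  A gRNA is assigned to a passing cell when its UMI count is
    >= umi_threshold.
    """
    totals = np.asarray(data.gene_umis.sum(axis=1)).ravel()
    unique_genes = np.asarray((data.gene_umis > 0).sum(axis=1)).ravel()
    guide_totals = np.asarray(data.guide_umis.sum(axis=1)).ravel()
    unique_guides = np.asarray((data.guide_umis > 0).sum(axis=1)).ravel()
    mito = data.covariates["mito_frac"].to_numpy()
    qc_pass = (mito <= mito_max) & (totals >= min_umis)
    cells = pd.DataFrame(
        {
            "cell_id": data.cell_ids,
            "total_umis": totals,
            "unique_genes": unique_genes,
            "mito_frac": mito,
            "lane": data.covariates["lane"].to_numpy(),
            "guide_umis": guide_totals,
            "unique_guides": unique_guides,
            "qc_pass": qc_pass,
        }
    )
    passing = data.guide_umis[qc_pass]
    assigned = (passing >= umi_threshold).tocsr()
    per_cell = np.asarray(assigned.sum(axis=1)).ravel()
    per_guide = np.asarray(assigned.sum(axis=0)).ravel()
    summary = {
        "n_cells": int(len(data.cell_ids)),
        "n_cells_qc": int(qc_pass.sum()),
        "assignment_rate": float((per_cell > 0).mean()) if qc_pass.any() else 0.0,
        "mean_guides_per_cell": float(per_cell.mean()) if qc_pass.any() else 0.0,
        "mean_cells_per_guide": float(per_guide.mean()),
        "effective_cells": float(per_cell.mean() * qc_pass.sum()),
    }
    return cells, GuideAssignments(
        assigned, np.asarray(data.cell_ids)[qc_pass], np.asarray(data.guide_ids), summary
    )


def cis_pairs(
    guide_sites: pd.DataFrame,
    gene_tss: pd.DataFrame,
    half_window: int = 1_000_000,
) -> pd.DataFrame:
    """(gRNA, gene) pairs with |TSS - site midpoint| <= half_window.

    guide_sites: columns guide_id, chrom, start, end.  gene_tss: columns
    gene, chrom, tss (one row per gene; multi-TSS genes use their
    canonical TSS here).  The window boundary is inclusive and pairs
    must share a chromosome.
    """
    rows = []
    mid = (guide_sites["start"] + guide_sites["end"]) // 2
    for (gid, chrom, m) in zip(guide_sites["guide_id"], guide_sites["chrom"], mid):
        sub = gene_tss[gene_tss["chrom"] == chrom]
        d = (sub["tss"] - m).abs()
        keep = d <= half_window
        for gene, dist in zip(sub.loc[keep, "gene"], d[keep]):
            rows.append({"guide_id": gid, "gene": gene, "tss_distance": int(dist)})
    return pd.DataFrame(rows, columns=["guide_id", "gene", "tss_distance"])


def _test_seed(master_seed: int, guide_id, gene) -> int:
    """Stable per-(gRNA, gene) seed so parallel execution is reproducible."""
    h = zlib.crc32(f"{guide_id}|{gene}".encode())
    return int((master_seed * 1_000_003 + h) % (2**31 - 1))


class ScreenTester:
    """Cached CRT machinery over the QC-passing cells.

    Fits one logistic carrier-probability model per gRNA and one
    negative-binomial null model (covariates only, log total-UMI offset)
    per gene; individual (gRNA, gene) tests then reduce to resampling
    the carrier indicator B times.
    """

    def __init__(
        self,
        data: ScreenData,
        cells: pd.DataFrame,
        assignments: GuideAssignments,
        B: int = 1000,
        seed: int = 0,
        min_treated: int = 20,
        dispersion_floor: float = 1e-4,
        pseudocount: float = 0.01,
    ):
        if B < 100:
            raise ValueError("B must be at least 100")
        self.B = int(B)
        self.seed = int(seed)
        self.min_treated = int(min_treated)
        self.pseudocount = float(pseudocount)
        self.dispersion_floor = float(dispersion_floor)
        self.assignments = assignments
        keep = cells["qc_pass"].to_numpy()
        sub = cells.loc[keep].reset_index(drop=True)
        self._gene_ids = np.asarray(data.gene_ids)
        self._genes_index = {g: i for i, g in enumerate(self._gene_ids)}
        self._guide_index = {g: i for i, g in enumerate(assignments.guide_ids)}
        self._Y = data.gene_umis[keep].tocsc()
        totals = sub["total_umis"].to_numpy(dtype=float)
        self._offset = np.log(np.maximum(totals, 1.0))
        self._size_factors = totals / np.median(totals)
        cols = [
            np.ones(len(sub)),
            np.log(np.maximum(totals, 1.0)),
            np.log1p(sub["unique_genes"].to_numpy(dtype=float)),
            np.log1p(sub["guide_umis"].to_numpy(dtype=float)),
            sub["mito_frac"].to_numpy(dtype=float),
        ]
        for lane in sorted(pd.unique(sub["lane"]))[1:]:
            cols.append((sub["lane"] == lane).to_numpy(dtype=float))
        self.X = np.column_stack(cols)
        self.n_cells = self.X.shape[0]
        self._gene_null: dict = {}
        self._guide_prob: dict = {}

    # -- cached model fits -------------------------------------------------
    def fit_gene_nulls(self, genes):
        todo = [g for g in genes if g not in self._gene_null]
        if not todo:
            return
        idx = [self._genes_index[g] for g in todo]
        Y = np.asarray(self._Y[:, idx].todense(), dtype=float).T  # genes x cells
        nonzero = Y.sum(axis=1) > 0
        mu = np.zeros_like(Y)
        alpha = np.full(len(todo), self.dispersion_floor)
        if nonzero.any():
            pois = batched_glm(
                self.X, Y[nonzero], family="poisson", offset=self._offset
            )
            a = estimate_nb_dispersion(
                Y[nonzero], pois["mu"], floor=self.dispersion_floor
            )
            fit = batched_glm(
                self.X, Y[nonzero], family="nb", alpha=a, offset=self._offset
            )
            mu[nonzero] = fit["mu"]
            alpha[nonzero] = a
        for j, g in enumerate(todo):
            self._gene_null[g] = (Y[j], mu[j], float(alpha[j]), bool(nonzero[j]))

    def fit_guide_probs(self, guides):
        todo = [g for g in guides if g not in self._guide_prob]
        if not todo:
            return
        idx = [self._guide_index[g] for g in todo]
        Xg = np.asarray(
            self.assignments.matrix[:, idx].todense(), dtype=float
        ).T  # guides x cells
        fit = batched_glm(self.X, Xg, family="binomial", ridge=1e-6)
        probs = np.clip(fit["mu"], 1e-8, 1 - 1e-8)
        for j, g in enumerate(todo):
            self._guide_prob[g] = probs[j]

    # -- single test -------------------------------------------------------
    def test(self, guide_id, gene, B: int | None = None) -> dict:
        """One-sided (upregulation) CRT p and average log2 fold-change."""
        B = self.B if B is None else int(B)
        x = self.assignments.column(guide_id)
        n_treated = int(x.sum())
        base = {
            "guide_id": guide_id,
            "gene": gene,
            "n_treated": n_treated,
            "B": B,
        }
        if n_treated < self.min_treated:
            return {**base, "p": np.nan, "log2fc": np.nan, "tested": False,
                    "zero_expression": False}
        self.fit_gene_nulls([gene])
        y, mu, alpha, nonzero = self._gene_null[gene]
        if not nonzero:
            return {**base, "p": 1.0, "log2fc": 0.0, "tested": True,
                    "zero_expression": True}
        self.fit_guide_probs([guide_id])
        prob = self._guide_prob[guide_id]
        score = (y - mu) / (1.0 + alpha * mu)
        t_obs = float(score[x].sum())
        rng = np.random.default_rng(_test_seed(self.seed, guide_id, gene))
        n_ge = 0
        chunk = max(1, int(5_000_000 // self.n_cells))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            draws = rng.random((b, self.n_cells)) < prob
            t_null = draws @ score
            n_ge += int((t_null >= t_obs).sum())
            done += b
        p = (1.0 + n_ge) / (B + 1.0)
        norm = y / self._size_factors
        c = self.pseudocount
        log2fc = float(
            np.log2((norm[x].mean() + c) / (norm[~x].mean() + c))
        )
        return {**base, "p": p, "log2fc": log2fc, "tested": True,
                "zero_expression": False}

    def run_tests(self, pairs: pd.DataFrame, B: int | None = None) -> pd.DataFrame:
        """Run the CRT for every (guide_id, gene) row; prefits in batch."""
        self.fit_gene_nulls(pd.unique(pairs["gene"]))
        self.fit_guide_probs(pd.unique(pairs["guide_id"]))
        return pd.DataFrame(
            [self.test(g, t, B=B) for g, t in zip(pairs["guide_id"], pairs["gene"])]
        )


def calibrate_ntc(
    ntc_pvalues,
    n_targeting_tests: int,
    seed: int = 0,
    alphas=(0.01, 0.05),
) -> dict:
    """Calibration report from non-targeting-control test p-values.

    Downsamples the NTC p-values to the number of targeting cis tests,
    then reports the Kolmogorov-Smirnov statistic against Uniform(0,1),
    empirical type-I error at the requested alphas, and a QQ table.
    """
    p = np.asarray(ntc_pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 50:
        raise ValueError("need at least 50 NTC tests")
    rng = np.random.default_rng(seed)
    if p.size > n_targeting_tests:
        p_ds = rng.choice(p, size=n_targeting_tests, replace=False)
    else:
        p_ds = p
    ks_stat, ks_p = sps.kstest(p, "uniform")
    sorted_p = np.sort(p_ds)
    expected = (np.arange(1, sorted_p.size + 1) - 0.5) / sorted_p.size
    return {
        "n_ntc_tests": int(p.size),
        "n_downsampled": int(p_ds.size),
        "ks_stat": float(ks_stat),
        "ks_p": float(ks_p),
        "type_i_error": {float(a): float((p < a).mean()) for a in alphas},
        "qq": pd.DataFrame({"expected": expected, "observed": sorted_p}),
    }


def call_hits_and_specificity(
    results: pd.DataFrame,
    tester: ScreenTester,
    guide_sites: pd.DataFrame,
    gene_tss: pd.DataFrame,
    fdr: float = 0.1,
    specificity_window: int = 1_000_000,
) -> pd.DataFrame:
    """BH over intended-target tests, then 1 Mb neighborhood re-testing.

    A hit gRNA is 'specific' when, among all genes with a TSS within the
    window of its site (BH within that neighborhood family), only the
    intended target is significant.
    """
    out = results.copy()
    tested = out["tested"].to_numpy(dtype=bool)
    q = np.full(len(out), np.nan)
    q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["hit"] = tested & (q < fdr)
    spec = np.array(["untested"] * len(out), dtype=object)
    neighborhoods = cis_pairs(
        guide_sites[guide_sites["guide_id"].isin(out.loc[out["hit"], "guide_id"])],
        gene_tss,
        half_window=specificity_window,
    )
    for i in np.flatnonzero(out["hit"].to_numpy()):
        gid = out.at[i, "guide_id"]
        target = out.at[i, "gene"]
        hood = neighborhoods[neighborhoods["guide_id"] == gid]
        res = tester.run_tests(hood)
        res = res[res["tested"]]
        if res.empty or target not in set(res["gene"]):
            spec[i] = "non_specific"
            continue
        qn = bh_adjust(res["p"].to_numpy())
        sig = set(res.loc[qn < fdr, "gene"])
        spec[i] = "specific" if sig == {target} else "non_specific"
    out["specificity"] = spec
    return out


def gene_summary(
    hits: pd.DataFrame,
    guide_meta: pd.DataFrame,
    assignments_summary: dict,
    proximal_bp: int = 100_000,
) -> dict:
    """Per-gene hit counts and headline screen figures.

    hits: output of :func:`call_hits_and_specificity` (needs guide_id,
    gene, hit).  guide_meta: columns guide_id, kind ('promoter' |
    'enhancer').  Distances for enhancer hits come from the
    ``tss_distance`` column when present.
    """
    merged = hits.merge(guide_meta[["guide_id", "kind"]], on="guide_id", how="left")
    hit_rows = merged[merged["hit"]]
    per_gene = (
        hit_rows.groupby(["gene", "kind"]).size().unstack(fill_value=0)
        if not hit_rows.empty
        else pd.DataFrame()
    )
    for col in ("promoter", "enhancer"):
        if col not in per_gene.columns:
            per_gene[col] = 0
    per_gene = per_gene.rename(
        columns={"promoter": "n_promoter_hits", "n_promoter": "n_promoter_hits",
                 "enhancer": "n_enhancer_hits"}
    )[["n_promoter_hits", "n_enhancer_hits"]]
    per_gene["n_hits"] = per_gene.sum(axis=1)
    enh = hit_rows[hit_rows["kind"] == "enhancer"]
    frac_proximal = (
        float((enh["tss_distance"].abs() <= proximal_bp).mean())
        if "tss_distance" in enh.columns and not enh.empty
        else np.nan
    )
    return {
        "per_gene": per_gene,
        "n_activating_guides": int(hit_rows["guide_id"].nunique()),
        "n_genes_upregulated": int((per_gene["n_hits"] >= 1).sum()),
        "n_genes_2plus": int((per_gene["n_hits"] >= 2).sum()),
        "frac_enhancer_hits_proximal": frac_proximal,
        "effective_cells": assignments_summary.get("effective_cells", np.nan),
    }
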