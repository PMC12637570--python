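import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crtkit.screen import (
    ScreenData,
    ScreenTester,
    calibrate_ntc,
    call_hits_and_specificity,
    cis_pairs,
    gene_summary,
    qc_and_assign,
)
from conftest import make_screen


def tiny_screen():
    """Four hand-built cells exercising every QC boundary."""
    gene = sp.csr_matrix(
        np.array(
            [
                [500, 400],  # 900 UMIs, mito 0.10 -> kept (strict <900 rule)
                [600, 500],  # 1100 UMIs, mito 0.25 -> dropped
                [450, 449],  # 899 UMIs -> dropped
                [800, 700],  # kept
            ]
        )
    )
    guide = sp.csr_matrix(np.array([[7, 4, 5], [9, 9, 9], [9, 9, 9], [0, 5, 2]]))
    cells = np.array([f"c{i}" for i in range(4)])
    cov = pd.DataFrame(
        {"lane": [1, 1, 2, 2], "mito_frac": [0.10, 0.25, 0.05, 0.20]},
        index=pd.Index(cells, name="cell_id"),
    )
    return ScreenData(gene, guide, cells, np.array(["gA", "gB"]),
                      np.array(["u1", "u2", "u3"]), cov)


class TestQCAndAssignment:
    def test_qc_boundaries(self):
        cells, _ = qc_and_assign(tiny_screen())
        assert list(cells["qc_pass"]) == [True, False, False, True]

    def test_umi_threshold_inclusive_at_five(self):
        _, asg = qc_and_assign(tiny_screen())
        first = np.asarray(asg.matrix[0].todense()).ravel()
        assert list(first) == [1, 0, 1]  # {7, 4, 5} -> two assignments

    def test_mismatched_cell_ids_rejected(self):
        d = tiny_screen()
        bad_cov = d.covariates.copy()
        bad_cov.index = ["x0", "x1", "x2", "x3"]
        with pytest.raises(ValueError):
            ScreenData(d.gene_umis, d.guide_umis, d.cell_ids, d.gene_ids,
                       d.guide_ids, bad_cov)


class TestCisPairs:
    def sites(self):
        return pd.DataFrame(
            {"guide_id": ["g1"], "chrom": ["chr2"], "start": [4_999_990],
             "end": [5_000_010]}
        )

    def test_window_filtering(self):
        tss = pd.DataFrame(
            {"gene": ["a", "b", "c"], "chrom": "chr2",
             "tss": [4_200_000, 5_500_000, 6_200_000]}
        )
        pairs = cis_pairs(self.sites(), tss)
        assert set(pairs["gene"]) == {"a", "b"}

    def test_boundary_inclusive(self):
        tss = pd.DataFrame({"gene": ["x"], "chrom": ["chr2"], "tss": [6_000_000]})
        assert len(cis_pairs(self.sites(), tss)) == 1

    def test_cross_chromosome_excluded(self):
        tss = pd.DataFrame({"gene": ["x"], "chrom": ["chr3"], "tss": [5_000_000]})
        assert cis_pairs(self.sites(), tss).empty

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        sites = pd.DataFrame(
            {
                "guide_id": [f"g{i}" for i in range(30)],
                "chrom": rng.choice(["chr1", "chr2"], 30),
                "start": rng.integers(0, 50_000_000, 30),
            }
        )
        sites["end"] = sites["start"] + 20
        tss = pd.DataFrame(
            {
                "gene": [f"t{i}" for i in range(800)],
                "chrom": rng.choice(["chr1", "chr2"], 800),
                "tss": rng.integers(0, 50_000_000, 800),
            }
        )
        got = set(map(tuple, cis_pairs(sites, tss)[["guide_id", "gene"]].to_numpy()))
        expected = set()
        for s in sites.itertuples(index=False):
            mid = (s.start + s.end) // 2
            for t in tss.itertuples(index=False):
                if t.chrom == s.chrom and abs(t.tss - mid) <= 1_000_000:
                    expected.add((s.guide_id, t.gene))
        assert got == expected


@pytest.fixture(scope="module")
def effect_screen():
    """Moderate screen with strong planted effects on half the target genes."""
    planted = {f"gd{i:04d}": 2.0 for i in range(0, 30, 2)}
    data, meta, truth, gene_table = make_screen(
        n_cells=6_000, planted=planted, seed=5
    )
    cells, asg = qc_and_assign(data)
    tester = ScreenTester(data, cells, asg, B=400, seed=9)
    return data, meta, truth, gene_table, cells, asg, tester


class TestCRT:
    def test_p_lower_bound_and_determinism(self, effect_screen):
        _, meta, truth, _, _, _, tester = effect_screen
        gid = truth["guide_id"].iloc[0]
        gene = truth["target_gene"].iloc[0]
        r1 = tester.test(gid, gene)
        r2 = tester.test(gid, gene)
        assert r1["p"] == r2["p"]  # derived per-pair seed
        assert r1["p"] >= 1.0 / (r1["B"] + 1)

    def test_planted_effect_detected_with_fc(self, effect_screen):
        _, meta, truth, _, _, _, tester = effect_screen
        res = tester.run_tests(
            truth.rename(columns={"target_gene": "gene"})[["guide_id", "gene"]]
        )
        assert (res["p"] < 0.05).mean() >= 0.8
        assert res["log2fc"].mean() == pytest.approx(1.0, abs=0.3)

    def test_zero_expression_gene_flagged(self, effect_screen):
        data, meta, truth, gene_table, cells, asg, tester = effect_screen
        # graft a silent gene onto the tester's matrix
        gid = truth["guide_id"].iloc[0]
        tester._gene_null["silent"] = (
            np.zeros(tester.n_cells),
            np.zeros(tester.n_cells),
            1e-4,
            False,
        )
        r = tester.test(gid, "silent")
        assert r["p"] == 1.0 and r["log2fc"] == 0.0 and r["zero_expression"]

    def test_too_few_treated_cells_untested(self, effect_screen):
        *_, tester = effect_screen
        tester_small = tester
        old = tester_small.min_treated
        tester_small.min_treated = 10**9
        try:
            r = tester_small.test("gd0000", "g000")
            assert not r["tested"] and np.isnan(r["p"])
        finally:
            tester_small.min_treated = old


class TestCalibration:
    def test_uniform_pvalues_pass(self):
        rng = np.random.default_rng(0)
        rep = calibrate_ntc(rng.random(2_000), 500, seed=1)
        assert rep["ks_p"] > 0.01
        assert rep["n_downsampled"] == 500
        assert rep["type_i_error"][0.05] == pytest.approx(0.05, abs=0.02)

    def test_minimum_test_count_enforced(self):
        with pytest.raises(ValueError):
            calibrate_ntc(np.random.default_rng(0).random(10), 5)


class TestHitsAndSpecificity:
    def test_bh_hand_example(self):
        res = pd.DataFrame(
            {
                "guide_id": ["a", "b", "c"],
                "gene": ["x", "y", "z"],
                "p": [0.001, 0.02, 0.5],
                "log2fc": [1.0, 1.0, 0.0],
                "n_treated": 100,
                "tested": True,
            }
        )

        class NoopTester:
            def run_tests(self, pairs):
                return pd.DataFrame(
                    columns=["guide_id", "gene", "p", "tested"]
                )

        sites = pd.DataFrame(
            {"guide_id": ["a", "b", "c"], "chrom": "chr9",
             "start": [0, 0, 0], "end": [20, 20, 20]}
        )
        tss = pd.DataFrame({"gene": [], "chrom": [], "tss": []})
        out = call_hits_and_specificity(res, NoopTester(), sites, tss)
        assert np.allclose(out["q"], [0.003, 0.03, 0.5])
        assert list(out["hit"]) == [True, True, False]

    def test_planted_hits_called_specific(self, effect_screen):
        data, meta, truth, gene_table, cells, asg, tester = effect_screen
        intended = meta[~meta["is_ntc"]][["guide_id", "target_gene"]].rename(
            columns={"target_gene": "gene"}
        )
        res = tester.run_tests(intended.iloc[:60])
        sites = meta[~meta["is_ntc"]][["guide_id", "chrom", "start", "end"]]
        tss = gene_table[["gene", "chrom", "tss"]]
        out = call_hits_and_specificity(res, tester, sites, tss)
        hits = out[out["hit"]]
        planted_ids = set(truth["guide_id"])
        tested_planted = planted_ids & set(res["guide_id"])
        assert tested_planted <= set(hits["guide_id"])  # full recall here
        # carriers of different guides overlap in a multiplexed screen, so
        # a guide sharing a planted guide's target can surface; allow a
        # bounded false-discovery proportion rather than none
        fdp = 1.0 - len(set(hits["guide_id"]) & planted_ids) / len(hits)
        assert fdp <= 0.2
        # genes are 200 kb apart here, so each hit is re-tested against
        # ~11 cis neighbours; most planted single-gene effects classify
        # specific, with occasional neighbour significance from the same
        # carrier-overlap leakage (the study itself reports 86%)
        planted_hits = hits[hits["guide_id"].isin(planted_ids)]
        assert (planted_hits["specificity"] == "specific").mean() >= 0.7


class TestGeneSummary:
    def test_mixed_hit_counts(self):
        hits = pd.DataFrame(
            {
                "guide_id": ["g1", "g2", "g3"],
                "gene": ["A", "A", "B"],
                "hit": [True, True, False],
                "tss_distance": [500, 50_000, 10],
            }
        )
        meta = pd.DataFrame(
            {"guide_id": ["g1", "g2", "g3"],
             "kind": ["promoter", "enhancer", "promoter"]}
        )
        s = gene_summary(hits, meta, {"effective_cells": 123.0})
        assert s["per_gene"].loc["A", "n_promoter_hits"] == 1
        assert s["per_gene"].loc["A", "n_enhancer_hits"] == 1
        assert s["n_genes_2plus"] == 1
        assert s["frac_enhancer_hits_proximal"] == 1.0
        assert s["effective_cells"] == 123.0

    def test_no_hits(self):
        hits = pd.DataFrame(
            {"guide_id": ["g1"], "gene": ["A"], "hit": [False]}
        )
        meta = pd.DataFrame({"guide_id": ["g1"], "kind": ["promoter"]})
        s = gene_summary(hits, meta, {})
        assert s["n_genes_upregulated"] == 0 and s["n_activating_guides"] == 0
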