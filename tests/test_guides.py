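import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtkit.guides import (
    ENHANCER_THRESHOLDS,
    annotate_distances,
    apply_filters,
    cage_mode_tss,
    default_on_target_score,
    enumerate_guides,
    finalize_spacer,
    iterative_select,
    make_ntc_spacers,
    sa_pam_compatible,
)


def regex_oracle(seq, start, end):
    """Exhaustive scan for 20-mer + NGG sites on both strands."""
    sub = seq[start:end]
    fwd = {
        (start + m.start(1), "+")
        for m in re.finditer(r"(?=([ACGT]{20})[ACGT]GG)", sub)
    }
    rev = {
        (start + m.start(1), "-")
        for m in re.finditer(r"(?=CC[ACGT]([ACGT]{20}))", sub)
    }
    return fwd | rev


class TestEnumeration:
    @pytest.mark.parametrize("seed", [0, 1, 2, 5])
    def test_matches_regex_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        cand = enumerate_guides({"c": seq}, ("c", 100, 1_900))
        got = set(zip(cand["site_start"], cand["strand"]))
        assert got == regex_oracle(seq, 100, 1_900)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=23, max_size=200))
    def test_enumeration_matches_regex_property(self, seq):
        cand = enumerate_guides({"c": seq}, ("c", 0, len(seq)))
        got = set(zip(cand["site_start"], cand["strand"]))
        assert got == regex_oracle(seq, 0, len(seq))

    def test_toy_single_site(self):
        # lone AGG PAM at (1-based) positions 21-23; no CC anywhere
        seq = "ATATATATATATATATATAT" + "AGG" + "ATATATA"
        cand = enumerate_guides({"c": seq}, ("c", 0, len(seq)))
        assert len(cand) == 1
        row = cand.iloc[0]
        assert (row["strand"], row["site_start"], row["site_end"]) == ("+", 0, 20)
        assert row["pam"] == "AGG"

    def test_region_shorter_than_site_is_empty(self):
        seq = "ACGT" * 100
        assert enumerate_guides({"c": seq}, ("c", 0, 22)).empty

    def test_pam_density_on_random_sequence(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        cand = enumerate_guides({"c": seq}, ("c", 0, 100_000))
        density = len(cand) / 100_000
        assert density == pytest.approx(2 / 16, rel=0.10)


class TestFilters:
    def frame(self, spacers):
        return pd.DataFrame(
            {
                "protospacer": spacers,
                "strand": "+",
                "chrom": "c",
                "site_start": range(len(spacers)),
                "site_end": [s + 20 for s in range(len(spacers))],
                "pam": "AGG",
                "flank6": "AGGAAT",
            }
        )

    def test_polyT_excluded(self):
        cand = apply_filters(self.frame(["ACGTTTTACGTACGTACGTA"]), {})
        assert cand.iloc[0]["flag_polyT"] and not cand.iloc[0]["passes_filters"]

    def test_extreme_gc_excluded(self):
        low = "ATATATATATATATATATGC"  # 10% GC
        cand = apply_filters(self.frame([low]), {})
        assert cand.iloc[0]["flag_gc"]

    def test_duplicate_spacer_excluded(self):
        sp = "ACGTACGGACTGACGGTCAG"
        genome = {"c": "TTTT" + sp + "TTTT" + sp + "TTTT"}
        cand = apply_filters(self.frame([sp]), genome)
        assert cand.iloc[0]["flag_duplicate"]


class TestDistances:
    def site(self, start):
        return pd.DataFrame(
            {
                "protospacer": ["A" * 20],
                "strand": ["+"],
                "chrom": ["c"],
                "site_start": [start],
                "site_end": [start + 20],
            }
        )

    def test_enhancer_center_distance(self):
        cand = annotate_distances(
            self.site(1290), "enhancer", ccre_interval=(1000, 1500)
        )
        assert cand.iloc[0]["distance"] == 50

    def test_promoter_upstream_negative_on_plus_strand(self):
        cage = (np.array([2000, 2001, 2002]), np.array([5, 50, 5]))
        cand = annotate_distances(
            self.site(1841), "promoter", strand="+", tss=2001, cage=cage
        )
        assert cand.iloc[0]["distance"] == -150

    def test_symmetric_cage_mode_matches_annotation(self):
        pos = np.arange(1990, 2011)
        counts = 100 - np.abs(pos - 2000)
        assert cage_mode_tss(pos, counts) == 2000

    def test_empty_cage_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="CAGE"):
            cand = annotate_distances(
                self.site(1990),
                "promoter",
                strand="+",
                tss=2000,
                cage=(np.array([]), np.array([])),
            )
        assert cand.iloc[0]["distance"] == 0


class TestSelection:
    def candidates(self):
        # scores/distances arranged so 2 pass round 1 and 3 more round 2
        return pd.DataFrame(
            {
                "protospacer": [f"{'ACGT' * 5}"] * 6,
                "strand": ["+"] * 6,
                "site_start": [100, 200, 300, 400, 500, 600],
                "site_end": [120, 220, 320, 420, 520, 620],
                "score": [0.9, 0.85, 0.75, 0.72, 0.71, 0.3],
                "distance": [10, 20, 10, 30, 40, 5],
                "passes_filters": [True] * 6,
            }
        )

    def test_round_labels_follow_relaxation(self):
        sel = iterative_select(self.candidates(), ENHANCER_THRESHOLDS, k=4)
        assert list(sel["round"]) == [1, 1, 2, 2]
        assert list(sel["score"]) == [0.9, 0.85, 0.75, 0.72]

    def test_shortfall_flag(self):
        sel = iterative_select(self.candidates().head(1), ENHANCER_THRESHOLDS, k=4)
        assert len(sel) == 1 and sel.attrs["shortfall"]

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            iterative_select(self.candidates(), [(0.5, 100), (0.8, 200)], k=4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permutation_invariant(self, seed):
        cand = self.candidates()
        perm = cand.sample(frac=1, random_state=seed).reset_index(drop=True)
        a = iterative_select(cand, ENHANCER_THRESHOLDS, k=4)
        b = iterative_select(perm, ENHANCER_THRESHOLDS, k=4)
        key = ["site_start", "round"]
        assert sorted(map(tuple, a[key].to_numpy())) == sorted(
            map(tuple, b[key].to_numpy())
        )

    def test_selected_pass_round_thresholds(self):
        sel = iterative_select(self.candidates(), ENHANCER_THRESHOLDS, k=4)
        for row in sel.itertuples(index=False):
            min_s, max_d = ENHANCER_THRESHOLDS[row.round - 1]
            assert row.score >= min_s and abs(row.distance) <= max_d
        assert list(sel["round"]) == sorted(sel["round"])


class TestSpacerFinalization:
    def test_g_start_unchanged(self):
        assert finalize_spacer("G" + "A" * 19) == "G" + "A" * 19

    def test_non_g_start_replaced(self):
        proto = "ATGCATGCATGCATGCATGC"
        out = finalize_spacer(proto)
        assert out == "G" + proto[1:]
        assert len(out) == 20 and out[0] == "G"


class TestSaPAM:
    @pytest.mark.parametrize(
        "flank,expected",
        [("TGGAGT", True), ("TGGACC", False), ("AAGGGT", True), ("AAGCGT", False)],
    )
    def test_nngrrt_pattern(self, flank, expected):
        assert sa_pam_compatible(flank) is expected

    def test_truncated_flank_warns_false(self):
        with pytest.warns(UserWarning, match="truncated"):
            assert sa_pam_compatible("TGG") is False


class TestNTC:
    def test_spacers_absent_from_genome(self):
        rng = np.random.default_rng(4)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=5_000))}
        ntcs = make_ntc_spacers(5, genome, seed=1)
        assert len(set(ntcs)) == 5
        from crtkit.guides import spacer_occurrences

        assert all(spacer_occurrences(s, genome) == 0 for s in ntcs)


def test_default_score_bounded():
    rng = np.random.default_rng(0)
    for _ in range(200):
        sp = "".join(rng.choice(list("ACGT"), size=20))
        assert 0.0 <= default_on_target_score(sp) <= 1.0
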