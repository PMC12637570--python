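"""CRISPRa gRNA design: enumeration, filtering, and iterative selection.

Protospacers are 20-mers adjacent to an NGG PAM (S. pyogenes), found on
both strands of a target region.  Candidates with poly-T stretches
(Pol III terminator), extreme GC content, or spacers occurring more than
once in the supplied sequence set are excluded.  Promoter-targeting
candidates are ranked by signed distance to the CAGE-mode transcription
start site; enhancer-targeting candidates by distance to the element
center.  Up to k guides per target are chosen over successive rounds of
relaxing score/distance thresholds.  Final expression spacers begin with
G (Pol III initiation) followed by the 19 PAM-proximal protospacer
bases.  A 6-bp 3' flank determines compatibility with the S. aureus
Cas9 PAM (NNGRRT), relevant for retargeting validated elements with
smaller effectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "enumerate_guides",
    "SpacerIndex",
    "apply_filters",
    "default_on_target_score",
    "cage_mode_tss",
    "annotate_distances",
    "iterative_select",
    "finalize_spacer",
    "sa_pam_compatible",
    "make_ntc_spacers",
    "PROMOTER_THRESHOLDS",
    "ENHANCER_THRESHOLDS",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

# default selection rounds: (min on-target score, max |distance| in bp),
# strictly relaxing; configuration, not a biological constant
PROMOTER_THRESHOLDS = [
    (0.8, 150),
    (0.7, 250),
    (0.6, 400),
    (0.5, 600),
    (0.4, 1000),
    (0.0, np.inf),
]
ENHANCER_THRESHOLDS = [
    (0.8, 25),
    (0.7, 50),
    (0.6, 75),
    (0.5, 100),
    (0.4, 135),
    (0.0, np.inf),
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def enumerate_guides(genome: dict, region: tuple) -> pd.DataFrame:
    """All NGG protospacers whose 23-mer site lies inside a region.

    region = (chrom, start, end), 0-based half-open.  The returned site
    interval [site_start, site_end) covers the 20-bp protospacer; the
    PAM and 6-bp 3' flank are reported on the protospacer strand (the
    flank's first three bases are the PAM, truncated at contig ends).
    """
    chrom, start, end = region
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise ValueError("region outside sequence bounds")
    rows = []
    sub = seq[start:end].upper()
    n = len(sub)
    for i in range(0, n - 22):
        # plus strand: spacer [i, i+20), PAM [i+20, i+23)
        if sub[i + 21] == "G" and sub[i + 22] == "G":
            g0 = start + i
            flank = seq[g0 + 20 : g0 + 26].upper()
            rows.append(
                {
                    "protospacer": sub[i : i + 20],
                    "strand": "+",
                    "chrom": chrom,
                    "site_start": g0,
                    "site_end": g0 + 20,
                    "pam": sub[i + 20 : i + 23],
                    "flank6": flank,
                }
            )
        # minus strand: CCN at [i, i+3) is the PAM; spacer [i+3, i+23)
        if sub[i] == "C" and sub[i + 1] == "C":
            g0 = start + i + 3
            flank = revcomp(seq[max(0, start + i - 3) : start + i + 3].upper())
            rows.append(
                {
                    "protospacer": revcomp(sub[i + 3 : i + 23]),
                    "strand": "-",
                    "chrom": chrom,
                    "site_start": g0,
                    "site_end": g0 + 20,
                    "pam": revcomp(sub[i : i + 3]),
                    "flank6": flank,
                }
            )
    cols = ["protospacer", "strand", "chrom", "site_start", "site_end", "pam", "flank6"]
    return pd.DataFrame(rows, columns=cols)


def _max_run(seq: str, base: str) -> int:
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_WEIGHTS = (4 ** np.arange(20)).astype(np.int64)


def _encode_20mers(seq: str) -> np.ndarray:
    """Base-4 packed values of every 20-mer of a sequence."""
    if len(seq) < 20:
        return np.empty(0, dtype=np.int64)
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, 20)
    return windows @ _WEIGHTS


class SpacerIndex:
    """Occurrence counts of every 20-mer on both strands of a genome.

    Built once per sequence set (packed 2-bit encoding + sort) so that
    duplicate-spacer screening of many candidates stays cheap.
    """

    def __init__(self, genome: dict):
        chunks = []
        for seq in genome.values():
            chunks.append(_encode_20mers(seq))
            chunks.append(_encode_20mers(revcomp(seq)))
        allv = (
            np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        )
        self._values, self._counts = np.unique(allv, return_counts=True)

    def occurrences(self, spacers) -> np.ndarray:
        vals = np.array([_encode_20mers(s)[0] for s in spacers], dtype=np.int64)
        idx = np.searchsorted(self._values, vals)
        idx = np.clip(idx, 0, max(len(self._values) - 1, 0))
        if len(self._values) == 0:
            return np.zeros(len(vals), dtype=int)
        hit = self._values[idx] == vals
        return np.where(hit, self._counts[idx], 0)


def spacer_occurrences(spacer: str, genome: dict) -> int:
    """Occurrences of a 20-mer across both strands of all sequences."""
    rc = revcomp(spacer)
    total = 0
    for seq in genome.values():
        total += seq.count(spacer) + seq.count(rc)
    return total


def apply_filters(
    candidates: pd.DataFrame,
    genome: dict,
    gc_bounds=(0.25, 0.75),
    max_polyT: int = 3,
    spacer_index: SpacerIndex | None = None,
) -> pd.DataFrame:
    """Flag poly-T, extreme-GC and duplicated spacers; set passes_filters.

    Pass a prebuilt :class:`SpacerIndex` when filtering many targets
    against the same genome.
    """
    out = candidates.copy()
    spacers = out["protospacer"]
    gc = spacers.map(lambda s: (s.count("G") + s.count("C")) / len(s))
    out["gc"] = gc
    out["flag_polyT"] = spacers.map(lambda s: _max_run(s, "T") > max_polyT)
    out["flag_gc"] = (gc < gc_bounds[0]) | (gc > gc_bounds[1])
    if len(out):
        if spacer_index is None:
            spacer_index = SpacerIndex(genome)
        out["flag_duplicate"] = spacer_index.occurrences(list(spacers)) > 1
    else:
        out["flag_duplicate"] = pd.Series(dtype=bool)
    out["passes_filters"] = ~(out["flag_polyT"] | out["flag_gc"] | out["flag_duplicate"])
    return out


def default_on_target_score(spacer: str) -> float:
    """Deterministic heuristic on-target score in [0, 1].

    Penalizes deviation of overall GC from 0.55 and of PAM-proximal
    (last 8 nt) GC from 0.6, plus homopolymer runs beyond 3 nt.  A
    documented placeholder ranking, pluggable via the ``scorer``
    arguments downstream.
    """
    gc = (spacer.count("G") + spacer.count("C")) / len(spacer)
    prox = spacer[-8:]
    gc8 = (prox.count("G") + prox.count("C")) / len(prox)
    run = max(_max_run(spacer, b) for b in "ACGT")
    score = 1.0 - 1.2 * abs(gc - 0.55) - 0.5 * abs(gc8 - 0.6) - 0.12 * max(0, run - 3)
    return float(min(1.0, max(0.0, score)))


def cage_mode_tss(positions, counts) -> int:
    """Position of the modal 5' CAGE tag count (ties -> leftmost)."""
    positions = np.asarray(positions)
    counts = np.asarray(counts)
    order = np.argsort(positions, kind="stable")
    positions, counts = positions[order], counts[order]
    return int(positions[np.argmax(counts)])


def annotate_distances(
    candidates: pd.DataFrame,
    target_kind: str,
    strand: str | None = None,
    tss: int | None = None,
    cage: tuple | None = None,
    ccre_interval: tuple | None = None,
) -> pd.DataFrame:
    """Attach the ranking distance for one target.

    Promoter targets: signed site-midpoint distance to the CAGE-mode TSS,
    negative upstream in transcript orientation (falls back to the
    annotated TSS when the CAGE profile is empty).  Enhancer targets:
    absolute distance from the site midpoint to the element center.
    """
    out = candidates.copy()
    mid = (out["site_start"] + out["site_end"]) // 2
    if target_kind == "promoter":
        anchor = tss
        if cage is not None and len(cage[0]) > 0:
            anchor = cage_mode_tss(*cage)
        elif cage is not None:
            warnings.warn("empty CAGE profile; falling back to annotated TSS")
        if anchor is None:
            raise ValueError("promoter target needs a TSS or CAGE profile")
        signed = mid - anchor if strand == "+" else anchor - mid
        out["distance"] = signed.astype(int)
    elif target_kind == "enhancer":
        start, end = ccre_interval
        center = (start + end) // 2
        out["distance"] = (mid - center).abs().astype(int)
    else:
        raise ValueError(f"unknown target kind {target_kind!r}")
    return out


def iterative_select(
    candidates: pd.DataFrame,
    round_thresholds,
    k: int = 4,
) -> pd.DataFrame:
    """Select up to k guides over successive threshold-relaxation rounds.

    Each round admits unselected candidates with score >= min_score and
    |distance| <= max_distance, ranked by score (desc), |distance| (asc),
    leftmost coordinate, then '+' strand before '-'.  Selected rows gain
    a 1-based ``round`` label; a ``shortfall`` attr records whether fewer
    than k candidates were available in total.
    """
    for (s0, d0), (s1, d1) in zip(round_thresholds, round_thresholds[1:]):
        if s1 > s0 or d1 < d0:
            raise ValueError("round thresholds must relax monotonically")
    pool = (
        candidates[candidates["passes_filters"]]
        if "passes_filters" in candidates
        else candidates
    ).copy()
    pool["_absd"] = pool["distance"].abs()
    pool = pool.sort_values(
        by=["score", "_absd", "site_start", "strand"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    chosen = []
    taken = set()
    for rnd, (min_score, max_dist) in enumerate(round_thresholds, start=1):
        if len(chosen) >= k:
            break
        ok = pool[
            (pool["score"] >= min_score)
            & (pool["_absd"] <= max_dist)
            & (~pool.index.isin(taken))
        ]
        for idx in ok.index:
            if len(chosen) >= k:
                break
            taken.add(idx)
            chosen.append((idx, rnd))
    sel = candidates.loc[[i for i, _ in chosen]].copy()
    sel["round"] = [r for _, r in chosen]
    sel.attrs["shortfall"] = len(sel) < k
    return sel


def finalize_spacer(protospacer: str) -> str:
    """Expression spacer: G + the 19 PAM-proximal protospacer bases."""
    return "G" + protospacer[1:]


def sa_pam_compatible(flank6: str) -> bool:
    """True when the 6-bp 3' flank matches the S. aureus PAM NNGRRT."""
    if len(flank6) < 6:
        warnings.warn("flank truncated at contig end; Sa-PAM undetermined")
        return False
    return (
        flank6[2] == "G"
        and flank6[3] in "AG"
        and flank6[4] in "AG"
        and flank6[5] == "T"
    )


def make_ntc_spacers(
    n: int,
    genome: dict,
    seed: int,
    max_tries: int = 1000,
    spacer_index: SpacerIndex | None = None,
) -> list:
    """Shuffled 20-mers verified absent from the sequence set."""
    rng = np.random.default_rng(seed)
    if spacer_index is None:
        spacer_index = SpacerIndex(genome)
    out = []
    bases = np.array(list("ACGT"))
    while len(out) < n:
        for _ in range(max_tries):
            spacer = "".join(rng.choice(bases, size=20))
            if spacer_index.occurrences([spacer])[0] == 0 and spacer not in out:
                out.append(spacer)
                break
        else:
            raise RuntimeError("could not find an absent spacer")
    return out
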