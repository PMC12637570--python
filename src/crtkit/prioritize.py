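"""De novo variant burden prioritization of haploinsufficiency candidates.

Given per-gene per-generation mutation probabilities (mu, per haploid
genome) for the variant classes lof (frameshift + canonical splice +
stop-gain), missense and synonymous, the expected number of de novo
variants in a cohort of N trios is E = 2 * N * mu.  Genes previously
implicated in neurodevelopmental disorders are retained as candidates for
cis-regulation therapy when their observed/expected de novo LoF ratio is
strictly greater than 1, consistent with haploinsufficiency as the
driving mechanism.

P-values are one-sided Poisson upper tails, reported for diagnostics;
selection filters on the ratio only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import poisson_upper_tail

VARIANT_CLASSES = ("lof", "missense", "synonymous")

__all__ = [
    "VARIANT_CLASSES",
    "expected_counts",
    "oe_poisson",
    "build_records",
    "prioritize",
    "cohort_oe",
]


def expected_counts(rates: pd.DataFrame, n_trios: int) -> pd.DataFrame:
    """Per-gene per-class expectation E = 2 * n_trios * mu.

    ``rates`` is indexed by gene with one column per variant class.
    """
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    if (rates < 0).any().any():
        raise ValueError("mutation probabilities must be non-negative")
    return 2.0 * n_trios * rates


def oe_poisson(observed, expected):
    """O/E ratio and one-sided Poisson upper-tail p, elementwise.

    expected == 0 with observed > 0 yields O/E = +inf with p = 0 as a
    sentinel; callers must treat such genes as unratable (see
    :func:`build_records`).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(
            expected > 0,
            observed / np.where(expected > 0, expected, 1.0),
            np.where(observed > 0, np.inf, 0.0),
        )
    p = np.where(
        expected > 0, poisson_upper_tail(observed, np.maximum(expected, 1e-300)), 0.0
    )
    p = np.where((expected == 0) & (observed == 0), 1.0, p)
    if oe.ndim == 0:
        return float(oe), float(p)
    return oe, p


def build_records(
    counts: pd.DataFrame, rates: pd.DataFrame, n_trios: int
) -> pd.DataFrame:
    """Long-format per-gene per-class table: observed, expected, oe, p.

    Genes with expected == 0 but observed > 0 are flagged ``unratable``
    (excluded from selection) with a warning rather than letting +/-inf
    ratios propagate silently.
    """
    genes = counts.index
    rates = rates.loc[genes]
    expected = expected_counts(rates[list(VARIANT_CLASSES)], n_trios)
    rows = []
    for cls in VARIANT_CLASSES:
        obs = counts[cls].to_numpy(dtype=float)
        exp = expected[cls].to_numpy(dtype=float)
        oe, p = oe_poisson(obs, exp)
        rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "class": cls,
                    "observed": obs,
                    "expected": exp,
                    "oe": oe,
                    "p": p,
                    "unratable": (exp == 0) & (obs > 0),
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    n_bad = int(records["unratable"].sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} gene/class pairs have zero expectation with observed "
            "variants; flagged unratable and excluded from selection"
        )
    return records


def prioritize(implicated_genes, records: pd.DataFrame) -> set:
    """Candidate set: implicated genes with LoF O/E strictly > 1."""
    implicated = set(implicated_genes)
    lof = records[records["class"] == "lof"].set_index("gene")
    missing = sorted(implicated - set(lof.index))
    if missing:
        raise KeyError(f"no prioritization record for implicated gene(s): {missing}")
    sub = lof.loc[sorted(implicated)]
    ok = (sub["oe"] > 1.0) & ~sub["unratable"]
    return set(sub.index[ok])


def cohort_oe(records: pd.DataFrame, variant_class: str):
    """Aggregate cohort O/E for one class: sum(observed)/sum(expected).

    The p-value is the Poisson upper tail of the summed observed count at
    the summed expectation.
    """
    sub = records[records["class"] == variant_class]
    if sub.empty:
        raise ValueError(f"no records for class {variant_class!r}")
    obs = sub["observed"].sum()
    exp = sub["expected"].sum()
    if exp == 0:
        raise ValueError("total expectation is zero")
    return float(obs / exp), float(poisson_upper_tail(obs, exp))
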