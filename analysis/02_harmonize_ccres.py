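"""Stage 2: harmonize multi-source enhancer predictions into cCREs.

Simulates five partially overlapping prediction sources (dropout,
boundary jitter, decoys) over the stage-1 reference, extends/merges
them, removes promoter- and exon-overlapping intervals, and reports
source-support structure.  Writes results/ccres.tsv and
results/ccre_support.tsv.
"""

import sys
from pathlib import Path

from crtkit.harmonize import harmonize, overlaps_any, support_summary
from crtkit.simulate import gen_cre_predictions, gen_reference

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

ref = gen_reference(seed=SEED, n_chromosomes=2, chrom_length=2_000_000, n_genes=100)
preds, truth = gen_cre_predictions(
    ref, n_sources=5, n_true_elements=60, jitter_sd=30.0, dropout=0.2, seed=SEED + 2
)
merged = harmonize(preds, ref.gene_models)
summary = support_summary(merged)

flat = merged.copy()
flat["sources"] = flat["sources"].map(",".join)
flat["genes"] = flat["genes"].map(",".join)
flat.to_csv(OUT / "ccres.tsv", sep="\t", index=False)
summary.to_csv(OUT / "ccre_support.tsv", sep="\t", index=False)

recovered = sum(
    overlaps_any(merged, truth.iloc[[i]][["chrom", "start", "end"]]).sum() == 1
    for i in range(len(truth))
)
frac_multi = summary.loc[summary["support"] >= 2, "n_ccres"].sum() / len(merged)
print(f"{len(merged)} merged cCREs from 5 sources over {len(truth)} planted elements")
print(f"{recovered}/{len(truth)} planted elements recovered as exactly one cCRE")
print(f"{100 * frac_multi:.0f}% of cCREs supported by 2+ sources")
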