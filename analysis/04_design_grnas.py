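"""Stage 4: CRISPRa gRNA design for validated cCREs and gene TSSs.

Enumerates NGG protospacers over each target, filters (poly-T, GC,
duplicates), scores, annotates CAGE-TSS or element-center distances,
selects up to 4 guides per target over 6 relaxing rounds, finalizes
G+19 expression spacers, and reports S. aureus PAM compatibility.
Writes results/grna_library.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from crtkit.guides import (
    ENHANCER_THRESHOLDS,
    PROMOTER_THRESHOLDS,
    SpacerIndex,
    annotate_distances,
    apply_filters,
    default_on_target_score,
    enumerate_guides,
    finalize_spacer,
    iterative_select,
    make_ntc_spacers,
    sa_pam_compatible,
)
from crtkit.harmonize import harmonize
from crtkit.simulate import gen_cre_predictions, gen_reference

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

ref = gen_reference(seed=SEED, n_chromosomes=2, chrom_length=2_000_000, n_genes=100)
preds, _ = gen_cre_predictions(
    ref, n_sources=5, n_true_elements=60, jitter_sd=30.0, dropout=0.2, seed=SEED + 2
)
ccres = harmonize(preds, ref.gene_models)
genome = ref.sequences
spacer_index = SpacerIndex(genome)

rows = []
# enhancer targets: the merged cCREs, guides ranked by center distance
for c in ccres.itertuples(index=False):
    cand = enumerate_guides(genome, (c.chrom, c.start, c.end))
    if cand.empty:
        continue
    cand = apply_filters(cand, genome, spacer_index=spacer_index)
    cand["score"] = cand["protospacer"].map(default_on_target_score)
    cand = annotate_distances(cand, "enhancer", ccre_interval=(c.start, c.end))
    sel = iterative_select(cand, ENHANCER_THRESHOLDS, k=4)
    sel["target_id"], sel["kind"] = c.ccre_id, "enhancer"
    rows.append(sel)

# promoter targets: 400 bp around each TSS, CAGE-mode distance
gm = ref.gene_models
for t in gm.tss.itertuples(index=False):
    region = (t.chrom, max(0, t.pos - 200), min(ref.chromosomes[t.chrom], t.pos + 200))
    cand = enumerate_guides(genome, region)
    if cand.empty:
        continue
    cand = apply_filters(cand, genome, spacer_index=spacer_index)
    cand["score"] = cand["protospacer"].map(default_on_target_score)
    prof = ref.cage[(ref.cage["gene"] == t.gene)
                    & (ref.cage["pos"].between(t.pos - 40, t.pos + 40))]
    cand = annotate_distances(
        cand, "promoter", strand=t.strand, tss=t.pos,
        cage=(prof["pos"].to_numpy(), prof["count"].to_numpy()),
    )
    sel = iterative_select(cand, PROMOTER_THRESHOLDS, k=4)
    sel["target_id"], sel["kind"] = f"{t.gene}@{t.pos}", "promoter"
    rows.append(sel)

lib = pd.concat(rows, ignore_index=True)
lib["spacer"] = lib["protospacer"].map(finalize_spacer)
lib["sa_compatible"] = lib["flank6"].map(sa_pam_compatible)
ntc = pd.DataFrame(
    {"spacer": make_ntc_spacers(max(1, len(lib) // 10), genome, seed=SEED + 5,
                                spacer_index=spacer_index)}
)
ntc["kind"], ntc["target_id"] = "ntc", "none"
lib = pd.concat([lib, ntc], ignore_index=True)
lib.to_csv(OUT / "grna_library.tsv", sep="\t", index=False)

counts = lib["kind"].value_counts()
sa_frac = lib.loc[lib["kind"] != "ntc", "sa_compatible"].mean()
print(f"designed {len(lib)} gRNAs: {counts.get('enhancer', 0)} enhancer-targeting, "
      f"{counts.get('promoter', 0)} TSS-targeting, {counts.get('ntc', 0)} NTC")
print(f"{100 * sa_frac:.1f}% of targeting gRNAs also carry an S. aureus NNGRRT PAM")
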