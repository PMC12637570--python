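# Methods

`crtkit` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the computational discovery chain used to find
CRISPRa-targetable cis-regulatory elements (CREs) for haploinsufficient
neurodevelopmental-disorder (NDD) genes: de novo burden gene
prioritization, multi-source enhancer harmonization, MPRA activity
calling, gRNA design, and single-cell CRISPRa screen hit-calling.

## Gene prioritization (`crtkit.prioritize`)

Under the standard trio mutation model, the expected number of de novo
variants of class *c* in gene *g* across *N* trios is
*E(g,c) = 2·N·μ(g,c)*, with μ the per-haploid-genome per-generation
mutation probability (consumed as input, not estimated here). The LoF
class is the sum of frameshift, canonical-splice and stop-gain
probabilities. Per gene and per cohort we report O/E = observed/E and a
one-sided Poisson upper tail P(X ≥ obs | X ~ Poisson(E)). Candidate
selection keeps implicated genes with LoF O/E strictly > 1; p-values
are diagnostic only — no multiple-testing correction enters selection.
Genes with E = 0 but observed > 0 are flagged unratable and excluded
rather than propagating infinite ratios. The source study reports the
cohort-level dnLoF enrichment twice with slightly different values
(O/E 2.357 in the results, 2.17 in the methods; missense 1.322 vs
1.22), without stating which subset each describes; this package
implements the single summed-counts definition and reports whatever it
computes.

## cCRE harmonization (`crtkit.harmonize`)

Coordinates are 0-based half-open (BED); overlap means intersection
≥ 1 bp, so bookended intervals do not merge. Each source's predicted
element is first extended from its floor midpoint to at least 500 bp
(clipping at the chromosome edge pads the other side to preserve
width), then all sources are merged by single-linkage overlap, each
merged element carrying the union of contributing sources and linked
genes. Merged elements overlapping a strand-aware promoter window
(default 2,000 bp upstream of any TSS, merged across isoforms) or any
protein-coding exon are removed. Support = number of distinct sources.
The promoter width for the exclusion step is a flag because the
upstream datasets used both 500 and 2,000 bp promoter definitions; the
default follows the 2,000 bp filter applied at the merge step.

## MPRA design and activity calling (`crtkit.mpra`)

Tiling: 270-bp tiles at 180-bp step (90-bp overlap) from the element
start; when the last aligned tile stops short of the element end one
right-aligned tile [end−270, end) is appended, and sub-270-bp elements
get a single centered tile with genomic flanks. This covers every base
of every element at least once.

Activity: barcode counts are summed per tile × modality × replicate
(barcode-level modeling is out of scope of the default path; summing is
stable at low barcode depth). Size factors are DESeq-style
median-of-ratios across libraries. Each tile is fit with an NB
log-link regression of count on modality (RNA vs DNA) and sequencing
batch with the log size factor as offset, and the modality coefficient
is Wald-tested.

Two numerical choices deviate from the obvious textbook recipe, both
forced by calibration at m ≈ 6 observations per tile:

* **Dispersion.** A naive moment estimator ignores the variance
  absorbed by the p fitted means and is biased low, making ~25% of null
  p-values fall below 0.05. We instead solve for α such that the
  Pearson χ² equals the residual degrees of freedom m−p (bisection,
  floored at 1e-4).
* **Reference distribution.** The Wald statistic is compared to
  t(m−p) rather than the normal. With these, null p-values are
  uniform (KS p ≫ 0.01) and type-I error is nominal.

A tile is *active* iff BH q < 0.01 and log2FC > 1 (two-sided test with
a directional filter, matching the compound rule). Tiles with no
barcode or total count < 10 are tracked but not tested. Two scores are
reported: the model coefficient `log2fc` and the plain normalized ratio
`raw_log2_ratio` (mean log2 normalized RNA − mean log2 normalized DNA
over positive libraries). The ratio score is *exactly* invariant to
rescaling any single library — the size factors absorb the constant —
whereas a reweighted GLM coefficient can only be approximately so; both
are exposed, and either can drive the element-validation rule.

Empirical FDR of the active rule is (scrambled pass-rate × number of
test tiles) / number of passing test tiles — the exact estimator is not
published, so this standard choice is a documented definition. Element
validation uses the top-10% score quantile over all scored tiles
(restrictable to test tiles via a flag). Enrichment odds ratios use
Haldane–Anscombe 0.5 correction with two-sided Fisher exact p.

## gRNA design (`crtkit.guides`)

Enumeration finds every 20-mer followed by NGG on either strand whose
23-bp site lies inside the target region. Hard filters: runs of ≥ 4 T
(Pol III terminator), GC outside [25%, 75%], and spacers occurring more
than once in the sequence set (a 2-bit-packed 20-mer index makes this a
sorted-array lookup; genome-wide off-target scoring is out of scope and
this duplicate rule stands in for it). The default on-target scorer is
a deterministic heuristic on [0,1] (penalties for GC distance from
0.55, PAM-proximal GC distance from 0.6, and homopolymers) and is
pluggable — the selection algorithm, not the scorer, is the point.

Promoter guides are ranked by signed distance from the site midpoint to
the CAGE-mode TSS (upstream negative in transcript orientation; empty
profiles fall back to the annotated TSS); enhancer guides by distance
to the element center. Selection runs 6 rounds of strictly relaxing
(min score, max |distance|) thresholds — defaults score ≥
{0.8,…,0.4,0} × distance ≤ {150,…,1000,∞} bp for promoters and
{25,…,135,∞} bp for enhancers, all configurable since the study does
not print its thresholds — taking candidates ranked by score, then
|distance|, then leftmost coordinate, then + strand, until 4 per target
are held. Expression spacers are G + the 19 PAM-proximal bases.
S. aureus retargetability is a 6-bp flank match to NNGRRT; on uniform
random sequence ~1/16 of NGG sites qualify (the G at NNGRRT position 3
is the NGG's second G, leaving R, R, T free), so the synthetic
compatible fraction (~6%) is far below the study's value on real
genome sequence.

## Screen analysis (`crtkit.screen`)

QC keeps cells with mitochondrial fraction ≤ 20% and ≥ 900 UMIs
(strict-exclusion boundaries). gRNAs are assigned at ≥ 5 UMIs in a
passing cell. Cis candidate pairs are genes with a TSS within 1 Mb
(inclusive) of the gRNA site midpoint on the same chromosome.

The upregulation test is a conditional randomization test (CRT). Per
gRNA, a logistic model of carrier status on covariates — log total
UMIs, log unique genes, log total gRNA UMIs, mitochondrial fraction,
lane — yields per-cell presence probabilities. Per gene, an NB
regression of UMI count on the same covariates with log-total-UMI
offset (dispersion by method of moments on all cells, floored at
1e-4) yields null means μ and α. The test statistic is the NB score
contribution T(x) = Σᵢ xᵢ(yᵢ−μᵢ)/(1+αμᵢ); B resampled carrier vectors
are drawn as independent Bernoulli(p̂ᵢ), and the one-sided p-value is
(1 + #{T* ≥ T_obs})/(B+1), so p ≥ 1/(B+1) by construction. Because the
null distribution comes from resampling, only the ranking property of
the statistic matters, not its asymptotic calibration. Per-test seeds
derive from the master seed by hashing (gRNA, gene), so execution
order and parallelism cannot change results. The average log2
fold-change compares size-factor-normalized means of carriers vs all
other QC-passing cells with pseudocount 0.01 (the study does not
define its estimator; this one is documented here).

NTC calibration downsamples non-targeting p-values to the targeting
test count and reports KS uniformity and empirical type-I error.
Discovery applies BH at FDR < 0.1 over intended-target tests; each hit
gRNA is then re-tested against every gene within 1 Mb, with BH applied
within that neighborhood family (the study does not state its
neighborhood correction), and is *specific* iff only the intended
target is significant. Gene summaries count activating promoter/
enhancer gRNAs per gene and the effective-cell figure (mean assigned
gRNAs per cell × QC-passing cells).

## Synthetic data (`crtkit.simulate`)

All generators are deterministic under their seed and record planted
truth. The genome is i.i.d. uniform ACGT (PAM density arises naturally
at ≈ 2/16 per position); genes sit on a non-overlapping slot grid with
1–2 TSSs, 2–4 exons, 90% protein-coding, log-normal mutation rates
around 1e-5 (capped below 1e-3), and a discretized-Gaussian CAGE peak
(σ = 8 bp) strictly maximal at each TSS. De novo counts are Poisson
with mean 2·N·μ, LoF inflated by a planted factor for risk genes.
Prediction sources report each true element with probability
1−dropout, boundaries jittered N(0, jitter_sd), plus decoys in later
sources. MPRA counts are NB (variance μ+αμ², α = 0.2 — typical UMI
overdispersion) around log-normal barcode abundances × library size
factors, with the RNA mean multiplied by the planted activity
multiplier; three replicates split across two sequencing batches with
a shared batch depth effect. The screen draws truncated-Poisson(10.3)
distinct guides per cell (Gumbel top-k with a skewed library
abundance), NB(20) gRNA UMIs for present guides vs Poisson(0.1)
background — so the ≥5-UMI rule is separative but imperfect —
log-normal(0, 0.3²) cell size factors with a 3% low-quality tail, lane
effects, and a Beta mitochondrial fraction mixture pushing ~5% of
cells past 20%. Carrier cells of an effective gRNA have the target
gene's mean multiplied by its fold-change; NTCs never carry effects.

`simulate.scenarios.scaled_screen` pins the study's per-guide coverage
(~130 cells/gRNA, 10.3 gRNAs/cell) while scaling the cell total down
by shrinking the guide pool, with intended targets at ~1 UMI baseline.

What the generator does **not** emulate: read-level sequencing,
linkage/haplotype structure, chromatin state, cell-type heterogeneity,
ambient RNA, or guide-guide interactions. Passing tests therefore show
the statistical machinery is correct and calibrated under the stated
count models, not that real-data preprocessing upstream of these
matrices is handled.

## Problem sizes and known limitations

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the Monte-Carlo error of each check is well
inside its tolerance: 10,000 tiles for the MPRA null, 20 seeds × 60
planted tiles for recall, 20,000-cell/500-test/B=500 screens for NTC
type-I error, and 6 seeds of ~6,000-cell screens (two guides per gene,
all guides of 10% of genes planted at 1.5–2.5×) for FDR and
fold-change recovery. Known limitations: in a multiplexed screen,
carriers of one guide overlap carriers of another, so a guide sharing
a planted guide's target can reach significance and control-group
contamination slightly attenuates fold-change estimates — both
effects are visible in the synthetic results exactly as the study's
86% specificity figure suggests; the headline discovery counts of the
source study depend on its real datasets and are reproduced here only
as arithmetic over its published composition tables.
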