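# Methods

## Scope and data model

The package analyzes a two-condition study (a small control group against a
small case/stimulated group) with four data layers: RNA-seq gene counts,
ChIP-seq signal tracks and peaks for four histone marks (H3K4me3, H3K4me1,
H3K27ac active; H3K27me3 repressive), a 4C viewpoint fragment-count
profile, and small qPCR/3C tables. Read alignment and peak calling are out
of scope; the package starts from BED/narrowPeak peaks and binned bedGraph
coverage with a declared library size.

All internal coordinates are 0-based half-open (BED convention); GTF's
1-based inclusive coordinates are converted at the parser boundary. The TSS
of a minus-strand gene is `end − 1`. Multi-transcript genes collapse to the
first-listed TSS with a logged warning. Signal tracks store mass per
fixed-size bin; window sums prorate partial bins linearly so results are
bin-size independent, and RPM = mass × 10⁶ / library size.

## Differential expression

Counts are modeled as NB with variance μ + αμ². Choices, in order of
consequence:

* **Size factors** — median-of-ratios against the per-gene geometric-mean
  reference (genes with any zero excluded from the reference). Matches the
  standard count-normalization used by the major DE packages (verified
  against one of them in the test suite).
* **Dispersion** — pooled within-group method-of-moments per gene, then a
  trend α(μ) = a₁ + a₀/μ fitted by least squares with one 3σ trimming pass,
  then log-space shrinkage `α = trend^w · genewise^(1−w)` with **w = 0.8**.
  At 4–5 samples per group the gene-wise moment estimate is extremely
  noisy; the heavy weight on the trend is what keeps the Wald test
  calibrated (empirical type-I error ≈ 0.057 at nominal 0.05 under the
  null simulation in the acceptance script). Dispersions are clipped to
  [1e−8, 10].
* **Test** — Wald statistic on log₂((m̄_case + 0.5)/(m̄_ctrl + 0.5)) with a
  delta-method variance from the NB model, standard-normal reference,
  BH FDR. Genes with all-zero counts are dropped before testing (logged).
* **Calls** — up iff FDR ≤ 0.01 and log₂FC ≥ 1.5; down mirrored. The 1.5
  threshold is on the log₂ scale (≈ 2.83-fold), taken literally from the
  convention this pipeline standardizes on; both knobs are exposed.

Only two-level designs are supported; with < 2 replicates per group the
fold change is reported without a p-value.

## Occupancy and integration

Peaks are assigned to the gene minimizing |TSS − anchor| where the anchor
is the narrowPeak summit when present, else the midpoint; ties break toward
the smaller TSS coordinate and the distance is reported signed.

TSS windows are strand-oriented (bin 0 upstream); for minus-strand genes
the window is [tss+1−h, tss+1+h) so that mirroring the genome maps windows
onto windows exactly. Windows off a chromosome edge are zero-padded with a
warning.

Differential occupancy reconstructs per-replicate window read counts from
the tracks (window mass, rounded) and reuses the NB engine. Two
normalizations coexist deliberately:

* **significance** uses the engine's median-of-ratios on window counts —
  composition-robust, so the minority of genes with genuine mark changes
  cannot drag the null genes' ratios off zero;
* **the reported log₂ ratio** (and the direction sign) is the
  depth-normalized RPM point estimate, so a genuine global occupancy shift
  stays visible in the fold change (doubling every case track doubles RPM
  and gives log₂ ratio 1).

Occupancy significance uses its own FDR knob (default 0.05), separate from
expression's 0.01. Congruence: an up gene is congruent iff ≥ 1 active mark
increased or H3K27me3 decreased (down mirrored); non-significant occupancy
never supports. The "≥ 1 concordant mark" rule and the ± 2 kb window are
defaults (`min_supporting_marks`, `occupancy_halfwidth`), chosen because an
AND-across-marks rule would be far stricter than the roughly-half
congruence rates this kind of integration typically reports.

## Super-enhancer calling

Stitching uses the published ROSE conventions as defaults: peaks fully
contained in TSS ± 2.5 kb are removed (overlap alone does not remove), the
rest merge at gaps ≤ 12.5 kb. Regions are scored by
max(0, RPM_case − RPM_input); with no input track, net = case. The ranked
curve is min–max scaled to the unit square and cut at the smallest index
whose forward-difference slope exceeds 1 — a discrete, reproducible version
of the tangent-slope-1 elbow; an exhaustive-slope oracle validates it in
tests. The is_super set is invariant under positive scaling and constant
shifts of the signals. Ties in net signal sort by (signal, chrom, start)
for deterministic ranks; degenerate inputs (n < 3 or all signals equal)
yield zero super-enhancers.

## Motif scanning

Column probabilities (count + 0.8·background)/(colsum + 0.8), entries
log₂(p/background); the 0.8 pseudocount split by background follows the
JASPAR tooling convention. The relative score min–max scales the log-odds,
so a 0.95 threshold operationalizes ">95 % consensus". Windows containing N
are skipped; minus-strand hits are scored with the reverse-complemented
matrix and reported on plus-strand coordinates.

## Enrichment

GSEA uses the weighted (p = 1) running sum; ES is the signed maximum
deviation, with an exact positive/negative tie resolving to the positive
extreme. The null is **gene-label permutation** per set size (the package
consumes a ranking, not sample-level data — a documented deviation from
phenotype permutation, appropriate when the ranking is the input).
NES = ES / mean(|ES_perm| of the matching sign); p one-sided with +1
continuity; FDR by the sign-stratified NES tail-ratio procedure, clipped to
[0, 1]. Sets with overlap < 5 are skipped.

Over-representation is the right-tailed hypergeometric tail with BH across
sets — an open, documented stand-in for proprietary pathway scoring. The
regulator activation z-score uses unit weights,
(concordant − discordant)/√informative, a simplification of proprietary
weighted variants; output headers say so.

## 4C / 3C / qPCR

The viewpoint fragment ± 2 neighbours are masked (self-ligation artifacts;
`exclude_k` knob), remaining counts scale to 10⁶. The background is a
power law fitted by least squares on log(count+1) vs log(distance) — the
fewest-parameter model and exactly recoverable in tests; slopes ≥ −0.01 are
clipped to b ≈ 0 and flagged as non-decaying. Residual z is the studentized
log residual; calls are maximal runs of ≥ 3 consecutive unmasked fragments
with z ≥ 2, reported as genomic intervals. 3C values are ratios to a named
control site. Percent input is 100·2^((Ct_input − log₂(1/f)) − Ct_IP); it
is invariant to shifting both Ct columns and strictly decreasing in Ct_IP.

## The synthetic-study generator

The generator emulates the statistical structure of a small patient cohort
(4 control vs 5 case samples, mirroring an RNA-seq/ChIP-seq design with
few subjects) with planted ground truth:

* counts NB(μ = 500, α = 0.05) with per-sample depth factors in
  [0.8, 1.25]; 5 % of genes up and 5 % down at log₂FC = 3;
* half of the DE genes (`congruent_fraction` = 0.5) get concordant
  promoter-mark amplitude changes (active marks scale with 2^±3, H3K27me3
  anti-correlated); promoter pileups are Gaussian (σ = 300 bp) on a
  Poisson background of 0.2 per 100-bp bin;
* one enhancer cluster (8 × 1.5 kb members over 60 kb, member amplitude
  150 reads) amplified 4-fold in the case condition, plus three
  constant-signal decoy clusters at 1.5/2/2.5× its unamplified total so the
  cluster's rank measurably rises under amplification, and 150 background
  enhancers (50–400 reads) for the hockey stick's body;
* a 4C profile of 400 fragments (1–4 kb), counts Poisson(2·10⁶ · d⁻¹),
  with a 5-fold bump on 6 consecutive fragments ~50 kb from the viewpoint,
  case condition only;
* a 2 kb promoter sequence with three planted GGGACTTTCC consensus sites on
  alternating strands (re-drawn if the random background happens to contain
  an extra ≥ 0.95 match), plus a synthetic NF-κB-like count matrix
  (85/5/5/5 per column) written in JASPAR text format;
* small qPCR and 3C tables with known percent-input and ratio values.

The toy chromosome is 20 Mb: with 2000 genes the grid leaves genuinely
intergenic space for enhancers at the required TSS clearance, which a
denser genome does not. Every random quantity derives from one seed through
named sub-streams in a fixed order (layout, counts, marks, tracks,
enhancers, fourc, sequence, tables), so identical configs give
byte-identical fixtures.

What the generator does **not** emulate: GC/mappability bias, read-level
noise, replicate-specific peak shapes, multi-chromosome genomes, diploid
genotypes, or any real effect-size distribution for disease-associated
histone changes — amplitudes are config, not biology. Passing recovery
tests therefore demonstrates the correctness and calibration of the
algorithms under the stated generative model, not performance on real
cohorts.

## Problem sizes and numerics

Tests and the acceptance script use the generator's default scale (2000
genes, 20 Mb, 36 tracks) and, for calibration, 500 null replicates of a
2000-gene 4 vs 4 design — sizes chosen so the full suite runs on a laptop
in a few minutes. Dispersion clipping bounds, the 0.5 pseudocount, the BH
implementation (statsmodels, validated against a literal step-up in tests)
and all tie-break rules above are the complete list of numerical choices.

## Known limitations

Single-factor designs only; no covariate adjustment or shrunken LFC
estimators. Occupancy testing is window-based (not peak-based), standardized
on TSS windows. Super-enhancer calling offers no two-condition differential
statistic beyond rank comparison, and no cell-type deconvolution — a mixed
tissue dilutes enhancer signal and can keep a genuine cluster below the
cutoff. GSEA's gene-label permutation understates inter-gene correlation
relative to phenotype permutation. The 4C module assumes a single cis
viewpoint chromosome and claims no p-values without replicates.
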