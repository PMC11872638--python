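# Methods

## Setting

Tomo-seq produces a genes × ordered-sections count matrix from consecutive
cryosections (here 100 µm) cut along one anatomical axis. The analysis treats
sections as samples ordered from epicardium to endocardium, identifies
transcriptionally coherent spatial domains, and asks which genes — and which
upstream regulators — characterize a domain of interest (in the motivating
application, a cardiomyocyte domain under mitochondrial stress marked by
NPPA, SOD2, BNIP3L and elevated EPAS1).

## Quality control

Per slice, the mitochondrial read percentage is
`100 · Σ_{g∈mito} C_gs / Σ_g C_gs` on raw totals (spike-ins in the
denominator); slices with zero raw total get 0% plus a warning flag.
Filtering order is fixed:

1. mitochondrial (`MT-`) and ERCC spike-in genes are removed;
2. slices with post-exclusion total `< slice_min_reads` (default 3000) are
   removed — strict, so a slice at exactly 3000 is kept;
3. genes lacking a count `> gene_min_count` (default 5, strict: a count of 5
   never qualifies) in at least `gene_min_slices` (default 3) of the
   *retained* slices are removed.

Slice totals for step 2 are computed after the exclusion of step 1 (the
excluded reads are technical/organelle signal, not library content relevant
to domain structure); a `totals="pre"` switch uses raw totals instead, since
either convention appears in practice. Gene classes come from the `MT-` /
`ERCC-` community naming conventions, overridable with an explicit class
table.

One-pass filtering is not exactly idempotent in an adversarial corner: after
step 3 removes genes, a slice's total could in principle drop back under the
read threshold. We keep the fixed one-pass order (no fixpoint iteration)
because it is the transparent reading of the procedure; in realistic data the
genes removed at step 3 carry a negligible share of any retained slice's
reads, and the idempotence test operates away from that boundary.

## Normalization and Z-scores

With per-slice totals `R_s` over the filtered matrix,
`N_gs = C_gs / R_s · median_s'(R_s')`; the median over retained slices (even
count: midpoint of the central pair) makes the scale interpretable as a
typical library size, every normalized slice sums to it exactly, and
within-slice gene ranking is preserved. Z-scores standardize each gene across
sections using the sample (n−1) standard deviation; `ddof=0` is available
since the convention is not universal. Zero-variance genes cannot be
standardized; they are kept as all-zero rows with a flag so matrix shapes
stay aligned across stages.

Z-scores are computed on normalized values (raw input is accepted by the
function for diagnostic use); computing them before normalization would let
per-slice depth masquerade as spatial signal.

## Spatial clustering

Sections are compared by Pearson correlation of their normalized expression
vectors across genes. Agglomerative clustering on `d = 1 − r` with complete
linkage (default) is cut to exactly `k` clusters; complete linkage favours
compact, banded blocks along the section axis, which matches how contiguous
tissue domains express themselves in the correlation heatmap. Average and
Ward-on-distance linkage are selectable. `k` is a user choice (5 for the fine
structure, 2 for the coarse fibro-fatty vs myocardial split in the motivating
study); no automatic model selection is attempted. Labels are renumbered by
first occurrence from the epicardial side, making repeated runs identical.
Clusters are never constrained to be contiguous — a domain may flank another
on both sides — but contiguity is reported as the ordered runs each label
occupies. Sections with zero variance across genes have undefined
correlations; they are flagged and must be removed before clustering.

## Marker detection

For a target cluster, each gene's normalized values in-cluster vs out are
compared with a two-sided Wilcoxon rank-sum test: exact null distribution for
group sizes ≤ 8 without ties, normal approximation with tie correction and
continuity correction otherwise; all-tied genes get p = 1. BH adjustment is
applied across genes, and a gene is called enriched when
`log2((mean_in + c)/(mean_out + c)) > 0.5` and adjusted `p < 0.05`, both
strict. The pseudocount `c = 1` on the normalized scale stabilizes the fold
change at zeros and is configurable. The underlying study reports only
"adjusted p" without naming the test; the rank-sum test is the
field-standard one-vs-rest marker test and is flagged to users as a choice
(Welch t-test available). Contrasts are one-vs-rest only.

## Motif scanning and over-representation

A PWM with pseudocount `c` (default 0.01 per cell, applied before
normalization) scores a window as `Σ_pos log2(p_pos(base)/bg(base))` with a
uniform background by default; a gene is a motif target when its best window
— over both strands by default, reverse-complementing the window — reaches
`threshold_fraction` (default 0.8) of the maximum achievable score
`Σ_pos max_base log2(p/bg)`. Windows containing N are skipped, not penalized,
so ambiguity codes cannot create hits. Which promoter window to extract
(e.g. −1 kb/+100 bp of TSS) is a genome-coordinate decision left to the
user: the scanner takes promoter FASTA as input.

Over-representation of a term (motif-target set, or any GMT gene set) in a
query list uses the one-sided Fisher exact test — the hypergeometric upper
tail `P(X ≥ a)` on the 2×2 table of query × term membership over a background
universe — with BH adjustment across terms. The universe defaults to the
genes surviving QC (the tested population), not the whole genome. Odds ratios
use the Haldane 0.5 correction when a cell is zero. Candidate regulators are
the terms with adjusted p below α, ordered by p, ties broken by descending
odds ratio then term ID.

## Synthetic tissue generator

Counts are gamma-Poisson (negative binomial) with
`mean(g, s) = baseline(g) · fold(g, domain(s)) · depth(s)` and
`var = μ + φ·μ²` (dispersion φ = 0.3 by default — mid-range for bulk-like
RNA-seq replicates). Defaults and rationale:

| parameter | default | why |
|---|---|---|
| `n_sections` | 173 | section count of the motivating tissue block (100 µm slices) |
| `domain_layout` | fatty 40, myocardial 55, stress 30, endocardial 10, fibroblast 38 | five contiguous domains epi→endo, a thin endocardial band, sizeable myocardium |
| `n_genes`, `n_markers_per_domain`, `marker_fold` | 2000, 50, 4.0 | enough genes for realistic multiple testing; 50 markers at fold 4 gives strong but not trivial domain signal |
| `baseline_mean_log_mu/sigma` | 1.5, 1.0 | log-normal baseline means (median ≈ 4.5 counts/slice) giving ≈ 15k biological reads per unit-depth slice and a heavy-tailed abundance spectrum |
| `depth_log_mu/sigma` | 0, 0.25 | moderate library-size spread; keeps honest slices clear of the 3000-read threshold |
| `n_low_depth_slices`, `low_depth_target_reads` | 20, 1000 | slices rescaled to ~1000 expected reads so they fail QC decisively; 173 − 20 leaves 153 retained sections |
| `mito_fraction_mean` | 0.30 | high mitochondrial content typical of myocardium; 13 `MT-` genes track each slice's biological reads |
| `n_spikein_genes` | 92 | the standard ERCC mix size; spike-in means are depth-independent (fixed control input per section) |
| `fatty_baseline_factor` | 0.5 | non-fatty-marker genes damped in the fatty domain: adipose tissue expresses the myocardial program weakly, so fatty markers stand ~8-fold above the local background and the k = 2 cut isolates the fibro-fatty area |
| `motif_positive_frac_stress/background` | 0.5, 0.1 | planted regulator: half of stress markers vs 10% of other genes carry the motif annotation |

Low-depth slices are made by scaling the slice's depth factor, not by zeroing
genes, so composition stays realistic. When engineered low-depth slices are
requested, the generator verifies that they fall below 3000 post-exclusion
reads and every other slice clears it, deterministically redrawing (seed,
attempt) on violation and recording the rejection count; the check is skipped
when no low-depth slices are requested, so small test designs need not reach
3000 reads. An off-by-default `split_stress_domain` places the stress domain
on both flanks of the myocardium, mimicking a non-contiguous cluster.

Canonical symbols (PLIN1, TTN, NPPA, SOD2, BNIP3L, EPAS1, COL1A1, …) are
seeded into the matching domains' marker sets so traces of familiar genes can
be requested by name. Companion helpers build the enrichment fixtures: a
motif annotation (planted term plus random decoy target sets at the
background rate) and promoter sequences with the motif consensus embedded in
motif-positive genes.

What the generator does **not** emulate: transcript-level structure, UMI/read
duplication, gene–gene correlation beyond the domain blocks, smooth
gradients within domains, section-to-section bleed-over, or batch effects.
Tests passing on this generator therefore demonstrate that the pipeline's
statistics and bookkeeping are correct under its stated model, not that the
biological conclusions of any particular tissue are reproduced.

## Numerical choices and degenerate inputs

Normalization requires positive slice totals (guaranteed after QC with a
positive read threshold) and reports an exact column-sum identity to ≤ 1e−9
relative error. Correlations are clipped to [−1, 1] and the diagonal forced
to 1 before clustering; the distance matrix is symmetrized exactly before
linkage. Hypergeometric tails with degenerate margins (empty universe/term)
return the deterministic-support answer instead of NaN. Tie-breaks are
deterministic everywhere (mergesort sorting; regulator ordering by p, odds
ratio, term ID), so reruns with one seed are byte-identical end to end.

## Problem sizes

The test suite and the reproduction script run the default design (2105 ×
173 counts) over 10–20 seeds per property — recovery is measured as medians
across seeds — and exhaustive oracle sweeps at small margins (all 2×2 tables
with margins ≤ 30; rank-sum enumeration at 6 vs 6). These sizes were chosen
so each statistical property is measured with enough replication to be
stable while the whole suite stays fast enough to run habitually.

## Known limitations

- Real Tomo-seq QC numbers depend on sequencing depth profiles the generator
  only caricatures; the 153/173 retained sections arise from the engineered
  design, and on real data the retained counts are whatever QC yields.
- The marker test treats sections as exchangeable units; spatial
  autocorrelation along the axis is not modelled, so p-values on strongly
  autocorrelated data are optimistic.
- The coarse k = 2 cut is a plain tree cut; no supervision or constraint is
  applied.
- Motif calling depends on the supplied promoter windows and PWM library;
  no genome coordinates, motif databases or GO hierarchies are bundled.
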