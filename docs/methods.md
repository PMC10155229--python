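# Methods

## Overview

`tfrank` ranks transcription factors by combining three lines of evidence
per condition pair and assay: the magnitude of a gene's expression change,
the biophysically modelled binding of a TF near that gene, and the ability
of TF binding *changes* to predict the gene's regulation direction. The
sections below describe each stage, the parameters that matter, the
synthetic data the tests rely on, and the design choices made where the
design was genuinely open.

## Coordinates and input formats

All internal coordinates are 0-based half-open (BED convention). The gene
annotation TSV carries a 1-based TSS, converted once at parsing. BED
flavors (BED3/BED6/narrowPeak/broadPeak) are auto-detected from column
count; narrowPeak summit offsets are retained as metadata but not used in
scoring. Motifs are JASPAR-style count blocks; a pseudocount (default
0.01) is added to every count before column-wise normalization so that
log-ratios in the energy model are always finite. Dimer motifs named
`A..B` or `A::B` are split into constituents.

## Expression stage

Size factors are median-of-ratios: for each gene with a positive
geometric mean across samples, the per-sample ratio to that geometric
mean is formed, and the factor is the exponential of the median log-ratio
(identical to the reference DESeq2 estimator, including the geometric
averaging of the two central genes at even counts; cross-checked against
pydeseq2 in the tests). No dispersion model or Wald test is fit — the
pipeline consumes only the fold change:

    log2fc(g) = log2((meanNorm_B(g) + 1) / (meanNorm_A(g) + 1))

The pseudocount of 1 normalized count keeps the ratio finite for genes
silent in one condition. Note the size-factor reference (per-gene
geometric mean) shifts when a library is rescaled, so normalized counts
are invariant to library size only up to one global constant; all
downstream quantities are ratios or ranks and are unaffected.

Gene filters: a gene is retained when its mean normalized count across
all samples is ≥ 50 and the **maximum over groups** of its mean TPM is
≥ 1 — the max, because a gene expressed in only one condition is exactly
the kind of gene the method is looking for. A motif is retained when
every constituent gene that has an expression record passes the TPM gate
(a dimer cannot act if a partner is absent); constituents without any
expression record carry no evidence either way and do not veto.

## Candidate regions

Replicate peak files of a sample group are merged (overlapping or
book-ended intervals coalesce), then blacklist-filtered (any ≥ 1 bp
overlap removes the peak). For histone-mark assays, every gap of 1–500 bp
between adjacent merged peaks is added as a "dip" region: regulatory
elements frequently sit in the accessible valley between two flanking
histone-modification peaks. Dips are scored **in addition to** the peaks
(`dip_mode: add`); `replace` and `off` are available, and dips are
disabled for ATAC/DNase/footprint assays, whose peaks already mark the
accessible element itself.

## Binding affinity

Region affinity follows the TRAP biophysical model with its published
defaults: mismatch energy per window
`E_i = (1/λ) Σ_j ln(M[j, consensus_j] / M[j, s_{i+j}])` with λ = 0.7,
occupancy `p_i = R0 e^{−E_i} / (1 + R0 e^{−E_i})` with
`ln R0 = 0.584·L − 5.66` for motif length L, summed over all offsets on
both strands. Windows containing any N score zero. A uniform motif gives
the analytic value `2(n−L+1)·R0/(1+R0)`, used as a closed-form oracle in
the tests, alongside reverse-complement symmetry and a brute-force
per-offset reference.

Per-gene aggregation (window w = 50,000 bp, decay constant d0 = 50,000 bp):
a region contributes iff its center lies within w/2 of the TSS; its
affinity is divided by max(|p| − l, 1) — clamped because the length
normalization is undefined for regions shorter than the motif, which
dips can be — and decayed by `exp(−d/d0)` with d the center-to-TSS
distance.

## Regression stage

For each condition pair and assay, features are per-gene
`log2((a_B + ε)/(a_A + ε))` (ε = 1e−6), standardized per TF; labels are
the sign of log2fc (zero-change genes dropped; at least 10 genes per
class required). An elastic-net logistic regression (l1_ratio 0.5, saga
solver) is fit, with the inverse penalty strength chosen from
{0.01, 0.1, 1, 10, 100} by 5-fold stratified cross-validation under the
**one-standard-error rule**: the strongest penalty whose held-out
accuracy is within one standard error of the best. Two properties drove
this choice over a plain ridge with max-accuracy selection:

* the L1 component sets the coefficients of uninformative TFs exactly to
  zero, removing them from the combined score instead of letting a
  noise-scaled |η| multiply their entire score distribution — without
  sparsity, the downstream significance gate admits ~30% of null TFs,
  because a Mann–Whitney test on hundreds of values is very sensitive to
  a small multiplicative shift of one TF's whole foreground;
* at these sample sizes (hundreds of genes, ~10 TFs) the differences in
  CV accuracy across the penalty grid are mostly noise, and maximizing
  them selects weak penalties essentially at random; the 1-SE rule is the
  standard conservative remedy.

η(t) is one coefficient per TF per (pair, assay) fit — a single logistic
model has no per-gene coefficients. The fit is deterministic given the
seed (default 42, recorded in the output).

## Combined score, gating, aggregation

ω(g,t) = |log2fc(g)| · a_w(g,t) · |η(t)|, computed for each TF's target
genes (a_w > 0). A component-ablation switch recomputes ω from any subset
of the three factors (omitted factors contribute 1) to assess each
component's contribution.

Per assay, the background BG(m) pools every positive ω across all TFs and
condition pairs (pooling over pairs is the only reading that yields one
background per assay); the foreground FG(t,m) is TF t's positive ω values
and is a sub-multiset of BG(m) by construction — the test is therefore
not between independent samples; this follows the method as published,
and an `exclude_self_from_bg` variant was deliberately not made the
default. A TF is significant when the one-sided Mann–Whitney p (foreground
greater) is < α = 0.05 **and** its foreground mean and median both exceed
the background's. The U test uses full enumeration of group assignments
(midrank U) for pooled sizes ≤ 12 — exact with and without ties — and the
tie-corrected normal approximation with continuity correction above that;
all-identical degenerate inputs give p = 1. No multiple-testing
correction is applied across TFs, matching the published behavior.

Within S(m), rank_m(t) counts the significant TFs whose mean ω is ≤ t's
(Iverson form: the best TF gets rank |S(m)|), and the global score is

    f(t) = Σ_{m ∈ HM(t)} 1 − rank_m(t)/|S(m)|,   rank_m(t) := |S(m)| if t ∉ S(m)

sorted ascending. Only TFs significant somewhere are listed (otherwise
every never-significant TF would tie at f = 0). Ties break by more assay
hits, then larger mean ω, then name — determinism where the formula is
silent. An assay/pair combination with missing peak data is skipped with
a warning and simply absent from HM(t); an assay whose combined scores
are all zero (every coefficient shrunk away) yields an empty significant
set rather than an error.

## Co-occurrence

The binding-site universe B is the coalesced union of the compared peak
sets (the construction is otherwise unspecified in the literature the
method follows; union-merge makes the counts well-defined and symmetric).
count(t) is the number of universe sites overlapped by ≥ 1 peak of t;
the 2×2 table over sites is scored with G² = 2 Σ obs·ln(obs/exp) using
standard independence expectations row·col/|B| (0·ln(0/e) := 0), plus
the plain percentage 100·n11/count(t1). G² is reported as a score, not
converted to a p-value: it must be read relative to the peak counts and
the rest of the co-occurrence table.

## Validation

A TF's "predicted regions" are the candidate regions whose affinity
reaches the per-TF 90th percentile of positive affinities (the selection
rule is otherwise undefined; the quantile is configurable). Each is a TP
if an experimental peak lies within `match_distance` of it (default the
scoring window, 50,000 bp — the affinity model localizes a broad
high-energy area, not the bound base pairs; set 0 for strict overlap),
else FP. An equal number of length-matched regions is then drawn
uniformly from the genome (chromosomes weighted by length, seeded
rejection sampling excluding the predictions, failing after 1000·n
attempts); each is FN if it hits a peak, else TN. The FN count is
expected to be inflated — inactive regulatory elements can carry real
binding sites — and no correction is applied. Sensitivity, specificity,
precision, accuracy, and F1 follow the standard definitions with
0-denominator ratios reported as 0.

## Synthetic data

The generator emulates a two-condition chromatin + expression study on
one synthetic chromosome, and its defaults are the conditions under which
all end-to-end claims are made: 5 Mb genome, 200 genes on a jittered
~25 kb grid (mammalian-like spacing relative to the 50 kb window, so one
regulatory region influences one or two genes — packing genes much
denser makes every peak ambiguous among ~16 neighbors and destroys the
regression signal by construction, not as a model failure), 10 motifs of
length 8 (consensus probability 0.85), one driver TF, 2 conditions × 3
replicates, 120 background peaks per group, 30 shared peaks carrying
decoy motif instances in both conditions, driver peaks with 4 planted
motif copies near 30% of genes in condition B only, matching 4-fold
expression scaling of those targets, and negative-binomial counts
(lognormal baseline means, dispersion 0.1). `effect_size = 1` yields the
matched null: no driver peaks, no expression effect.

What the generator does **not** model: chromatin-state biology,
mappability and GC structure, read-level noise, cooperative or
competitive binding, indirect regulation. Passing recovery tests
demonstrates that the scoring chain works as designed under its own
assumptions — not performance on real data.

Observed under these conditions (recomputable via
`scripts/acceptance.py`): the driver tops the global ranking in ≥ 18 of
20 seeds with no decoy admissions, and under the null ~10% of decoy
TF-study combinations enter the significant set at α = 0.05.

## Numerical choices and degenerate inputs

* Sequences shorter than the motif score affinity 0 (warning).
* |p| − l clamped to ≥ 1; empty foregrounds are errors for the U test
  but handled at the pipeline level.
* Quantile ties in predicted-region selection are kept (≥ threshold).
* Stable, documented tie-breaks everywhere a ranking is emitted (gene id
  for loci/targets; hits/mean/name for f).
* Every TSV is byte-reproducible for a fixed config and seed.

## Known limitations

* The foreground-in-background U test is anti-conservative under strong
  per-TF scale heterogeneity; the sparse regression mitigates but cannot
  remove this, and the reported p-values are gates, not calibrated error
  rates.
* One η per TF per fit cannot express gene-specific regulation direction.
* The window/decay model ignores chromatin loops; a Hi-C-aware window is
  out of scope.
* Validation treats experimental peaks as truth; antibody and condition
  mismatches are not modelled.
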