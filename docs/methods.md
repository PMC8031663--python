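# Methods

This note documents the models, the defaults and the numerical choices
behind `evsort`, and what the synthetic-data generator does and does not
emulate.

## Study design being modelled

Two isogenic prostate-cancer states are compared: CONT (CAV1+/CAVIN1−,
aggressive, selective miRNA export active) and CAVIN1 (CAV1+/CAVIN1+,
export suppressed). Each state is profiled in two compartments — whole
cells and their EVs — over three biological replicates, giving a
2 × 2 × 3 design of miRNA counts. Selective export appears as a CAVIN1-
dependent depletion in EVs that is *not* mirrored in cells.

## Synthetic count generator

Counts are negative binomial with mean µ and variance µ + αµ² (single
global dispersion α, the DESeq2 variance form). Per-miRNA baseline
log2-means are Normal(8, 2) — a median of ~256 expected counts per miRNA
per sample with a long right tail, consistent with ~10⁶ reads spread over
~300 miRNAs. Per-sample library-size factors are log-uniform in [0.5, 2]
so normalization is actually exercised. Defaults follow the study's
observed scale: 317 miRNAs detected in both compartments, 47 exported,
3 replicates, dispersion 0.1.

`export_effect` is defined as the planted log2FC (CAVIN1 vs CONT) of
exported miRNAs in the EV compartment, realised as a `−export_effect`
log2 shift of the EV-CONT mean: CAVIN1 suppresses export, so CONT EVs
carry more of these miRNAs. The default −2 matches the "at least
twofold decrease" selection threshold. Cellular means are untouched.

Sequences are i.i.d. draws from a 0-order background (uniform by
default), lengths uniform in 18–25 nt. Each exported miRNA receives one
instantiation of the degenerate consensus (default AsUGnA; degenerate
positions sampled uniformly among allowed bases) at a uniform random
offset with probability 0.45 — matching the observed 21-of-47
motif-containing fraction — overwriting background bases so lengths stay
fixed, as mature miRNAs are fixed-length molecules.

What the generator does **not** emulate: read-level artefacts (adapters,
mapping ambiguity), per-miRNA dispersion heterogeneity (α is global; a
pooled-dispersion flag exists in the test, not the generator),
compositional correlations between miRNA families, and sequence
composition biases of real mature miRNAs. Passing tests therefore show
the chain is correct and well calibrated under its stated model, not that
real libraries satisfy that model.

## Differential abundance

Per compartment, the CAVIN1-vs-CONT contrast is a per-miRNA NB log-linear
model with known offsets: log size factors (median-of-ratios against a
geometric-mean reference over all-positive miRNAs, factors rescaled to
geometric mean 1) plus, optionally, remove-unwanted-variation offsets.
RUV uses empirical controls — the miRNAs with the largest first-pass
p-values (default 20% of retained) — takes the top-k left singular
directions of their centred log normalized counts over samples, fits each
miRNA's loadings by least squares, and supplies the fitted unwanted
component as an offset. k defaults to 1; neither k nor the control-set
size is reported for the original analysis, so these are package
decisions.

Dispersion is per-miRNA method-of-moments against group-wise fitted means
(a 0.5 pseudo-count enters only the moment estimator, never the
likelihood), floored at 1e-8, with an optional trimmed-mean pooling flag.
The Wald statistic on the condition coefficient is referred to a t
distribution with residual degrees of freedom rather than the normal: at
n = 3 + 3 the normal reference is visibly anti-conservative, and with the
t reference the observed null level is ≈0.05–0.06 (the suite asserts
[0.03, 0.07] over 2,400 null tests). BH adjustment is applied across
retained miRNAs per compartment.

This module intentionally does not replicate DESeq2 numerics: no
dispersion shrinkage, no LFC shrinkage, no Cook's-distance refitting, no
independent filtering. Analyses that depend on the published log2FC
values consume those tables directly through the external-table path of
the classifier.

## Selective-export classification

FE = log2FC_EV − log2FC_cell; selection requires `log2FC_EV ≤ τ_ev` and
`FE ≤ τ_fe` with τ_ev = −1 and τ_fe = −0.5, both inclusive, so boundary
rows select. No significance gate is applied by default (the published
criterion is purely on fold changes); an optional BH-q gate exists behind
a flag. Rows observed in only one compartment are excluded with a logged
count, since FE is undefined for them.

## ZOOPS motif discovery

The site model: a length-L sequence contains no site with probability
1 − λ, or exactly one width-W site at a uniformly chosen start (λ/m per
start, m = L − W + 1). Site columns follow the PWM θ, everything else the
0-order background θ₀ pooled from the input. The E-step computes per-start
responsibilities ∝ (λ/m)·∏θ/θ₀ against a no-site mass ∝ (1 − λ); the
M-step re-estimates θ from responsibility-weighted counts plus a Dirichlet
pseudocount of total mass 0.01 split by background frequencies, and λ from
the mean per-sequence site mass. The penalized log-likelihood (likelihood
plus the pseudocount prior) is asserted non-decreasing at every iteration
for every start (tolerance 1e-9); convergence is a relative change below
1e-6 or 200 iterations.

Starts: one seeded start per distinct W-mer in the data (seed base at
probability 0.55, rest background; capped at 500, sampled with an RNG
keyed to sequence *content* so input order is irrelevant) plus 20 random
Dirichlet starts. All starts run as one vectorized batch; after 15
iterations the batch is pruned to the best tenth (at least 10) by current
likelihood — the MEME-style two-phase search — and the winner is the best
final data log-likelihood.

**E-value.** MEME's analytic E-value is not reproduced. Instead, the
observed log-likelihood ratio against the background-only model is
compared with the same statistic on mononucleotide-shuffled copies of the
input (within-sequence permutation preserves composition exactly), EM
re-run per shuffle at the same width with a reduced start budget (60
seeded + 5 random). The E-value is the add-one empirical tail probability
times the number of widths scanned (Bonferroni), with reporting floor
`n_widths / (1 + n_shuffles)`; at the 200-shuffle default and seven widths
the floor is 0.035, below the 0.05 significance convention. The reduced
shuffle start budget makes the null statistic slightly easier to exceed;
the suite checks the net calibration directly (background-only inputs
reach E ≤ 0.05 in at most 10% of 20 seeds).

**Width selection.** Candidates are ranked by E-value; because every
adequately strong candidate saturates the floor, ties are broken by the
shuffle-null z-score of the LLR (surprise relative to the same width's
null), then raw likelihood, then smaller width. Raw likelihood alone
always favours wider models — a planted hexamer was otherwise reported as
an n-padded 9-mer — whereas the null-normalized surprise peaks at the true
width.

The consensus uses one base (uppercase) when its column probability is
≥ 0.5 and ≥ 2× the runner-up, a two-base IUPAC code (lowercase) when the
top two sum to ≥ 0.75, else `n`. Only the single best motif is reported;
there is no iterative masking for secondary motifs. Sequences shorter than
W are dropped per width with a logged id list.

## Similarity scanning and enrichment

The percent similarity of a window is the percent-of-range of its
log-odds score: 100·(S − S_min)/(S_max − S_min), where S_max/S_min pick
the best/worst base per column. It is bounded, PWM-weighted, and reduces
to the fraction of consensus matches for point-mass columns. The original
"% similarity" is undefined in print, so this definition is a package
decision; "over 70%" is strict, per the published wording. Note that with
near-point-mass PWMs and best-of-~17-windows scanning, the 70% rule is
permissive on background sequences — enrichment of a planted motif is
therefore detected with modest scores under this definition, and the
planted sequences themselves score near 100%.

Enrichment reports both the overlapping hypergeometric tail (draws =
selected set, population = all detected, successes = all above-threshold)
and a disjoint "Church-style" specificity variant with the foreground
removed from the urn; the disjoint variant is the headline when the
foreground is a subset of the background. A zero-hit background with a
positive foreground reports an infinite score with the exact tail
retained.

## Proteomics comparison

log2FC = log2(mean metastatic / mean early) on arithmetic means of
normalized intensities; two-sided unpaired Student t-test by default (the
published methods say only "unpaired t-test"; `--welch` switches), raw
p < 0.05 with no multiple-testing correction, exactly the volcano
convention. The intensity generator is log-normal (baseline log2 ~
Normal(14, 2), per-sample log2 noise sd 1.0 by default — plasma-EV SWATH
replicate variability is large) with planted proteins shifted in the
metastatic group.

## Binding and ddPCR models

Hill fits use bounded least squares (`scipy.optimize.curve_fit`):
response = bottom + (top − bottom)·xʰ/(Kdʰ + xʰ); initialization from
response extremes and the half-range concentration, h = 1; bounds
Kd ∈ [min(x)/100, 100·max(x)], h ∈ [0.2, 5]. h is fitted by default with
a fix-h option, since the original fitting software's choice is not
stated. se(Kd) comes from the curvature at the optimum; replicate curves
are averaged pointwise before fitting. Noise-free recovery is exact to
<0.1% relative error; under 5%-of-range noise the Wald interval covers
the truth in ≥90% of seeds.

ddPCR: λ = −ln(1 − k/n) copies per droplet, c = λ/v copies/µL with
droplet volume v = 0.85 nL (QX200 convention; exposed as an option since
the published methods do not state it). The 95% interval is exact
Clopper–Pearson on k/n propagated through the same transform; k = n is a
saturation error instructing dilution, and k = 0 gives zero with a zero
lower bound.

## Problem sizes

The test suite and the acceptance script use the study-scale defaults
(317 × 12 counts, 47 exported, 1150 × 16 intensities) for single runs and
20-seed replication for rate estimates; the motif null-calibration and
shuffle budgets in tests use reduced start counts and 25–50 shuffles,
which keeps the whole suite around a minute while the acceptance script's
full-width, 200-shuffle discovery takes about two minutes.

## Known limitations

- The NB test is calibrated, not a DESeq2 replica; published log2FCs
  should be consumed directly when exact concordance with the original
  tables matters.
- The empirical E-value cannot distinguish candidates below its reporting
  floor except through the null z-score tie-break.
- The percent-of-range similarity is one of several defensible readings
  of the undefined "% similarity"; the 70% rule's stringency depends
  strongly on PWM sharpness.
- The disjoint specificity variant can return p = 0 when the foreground
  holds more hits than the depleted urn can supply; the overlapping tail
  is always reported alongside.
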