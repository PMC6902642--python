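# Methods

This note documents the statistical model behind `tmra`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that shape the results.

## Problem setting

Given a log-scale gene × sample expression matrix with a two-class
phenotype (case = tumor-like, control = normal-like), the pipeline asks:
which transcription factors (TFs) are the *master regulators* of a chosen
functional domain — here, signal-transduction pathways? A master
regulator is a TF whose inferred target set (*regulon*) is maximally
enriched with the genes most differentially expressed between the two
phenotypes. Around that core question the package also scores per-sample
pathway deregulation (a principal-curve score) and tests gene lists for
pathway over-representation.

## Regulon inference

**Mutual information.** Dependence between a TF and a candidate target is
measured by the plug-in mutual information (nats) of the joint histogram
on an equal-frequency grid: each profile is ranked (average ranks on
ties), rank quantiles define `n_bins` right-closed cells per axis, and
MI = Σ p·log(p / p₁p₂) over joint cells. The estimator is invariant under
strictly monotone marginal transforms — appropriate for expression data
whose scale is arbitrary — and is exactly reproducible, unlike kernel
estimators. Default `n_bins = max(2, ⌊√(n/5)⌋)` keeps roughly five
observations per joint cell (5 bins at n = 150).

**Significance.** Edge p-values come from a pooled permutation null:
MI values of randomly drawn gene pairs after independently permuting one
profile (default 10,000 pairs), with the empirical upper-tail p
`(1 + #{null ≥ mi}) / (1 + |null|)`. Edges are kept at p < 0.005. A
pooled null is the standard choice at this scale; a per-pair null at
0.005 resolution would need ≥ 200 permutations per pair across hundreds
of thousands of pairs.

**DPI pruning.** For every edge triangle, the edge (i, j) is removed when
`mi(i,j) < (1 − ε)·mi(i,k)` **and** `mi(i,j) < (1 − ε)·mi(j,k)` with
tolerance ε = 0.2; all removals are decided on the input network and
applied simultaneously. The multiplicative reading of the tolerance and
the simultaneous removal match the dominant practice for this rule.

**Modes and weights.** The undirected network is oriented TF → target
(TF–TF edges place each TF in the other's regulon). The *mode of
regulation* is the raw Spearman correlation of TF and target profiles
(sign = activation/repression; an exactly-zero mode is treated as
activation). The *weight* is the edge MI divided by the largest MI in
that TF's regulon, so weights are comparable across regulons and every
non-empty regulon has max weight 1.

## Molecular signature and null model

Per gene, a Welch two-sample t statistic (case − control) is converted to
the standard-normal scale: `z = sign(t) · Φ⁻¹(1 − p/2)`, clamped at
|z| ≤ 8. The quantile transform makes z exactly standard normal under the
null whatever the per-gene degrees of freedom, which is what cross-gene
comparability requires in a GSEA; Welch rather than pooled-variance
Student is the safe default for strongly unbalanced designs. The
signature is restricted to the union of the supplied pathway collection.

The null model recomputes the whole signature under K = 1,000 random
case/control label permutations preserving class sizes (an error asks
for exact enumeration when fewer than K distinct assignments exist).

## Master-regulator ranking

Each regulon is scored with a weighted Kolmogorov–Smirnov running sum
(weight exponent 1): genes ranked by z (ties broken by symbol for
reproducibility), member positions climb by normalized |z| (optionally
scaled by the regulon weight), non-members fall by 1/(n − m); the ES is
the signed extremum. Because modes are signed, the enrichment is
two-tailed: positive-mode targets are scored on the z-descending list,
negative-mode targets on the z-ascending list, and the two ES are
combined weighted by subset sizes. A positive combined ES means the
targets behave as an *active* TF predicts; negative as an *inactivated*
one.

Only regulons with ≥ 20 signature-restricted targets are tested. Each
regulon's ES is recomputed on every null-model column;
`NES = (ES − mean)/sd` and `p = 2(1 − Φ(|NES|))`. FDR is
Benjamini–Hochberg across tested regulons; ranking is by ascending p,
ties by descending |NES|, then symbol. The coverage curve reports, for
k = 1…n, the fraction of signature genes covered by the union of the
top-k regulons.

**Calibration caveat.** The Gaussian tail converts NES to p, which is
accurate when the null ES distribution is approximately normal. For
regulons whose targets are driven by a *single* latent factor — the
extreme of co-regulation, and exactly what the synthetic generator
plants — the null ES distribution is bounded and strongly platykurtic
(excess kurtosis ≈ −1.5): the whole regulon moves coherently under any
label permutation, so ES saturates and no permutation reaches
mean ± 1.96 sd. The Gaussian p is then *conservative* (type-I error
below nominal, in the planted simulations essentially zero). Real
regulons are multi-factor and less coherent, and their null ES is closer
to normal; this is a known limitation of the Gaussian approximation, not
of the ranking (which depends only on the ES ordering and is unaffected).

## Pathway deregulation scores

Per pathway: genes are standardized against the control samples (zero
control-variance genes dropped), samples are reduced by PCA to the
fewest components explaining 80% of variance (≤ 10), and a
Hastie–Stuetzle principal curve is fitted: initialized on the first
principal component, then alternating (a) projection of all samples onto
the current polyline and (b) smoothing of each coordinate against arc
length with a cubic smoothing spline. A single smoothing penalty shared
by all coordinates is selected once, on the first smoothing pass, by
3-fold interleaved cross-validation over a log-spaced grid, and held
fixed afterwards; pooling the CV error across coordinates keeps the
selection stable when most retained components are noise, and selecting
once avoids re-running the search at every iteration for no measurable
benefit. An iteration is accepted only if it does not increase the total
squared projection distance, so the distance sequence is non-increasing
by construction; iteration stops at relative improvement < 1e−4 or 10
iterations.

Each sample's PDS is its arc-length position on the curve, oriented so
the case median lies above the control median, centred at the control
median and divided by the total curve length: controls sit at 0 by
construction and positive values mean case-like deregulation. The
control median is computed through the same code path used for scoring,
so the control median PDS is exactly zero (for an even number of
controls, exact up to the float averaging of the two middle values).
Pathway genes and samples are sorted internally before fitting, making
the scores exactly invariant to input ordering. Translation of all
samples by a constant vector cancels in the control-reference
normalization; numerically the discrete penalty-grid choice can amplify
float-level differences to ~1e−3 in PDS units. Pathways that cannot be
scored (fewer than two usable genes, degenerate geometry) are skipped
with a logged reason. A clipped-to-[0,1] view can be obtained by min–max
scaling the returned matrix if a heatmap-style display is wanted.

## Over-representation analysis

For each gene set, with N the reference-universe size, M the set size in
the reference, s the query size and k the overlap, the p-value is the
hypergeometric upper tail P(X ≥ k), accumulated in log space
(log-gamma + logsumexp) for stability; the enrichment ratio is
(k/s)/(M/N). FDR is Benjamini–Hochberg. The reference defaults to the
expression-matrix gene list and is caller-overridable; only
over-representation is tested. Note the exact test is discrete: with
small sets the attainable significance levels sit below the nominal one,
so the realized type-I rate at p < 0.05 is ≤ 0.05 and approaches it only
for large overlapping sets.

## Synthetic study generator

The generator emulates the shape of a tumor/normal expression study at
desk scale, with planted ground truth for every downstream stage:

* Samples: 120 case / 30 control by default — unbalanced like
  tumor-bank cohorts.
* 50 TFs with disjoint regulons of 50–80 targets; latent activity
  `a_f ~ N(0,1)`; TF expression `a_f + N(0,σ)`; target expression
  `β·g·a_f + N(0,σ)` with mode sign g (repressed with probability 0.3).
  β = σ = 1: targets carry as much regulatory signal as noise
  (TF–target correlation 0.5), a strong but plausible direct-target
  coupling.
* 10 differential TFs whose activity is shifted by δ = 1 standard unit
  *downward* in cases, so their regulons (and they themselves) are the
  planted answer; the shift is applied to activity, not to targets, so
  TF and targets co-shift coherently, which is what regulon enrichment
  assumes.
* 1,000 i.i.d. N(0,1) background genes.
* 25 pathway gene sets of 80–140 genes, 80% drawn from the union of
  regulon targets and 20% from background, so the pathway-restricted
  signature covers each regulon well above the ≥ 20-target filter
  (median signature-restricted regulon size ≈ 32).

All draws come from one seeded generator in a documented order, so a
config + seed reproduces the matrix bitwise. Expression is Gaussian on
the log scale rather than counts: every downstream statistic is rank- or
mean-based, so a count layer would add nothing the tests could detect
(a `log2(x+1)` import flag covers real count matrices).

What the generator does **not** emulate: library-size and batch effects,
count overdispersion, overlapping regulons (available via a knob but off
by default to keep ground-truth ranking unambiguous), multi-factor
regulation of a target, and correlated background. Passing tests
therefore demonstrate correctness of the statistics and recoverability
of a planted signal under idealized co-regulation — not performance on
real RNA-Seq, where normalization quality and annotation coverage
dominate.

## Numerical choices and degenerate inputs

* Ties: average ranks everywhere; GSEA ranking ties broken by gene
  symbol; rank ties in the MRA table broken by |NES| then symbol.
* Constant profiles: an error in MI and Spearman (a degenerate gene
  should be filtered upstream, not silently scored); zero variance in
  both t-test groups is t = 0, p = 1 when means agree and an error
  otherwise.
* |z| clamped at 8 (p ≈ 1.2e−15) to avoid infinities at p underflow.
* Empirical edge p-values use the add-one form, so p > 0 always.
* The MRA fast path shares the per-column ranking across regulons and is
  checked against the straightforward per-regulon implementation in the
  tests.
* Problem sizes: the default synthetic study (≈ 4,300 genes × 150
  samples, 10,000 null pairs, 1,000 signature permutations) runs the
  full pipeline in ≈ 30–40 s on one CPU; these sizes were chosen so a
  three-seed validation fits comfortably in an interactive session while
  keeping every filter (≥ 20 signature targets, p < 0.005 edges)
  meaningfully exercised.
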