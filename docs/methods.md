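# Methods

This note documents the models, conventions and design choices behind
`singlebud`, in the order the pipeline applies them.

## Relative quantification

Each amplicon's standard curve is an ordinary least-squares fit of mean
Cq on log10 template quantity over a dilution series (≥3 distinct
points; the synthetic default is five ten-fold dilutions). The slope m
(cycles per decade, negative) gives the amplification efficiency
E = 10^(−1/m) − 1; m = −3.3219 corresponds to E = 1 (perfect doubling).
Quantities are recovered as q = 10^((Cq − b)/m). Technical replicates
(1–3 per bud × gene) are averaged on the Cq scale; a replicate range
above 0.5 cycles raises a QC flag but never drops the measurement —
0.5 cycles corresponds to roughly a 40% quantity discrepancy at perfect
efficiency, a conventional re-check threshold. Undetected reactions are
missing values throughout; they are never coerced to zero expression.
Target quantities are divided by the reference-gene quantity of the same
bud; a missing or zero reference makes that bud × gene missing.

Genes detected in less than a configurable fraction of buds (default
0.5; the threshold has no canonical value and is exposed as a parameter)
are removed before analysis. Each remaining gene is rescaled by the
maximum over stages of its within-stage median, putting every gene's
peak stage at 1. Medians everywhere use the average-of-central-order-
statistics convention for even n; the rescaling is idempotent and
invariant to global positive scaling of the input.

## Stage statistics

Stage contrasts use the two-sided Mann–Whitney U test. Mode selection
mirrors the behaviour of R's `wilcox.test` at these sample sizes: the
exact null distribution when both samples have ≤49 observations and the
pooled data carry no ties, otherwise the tie-corrected normal
approximation with continuity correction. With the study layout
(10/10/71/10 buds) this makes 10-vs-10 contrasts exact and every
contrast against the 71-bud transition stage approximate. Raw p-values
are compared against α = 0.001 with no multiplicity adjustment; output
tables record the raw p and the method used, so readers can apply their
own correction.

Spearman's rho is the Pearson correlation of mid-ranks (ties averaged);
its p-value uses the t-approximation on n−2 degrees of freedom, with an
exact permutation option for n ≤ 8 used as a cross-check. Both are
standard and match the common interactive implementations at n ≥ 40.

## Outlier screening

Extreme-high buds are flagged per gene within a stage when expression
strictly exceeds Q3 + k·IQR with k = 3 ("far out" fences); only the
upper side is screened because the phenomenon of interest is unusually
high expression. Quartiles use linear interpolation of order statistics
(the "type 7" convention, default in both numpy and R) — the convention
changes which buds are flagged, so it is fixed here. A variant anchoring
the fence at the median (median + k·IQR) is available as a display
convention; all analyses use the Q3 anchor.

## Hartigan's dip statistic

The dip D is the minimum over all unimodal CDFs G of sup |F̂ − G|, where
F̂ is the empirical CDF. The implementation iterates the classical
scheme: on the current modal interval, compute the greatest convex
minorant (GCM) of the ECDF's left limits and the least concave majorant
(LCM) of its values, measure the largest gap between the two fits at
their touch points, shrink the modal interval toward that gap, and
accumulate the one-sided deviations of the ECDF from the convex fit to
the left and the concave fit to the right; half the accumulated maximum
(in probability units) is the dip. Ties are handled through the left and
right limits at each distinct value, with one subtlety: a point mass *at
the mode* costs nothing, because a unimodal distribution may carry an
atom there, so at the candidate mode only the approaching limits are
charged. For n distinct values D ∈ [1/(2n), 1/4], the lower bound
attained by equally spaced data.

The implementation is validated against an independent exact oracle that
minimizes the band width over piecewise-linear unimodal CDFs by linear
programming (every candidate mode point, allowing an atom, plus every
between-point mode interval). The dip is invariant under affine maps and
reflections of the data but **not** under general monotone transforms —
spacing matters ([0,1,2,3] has dip 1/8; [0,1,10,11] has dip 0.225) — so
the scale on which bimodality is asked about is part of the question.
The pipeline tests the relative-expression scale, matching how such
distributions are inspected in practice.

P-values are Monte-Carlo: the fraction of uniform(0,1) samples of the
same size with dip ≥ D (default 10,000 draws; the pipeline uses 1000 and
shares one null table across genes, since the null depends only on n).
The uniform is the classical least-favourable unimodal null, which makes
the test conservative for peaked unimodal data — the suite measures a
0.2% rejection rate at nominal 5% on normal samples of n = 71. The price
is moderate power: the suite's power simulation at n = 71 with an equal
two-component mixture 4 component-sd apart rejects in ~60% of runs;
separations must be larger before rejection becomes near-certain. This
is a property of the dip test itself, not of the implementation (the
statistic matches the exact LP oracle).

## Resampling procedures

**Balanced subsampling.** The transition stage deliberately holds ~7×
more buds than the others; correlations over all stages would otherwise
be dominated by it. Each of 1000 replicates draws 10 transition buds
without replacement, joins all other buds, and computes the full
Spearman matrix. Aggregation: mean rho across replicates, and a pair is
significant only when p < α in strictly more than 80% of replicates.
The same replicate set feeds both the mean-rho matrix and the
significance fractions.

**Transition-only network.** Spearman over the 71 transition buds, edges
at p < α. With outlier removal, a bud flagged for gene g is excluded
from every pair involving g (pairwise deletion — outliers are defined
per gene, so deletion is per gene; a listwise switch exists). Pairs left
with fewer than 4 complete observations are skipped with a logged
warning. Structurally, removal can only change edges incident to genes
with flagged buds; all other pairs are bit-identical.

**In-silico pooling.** An artificial multi-bud sample is the per-gene
mean of 5 transition buds drawn without replacement *within* the pool;
pools are drawn independently of each other and therefore overlap
(unavoidable when 71 pools of 5 are drawn from 71 buds). One simulated
experiment holds 71 artificial samples — the same sample size as the
single-bud data — and the experiment is repeated 1000 times. Pooled
stage tests compare each gene's artificial samples against the single
buds of the other stages (normal-approximation Mann–Whitney; the 71-bud
side always routes there); pooled networks compute the Spearman matrix
per repetition. Both aggregate with the >80% rule. When outliers are
removed, removal happens on the single-bud table *before* pooling
(flagged cells become missing and drop out of their pools' means),
because the fences are defined on single-bud values. The mean of an
artificial sample is an unbiased estimate of the stage mean, with
variance σ²/5 · (1 − 4/70) by the finite-population correction for a
without-replacement mean of 5 from 71 — both verified in the suite at
10,000 pools.

Negative-correlation edges are retained in edge lists with their sign;
a positive-only view reproduces the conventional network display.

**Randomness.** Every procedure takes a single seed; replicate r uses
the r-th spawned child of the seed sequence, so enlarging the replicate
count never perturbs earlier replicates, and every operation is a pure
function of (inputs, seed). The pipeline derives independent sub-seeds
for the dip null table, the balanced matrix, the pooled tests and each
pooled network from its one master seed.

## PCA and clustering

Genes are standardized to unit sample standard deviation with either
median centering (each gene's median becomes 0; the default, matching
how skewed relative-expression panels are usually standardized) or mean
centering (the classical correlation-matrix convention); outputs record
which was used. PCA is the SVD of the standardized matrix — no further
centering — with variance fractions s²ᵢ/Σs², components sorted
descending, and a deterministic sign convention (the largest-magnitude
loading of each component is positive). With all components kept,
scores · loadingsᵀ reproduces the standardized matrix.

Bud clustering operates on gene-wise z-scores (mean 0, sd 1 per gene;
zero-variance genes dropped with a warning) with Euclidean distance and
complete linkage by default — the defaults of the common heatmap tools —
cut into as many flat clusters as there are stages, and reported as a
cluster × stage composition table. Optional seeded k-means row
aggregation mirrors the heatmap tools' row-collapsing behaviour.

## Phenology

A stage is called dormancy-released when the budbreak-forcing ratio
reaches 0.5 (boundary inclusive). Utah chilling uses the classical
weight bands (0 below 1.5 °C; 0.5 for 1.5–2.4; 1.0 for 2.5–9.1; 0.5 for
9.2–12.4; 0 for 12.5–15.9; −0.5 for 16.0–18.0; −1.0 above 18 °C),
evaluated per hour and accumulated; the band table is an argument, so
other dialects of the model can be swapped in. Totals are additive over
concatenation and invariant to hour order.

## Synthetic data generator

The generator emulates the statistical structure of a single-bud
dormancy study: stage sizes {S1: 10, S2: 10, S3: 71, S4: 10}; 13
detectable genes in two modules (a dormancy-high module of the DAM-like
genes, SAP1-like and TOR-like; a release-high module of the
jasmonate-biosynthesis genes, TIP-like and SWEET15-like) plus an
idiosyncratic FT-like gene and one undetectable amplicon exercising the
detection filter. On the natural-log scale,

    y = stage_mean(gene, stage) + √ρ·s·Z(module, bud) + √(1−ρ)·s·ε

with one shared latent factor Z per module per bud, so every
within-module pair has log-scale Pearson correlation ρ (default 0.75)
and between-module pairs are independent; expression is exp(y).
Marginal log-sd s defaults to 0.6 — moderate right skew, chosen as a
realistic relative-expression dispersion. Stage-mean profiles are
illustrative presets tracing the canonical shapes (dormancy module
falling from dormant to released stages, release module peaking after
release, FT-like peaking in late dormancy); they are not measured
values. Outliers are multiplicative upper spikes (default rate 0.01,
factor 20), matching the observed "unusually high" single-bud values.
An optional transition-stage mixture assigns each transition bud to one
of two components separated by a configurable multiple of s (shared
across genes, as if buds differed in developmental state); separation 0
reduces exactly to the unimodal generator. Ground truth records module
membership (hence true edges), spiked cells and mixture components, so
network recovery, outlier screening and bimodality power can all be
scored.

What the generator does *not* emulate: technical qPCR error structure
beyond Gaussian Cq noise, reference-gene instability, stage-dependent
dispersion, negative regulatory relationships between modules, and any
temperature-driven dynamics. Passing tests therefore demonstrate that
the procedures recover known structure under a faithful statistical
caricature of the design — not that any particular biological dataset
satisfies these assumptions.

## Problem sizes in the test suite

The suite runs the procedures at the study's own scale (101 buds, 13
genes, 1000 replicates) where a single run is cheap, and reduces only
the outer repetition counts of simulation studies: 100 seeds for
network-recovery and spike-recovery rates, 50 outer seeds × 200
replicates for the null control of the >80% rule, 500 datasets for the
dip size check, 10,000 pools for the pooling moments. Stochastic
acceptance checks are derandomized; the two checks that compare against
Monte-Carlo oracles account for the oracle's own sampling error (the
Mann–Whitney permutation comparison adds the oracle's 3σ to the 0.01
band; the pooling 2-SE law-of-large-numbers check is asserted at its
nominal violation rate across replicate datasets).

## Known limitations

- Missing values are supported through quantification, filtering and
  outlier-aware correlation, but PCA and clustering require complete
  tables (filter first); no imputation is provided.
- The dip test's uniform calibration is conservative; weak or
  asymmetric mixtures at n ≈ 71 often go undetected (see above).
- Mann–Whitney exact mode refuses tied data rather than falling back
  silently; callers asking for exactness with ties get an error.
- The >80% aggregation rule is reported as stated, without a
  family-wise error interpretation across the 78 gene pairs.
- Utah chill totals depend on the chosen band dialect; only the
  classical table ships.
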