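# Methods

`moanet` builds a drug mode-of-action (MoA) network from replicate
compound-treatment expression profiles and ranks MoAs and drugs against
a query profile.  This note describes the model, its assumptions, the
parameters that matter, and the deliberate design choices made where
the procedure was genuinely open.

## Setting and assumptions

The input is a genes × samples matrix of log2 fold changes: each
treated sample's expression relative to the median of its vehicle
(untreated control) group, processed on the same platform and cell
line.  Connectivity-map style corpora have very few replicates per
compound — most drugs have only two treated samples — so conventional
differential statistics (t-tests, moderated t) are unusable.  The
entire pipeline is built around statistics that remain meaningful at
n = 2.

## Preprocessing chain

For probe- or gene-level absolute intensities (assumed
background-adjusted; background correction of raw scanner data is out
of scope):

1. **Quantile normalization** of the vehicle samples: every column is
   mapped onto the cross-column mean of order statistics; ties receive
   the mean of their reference values.  Idempotent on tie-free data.
2. **Rank-invariant normalization** of each treated sample against the
   per-gene median of its vehicle group (grouping key: batch ×
   cell line).  Genes whose rank differs by at most `rank_tolerance`
   (default 0.05, a fraction of the gene count), excluding the extreme
   5% of ranks at each tail, anchor a monotone piecewise-linear
   sample→baseline mapping (running-median smoothed, cumulative-max
   monotonized).  Outside the anchored range the mapping is
   extrapolated linearly with slopes fitted by least squares over the
   outer decile of anchors — a two-point end slope is noise-dominated
   and would systematically attenuate exactly the strongly-regulated
   genes that live outside the rank-invariant range.  If fewer than 50
   invariant genes exist the sample falls back to a median shift, with
   a warning.  The mapping is the exact identity when sample equals
   baseline.
3. **Median-polish summarization** of probe-level blocks: per gene, a
   two-way Tukey polish (rows = probes, columns = samples; at most 10
   sweeps or total adjustment < 1e-6); the per-sample summary is
   overall + column effect.  Summaries are invariant to probe order.
4. **Fold-change assembly**: treated minus the per-gene median of its
   vehicle group; treated samples with no matching vehicles are
   excluded with a warning and listed in the run report.

## Signature selection

Each fold-change vector is scaled by its own across-gene standard
deviation, z = x/σ_x.  A gene in a pair of replicates is scored with
the consistency statistic

    R = z_x · z_y − |z_x − z_y|

which is symmetric, rewards strong concordant regulation, and
penalizes discordance.  Significance comes from an empirical null: R
pooled over random pairs of samples from *different* drugs (one random
gene per pair; ≥ 10^5 draws, default 2×10^5), representing genes that
are not consistently differentially expressed.  Within-drug resampling
is available via `pairing="within_drug"` but is not the default:
within-drug pairs carry real signal and would absorb exactly the
effect being tested.  The p-value is the upper-tail fraction with
+1/(n+1) continuity.  A pair signature is the set of genes with
p < α (default 0.001) and agreeing signs; a drug signature is the
intersection of all pairwise signatures, with direction taken from the
mean z and p from the worst pair.  Raw p-values are thresholded with
no multiplicity correction — the α = 0.1% cutoff is itself the
selection rule.  Single-sample drugs and drugs with an empty
intersection are flagged (`single_sample` / `no_signature`) and
removed; the two categories are reported separately.

Because both samples are scaled by their own σ, selection is invariant
to rescaling a sample by any positive constant.  One known consequence
of z-scaling: strong planted signal inflates σ and slightly shrinks
the z of null genes, making selection marginally conservative on
heavily-regulated samples.

## Replicate quality control

QC applies to drugs with more than 3 samples; smaller drugs pass
through untouched.  Pairwise *agreement* is the pair-signature size
divided by the chance expectation (n_genes × α), so ≈ 1 means chance
consistency.  While any remaining pair scores below `min_agreement`
(default 5.0), the sample with the lowest mean agreement is removed
(ties: remove the lexicographically larger id, for determinism),
stopping at two samples; if the final pair still fails the whole drug
is removed.  The removal schedule is this package's reconstruction of
a procedure whose original pseudo-code is not available; it is
deliberately simple, fully parameterized, and validated on planted
outliers (a pure-noise sample among 4-σ replicates is removed, and
nothing else, in ≥ 95% of seeded runs — observed 100%).

The default `min_agreement = 5.0` sits between the noise level (≈ 1)
and the agreement of true replicates: with the generator defaults
(signature ≈ 100 genes, 10,000 genes, α = 0.001) a true pair scores
≈ 100/10 = 10.

## Drug distance, background threshold, MoAs

Each surviving drug is summarized as a consensus profile (per-gene
median over QC-passed samples; the aggregation is a package choice —
the source procedure moves from sample-level to drug-level distances
without stating one).  Similarity evaluates each drug's signature in
the other drug's profile:

    S_ab = ½ [ (1/n) Σ_{i∈sig(a)} dir_i a→b_i / var(b)
             + (1/m) Σ_{j∈sig(b)} dir_j b→a_j / var(a) ]

where var(·) is the variance of the consensus profile across genes
(taken literally as a variance; standard deviation is available by
option).  The direction weighting `dir_i` is deliberate: an unsigned
sum would score a shared *down* signature as dissimilar;
`signed=False` restores the literal unsigned reading.  Distances are
`D = D_max − S` with `D_max` the maximum off-diagonal similarity, so
the most similar pair has distance exactly 0.

Two drugs share a MoA when their distance is smaller than expected
under the background (population) distance distribution at level
`p_level = 0.01`.  Two estimators of that background quantile are
provided:

* **pooled** — the empirical `p_level` quantile of all off-diagonal
  distances (linear interpolation).  Unbiased when same-MoA pairs are
  a negligible (< `p_level`) fraction of all pairs, the regime of a
  large corpus with many small MoAs (~500 drugs in ~100 MoAs gives
  < 1% same-MoA pairs).
* **robust** (pipeline default) — location/scale of the background
  bulk by median and 1.4826·MAD, threshold at the normal `p_level`
  lower quantile.  On a small dataset with pronounced structure,
  same-MoA pairs can be 10–20% of the pool; they contaminate the lower
  tail and drag the pooled quantile *inside* the intra-MoA distance
  cloud, splintering the clustering.  The robust fit tolerates such
  contamination and agrees with the pooled estimate when the pool is
  clean (approximately normal background bulk assumed).

Average-linkage (UPGMA) hierarchical clustering on D is cut at the
threshold; the resulting clusters are the MoAs, singletons included —
some compounds simply share no treatment effect.  Linkage is
configurable; average is the customary choice for correlation-like
distances.  Each MoA's center is its highest-betweenness member on the
subgraph of intra-MoA edges (drug pairs with D below the threshold;
unweighted betweenness; ties broken by drug name).  Two MoAs are
linked at the secondary level when their *minimum* member-pair
distance is below the threshold — with average linkage two clusters
can stay unmerged at the cut while containing a sub-threshold pair, so
a minimum-based link is the only definition consistent with the cut;
intra-MoA edges shown are likewise only the sub-threshold pairs.

## Prediction

A query (log2 fold-change vector; must cover ≥ 50% of the network's
signature genes) is scored against every drug: the drug score ("mean
expression") is the direction-adjusted mean of its signature genes'
values in the query.  Scoring is one-sided — a raw query has no
signature of its own, so this is the natural reduction of the
two-sided S_ab.  The query is not variance-rescaled; all orderings are
invariant to positive scaling anyway.  MoA score aggregates member
drugs (mean by default; max by option — with mean, and only mean, the
reverse/similar duality below is exact).  Similar mode sorts MoAs and
drugs descending, reverse mode ascending, ties by MoA id / drug name;
the report lists contiguous MoA blocks with dense global ranks, drugs
with no overlapping signature genes appended at the bottom with NaN
scores rather than silently dropped.  For every query,
`reverse(q)` equals `similar(−q)` exactly.

## Synthetic data generator

The generator emulates the corpus structure the pipeline assumes:
`n_moas` MoAs each with a planted signature gene set (random ±1
directions), `drugs_per_moa` drugs per MoA, `samples_per_drug`
replicates, values = direction × effect_size × noise_sd at signature
genes plus i.i.d. N(0, noise_sd²) everywhere, and with probability
`outlier_rate` a sample is pure noise (recorded in the ground truth).
Defaults: 10,000 genes, 6 MoAs × 5 drugs × 3 replicates, 100
signature genes, effect 5, noise 1, overlap 0.  Signature size 100 is
a realism choice in the range typical of perturbation signatures; with
these defaults it also places true-replicate QC agreement (≈ 10) well
above the `min_agreement` floor.  A probe-level mode adds per-probe
offsets, vehicle columns, and *technical-scale* gene noise around the
planted pattern, because rank-invariant normalization assumes
unchanged genes sit at technical-noise distance from the baseline; the
fold-change fixture's per-gene noise is measurement/biological spread
that would otherwise be wrongly "corrected".

What the generator does **not** emulate: gene–gene correlation (noise
is independent by default), dose–response structure, batch effects,
platform-specific intensity artifacts, or heavy-tailed noise.  Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under its own assumptions, not that real-corpus headline
counts would be reproduced.

## Problem sizes and numerical choices

The test suite and the acceptance script run the stages at: null
calibration on a 10,000-gene, 20-drug × 2-sample noise corpus
(2×10^5 null draws); signature recovery with 50 planted 5-σ genes over
20 seeds; QC on 6-replicate drugs with one planted 4-σ outlier over
100 runs; full-pipeline MoA recovery on 30 drugs / 6 MoAs / 10%
outliers over 20 seeds; query self-retrieval over 50 noisy trials.
These sizes give Monte-Carlo error comfortably inside the asserted
bands while keeping a full run in tens of seconds.

Determinism: every stochastic component takes an explicit seed; QC and
ranking tie-breaks are lexicographic; cluster labels are assigned by
first appearance in drug order, making the partition invariant to
input order.  Degenerate inputs (all-equal distances, single-column
quantile input, sub-50-gene invariant sets, zero-variance samples)
either warn and fall back or raise with a named offender.

## Known limitations

* The QC schedule and the drug-level consensus aggregation are
  reconstructions of under-specified steps; both are flagged and
  parameterized rather than hidden.
* The empirical null is contaminated when few drugs exist and they
  share signatures (cross-drug pairs then carry real signal); the null
  should be built on a corpus-scale dataset, not a handful of drugs.
* The robust background estimator assumes a roughly normal background
  bulk; grossly skewed distance distributions would mis-place the
  threshold.
* Corpus-scale headline counts (numbers of MoAs, drugs and samples
  passing QC on the real connectivity-map corpus) depend on the full
  proprietary-scale input and on the unavailable original QC
  pseudo-code; they are outside what the synthetic surface can or does
  claim.
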