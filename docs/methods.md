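# Methods

This note records the models implemented in wgdkit, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## NG86 Ka/Ks

For each codon the expected numbers of nonsynonymous (N) and synonymous
(S) sites are counted fractionally: each of the nine single-base mutants
contributes 1/3 of a site to the class of its effect under the standard
genetic code, with mutations to stop codons counted as nonsynonymous. For
each differing codon pair, the numbers of nonsynonymous and synonymous
differences are averaged with equal weights over all minimal mutational
pathways (1, 2 or 6 orderings); pathways passing through a stop codon are
excluded, and if every pathway is blocked the stop-transit pathways are
used with stop-adjacent steps counted as nonsynonymous and the estimate
flagged. Proportions `pn = Nd/N` and `ps = Sd/S` are corrected for
multiple hits with Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`.

Conventions left open by the classical recipe, fixed here:

- codon pairs containing a gap, an `N` or a stop codon are skipped
  pairwise (locally), not column-masked across the whole table;
- a proportion ≥ 3/4 saturates the correction; the rate is reported as
  missing with a flag, never as a number;
- `ω = Ka/Ks` is undefined (None) when Ks is missing or zero — zero
  synonymous divergence carries no rate information.

There is no transition/transversion weighting (unweighted NG86), matching
the behaviour of the NG output of YN00-class implementations on clean
alignments.

## Syntenic blocks and Ks distributions

Collinearity anchors (produced by MCscan-class tools, or by the synthetic
generator) are grouped by block. Missing and saturated Ks values are
dropped *before* the block-size filter so that a thin block cannot be
rescued by unusable pairs; blocks then need at least 10 usable collinear
pairs (configurable) to contribute their median Ks to a distribution. A
Ks ceiling of 5.0 guards against saturation artifacts; the fitting window
(below) is tighter anyway. Even-sized blocks use the midpoint of the two
central order statistics.

## Mixture peaks

Block-median Ks values are fitted with a finite Gaussian mixture by EM on
raw Ks over a default window of (0, 3] — block medians are already
unimodal per event, so no log transform is needed; log-space fitting is
available as an option. Numerical choices:

- convergence at relative log-likelihood change < 1e-8 or 2,000
  iterations; the observed-data log-likelihood is asserted non-decreasing
  at every iteration (the EM ascent property doubles as a self-check);
- initialization by k-means from the given seed, plus four random restarts
  run briefly (300 iterations), after which only the best short run is
  polished to convergence — EM on 1D mixtures with unequal spreads
  otherwise falls into merged/split local optima;
- a component whose variance or responsibility mass collapses is pruned
  and the model refitted with one component fewer, flagged;
- model selection (`k="auto"`) minimizes BIC over k = 1..5 with 3k − 1
  free parameters;
- bootstrap peak uncertainties resample the values with replacement,
  refit (initialized at the full-sample optimum), match components to the
  full-sample peaks by Hungarian assignment on |Δmean| to prevent label
  switching, and report the standard deviation of matched means; more
  than 10% failed replicates is an error, not a silent average.

The library default seed is 20221214; every stochastic operation takes an
explicit seed.

## Rate correction and dating

All dating is anchored on the core-eudicot common hexaploidization (ECH),
taken as 115–130 Ma. With the focal genome's paralog ECH peak at `k_H`
and a reference genome's at `k_V`, the relative rate is
`r = (k_H − k_V)/k_V` and the correction coefficient `W_H = 1/(1 + r) =
k_V/k_H`; corrected focal Ks values are `W_H·k`, and between-genome
ortholog peaks are corrected the same way. Ages use the reference clock
`rate = k_V/(2·T_cal)`, which algebraically reduces to the closed form
`T = (k/k_H)·T_cal`: the reference peak cancels, and the property suite
asserts this cancellation to 1e-12. Ages are reported as an interval over
the calibration bounds (both bounds, to one decimal Ma), mirroring how
such results are printed, rather than as a point estimate. Substitution
rates are per site per *year* with an explicit 1e6 factor on Ma; where a
source quotes a rate "per generation" for a woody perennial, it is treated
as per year — the two are numerically interchangeable only under a
one-year generation time, and the package does not attempt to model
generation-time differences. A peak larger than the ECH anchor is dated
anyway but flagged as predating the calibration.

The printed per-species rates and the printed ECH peak position are not
mutually consistent with any single calibration time inside 115–130 Ma;
`T_cal` is therefore an explicit free parameter and no reconciliation is
attempted.

## LTR insertion clocks

The two LTRs of an element are identical at insertion; their divergence
`K` dates it via `T = K/(2μ)`. Divergence uses JC69 by default (K2P as a
config switch recorded in the output), computed over columns where both
sequences carry an unambiguous base, with at least 50 comparable columns
required. Whether the headline age of an amplification burst is the mode,
the mean or the median of the insertion-age distribution is a reporting
choice; the profile reports all three, per superfamily and overall.

## GO-category binomial test

Counts are aggregated as raw pathway-averaged NG86 differences (not
rates); the null is the pooled genome-wide nonsynonymous fraction of
differences in the same lineage. The one-sided tail `Pr[X ≥ a]` for
`X ~ Binomial(a + s, p_expect)` is evaluated through the regularized
incomplete beta `I_p(a, n − a + 1)`, which equals the exact binomial
survival function at integer counts and interpolates smoothly for the
fractional counts pathway averaging produces. Categories need more than
20 member orthologs to be tested; genes contribute to every category they
are annotated to, with no ancestor propagation up the GO graph. No
multiple-testing correction is applied to the headline labels (raw
P < 0.05), but Benjamini–Hochberg adjusted values are always attached in
a separate column and can drive the labels via a flag. Both lineages are
grouped by the focal gene's GO annotation so their category universes
match by construction.

## TE proximity

Distances are boundary gaps in bp on 0-based half-open intervals; overlap
gives 0, strand and feature subtype are ignored, and gene intervals are
merged per chromosome before a binary-search sweep (verified exactly
against an all-pairs scan). The primary test is a chi-square on the 2×2
table of status × (≤ 1 kb / > 1 kb); the 1 kb edge is a documented choice,
not a reconstruction of any particular publication's binning, and the
test is always accompanied by a two-sided Mann–Whitney comparison of the
full distance distributions. The chi-square uses no Yates continuity
correction: with the group sizes this analysis targets (hundreds of
elements per cell) the uncorrected statistic is calibrated — the null
false-positive rate sits at the nominal 5% — whereas the correction makes
it conservative.

## Synthetic data

The generator emulates the statistical structure each stage assumes, at
the scale the analyses operate on:

- **gene pairs**: uniform sense-codon ancestors (no codon-usage bias, so
  NG86 site counts are unbiased by construction) diverged by a
  neutral-proposal process — proposals uniform over positions and bases,
  stop-creating proposals rejected, synonymous proposals accepted,
  nonsynonymous ones accepted with probability ω; the number of
  synonymous hits is Poisson with mean `target_Ks × synonymous sites`.
  This per-event filter is not a full continuous-time codon model; it is
  accurate for estimator recovery at Ks ≤ 1 and biases realized Ks
  slightly low beyond Ks ≈ 2 (the generator warns at ≥ 3).
- **synteny**: each block draws a centre from its WGD cohort's
  Normal(mean, sd) and adds small within-block pair noise (sd 0.02), so
  block medians follow the configured mixture exactly; about 10% of
  blocks are emitted below the 10-pair threshold to exercise the filter.
  Default cohorts sit at Ks 0.329/0.502/2.019 with sds 0.04/0.06/0.25 and
  weights 0.35/0.35/0.30.
- **LTR pairs**: columns of the 3′ copy mismatch the 5′ copy with the JC
  expectation `p = 3/4(1 − e^{−4k/3})` at `k = 2μT`; default cohort 500
  elements of 1 kb at 1.0 Ma with μ = 7.06e-9.
- **annotations**: genes are placed one per uniform slot (guaranteed
  non-overlap); intact TEs land within 500 bp of a random gene with
  probability `near_gene_fraction` (default 0.8), fragmentary TEs
  uniformly.
- **ortholog counts**: Poisson totals (mean 20 differences per ortholog)
  split binomially at the null nonsynonymous fraction, with planted
  categories enriched on the odds scale (a 3× odds factor models a
  threefold dN/dS increase at a 3:1 site ratio).

All randomness flows from the configuration seed through fixed, numbered
substreams per product, so each output is independent of generation
order and byte-identical across runs. What passing tests on these data do
*not* show: robustness to codon-usage bias, indels and alignment error,
GC-biased gene conversion, rate variation among sites, nested/fragmented
TE annotations, or real collinearity-detection noise — all of which real
genomes have and the generator deliberately omits.

## Problem sizes in the test suite

The suite exercises the estimators at the sizes the recovery statements
refer to: 1,000 random 300-codon pairs against the brute-force NG86
oracle, 2,000 synthetic block medians for the three-peak recovery, 500
LTR pairs of 1 kb for the clock recovery, 2,000 null GO categories for
the type-I calibration and 1,000 replicates for the proximity-test null.
Smaller versions of the same checks run inside the per-module tests. The
Monte-Carlo yardstick for the bootstrap peak SEs uses a robust
(IQR-based) spread, since a single local-optimum fit among the fresh
replicates would otherwise dominate the plain standard deviation.

## Known limitations

- NG86 is a counting method; at high divergence it underestimates rates
  relative to maximum-likelihood codon models, and no ML alternative is
  provided.
- Gaussian components on raw Ks are an approximation; heavily skewed
  single-event distributions would be better served by the log-space
  option.
- The binomial test treats orthologs within a category as independent;
  shared tree structure among paralogs is not modelled.
- The CLI's `date` stage requires the user (or the `all` driver) to name
  which fitted component is the ECH anchor; it does not infer event
  identity from the data.
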