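# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `prxmap`, in the
spirit of a model-description appendix.

## The probabilistic dropout model

Let `y_ij` be the log2 LFQ intensity of protein *i* in sample *j*, after
filtering and quantile normalization, and let `c(j)` be sample *j*'s
condition (bait isoform × genotype). The model treats the pair
(missingness indicator, value) of each cell as one observation from a
properly normalized joint density:

- a latent value is drawn from `N(mu_{i,c(j)}, sigma_i^2)`;
- it is *observed* with probability `1 − Phi((rho_j − y)/zeta_j)` and
  *missing* otherwise.

Integrating the latent value out of the missing branch gives the closed
form `P(missing) = Phi((rho_j − mu_ic)/sqrt(zeta_j^2 + sigma_i^2))`
(verified against adaptive quadrature to 1e-6 in the tests). The
log-likelihood of a protein row is the sum of Gaussian + selection terms
over observed cells and probit terms over missing cells. The selection
term on observed cells does not depend on the parameters and is included
only so that reported objective values are true joint log-likelihoods.
There is no imputation anywhere: missing cells contribute exactly their
probability of being missing.

**Dropout curves.** `(rho_j, zeta_j)` are the mean and sd of sample *j*'s
*detection-limit proxy set*: observed values in *j* of proteins missing
in at least one replicate of the same condition. These are values caught
at the edge of detectability, so their location tracks the 50%-dropout
intensity. Because only observed values can enter, the estimator has a
modest upward selection bias (~0.5·zeta at the simulated conditions);
this shifts the curve, not the differential-abundance calibration, which
is checked directly (type-I error 3.5–4.5% at nominal 5%). With fewer
than 20 proxies (nearly complete data) the curve falls back to the 10th
percentile of the sample's observed values with unit width and is
flagged.

**Fitting.** Coordinate ascent: per-condition means are updated by
safeguarded Newton steps (the per-condition likelihood is concave in
`mu`), vectorized across all proteins; `sigma_i` is then updated by a
coarse log-grid plus golden-section search on [0.05, 10]; the loop stops
when the objective improves by less than 1e-8 (max 200 rounds).
Initialization is deterministic: observed condition means and pooled
residual sd. The observed-data part of the likelihood is evaluated from
per-condition sufficient statistics and the missing part from flattened
missing-cell indices, so a 1,000 × 45 fit takes well under a second.

**Conditions with no observations.** Below the dropout curve the
likelihood in `mu` is one-sided and asymptotically flat: the data say
only "this protein's level is at or below detection". The mean of such a
condition is pinned at the condition-average detection limit,
`mean_j(rho_j − zeta_j)` (which respects the bound `max_j rho_j + zeta_j`),
and the missing values are treated as distributed around the detection
limit with the curve's spread, giving information
`n_miss/(zeta^2 + sigma^2)` for the pinned mean. Two consequences are
documented rather than hidden: (i) fold changes of proteins never seen in
the depleted condition are censored at the detection limit, so planted
effect sizes are attenuated for baselines below detection; (ii) the
reported interval for such proteins reflects detection-curve width, not
Gaussian replicate noise.

**Variance moderation.** Per-protein ML variances are noisy at n = 3.
A scaled-inverse-χ² prior `(d0, s0²)` is fitted by matching log-scale
moments (digamma/trigamma relations, with the per-protein residual
degrees of freedom absorbing the sampling contribution); raw-moment
matching was rejected because the inverse-χ² second moment diverges for
d0 ≤ 4, exactly the regime of interest. Posterior (moderated) variances
`(d0·s0² + df_i·s_i²)/(d0 + df_i)` feed the Wald standard errors; when
the spread of variances is within sampling noise, `d0 = ∞` and all
proteins share `s0²`.

**Contrasts.** `delta = mu_iA − mu_iB`, with squared standard error
`1/I_A + 1/I_B` from the observed Fisher information per condition at the
moderated variance (Gaussian term per observed cell, probit curvature per
missing cell, the detection-limit information for pinned conditions).
Two-sided p-values use a t reference with `df = max(n_obs − 2, 1) + d0`;
BH adjustment is applied within each contrast family.

## Threshold calibration

WT/C<sub>PR</sub>S labels are shuffled *within each isoform* (replicate
structure kept, replicates renumbered), the model is refit per
permutation, and all |delta| are pooled across permutations and isoforms;
`tau` is the pooled 95th percentile (numpy's default type-7 linear
interpolation), so by rank construction 5% of the randomized data exceeds
it. The companion FDR estimate at any threshold is the mean
per-permutation exceedance count over the real exceedance count, clipped
to [0, 1] and marked undefined when there are no real discoveries. With
strong true effects this estimate is deliberately conservative — label
shuffles redistribute real effects into the null pool — which the tests
assert as an upper-bound property rather than pretending it is unbiased.

## Classification and downstream analyses

A protein is called enriched when `delta > delta_min` and its p-value
(raw for cysteine-dependence, BH-adjusted for isoform-specificity — both
configurable and recorded in the run manifest) is below `alpha`; defaults
`delta_min = 1`, `alpha = 0.05`. Only WT-directed enrichment counts as
binding; mutant-enriched proteins are reported separately. The mechanism
partition is pure set algebra on the WT and C<sub>R</sub>S binder sets
(`SOH = WT ∩ CRS`, `SS = WT \ CRS`, C<sub>R</sub>S-only reported but not
classified), the isoform-specific view refits the model with
one-isoform-vs-rest condition labels, and the "cysteine-dependent and
isoform-specific" view is the intersection of the two calls, not a third
model. Exclusive intersection counts are exact (every union member is
assigned to exactly one membership pattern). Compartment enrichment
selects set members with `delta > log2(10)` on the WT-vs-C<sub>PR</sub>S
contrast (the contrast that defines binding) and compares their
neighborhood fractions to the full annotation table; multi-row
annotations collapse to the top-scoring call.

## Sequence analyses

Global alignment is a Gotoh affine-gap Needleman–Wunsch with BLOSUM62,
gap open 10, gap extend 0.5 (a gap of length L costs `10 + 0.5(L−1)`),
end gaps free, and deterministic tie-breaking (diagonal, then up, then
left). Similarity is the percentage of alignment columns with a positive
substitution score; identity the percentage of exact matches; both are
over the full alignment length including end gaps. Scores are verified
against exhaustive enumeration (lengths ≤ 8) and an independent library
implementation.

Cysteine windows are ±4 residues around every C, padded with `-` at the
termini; pads and the center are excluded from all counting.
Composition enrichment smooths both window sets with 0.5 pseudocounts per
residue and tests foreground counts with a two-sided binomial against the
smoothed control frequency, BH over the 20 residues. Motif discovery is
the classic greedy scheme: repeatedly fix the (position, residue) pair
with the smallest one-sided binomial p-value (threshold 1e-4, minimum
support 10, ties broken by (p, position, residue)), filter both sets to
matching windows, and on completion remove the motif's windows from the
foreground and restart. Shuffled backgrounds permute each sequence
uniformly (composition preserved) and re-extract windows; 100 shuffles by
default.

## The synthetic-data generator

The generator emulates the screen the pipeline targets, and its defaults
are the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| design | 5 isoforms × {WT, CRS, CPRS} × 3 replicates | the screen's layout |
| baseline abundance | N(25, 3²) log2 units | typical LFQ dynamic range |
| planted effect | +4 log2 units | a 16-fold pulldown enrichment |
| replicate noise | 0.5 log2 units | ~35–40% intensity CV, typical IP-MS replicate noise, and the level at which the `delta>1, p<0.05` gates can keep FDR ≤ 0.1 at all |
| missingness | solved per sample to 34% mean | the screen's observed missingness level |
| dropout width zeta | 1.0 log2 units | a soft, realistic detection edge |
| mechanism mix | 70% SOH / 30% SS | majority peroxidatic-cysteine relay |
| cysteine-dependent fraction | 0.85 | most binding is disulfide-mediated |
| decoys | 20 reverse + 20 contaminant rows | exercises the filters |

Binding is routed by mechanism: non-cysteine-dependent binders are
enriched in all three genotypes of their isoform, SOH-relay binders in WT
and C<sub>R</sub>S, disulfide-relay binders in WT only. Sequences are
uniform over the 20 amino acids with at least one guaranteed cysteine and
optional planted flank enrichments; compartments are uniform with
configurable per-isoform biases. One RNG stream per generator operation,
derived from the single config seed by fixed offsets, keeps partial
regeneration stable.

What the generator does **not** emulate: peptide-level rollup and shared
peptides, intensity-dependent (heteroscedastic) noise, correlated
replicates, batch effects, protein groups with ambiguous members, or any
relationship between sequence and binding beyond the planted motifs.
Passing recovery tests therefore demonstrates that the pipeline's
inferences are correct *under its own modeling assumptions* and robust to
the missingness mechanism it models — not that real IP-MS data meet
those assumptions.

## Problem sizes and determinism

Tests and the acceptance script run on desk-scale instances — ~1,000
proteins, 6–45 samples, 5–20 permutations in tests (100 remains the
pipeline default), 2,000-window sequence corpora — chosen so the full
suite completes in about half a minute while leaving the statistical
assertions well-powered. All randomness flows from explicit integer
seeds; two runs of any stage with the same config and seed produce
byte-identical outputs.

## Known limitations

- Fold changes of proteins never observed in one condition are censored
  at the detection limit (see above); their ranking is still correct but
  their magnitude is a lower bound.
- The permutation FDR estimate is conservative when many strong true
  effects exist.
- The dropout-curve location estimator carries a small positive selection
  bias; it calibrates the model adequately but is not an unbiased
  estimate of the 50%-dropout intensity.
- The isoform-vs-rest contrast pools all other isoforms into one
  condition, so an interactor shared by two isoforms dilutes both calls.
- Alignment similarity uses the substitution-matrix sign convention;
  percentages depend on the matrix chosen (BLOSUM62 by default).
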