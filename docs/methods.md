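# Methods

This note documents the models and numerical choices behind `methylmark`:
what each stage computes, what the synthetic-data generator does and does
not emulate, and where the design was genuinely open.

## qMSP percent methylation

Methylation-specific PCR runs three reactions per bisulfite-converted
sample: methylation-specific, unmethylation-specific, and an internal
control insensitive to methylation state. With perfect per-cycle doubling,
`2^(−ΔCt)` is proportional to template amount, so

    % methylation = 100 / (1 + 2^(ΔCt_meth − ΔCt_unmeth)),
    ΔCt_x = Ct_x − Ct_internal,

is the methylated fraction of total template. The estimate lives in the
open interval (0, 100); a Ct difference can make one allele arbitrarily
rare but never absent. The implementation satisfies three exact
identities that the tests enforce: channel swap complements the estimate
(`m ↔ 100 − m`), adding a constant to all three Cts changes nothing, and
the zero-noise simulator round-trips any planted value to machine
precision. Replicates are averaged on the Ct scale *before* the nonlinear
transform (Ct noise is approximately additive); a per-replicate variant
is not offered here because with the complementary identity the ordering
only matters at high noise. Undetermined reactions (NaN Cts) propagate to
a missing estimate, never silently to 0% or 100%.

## Comparative ΔΔCT expression

`ΔCt = mean Ct_target − mean Ct_reference` per condition,
`ΔΔCt = ΔCt_case − ΔCt_control`, `fold = 2^(−ΔΔCt)`. Amplification
efficiency is assumed exactly 2 (no efficiency correction), the assumption
the comparative method rests on. Replicates are averaged per
(condition, gene) cell by default; a per-replicate mode (arithmetic mean
of per-replicate ΔΔCt, i.e. geometric-mean fold) is available and agrees
exactly at zero noise.

## Array β-values and the Δβ screen

`β = (M − bg)⁺ / ((M − bg)⁺ + (U − bg)⁺)` — a plain background-subtracted
ratio, clamped at zero. There is deliberately **no** +100 denominator
offset (the Illumina convention); the offset is exposed as an option but
defaults to 0 because the plain ratio is what the upstream description of
this assay computes. A probe whose two corrected channels are both zero
yields a *missing* β, not 0 — a dead probe must not masquerade as
hypomethylated. Detection filtering is probe-wise: any record with
detection p strictly above α (default 0.05) removes the probe from every
sample. The differential screen compares group-mean β values,
`Δβ = mean β(B) − mean β(A)`, and calls hyper (Δβ > 0.06) or hypo
(Δβ < −0.06) with strict inequalities; the threshold is taken as given
(it encodes the assay's replicate SD), not re-estimated.

## Amplicon bisulfite calling

Bisulfite converts unmethylated C to U (read T) while 5-mC is protected.
For a known amplicon the analysis is: find CpGs on the untreated
reference; convert the reference in silico (non-CpG C → T, CpG C → the
pyrimidine ambiguity Y); align each read ungapped at the
minimum-mismatch offset (Y matches C or T freely, ties to the smallest
offset, both orientations tried, forward preferred on ties); accept if
the mismatch fraction is ≤ 5% (default). Per aligned read, the base over
each CpG cytosine gives the call (C = methylated, T = unmethylated,
anything else missing), and the fraction of covered non-CpG reference
cytosines read as T — computed as T/(T+C) so isolated sequencing errors
at those positions do not distort the denominator — is the per-read
conversion rate, a QC statistic meaningful because somatic non-CpG
methylation is negligible.

Ungapped alignment is a deliberate simplification: clone/amplicon
sequencing of a known ~1 kb region needs no indel model, and indel-bearing
reads fall out via the mismatch threshold. Coordinates are genomic
1-based inclusive; TSS-relative offsets are the plain difference
`coord − tss` (TSS ↦ 0, reported conventionally as +1), which makes the
offset↔coordinate maps exact inverses. BED export is 0-based half-open.
The site summary excludes reads below a conversion-rate floor only when
one is requested; the default floor is 0 (no filtering).

## Synthetic cohort

Each clinical group's age, MMSE and methylation % follow truncated-normal
marginals coupled by a Gaussian copula; sex and APOE ε4 status are
independent Bernoulli draws at the configured fractions (with an explicit
`missing` level for APOE). Two calibrations make the generator reproduce
published summary statistics rather than merely resemble them:

1. **Marginal moment matching.** The parent (μ, σ) of each truncated
   normal is solved (bracketed root for the mean, bounded 1-D
   minimization for the SD) so the *truncated* distribution has the
   configured mean and SD inside the configured range. Some published
   (mean, SD, range) triples lie outside the truncated-normal moment
   region — a heavy-tailed sample can report a larger SD than any
   truncated normal supports at that mean and range (the MCI age and MMSE
   and control MMSE blocks are such cases). The mean is then matched
   exactly and the closest achievable SD used; group means, which drive
   every downstream comparison, stay unbiased.

2. **Pooled-correlation decomposition.** Published correlations are
   pooled over all subjects, so they mix the between-group signal (sick
   groups are older, score lower, methylate less) with within-group
   coupling. The generator decomposes each pooled target
   (`Cov_pooled = Σ w_g Cov_g + Cov of group means`, weights w_g = n_g/N)
   using the configured group moments and solves for a common
   within-group latent correlation. The methylation–MMSE coupling is
   configured as the age-adjusted partial correlation — the form such
   studies report — and converted to a raw pooled target by inverting the
   first-order partial-correlation formula. Infeasible targets (implied
   within-group |r| > 1, or a non-PSD latent matrix) raise a calibration
   error naming the offending pair.

MMSE is rounded to its integer clinical scale; methylation % stays
continuous. Monte-Carlo over 50 seeds confirms the generated pooled
Pearson correlations average −0.586 / −0.468 against targets
−0.589 / −0.465 and that group means are unbiased.

What the generator does **not** emulate: measurement error correlated
across assays, batch effects, PCR amplification bias, non-normal trait
shapes (floor effects in severe dementia MMSE), or informative
missingness in APOE status. Passing tests therefore demonstrate the
*pipeline's* correctness and calibration, not that real cohorts satisfy
the generative assumptions.

## Assay simulators

Each simulator is the exact algebraic inverse of its quantifier at zero
noise: qMSP triplets place `ΔCt_meth − ΔCt_unmeth = log2((100−m)/m)`;
expression tables place the case target `log2(fold)` cycles below the
control; array intensities are `bg + β·T` / `bg + (1−β)·T` with shared
background so the β computation returns the planted value; bisulfite
reads keep each CpG C with its site probability and convert non-CpG Cs at
the configured efficiency, with independent substitution errors on top.
Defaults follow the emulated study: triplicate reactions, ~0.15-cycle Ct
noise, a 27,578-probe array with 43 planted detection failures, 200
full-length amplicon reads (clone-scale sequencing; a fragmentation
option produces 454-style partial reads), conversion efficiency 0.99.
Probes carrying a planted Δβ get their baseline redrawn inside the
feasible band so the planted effect always fits in [0, 1]; deltas that
cannot fit at any baseline are an error. One seed per dataset is split
into independent per-simulator streams.

## Cohort statistics

Kruskal–Wallis and the correlation tests delegate to scipy (with the
all-values-identical degenerate case returning H = 0, p = 1 explicitly);
the test suite cross-checks H against a from-scratch rank-formula oracle
on all three-group size combinations up to 5. Dunn's post hoc uses the
pooled tie-corrected rank variance
`σ² = N(N+1)/12 − Σ(t³−t)/(12(N−1))` with Bonferroni multiplication
(capped at 1), matching the convention of common graphing software; the
adjustment is a parameter. The partial correlation is the first-order
formula with a t-test on n−3 df, verified against pingouin.

ROC analysis requires an explicit `direction` — for this biomarker
`lower_is_positive`, since hypomethylation marks disease — and never
infers it from the data. AUC is computed as pairwise concordance via the
Mann–Whitney statistic (ties credited 1/2), which equals the trapezoidal
area under the swept empirical curve exactly (asserted on 1,000 random
tied instances). The operating point maximizes Youden's J with ties
broken toward higher specificity; alternative cutoff rules were out of
scope. Power uses the noncentral-t distribution with either pooled
(default) or Welch–Satterthwaite df; the pooled form is exact only under
equal variances, which is how the simulation oracle tests it.

MMSE severity bins: the clinical scheme quotes mild 21–26, moderate
10–20, moderately severe 10–14 and severe <10 — an overlapping set. The
finer band carves the coarser one, so the implementation uses severe <10,
moderately severe 10–14, moderate 15–20, mild 21–26, and labels 27–30
`mild_or_above` (outside the quoted dementia bins).

## Problem sizes and tolerances

The test suite runs the full 27,578-probe array once, 1,000-read
bisulfite recovery once, and 10,000-replicate power simulations twice;
cohort Monte-Carlo checks use 15–50 seeds of the 128-subject cohort.
Stochastic assertions use 3 standard errors for planted-parameter
recovery (binomial or mean SEs), 2 SE for power-vs-simulation agreement,
and exact (1e-12) equality for the algebraic identities and zero-noise
round trips. Note that with a 10-subject control group, the Dunn AD vs
control contrast has only ~30% power at Bonferroni-corrected 0.05 under
the study's own distributional parameters; tests assert its direction and
the stable parts of the pairwise pattern rather than a per-seed
significance that the conditions cannot deliver.

## Known limitations

- Ungapped alignment cannot place reads with indels; they are reported
  unaligned rather than recovered.
- The analytic pooled power is an approximation when true variances
  differ; use the Welch method there.
- The copula calibration assumes a common within-group correlation across
  groups; per-group correlations are emergent, not controlled.
- The β-value screen operates on summary intensities; idat parsing,
  probe-type normalization and batch correction are out of scope.
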