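# Methods

## The model and its assumptions

`masterreg` tests for a master regulator transcription factor — a TF at the
top of a regulatory hierarchy, itself unregulated — using expression data
from two conditions only. The working assumption is rank concordance: if a
master exists, then TFs that sit close to it in the hierarchy (high absolute
correlation with it) should also be the TFs whose connectivity to the
downstream genes changes most between the conditions. The null hypothesis is
the absence of such concordance for every candidate.

Connectivity is measured by within-group Pearson correlation. The
differential-connectivity score

x_i = (1/N) Σ_g | r(TF_i, g | case) − r(TF_i, g | control) |,  x_i ∈ [0, 2],

averages over all N non-TF genes, not only a TF's own targets, so it needs
no target annotation; genes unrelated to TF_i contribute only sampling noise
to the average. The hierarchy matrix y takes absolute correlations — sign of
regulation (activation vs repression) is deliberately ignored — and pools
both groups, because the hierarchy is assumed to be a property of the system
rather than of one condition.

Per candidate j, K_j is a Kendall tau-a over the pairs
(x_1, y_j1) … (x_M, y_jM): fixed denominator M(M−1)/2, ties counting toward
neither the concordant nor the discordant count. Tau-b's tie-corrected
denominator would rescale a statistic whose denominator the procedure fixes,
so it is not used. The self pair (x_j, y_jj = 1) participates like any
other element; since y_jj is maximal, it is concordant with every x_i < x_j
and discordant with every x_i > x_j, which effectively rewards candidates
whose own connectivity change is large (consequences below). K = max_j K_j
is the test statistic and T = argmax_j K_j the identified master set; ties
within 1e-10 of the max are reported together (K_j values are rationals
with denominator M(M−1)/2, so exact ties are the norm, and the tolerance
only absorbs float noise).

## The bootstrap null

The sampling distribution of a maximum of M dependent rank statistics is
intractable, so significance comes from resampling: B draws of r1 + r2
columns, with replacement, from the pooled sample ignoring group labels;
the first r1 drawn columns are relabeled case; x, y and all K_j are
recomputed per replicate (y too — the columns changed); and
p = #{K_b > K}/B with strict inequality, so p is a multiple of 1/B and
p = 0 is possible. An add-one corrected variant (1 + #)/(1 + B) and a
label-permutation mode (resampling without replacement) are available
behind flags for sensitivity analysis; defaults follow the plain bootstrap.
Empirically the test is slightly conservative (see calibration below),
which the permutation mode does not materially change.

Reproducibility contract: one master seed spawns an independent RNG
substream per bootstrap replicate (`numpy` `SeedSequence`), so serial and
parallel execution give bit-identical results for any worker count. The
Monte-Carlo drivers pre-draw per-repetition seeds the same way.

## The synthetic-data generator

The generator plants a three-layer hierarchy. Per subject: TF_1 ~ N(μ, 1)
in cases and N(ϑ, 1) in controls; independent V_i ~ N(0, 1); downstream
factors TF_i = (ρ_i·TF_1 + V_i)/√(1 + ρ_i²) with ρ_2 > … > ρ_M, so
correlation with TF_1 decays down the cascade. Genes come in consecutive
blocks of sizes (m_1, …, m_M) summing to N: TF_1's block loads on TF_1
itself with γ_1 (case) / γ_2 (control); TF_i's block loads on V_i with
r_1i (case) / r_2i (control); all noise is unit Gaussian. All implied
population correlations are available in closed form
(`expected_tf_correlation`, `expected_tf_gene_correlation`) and are
verified by Monte-Carlo in the test-suite at n = 1e5 within ±0.01.

The reference configuration (`reference_design`) fixes M = 10, N = 105,
μ = 50, ϑ = 5, blocks (30, 10×6, 5×3), ρ = (0.95, 0.8, …, 0.1), γ_2 = 0.5,
r_12 = 0.45 with r_1i decreasing by 0.05, and parameterizes the alternative
by one knob δ ∈ [0, 1]:

    r_2i = (1 − δ)·r_1i,   γ_1 = γ_2 + δ²·r_12.

δ = 0 is the exchangeable null for the statistic (identical connectivity in
both groups); δ = 1 zeroes every control branch loading. The μ ≠ ϑ mean
shift propagates to TF_1's gene block (group means γμ vs γϑ), so expression
*levels* differ between groups even at δ = 0; correlations are
location-invariant, so the statistic is unaffected, and the shift is kept
for fidelity to the reference configuration. What the generator does not
emulate about real data: count/heteroskedastic noise, batch effects,
feedback loops, more than three layers, and any direct TF_i → TF_k edges
below the top — so passing tests demonstrate calibration and power under a
clean factor hierarchy, not robustness to those complications.

A two-master variant concatenates two independent cascades (disjoint TFs
and genes) over the same subjects; cross-block correlations are zero in
population.

## Calibration and power at the reference design

Computed by `scripts/acceptance.py` (500 subjects per group, B = 500;
repetition counts 500 for null rates, 100 for power points — chosen so the
binomial standard error of a ~3% rate is under one percentage point while
the script stays within minutes on one CPU). With seed 1: empirical size
0.025–0.05 around nominal 0.05 (the test runs conservative), power 83% at
δ = 0.6 and 100% at δ = 1. The Monte-Carlo drivers expose the same
quantities at any scale; at 200 subjects per group the δ = 0.6 power drops
to roughly 0.35 — halving the sample size costs substantial power at
moderate effect sizes, consistent with the test being recommended for
studies with on the order of hundreds of subjects per group.

`empirical_size` literally calls the power driver at δ = 0 with the same
seed stream, so a power curve's left endpoint reproduces the size estimate
bit-exactly — asserted as a regression identity in the tests.

## Identification concentrates on the top tier, not the single top factor

A consequence of the generative design worth stating precisely. Because
TF_i = (ρ_i·TF_1 + V_i)/√(1+ρ_i²), every downstream factor inherits part of
TF_1's differential correlation with TF_1's own gene block:
Corr(TF_i, g ∈ block 1) = ρ_i·γ/(√(1+ρ_i²)·√(1+γ²)) ≠ 0, and this
correlation differs between groups whenever γ_1 ≠ γ_2. Adding each factor's
own-block differential signal, the population differential-connectivity
vector at δ = 1 orders as x_2 > x_3 > x_1 > x_4 > …, not x_1 first. The
self pair then hands the larger-x candidate an advantage, and the
population concordances work out to K_2 = 43/45 > K_1 = K_3 = 41/45 (M = 10).
So the argmax identifies a top-*tier* TF — empirically one of {TF_1, TF_2,
TF_3} in ≥ 95% of draws at 500 subjects per group — but recovers exactly
TF_1 alone only rarely, and asymptotically never. Existence testing is
unaffected: K is large under the alternative regardless of which top-tier
candidate attains it. Excluding the self pair from K_j would make TF_1 the
unique population argmax here, but the fixed-denominator pair list over all
M elements is the defining convention of the statistic and is kept.

## Numerical and design choices

- **Minimum group size 3** for differential connectivity: with 2 samples
  every Pearson correlation is ±1 and x degenerates.
- **Zero-variance features** (constant within a group, or within a
  bootstrap resample) get correlation 0 with a `ZeroVarianceWarning` naming
  the feature: they carry no connectivity signal, and 0 keeps the average
  well-defined.
- **Missing values** are rejected at load time by default; an opt-in
  pairwise-complete mode (minimum overlap 3, via pandas) serves exploratory
  profiles, but bootstrap inference requires a complete matrix.
- **Correlation engine**: rows are centered and scaled to unit norm once
  per group, correlations are matrix products, clipped to [−1, 1]; all M
  concordance rows are computed in one vectorized pass over the
  M(M−1)/2 sign pairs. One statistic + B = 500 bootstrap evaluation at
  115 × 1000 costs ~0.5 s on one CPU.
- **Connectivity score is pluggable**: `differential_connectivity` accepts
  any function mapping two within-group row-matrices to a cross-association
  matrix (rank-based scores, partial correlations); Pearson is the default
  and the only built-in.
- **Case label** only fixes which bootstrap block has size r1; the
  statistic uses an absolute difference and is symmetric in the groups.
- **Pre-filter**: the optional differential-expression filter is a plain
  Welch t-test with Benjamini–Hochberg control. It is not a moderated
  (empirical-Bayes) analysis, and feature counts on real data will differ
  from those obtained with such tools; it is off by default.
- **Power-curve monotonicity** is asserted on an isotonic fit, not point by
  point, to tolerate Monte-Carlo noise.

## Known limitations

Small samples (tens per group) leave little power at moderate δ. The test
presumes the concordance mechanism: a real system can host a master
regulator whose hierarchy ranking is not concordant with differential
connectivity, and the test will miss it. Identification inherits the
top-tier ambiguity described above, and near-tied candidates (the reference
design's ρ_2 = 0.95 makes TF_2 nearly a copy of TF_1) cannot be separated
by any rank statistic at realistic n. TF annotation is user-supplied; the
package does not decide which features are transcription factors.
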