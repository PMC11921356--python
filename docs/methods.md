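# Methods

This note documents the statistical procedures, the simulator, the
default parameters, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Interaction calling

### Model and procedure

The experimental unit is a (strain pair, carbon source) *triad*: two
monocultures and one coculture, each with n ≥ 3 biological replicates of
an OD₆₀₀ time series (default sampling days 1, 3, 5, 7, 9). The summary
statistic per replicate is the maximum OD₆₀₀ over the recorded
timepoints; only timepoints present in the input are considered (no day-0
extrapolation). Maxima are taken per replicate and then averaged — not
the maximum of the mean curve — so that replicate variance is preserved
for the *t*-test.

Each coculture group is compared with each monoculture group by a
two-tailed pooled-variance Student's *t*-test (df = n₁ + n₂ − 2). The
pooled form is the default because replicate variances at this scale are
comparable; Welch's correction is available (`AnalysisConfig(welch=True)`).
All raw *p*-values of an experiment — two per complete triad — are pooled
into a single Benjamini–Hochberg family before labeling. Pooling the whole
experiment is the most conservative reading of a multiple-testing family
for this design; the per-triad family is what `classify_interaction`
applies when used standalone.

Labels:

* **positive** — both comparisons significant (q < α) with the coculture
  mean above each monoculture mean;
* **negative** — at least one comparison significant with the coculture
  mean below that monoculture mean (if significant comparisons disagree
  in direction, the "at least one" rule makes the call negative);
* **neutral** — anything else.

A comparison is eligible only if the **larger** of its two group means
exceeds the noise floor (0.05 OD, strict inequality). Requiring *both*
means above the floor would make positive calls impossible exactly in the
cross-feeding case of interest, where one monoculture does not grow; the
floor exists to exclude instrument noise, which the larger-mean rule
achieves. The same floor, applied to a monoculture mean, defines carbon
*utilization* for the case annotation (both_use / single_use /
neither_use).

### Normality gating

Shapiro–Wilk is run per group at α = 0.05. Default policy is
`warn` — log and proceed with the *t*-test, appropriate when groups are
expected normal; `fallback_nonparametric` switches the affected
comparison to a two-sided Mann–Whitney U test. Groups with zero variance
or n < 3 skip the gate (the statistic is undefined there).

### Degenerate inputs

Two zero-variance groups with equal means give t = 0, p = 1; with unequal
means, t = ±∞, p = 0, logged as degenerate. A coculture/monoculture ratio
with both monoculture means zero is reported as NaN rather than raising.
The BH adjustment rejects p-values outside [0, 1].

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level on corrected p-values |
| `fdr_method` | BH | Benjamini–Hochberg step-up (BY available) |
| `noise_floor` | 0.05 OD | instrument-noise biomass floor (strict >) |
| `normality_alpha` | 0.05 | Shapiro–Wilk gate level |
| `normality_policy` | warn | warn / fallback_nonparametric |
| `welch` | False | unequal-variance t-test |

The FDR procedure is Benjamini–Hochberg rather than a density-based
estimator: density-fit FDR methods are unstable on families of a few
hundred p-values, and BH is the defensible standard; the method is
pluggable.

## Expression analysis

RPKM is computed literally as
`reads / (gene_length/1000 × total_reads/1e6)`; per-sample totals default
to column sums but may be overridden (flagged) when library-wide mapped
totals exceed the sum over annotated genes. Differential expression
between coculture and monoculture transcriptomes is a per-gene two-tailed
pooled *t*-test on RPKM values with BH correction across genes and strict
gates fold change > 4 and q < 0.05. Fold change is
`(mean_co + c)/(mean_mono + c)` with pseudocount c = 0.01 RPKM, which
guards zero denominators and converges to the plain ratio for expressed
genes; genes with zero counts in every sample are excluded before
testing. Testing normalized values directly (rather than fitting a count
model such as a negative-binomial GLM) deliberately reproduces the
simpler classical procedure; with n = 3 replicates per condition its
power is limited, which the recall figures below quantify.

## Community abundance

Amplicon read counts are divided by per-strain genomic 16S rRNA copy
numbers before closing to relative abundances (aᵢ = (rᵢ/cᵢ)/Σⱼ(rⱼ/cⱼ));
replicate tables are averaged *after* normalization. Metagenome
read-recruitment tables are rarefied to a fixed depth (default 1,000,000
reads) by a multivariate hypergeometric draw (without replacement;
multinomial with-replacement available for shallow samples), then all
strain pairs are correlated by Spearman's ρ with the *t*-approximation
p-value and BH correction across pairs. The t approximation is adequate
at the sample counts this analysis targets (dozens to hundreds of
samples); an exact permutation variant is provided for n < 10. A
recruitment table may carry an `other` column of unrecruited reads so
that the strains remain a small fraction of each rarefied library, as
they are in real metagenomes — without it, fixed-depth closure over a
handful of strains forces spurious negative correlation.

## Assay quantification

The enzymatic assay's standard curve is an ordinary-least-squares line of
ΔA₃₄₀ (= A2 − A1) on concentration, intercept estimated rather than
forced through zero (blank wells rarely read exactly zero); r² < 0.98 is
warned as a suspect calibration. Unknowns are inverse-predicted as
`(ΔA − intercept)/slope` and flagged when outside the calibration range
(default grid 0.001–1 g/L). Consumption is the signed before-minus-after
difference; negative values mean net production and are not clamped.

## The consortium simulator

### Model

Two strains on one carbon source C with one secreted metabolite pool M:

    dA/dt = μ_AC(C)·A
    dB/dt = [μ_BC(C) + μ_BM(M)]·B
    dC/dt = −μ_AC(C)·A/Y_AC − μ_BC(C)·B/Y_BC
    dM/dt = γ·μ_AC(C)·A − μ_BM(M)·B/Y_BM

with Monod uptake μ_X(S) = μmax_X·S/(K_X + S). One pooled metabolite
stands in for the branched-chain amino acids (L-leucine, L-isoleucine,
L-valine) that mediate cross-feeding in the motivating system: a single
pool suffices for label-level ground truth. Secretion is proportional to
donor growth (γ, g/L per OD of growth) and is not debited from the
donor's own yield — a deliberate simplification that leaves the carbon
mass balance (A and B growth on C vs C consumed) exact. OD additivity is
assumed (observed OD = A + B, calibration 1 OD per biomass unit), with
independent Gaussian observation noise truncated at zero and no
autocorrelation (plate readings are days apart).

### Defaults and units

| parameter | default | units | rationale |
|---|---|---|---|
| μmax (carbon) | 2.0 | /day | plateaus well within the 9-day window |
| K (all substrates) | 0.1 | g/L | saturating at the 1 g/L dose |
| Y (carbon) | 0.15 | OD per g/L | mono max ≈ 0.155 OD at 0.1% carbon, the observed magnitude |
| γ | 2.0 | g/L per OD | coculture ≈ 2× donor monoculture |
| μmax_BM / Y_BM | 2.5 / 0.5 | /day, OD per g/L | recipient consumes M within the window |
| C₀ | 1.0 | g/L | 0.1% w/v carbon dose |
| inoculum | 0.005 | OD | total, split equally in coculture |
| noise sd | 0.01 (0.005 in the pattern fixture) | OD | plate-reader repeatability |
| coculture penalty | 0.15 | × μmax | interference strong enough that the penalized strain stays in early growth through day 9 |

No kinetic parameters are claimed as estimates of any real strain; they
are chosen once to reproduce the qualitative magnitudes (monoculture
maxima ~0.1–0.35 OD on 0.1% carbon) and are config-exposed.

### Integration

Classical fixed-step 4th-order Runge–Kutta, step 0.01 day (no adaptive
stepping, for bit-reproducibility across platforms); state clipped at
zero after each step; non-finite states raise. The trajectory carries the
cumulative partner-growth-from-carbon integral U so the carbon balance
(A−A₀)/Y_AC + U/Y_BC = C₀−C can be checked along the whole trajectory;
the suite verifies it to well within 1% and step-halving agreement to
within 0.1% at day 9.

### Scenario construction

Per-(pair, carbon) scenarios compose a dataset. Positive scenarios are
cross-feeding (γ > 0, recipient grows on M; in the both-utilizer variant
the partner also grows on C). Negative scenarios are interference,
implemented as a coculture-specific multiplier on one strain's growth
rate — the mechanism of real negative interactions here is not
characterized, and a rate penalty is the minimal interference model. A
both-utilizer negative additionally gives the penalized strain a high
yield (0.35) so that the coculture, which tracks the low-yield partner,
falls significantly below the penalized strain's monoculture despite OD
additivity. Neutral scenarios are independent growth or joint
non-growth. Monocultures shared between pairs on one carbon are simulated
once from one parameter set; conflicting specifications are rejected.

### The pattern fixture

`pattern_fixture` lays 84 (pair, carbon) combinations over 4
strains × 14 carbons so that 33 are positive (28 single-utilizer, 5
both-utilizer), 7 negative (4 single, 3 both) and 44 neutral, the
composition reported by the motivating study. All 44 neutral triads are
joint non-growth: every group mean sits below the 0.05 OD floor, so their
comparisons are ineligible by construction and the engineered composition
is recovered deterministically — the observation seed only perturbs
noise, not labels. This is a deliberate property of the fixture, not of
real experiments: a neutral triad *above* the floor contributes genuinely
null p-values, and with 3 replicates some of those will always clear any
FDR threshold by chance. The fixture therefore demonstrates correctness
of the decision logic at large effect sizes; the null calibration suite
(500 same-distribution triads, σ = 0.01, non-neutral rate ≤ 7%) is what
bounds the false-call behavior in the regime the fixture avoids.

### Planted-effect generators

Expression: baseline per-gene means log-uniform on [5, 500] expected
counts, negative-binomial replicates (variance m + φm², default
φ = 0.05 — biological-replicate scale; φ = 0 is the noise-free limit with
counts equal to rounded means), planted genes scaled by the effect fold
in the coculture condition, gene lengths uniform on 300–3000 bp. With 3
replicates the RPKM t-test recovers ≥ 90% of 8-fold planted genes only at
low dispersion (φ ≤ 0.01); at φ = 0.05 recall drops to roughly a third —
an honest limitation of the classical procedure, quantified in the suite.

Recruitment: a per-sample community factor drives all strains through a
Gaussian copula with latent correlation r = 2·sin(πρ/6), chosen so
pairwise Spearman ρ matches the requested rank agreement in expectation;
strain relative abundances are log-normal (spread 0.8) around ~0.5% of
the library, the remainder being unrecruited reads; counts are
multinomial at a per-sample depth drawn from 1.2–3 M reads.

## What the synthetic data does not show

The generators emulate design, magnitudes and noise structure — not real
strains. Passing tests demonstrate that the inference chain recovers
known ground truth under the stated noise models; they say nothing about
growth-curve shapes beyond Monod kinetics, about transcriptome-wide
dispersion structure, or about compositional effects in real metagenomes
beyond the minority-strain regime. Results that depend on the original
sequencing data (specific differentially expressed gene counts, observed
biofilm correlations, CFU counts, genome statistics) are out of scope;
the corresponding pipeline stages are validated on planted synthetic
effects instead.

## Problem sizes

The default suite exercises: the 84-triad pattern dataset (420 curves);
1,000 random instances per statistical-oracle check; 500 null triads and
2,000-gene null count matrices for calibration; 100 simulated datasets
per scenario type for label recovery; and 20-sample, 4-strain
recruitment matrices. These sizes give stable pass/fail behavior at
desk scale.
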