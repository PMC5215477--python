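# Methods

This note documents the statistical machinery of `crvi-bmd`: the models,
their assumptions, the defaults and why, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was genuinely open. No empirical claim here goes beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## Differential-expression screening

Intensities are modeled on two scales: statistics on log2 (where
microarray noise is approximately additive with constant variance), fold
changes on the linear scale (ratios of group means). The chain is:

1. **Quantile normalization.** Every array is mapped onto the common
   distribution of row-rank means; mid-ranks average tied quantiles. The
   transform is idempotent on tie-free data. A known consequence worth
   stating: when responsive probes sit near the top of the intensity
   range, forcing arrays onto a shared distribution compresses their
   apparent fold change (a ceiling effect). In the planted-truth
   simulations this attenuation costs a few percentage points of
   sensitivity at the |FC| ≥ 2 gate for probes whose shifted intensity
   exceeds the common maximum.
2. **Background filter.** A probe is removed only when it falls below
   its array's median intensity in a strict majority of samples; a probe
   below the median in exactly half the samples is retained.
3. **Gates.** Per exposed group vs. control, a one-way ANOVA on log2
   values (for two groups this is algebraically the pooled-variance
   t-test, F = t²). DEG: |FC| ≥ 2, p < 0.05 and Benjamini–Hochberg
   q < 0.05; pDEG: |FC| ≥ 1.5 and p < 0.05 with no q gate. FDR is
   corrected within each exposed-vs-control comparison across all
   retained probes; the correction universe is not prescribed anywhere
   authoritative, and per-comparison correction is both the default in
   comparable array workflows and the choice that keeps comparisons
   exchangeable. An all-groups omnibus ANOVA mode exists but is not the
   default, matching the pairwise n=3-vs-n=3 design. Zero-variance
   probes receive a pooled-variance floor of 1e-12 (logged) instead of a
   division error.
4. **Per-animal counts.** For each exposed animal, among the probes
   flagged DEG in its dose group, those whose individual fold change
   (animal intensity / control-group mean) passes |FC| ≥ 2 are counted.
   This is the replicate-level response measure the breakpoint model
   consumes; it can legitimately differ from the group-level DEG total.
5. **PCA QC.** Sample scores on the first three components of the
   centered log2 data; a sample is flagged when its distance to its
   dose-group centroid exceeds 3x the median such distance. Flags are
   reported and never acted on — outlier removal without a substantive
   cause is poor practice, so nothing downstream ever drops a sample.

## Continuous benchmark-dose modeling

Four mean models (Hill, power, linear, quadratic) are fitted to log2
expression by maximum likelihood under Normal(mu(d), sigma²) with a
shared constant variance. Linear and quadratic are exact OLS; power and
Hill profile their linear coefficients out by OLS and optimize only the
shape parameters (delta, or k and n), with five deterministic
data-driven starts for Hill and a 40-point grid plus bounded refinement
for power. Shape exponents are constrained to [0.1, 18] to exclude
degenerate step-function fits; optimizer iterations are capped at 250.
Non-convergence is recorded and the fit marked unusable.

* **BMD.** The smallest positive dose shifting the mean by
  1.349 * sigma-hat from the control mean, direction-agnostic (|shift|,
  since the screen treats down-regulation symmetrically). Closed forms
  are used for all four models, with a bracketed root-finder on
  [0, 10 x max dose] as a cross-check; the two agree to 8+ significant
  digits in the tests. Because sigma-hat is the ML estimate (SSE/N), it
  is biased low in small samples — at 6 doses x 3 replicates this
  deflates BMD estimates by roughly 10%, visible in the recovery
  simulations. This is the convention of the reference tools and is kept
  deliberately.
* **BMDL.** One-sided 95% profile likelihood: each model is
  reparameterized so the BMD is an explicit parameter (one natural
  parameter is substituted using the benchmark-response constraint, with
  sigma a free parameter of the constrained fit), the constrained
  likelihood is maximized by Nelder-Mead from the unconstrained optimum,
  and the deviance is bisected against chi²₁(0.90) = 2.7055 (the
  one-sided 95% cutoff). Failure to bracket (flat likelihood) leaves the
  BMDL undefined, which the retention filters then treat as a removal.
* **Selection.** Hill is ineligible when its half-maximal dose k is at
  or below one third of the lowest tested dose (guarding against
  artificially minimized BMDs); quadratic must beat linear in a nested
  LRT at p < 0.05; among the eligible, lowest AIC wins, with AIC =
  2(#mean params + 1) − 2 loglik (the +1 counts sigma; it cancels in
  comparisons and matters only for documentation). Exact AIC ties go to
  the simpler model in the order linear < power < poly2 < hill — the
  operational reading of "least complexity". Whether the nested LRT
  should cover pairs beyond linear/quadratic is unspecified in the
  conventions this follows; only the linear-in-parameters nesting is
  tested, matching common practice.
* **Retention.** A selected fit is kept iff BMD/BMDL ≤ 20, BMD ≥
  lowest dose / 3, BMD ≤ highest dose, and the lack-of-fit p > 0.1,
  where the lack-of-fit test is the likelihood ratio against the
  saturated per-dose-means model with df = #dose groups − #mean
  parameters (df ≤ 0 returns p = 1: the model saturates the means). All
  rules are evaluated unconditionally so the verdict is independent of
  evaluation order. Caveat: with 3 replicates per dose the chi-square
  LRT is anti-conservative (empirical type-I error ~15–25% at the 0.1
  gate rather than the nominal 10%), so the gate sheds a material
  fraction of genuinely dose-responsive probes. The gate is kept as
  specified; the recovery tests budget for it.

## Multistage cancer modeling and risk arithmetic

P(d) = gamma + (1−gamma)(1−exp(−sum beta_i d^i)) with gamma in [0, 1)
and beta_i ≥ 0, fitted by binomial maximum likelihood (bounded L-BFGS-B
from a grid of starts, polished by projected Nelder-Mead). Extra risk
[P(d)−P(0)]/[1−P(0)] does not involve gamma for this family, so the
BMD₁₀ solves sum beta_i d^i = −ln(0.9); degree 1 in closed form, higher
degrees by root-finding (the two agree to 10+ digits). The BMDL₁₀ is the
one-sided 95% profile-likelihood bound computed by substituting beta_1
from the extra-risk constraint (respecting beta_1 ≥ 0) and bisecting the
deviance against 2.7055. Coverage measured over 500 simulated 50-animal
studies is ~95%.

Model selection takes the lowest-AIC fit among those with Pearson
chi-square goodness-of-fit p > 0.1 (the conventional "acceptable"
threshold), ties to the lowest degree; if none is acceptable the
best-AIC fit is returned flagged. Parameters estimated at a bound
(beta_i = 0, gamma = 0) are excluded from both the AIC parameter count
and the GOF degrees of freedom — the convention of the regulatory BMD
software this module mirrors, and the one that reproduces its printed
fit statistics on the bundled tumor table.

Risk arithmetic from a BMDL point of departure: slope factor = BMR/BMDL;
risk-specific dose = target risk / slope factor; RfD = BMDL / UF
(default composite UF 30); drinking-water concentration = dose x body
weight / daily intake (defaults 80 kg, 2.5 L/day). Animal-to-human dose
conversion uses body-weight-¾ allometry, HED = dose x
(BW_animal/BW_human)^¼; study-specific animal body weights are
user-supplied configuration, since time-weighted average weights are
external data. Internally everything is full precision; the report layer
rounds to 2 significant figures and derives the reported risk-specific
dose from the rounded slope factor, which is how assessment documents
chain their printed values (1e-6 / 0.12 = 8.3E-6, whereas the
full-precision chain gives 8.4E-6).

The bundled `ntp_female_rat_oral_tumors()` table (oral-cavity squamous
papilloma/carcinoma in female F344 rats, 50/group at 0/5/20/60/180 ppm
Cr(VI)) is real public bioassay data (NTP TR-546), included so the
ppm-metric chain is reproducible end to end.

## Bilinear breakpoint (BPD/BPDL)

The hockey-stick mean beta0 + beta1 x + beta2 (x − psi)+ with Gaussian
error is estimated by iterative linearization: the working model adds
the gap covariate (x − psi)+ and the indicator derivative −1{x > psi},
and psi is updated by gamma-hat/beta2-hat until |Delta psi| <
1e-8 x range(x) (max 100 iterations). Divergence falls back on a
deterministic 200-point grid search over admissible breakpoints (at
least two distinct x on each side). se(psi) comes from the delta method
(se(gamma-hat)/|beta2-hat| at convergence) and BPDL = psi −
1.645 se(psi), a one-sided 95% bound that is explicitly approximate —
the delta method understates uncertainty when the break is weak. A
slope change whose two-sided 95% CI spans zero marks the fit
unreliable. On noise-free piecewise-linear input the estimator is exact
to solver tolerance; at noise of 10% of the response range (3
replicates per group) the median breakpoint error is ~13% and
delta-method coverage stays near the nominal 95% in the tests. Each
animal's x is its dose group's mean tissue chromium, because tissue
chemistry and transcriptomes come from different animals in this study
design.

## Enrichment

One-sided hypergeometric upper tail P[X ≥ k] per gene set, after
intersecting sets with the universe; the EASE variant tests k−1
(P[X ≥ k−1], so k = 1 gives p = 1). The default universe is the probes
surviving the background filter mapped to unique gene symbols — the
defensible stand-in for an unstated enrichment background, and
configurable. Enrichment is gated at raw p < 0.05 (matching the
original workflow); a BH-adjusted column is emitted for information
only. The implementation is verified against direct combinatorial
enumeration for every instance with N ≤ 25.

## Dosimetry

SDD→Cr(VI): cr6 = sdd x 2 M_Cr / M_SDD with M_Cr = 51.9961 and
M_SDD = 298.00 g/mol (mass fraction 0.34897), exactly invertible.

Shirley's test: at each step-down stage the highest remaining dose is
tested against control using joint mid-ranks, pool-adjacent-violators
amalgamation of the treated-group mean ranks (the monotone
alternative), tie-corrected rank variance, and Williams-type one-sided
t-bar critical values at infinite degrees of freedom (the rank-limit
values), embedded for alpha = 0.05 and 0.01 with linear interpolation
in the number of dose groups. A non-significant dose stops the
procedure, making the significance flags downward-closed. One-sided
increasing is the default (tissue burden rises with dose);
`alternative="less"` negates the data. Values reported at the 0.02
mg/kg detection limit enter as ties at the limit.

## Synthetic data

`simulate_expression` emulates the statistical structure of the study
arm: 6 dose groups (0, 0.3, 4, 60, 170, 520 mg/L SDD by default — the
rat grid; mice add 14), 3 biological replicates, per-probe baselines
uniform on log2 [6, 12], Gaussian log2 noise (sigma 0.25 by default,
i.e. constant CV on the linear scale, consistent with the constant-
variance assumption of the BMD stage), and a planted fraction of
dose-responsive probes drawn from Hill/power/linear/quadratic families
with top-dose effect sizes of 1–2 log2 units and random sign. True
benchmark doses are recorded per planted probe from the noiseless curve
and the true sigma. Because the real oral-mucosa data showed
essentially no responders, the effect-size defaults are chosen for test
power, not biological fidelity. Not emulated: probe-level spatial
artifacts, dye bias, batch effects, inter-probe correlation, or
heavy-tailed intensity distributions — so passing tests demonstrate the
statistical behavior of the pipeline under its own assumptions, not
robustness to real-array pathologies.

`simulate_tissue_burden` draws hockey-stick tissue chromium with
Gaussian noise, reporting values below the 0.02 mg/kg detection limit
at the limit with a censored flag (report-at-limit convention; the
reporting convention of the original chemistry is not stated, and this
is the common ICP-MS choice). `simulate_tumor_incidence` draws binomial
counts from the multistage response.

All generators are deterministic given a seed.

## Problem sizes

The test suite and acceptance script measure stochastic guarantees at
deliberately modest sizes chosen as a sensible compute budget: 2,000
probes per simulated array (a 10x scale-down of a whole-genome array
that leaves every rate estimate well-resolved), 100 seeds for null-FDR
control, 500 simulated studies for profile-BMDL coverage, 200 seeds for
breakpoint recovery, 30 seeds for the end-to-end negative-result run.

## Known limitations

* BMDL profiles assume the chi-square deviance calibration; with 3
  replicates per dose the continuous-model bounds are approximate.
* The BPDL is a delta-method bound, not a profile or bootstrap bound.
* Shirley critical values are the infinite-df Williams values;
  small-sample exactness is not claimed.
* Enrichment treats genes as exchangeable (no gene-length or
  expression-level bias modeling).
* The HED-metric tumor chain depends on externally supplied animal body
  weights and dose conversions; only the ppm-metric chain is
  reproducible from the bundled incidence table alone.
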