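# Methods

This note documents the statistical model, the synthetic-data generator, and
the numerical and design choices behind `btpp`, in the spirit of the methods
documentation of packages such as statsmodels or msprime: enough detail to
reimplement the analysis, plus an honest account of what the simulations do
and do not establish.

## Melting-curve model

The soluble (non-denatured) fraction of a protein at temperature `T` (°C) is

    f(T) = (1 − plateau) / (1 + exp(−(a/T − b))) + plateau

a logistic in the reciprocal-temperature coordinate. `a > 0` (units °C) sets
the transition steepness, `b` its location, `plateau ∈ [0, 1)` the fraction
that never precipitates. For `a > 0` the curve decreases monotonically from
1 towards `plateau`. The melting point is the half-denaturation temperature,

    Tm = a / (b − ln(0.5 / (0.5 − plateau))),

defined only when `plateau < 0.5`, the denominator is positive, and the root
lies within the gradient span widened by an extrapolation margin `E` (default
10 °C); otherwise Tm is reported undefined rather than extrapolated. The
steepest slope is the minimum of the analytic derivative

    df/dT = −(1 − plateau) · (a/T²) · e^{−(a/T−b)} / (1 + e^{−(a/T−b)})²

on a 0.01 °C grid over the gradient span.

Fold changes are defined per (condition, replicate) experiment relative to
the lowest temperature, so `FC(T_min) = 1` holds by construction and enters
each fit as an ordinary data point; no explicit constraint is imposed. This
is observationally equivalent to constraining `f(T_min) = 1` for every
statistic reported here.

## Fitting

Per-curve fits use `scipy.optimize.least_squares` (trust-region reflective)
with bounds `a ∈ [0.01, 10⁶]`, `b ∈ [−100, 500]`, `plateau ∈ [0, 1)`.
Initialisation is deterministic: `plateau₀ = min(FC)/2` (capped at 0.4),
`Tm₀` the linearly interpolated first crossing of 0.5 (falling back to the
hottest observed temperature), `a₀ = 550`, `b₀ = a₀/Tm₀`. A fit requires at
least 5 of the 7 points including the reference; fewer points, or solver
failure, yields a non-converged fit that automatically fails the quality
criteria. R² is computed against the mean of the points used (reference
included). Ties in downstream reference-experiment selection are broken
lexicographically, so every result is reproducible bit-for-bit under a fixed
seed.

The NPARC permutation engine needs millions of 3-parameter fits, far beyond
what per-curve scipy calls allow, so the package includes a batched damped
Gauss–Newton (Levenberg–Marquardt) solver operating on thousands of curves
simultaneously: analytic Jacobians, Marquardt diagonal scaling, closed-form
3×3 solves, per-problem damping, and an active-set treatment of bound
constraints (a parameter sitting on a bound with an outward-pointing
gradient is frozen out of the step; naive step clipping creeps along the
boundary and stalls, typically at `plateau = 0`). Two deterministic starts
(the rule above, and a variant whose `a₀` is estimated from the largest
observed per-°C drop) guard against the shallow-valley local minimum that a
fixed `a₀` produces for steep high-Tm curves. The unit tests verify that the
batched solver matches the scipy optimum on every problem in a 150-curve
noisy benchmark.

## Quality criteria

A protein is a candidate target (`is_target`) when all four hold, strictly:

1. every one of the four curves converged with R² > 0.8;
2. both vehicle plateaus are < 0.3;
3. the two replicate shifts ΔTm_r = Tm(treatment, r) − Tm(vehicle, r) share
   a sign and `min(|ΔTm₁|, |ΔTm₂|) > |Tm(vehicle,1) − Tm(vehicle,2)|`;
4. in each replicate, the steeper of the vehicle/treatment pair is below
   −0.06 per °C.

Undefined melting points fail criterion 3; they are never imputed. The
sign-consistency reading of criterion 3 reproduces 9/9 and 19/19 passing
rows when applied to the printed melting temperatures of the published
bTPP and TPP target tables (all printed shifts are stabilising).

`passes_significance` additionally requires NPARC p < 0.05. The two flags
are kept separate deliberately: the published tables list every
criteria-passing protein but star only the significant subset, and under the
null the shift-consistency criterion alone passes ≈ 20% of proteins (it
compares three same-scale noise quantities), so the criteria-only call is a
candidate list, not an error-controlled decision. No multiple-testing
correction is applied to the calling rule; a Benjamini–Hochberg column is
available for reporting.

## NPARC

The null model fits one melting curve to all points of both conditions
(replicates pooled, up to 28 points); the alternative fits one curve per
condition. With RSS₀ and RSS₁ the residual sums of squares,

    F = ((RSS₀ − RSS₁)/3) / (RSS₁/(n − 6)).

Alternative fits warm-start from the null optimum, which guarantees
RSS₁ ≤ RSS₀ (monotone descent from the nested optimum) and treats observed
and permuted label assignments identically. Two p-values are available:

* `theoretical_f` — the F(3, n−6) tail. Known to be approximate for nested
  *nonlinear* fits; measured on simulated null proteomes it is
  anti-conservative (≈ 0.09–0.14 at nominal 0.05).
* `permutation` (default, 1000 permutations) — condition labels are
  shuffled within each temperature, independently per protein, and the
  observed F is ranked against the permuted ones with the add-one estimator
  `p = (1 + #{F_perm ≥ F_obs})/(1 + N)`.

Degenerate perfect fits (both RSS zero, e.g. zero-noise identical
conditions) report F = 0, p = 1; a non-convergent alternative fit reports
p = 1 with a flag.

### Amplitude correction for ratio-normalised fold changes

Fold changes computed as `abundance(T)/abundance(T_min)` all share the
reference measurement's multiplicative error, so the points of one
experiment are mutually correlated. Because the observed condition grouping
coincides with experiment boundaries while within-temperature permutations
break them, this correlation makes the raw permutation test strongly
anti-conservative (≈ 0.12 at nominal 0.05 on simulated null proteomes — the
same pseudo-replication that afflicts the theoretical F). Before testing,
the package therefore estimates one multiplicative amplitude per experiment
per protein — alternating least squares between a shared fitted curve and
per-experiment scales, a label-independent operation — and divides it out of
the non-reference points. The reference points (identically 1, noise-free)
are left untouched. After correction the residual noise is approximately
independent across points and the permutation test is calibrated (measured
0.037–0.05 at nominal 0.05). The correction is applied identically before
observed and permuted statistics, preserving permutation validity, and can
be disabled (`amplitude_correction=False`).

Measured agreement between the two methods on 200 simulated null proteins is
Spearman ρ ≈ 0.8: the permutation p is a rank within each protein's own
null distribution, while the F-to-p map is shared across proteins whose null
distributions differ, which caps the attainable rank correlation.

## Normalization

Systematic per-experiment distortions are corrected jointly: proteins with
complete profiles whose fold changes fall inside per-temperature windows in
every experiment (defaults FC(52) ∈ [0.4, 0.6], FC(62) ∈ [0, 0.3],
FC(67) ∈ [0, 0.2] — the published 10-temperature window positions transposed
onto the 7-point ladder; configurable) form the normalization set. Each
experiment's median fold-change curve over that set is fitted; the
experiment with the best R² is the reference. With `g(T)` the reference
fitted curve rescaled to equal 1 at `T_min`, the correction factor is
`factor(e, T) = g(T)/median(e, T)`, which is exactly 1 at the reference
temperature (median fold changes there are exactly 1). By construction the
post-normalization median curves of all experiments coincide with `g` to
machine precision at every temperature, the between-experiment spread of
median curves collapses, and renormalising already-normalised data yields
factors within 1% of unity. Normalization can be disabled for
pre-normalised input.

## Synthetic-data generator

The generator emulates a label-free, two-condition (vehicle/compound),
two-replicate, 7-temperature study.

Per protein it draws: melting point `Tm ~ Normal(50, 4)` °C truncated to the
gradient span; `plateau ~ Uniform(0, 0.25)`; the at-Tm slope magnitude
`~ Uniform(0.065, 0.13)` per °C, from which the steepness constant is solved
as `a = 2·s·Tm²·(1−plateau)/(0.5−plateau)` (giving `a ≈ 450–2400`). The
slope-based parameterisation makes every simulated curve steep enough to
clear the −0.06 criterion by construction, matching the observation that the
published analysis retains mostly steep melters; an `a`-range draw of
400–800 would instead leave most curves shallower than the criterion.
Exactly `round(n_proteins × target_fraction)` proteins are targets with a
stabilising shift `ΔTm ~ Uniform(2, 6)` °C by default (validation scenarios
pin it to 4 °C). Baseline abundances are log-normal (geometric mean 10⁶,
1.0 decades sd); any positive scale works since the analysis uses fold
changes. Measurement noise is multiplicative log-normal with mean 1 and
coefficient of variation `noise_cv` (default 0.05, typical of label-free
MS1 quantification); measurements drop out independently with probability
`missing_rate` (default 0.05). All draws flow from a single seed;
identical configuration and seed give byte-identical tables.

### The microsomal confound (TPP mode)

In TPP mode a per-protein `vesicle_fraction` (default Uniform(0.2, 0.8))
of the signal resides in membrane vesicles. The observed signal is the
convex mixture

    signal(T) = baseline · [(1 − vf) · f(T) + vf · carryover(T)],

where `carryover(T) = 1 − 1/(1 + exp((T − T50)/w))` is the fraction of
vesicular material escaping the post-heating sedimentation — increasing in
temperature because hotter incubations leave smaller vesicles that need a
larger sedimentation force. The logistic form is the simplest bounded
monotone choice. Defaults `T50 = 70 °C`, `w = 5 °C` were calibrated once to
the qualitative published record: the aggregate TPP-mode solubility signal
is bimodal (drops with melting, then rises with carryover) while melting
points remain estimable for the large majority of proteins — as they must
be, since the published vesicle-containing (TPP-arm) target table reports
four fitted melting temperatures per protein. (A lower `T50` of 55 °C makes
the soluble fraction never cross half its reference value, contradicting
that record.)
Additionally the membrane pool sequesters part of the compound: targets
express only `ΔTm·(1 − sequestration)` (default sequestration 0.5). In
simulation this halves the fitted shifts — the measured TPP/bTPP fitted-shift
ratio is ≈ 0.49 — reproducing the mechanism by which the vesicle-containing
protocol attenuates and distorts target signals. bTPP mode sets every
vesicle fraction to zero and reduces exactly to the pure sigmoid.

What the generator does *not* emulate: peptide-level sampling and
identification, intensity-dependent missingness (dropout is uniform),
between-replicate biological variation in Tm, correlated co-complex melting,
and any real distribution of vesicle association across protein classes.
Passing the recovery and calibration suites therefore demonstrates
correctness of the statistical machinery under the stated noise model, not
performance on any particular real dataset.

## Validation scenarios and problem sizes

The acceptance suite (`tests/test_acceptance.py`) recomputes:

* shift-criterion consistency on both published target tables (9/9, 19/19);
* closed-form Tm vs bisection on 1000 random parameter sets (≤ 10⁻⁶ °C);
* noiseless 7-point recovery of Tm on 500 random curves (≤ 0.05 °C, 100% of
  converging fits);
* permutation-NPARC null calibration on a 2000-protein null proteome
  (fraction p < 0.05 within [0.02, 0.09]);
* power/recovery at 1000 proteins, 10% targets, ΔTm = 4 °C, 5% noise
  (sensitivity ≥ 0.7, false positives ≤ 2%, median shift error ≤ 1 °C);
* normalization exactness and spread reduction under injected
  per-experiment distortions;
* the confound-model contrasts above at 200 proteins.

These sizes keep the full suite within a routine desktop run while leaving
each statistical check adequately powered.

## Known limitations

* The Tm of proteins melting near the reference temperature is biased by
  ratio normalisation itself: when `f(T_min)` is materially below 1, fold
  changes are inflated by `1/f(T_min)` and the fitted curve compromises.
  At zero noise the median recovery error through the full pipeline is
  < 0.01 °C, but proteins with true Tm within ~5 °C of the reference can be
  off by several tenths. This affects any analysis normalising to the lowest
  temperature, not just this implementation.
* The theoretical F method is provided for speed and cross-checking but is
  anti-conservative; the permutation method is the one whose error rate is
  controlled.
* With two replicates per condition, experiment-level (rather than
  point-level) resampling is impossible; the amplitude correction removes
  the dominant experiment-level correlation, but residual model misfit is
  attributed to noise.
* The normalization windows for the 7-temperature ladder are a declared
  convention (the published analysis adjusted its windows without printing
  them) and should be revisited for gradients with different coverage.
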