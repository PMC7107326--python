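# Methods

## The Regulation Index

Closed-chamber respirometry yields, per individual, paired observations of
dissolved oxygen (DO, % air saturation) and mass-specific oxygen consumption
MO₂ (mL O₂ h⁻¹ g wet weight⁻¹) as the animal draws its chamber down. The RI
locates that response between two idealized strategies by area, over the
*observed* oxygen range [DO_lo, DO_hi]:

- A_c = ∫ curve, where the curve is a natural cubic interpolating spline
  through the (DO, MO₂) points (duplicate DO values mean-aggregated);
- A_f = area under the perfect-conformity line: through (0, 0) and
  (DO_hi, curve(DO_hi)). Anchoring at the curve's normoxic value (not the
  maximum) makes the reference "a conformer with the same normoxic rate";
- A_r = area under the horizontal perfect-regulation line at the maximum of
  the fitted curve, located on a dense grid (default 512 points) so an
  interior peak is found, not just an endpoint.

RI = (A_c − A_f)/(A_r − A_f) when A_c ≥ A_f; otherwise the response sits
below conformity and RI = (A_c − A_f)/A_f, which reaches −1 when respiration
has collapsed to zero over the range. Both branches vanish on the conformity
line, so RI is continuous in the data; values are clamped to [−1, 1] with a
logged warning if spline overshoot carries them outside. When the curve
crosses the conformity line the sign of the *net* area decides the branch
and the result is flagged `branch="mixed"`; the net-area rule is the only
choice that keeps RI continuous as a crossing profile is perturbed.

Two deliberate scope restrictions: integration never extrapolates beyond
the observed range (an interpolating spline is untrustworthy outside its
knots, even though the conformity line is anchored at the origin), and no
parametric response model is fitted or selected — the index is a property of
the data, not of a model choice.

### Numerical choices

- Quadrature: adaptive Gauss–Kronrod with a purely relative tolerance
  (1e-10), so the integral — and hence RI — is equivariant under rescaling
  of the rate axis and of the oxygen axis. RI is invariant to both (checked
  to 1e-9 relative), which is what makes values comparable across units.
- Reference areas (a line and a constant) are closed-form.
- A profile needs ≥ 3 distinct oxygen values; a flat-zero profile, or a
  below-conformity profile whose conformity area is itself zero, has no
  defined RI and raises a degenerate-geometry error rather than returning a
  number.
- Optional lowess pre-smoothing (span 0.75 by default) before spline
  interpolation. This matters under measurement noise: the regulation level
  is a *maximum*, so an interpolating spline through noisy points inflates
  A_r and biases RI toward 0 for strong regulators (about −0.2 at 5 % rate
  noise). Smoothing first removes most of that attenuation; it is kept
  off by default for noise-free or pre-averaged data and enabled in the
  noisy-data analyses here.

## Preprocessing model

Traces are % air saturation vs time. The first 30 min (configurable) are
discarded as chamber acclimation. Rates come from sliding
ordinary-least-squares slopes (default 5-min window, half-window step) — the
window parameters are exposed because point-rate derivation from 15–30 s
samples is a choice, not a given. Background (bacterial) oxygen demand is
subtracted as a time-interpolated mean of blank-chamber slopes (blanks and
animals desaturate at different speeds, so correction is done in the time
domain); corrected slopes are capped at zero from above and negative rates
floored at zero, since a chamber cannot produce oxygen and the RI geometry
assumes MO₂ ≥ 0. Slopes convert to mL O₂ h⁻¹ g⁻¹ via the chamber volume and
the oxygen solubility of seawater (Benson–Krause coefficients in the
García–Gordon combined fit; vapour-pressure-corrected partial pressures for
kPa conversions). Dry weights convert to wet only through configured
coefficients (ratio, linear or log-linear form) with their provenance
recorded — no conversion constant is built in.

QC: a profile is flagged unless its oxygen dropped to ≤ 50 % of the start
value (configurable). The test is a pure ratio, hence unit-invariant.
Failing profiles are carried through with `qc_pass=False` and excluded from
RI statistics, never silently dropped.

## Classification and group statistics

Per species × temperature group: median, Q1, Q3 of individual RI by
linear-interpolation quantiles (the default convention of standard
statistical environments, recorded in the rule trace). Strategy clauses, in
precedence order: metabolic suppression (median, Q1, Q3 all < 0); high
oxyregulation (0.5 ≤ median < 1 and Q1 > 0.25 or Q3 > 0.75); low
oxyregulation (0.25 < median < 0.5); conformity/regulation (0 < median <
0.5, Q1 < 0, Q3 > 0.25); conformity (|median| ≤ 0.25, Q1 < 0, Q3 > 0).
"Median ≈ 0" is operationalized as |median| ≤ 0.25, the only reading
consistent with the published low-oxyregulation lower bound; the hybrid
clause precedes plain conformity so that a group with median exactly 0.25
and a wide positive quartile is labelled conformity/regulation, matching
published usage. The published verbal clauses are not mutually consistent
for borderline medians (0.48–0.49 with Q1 > 0.25 appears as "high
oxyregulation"), so a `table2_compat` mode rounds the median to one decimal
before the high-oxyregulation clause; `literal` mode applies the clauses as
printed. Neither mode guesses a single "intended" rule; the fired clause is
always recorded.

Groups are compared with the tie-corrected Kruskal–Wallis H (chi-square
approximation; the group sizes involved, 2–22, are conventional for it) and
the Siegel–Castellan multiple-comparison procedure: pair (i, j) differs at
family level α when |R̄_i − R̄_j| > z_{1−α/(k(k−1))} √(N(N+1)/12 (1/n_i +
1/n_j)). A compact letter display is built by greedy insert-absorb; letters
are a presentation of the significance matrix, and the pairwise table is
always emitted alongside.

## The simulator and what passing tests show

Archetypes (power-law, Michaelis saturation, breakpoint regulator,
suppressor with a linear suppression ramp, default 10 % air saturation wide
— suppression engages progressively, not as a step) have closed-form RI via
piecewise integration, over any oxygen sub-interval. That range argument
matters: a chamber run never reaches 0 % air saturation, and the RI of a
truncated range differs slightly from the full-range value (for a
breakpoint regulator with P = 25 % measured over [2, 97] %, by about +0.03),
so pipeline-recovery tests compare against the oracle evaluated on the
realized range, and full-range comparisons use a ±0.05 band.

Chamber traces are forward-Euler integrations of dC/dt = −R(C)·W/V at the
sensor sampling interval (15 s default) — adequate because the response is
smooth and desaturation takes hours; a halving-step convergence check and a
mass-balance check (oxygen removed = time-integral of the rate to 1 %) are
part of the suite. Sensor noise is Gaussian on the oxygen *readings* (where
it physically arises), background drift is a constant blank slope, and all
randomness descends from a single seed through spawned generators.

The simulator emulates: monotone drawdown from ~100 % saturation, 15–30 s
sampling, realistic chamber/animal scales (20 mL, tens of mg, rates a few
tenths of mL O₂ h⁻¹ g⁻¹), blanks, and per-individual rate variability. It
does **not** emulate animal activity bursts, sensor drift/recalibration
error, temperature fluctuation, or non-stationary bacterial growth — so
passing recovery tests validate the estimator under its stated measurement
model, not robustness to every field artifact.

Simulation sizes in the test suite (n = 20 individuals per group, 60-point
profiles, 10⁴ null replicates for the type-I check) were chosen as the
smallest designs at which the asymptotics being checked are expected to
hold; the reproduction-mode fixture mirrors the motivating study's shape
(141 individuals in 17 species × temperature groups) with synthetic
archetypes, since the deposited per-individual data sets are not bundled
here.

## Known limitations

- Closed chambers only; intermittent-flow (flush-cycle) designs are out of
  scope.
- No P_crit estimation and no parametric model competition, by design.
- RI under noise is attenuated for strong regulators unless pre-smoothing
  is enabled (see above); with smoothing the residual bias at 5 % rate
  noise is within ±0.05.
- The negative branch normalizes by the conformity area over the observed
  range; if a deposited analysis normalized over [0, DO_hi] instead, values
  below 0 would shrink toward 0 by a factor (DO_hi²−DO_lo²)/DO_hi² — the
  bounds are kept identical to the positive branch here.
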