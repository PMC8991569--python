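# Methods

## Screening model

The Plackett–Burman stage treats the response (melanin yield, g/L) as
additive in the 11 factors with no interactions — the standard working
assumption of a saturated two-level screen. Supported run counts are
8, 12, 16 and 20, built from the classical cyclic first-row generators
(N−1 cyclic shifts plus the all-minus row), truncated to the requested
number of factors. Any number of all-center runs can be appended; they
support a curvature glance but are **excluded from effect and t
computations**, since a 0-level run belongs to neither the high nor the
low group of the ± contrast. On the reference table, the printed
effects are only reproduced with the center trial excluded.

The main effect is the high-group mean minus the low-group mean. Its
t statistic is the equal-variance unpaired two-sample t (pooled
variance, df = n − 2 with equal halves), computed on the single
response per run — for the 12-run screen, 6-vs-6 groups with df = 10,
which reproduces the published 2.53 and 2.47 exactly. Significance is
read off an inclusive-boundary critical-value ladder; the default
ladder is (1%: 3.70, 5%: 2.446, 10%: 1.94, 20%: 1.372), the two-tailed
df = 10 values used by the reference study, and it is a plain
configurable table. Factors are ranked by |t| (ties by |effect|, then
input order); the effect sign decides the direction the follow-up
design explores.

Degenerate case: a factor whose both groups are constant gets t = ±∞
with a warning when its effect is nonzero, t = 0 otherwise.

## Response-surface model

The Box–Behnken design for k = 3..5 factors places runs at the edge
midpoints of the factor cube (every pair of factors at ±1, all others
at 0) plus replicated center runs. All modelling is on coded variables,
where the design's orthogonality makes the linear and interaction
coefficients simple contrasts; natural-unit values are derived only for
reporting. The full 10-term (k = 3) second-order polynomial is fitted
by ordinary least squares with no term elimination. R² = 1 − SSE/SST
about the response mean. The fit cross-checks its linear and
interaction coefficients against their closed-form contrasts whenever
the design passes the BB structure check, and refuses rank-deficient
model matrices, naming the collinear columns.

On the shipped 15-run table only the intercept (the center-run mean)
and the CaCl₂×trace interaction are exactly recoverable: the table's
responses are printed to 2 decimals while the original fit used
unrounded data, so the remaining coefficients and R² carry a ±0.03
reproduction tolerance. The built-in comparison report prints this
caveat rather than silently absorbing it.

## Maximization over the design cube

A quadratic restricted to a face of [−1, 1]^k is again a quadratic, and
its maximum over the face is either an interior stationary point or on
the face's boundary — itself a lower-dimensional face. The optimizer
therefore enumerates all 3^k faces (each subset of coordinates fixed at
±1), solves each restricted stationary system, keeps interior
solutions, always includes the 2^k corners, and returns the best
candidate. This is exact: no starting point, step size or convergence
tolerance exists. Singular restricted Hessians contribute no interior
candidate and are covered by smaller faces (a linear restriction's
maximum is on the boundary). k ≤ 5 keeps the enumeration trivial
(≤ 243 faces). Tests verify the result against a 0.01-step grid and a
multistart L-BFGS-B solver.

Coordinates of the optimum are flagged as boundary-clamped when they
sit at ±1 — on the reference polynomial all three do, meaning the true
optimum may lie outside the explored region (a known limitation of the
original experiment, not of the solver).

## Synthetic data

The generator emulates exactly the structure the analysis assumes:

* **PB**: yᵣ = μ + Σⱼ (Eⱼ/2)·xᵣⱼ + εᵣ, so factor j's expected main
  effect is exactly Eⱼ;
* **BB**: the chosen quadratic evaluated at the coded runs plus εᵣ;

with εᵣ i.i.d. N(0, σ²) by default (a variance-matched Laplace option
exists for robustness checks). Defaults: baseline μ = 0.36 g/L (the
grand mean of the reference screen, putting synthetic yields on a
realistic scale) and σ = 0.05 g/L, a run-to-run repeatability typical
of duplicate-flask pigment assays and the value used throughout the
Monte-Carlo suites. Responses are clamped at zero only when the
`nonnegative` flag is set (off by default, so estimator checks stay
unbiased). What passing these tests does **not** show: real
fermentation data can be heteroscedastic, non-Gaussian, and carry
factor interactions the screening model omits; the generator makes
none of these.

Monte-Carlo sizes: 500 replicates for both the BB coefficient-recovery
and the PB ranking-power checks, matching the precision needed to
resolve the ≥99% / ≥95% pass criteria. Coefficient recovery is judged
per coefficient against 3 standard errors computed from the **known**
simulation σ via σ²(MᵀM)⁻¹ (normal coverage 99.73%); residual-based
SEs would have only 5 error df on the 15-run design and a t₅ 3-SE
coverage near 97%, which would misstate the estimator's quality.

## Numerical choices

* Coded levels are stored as exact small integers {−1, 0, +1}; balance
  and orthogonality checks are integer arithmetic, immune to float
  equality pitfalls.
* Natural three-level CSV files must use each factor's exact
  low/center/high values (relative tolerance 1e−9); anything else is a
  reported error with its row number, not a silent nearest-level snap.
* Significance boundaries are inclusive: |t| exactly at a critical
  value earns that level.
* Stationary-point candidates within 1e−12 of the cube boundary are
  accepted and clipped; the boundary flag uses the same tolerance.
* Fold-changes and report values are rounded only at presentation.

## Design choices

* The reference tables are shipped verbatim as fixtures and every
  reproduction test runs on the printed matrix, not on a generated
  design; the generators (canonical row order, centers last) serve
  reuse, and the published run order of the BB table is recorded as an
  explicit permutation of the canonical order.
* Culture volume is an ordinary numeric factor in "mL per 500-mL
  flask" units.
* The wet-lab yields 0.938, 0.646, 0.876 and 0.509 g/L are inputs to
  the verification report, never recomputed claims.
* Out of scope: fold-over PB designs, central-composite/D-optimal
  designs, ANOVA decomposition, Lenth's method, canonical/ridge
  analysis, desirability functions, confidence intervals on the
  optimum, and any mechanistic growth-kinetics simulation.

## Limitations

* The screen estimates main effects only; aliasing with two-factor
  interactions is the price of 12 runs for 11 factors.
* The quadratic is trusted only inside the coded cube; the reference
  optimum sits on its boundary, so extrapolation beyond ±1 is
  unsupported by construction.
* With 15 runs and 10 terms the fit has 5 residual df; R² is reported
  without adjustment, as in the original analysis.
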