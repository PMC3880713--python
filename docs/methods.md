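# Methods

## Model and procedure

The package implements the standard response-surface-methodology (RSM)
workflow for a k-factor bioprocess, specialized to the packaged five-factor
lipase fermentation study and reusable for any continuous-factor box.

1. **Design.** Factors are coded by `x = (natural − center) / half_range`,
   so each design range maps onto [−1, +1]. The design generator produces
   face-centred central-composite designs (α = 1): a two-level factorial
   portion (full `2^k`, or the principal resolution-V half fraction with
   defining relation `x_k = x_1⋯x_(k−1)`), 2k axial points on the face
   centres, and replicated centre runs. Every coded level is −1, 0 or +1,
   which is what makes a three-level CCD support the full quadratic. For
   k = 5 the half-fraction design with 7 centre runs has 16 + 10 + 7 = 33
   runs, the layout of the packaged study table.

2. **Fit.** The full second-order polynomial (1 + 2k + k(k−1)/2 = 21 terms
   for k = 5) is fit by ordinary least squares in coded units, via a
   QR-based solve (`numpy.linalg.lstsq`); explicit normal-equations
   inversion appears only as an independent oracle in the test suite.
   Standard errors come from `σ̂²(XᵀX)⁻¹`, p-values are two-sided t on the
   residual degrees of freedom, with no multiple-testing correction (the
   conventional presentation for designed experiments of this size).
   Natural-unit coefficients are a derived view; the coded fit is primary
   because design-unit coefficients are directly comparable across factors.

3. **ANOVA.** Sequential (type-I) sums of squares add term blocks in the
   order Linear → Square → Interaction (the convention of mainstream DoE
   software); adjusted SS is the SS drop when a block is removed from the
   full model. The residual is split into pure error — within-group squared
   deviations over runs with identical coded settings — and lack-of-fit.
   Block F statistics are tested against the full-model residual mean
   square; lack-of-fit against pure error. With no replicated runs the
   lack-of-fit rows are reported as undefined (NaN), never as zero.

4. **Diagnostics.** Externally (R-) studentized residuals use the
   leave-one-out variance `s²₍₋ᵢ₎ = (SSE − eᵢ²/(1−hᵢ))/(df−1)`; runs with
   leverage numerically 1 are reported as missing, and the LOO variance is
   clamped at zero to keep near-perfect fits from producing spurious NaNs
   via rounding.

5. **Optimization.** The fitted (or published) surface is maximized over
   the natural-unit factor box by a generational binary-coded GA. Each
   variable occupies `bits_per_variable` bits (default 10, so a 50-bit
   chromosome for k = 5), decoded most-significant-bit-first by linear
   mapping of the slice's integer value onto [low, high]; decoded points
   therefore can never leave the box. Maximization is posed as
   minimization through a duality transform. Every GA result is
   cross-checked against `certified_box_max`, which enumerates the
   stationary points of the quadratic restricted to each of the 3^k faces
   of the coded box (each coordinate fixed at −1, at +1, or free; the free
   block solves the reduced linear system) — the box maximum of a quadratic
   must be such a point, so the certificate is exact and upper-bounds any
   stochastic search. A grid-search oracle with one refinement pass is also
   provided as an assumption-free cross-check.

## GA parameters

| parameter | default | meaning |
|---|---|---|
| `bits_per_variable` | 10 | resolution ≈ range/1023 per variable |
| `population_size` | 210 | strings per generation |
| `max_generations` | 815 | fixed-budget termination, no early stop |
| `crossover_prob` (Pc) | 0.5 | pair-level probability of uniform crossover |
| `mutation_prob` (Pm) | 0.0015 | per-bit flip probability (≈ 0.075 flips/string) |
| `tournament_size` | 2 | selection pressure: fitter of 2 wins w.p. 0.75 |
| `elitism` | on | best-ever copied into each generation |
| `transform` | negate | duality transform (alternative: 1/(1+f)) |

The defaults are the tuned settings reported by the original study. Design
choices the study left open, resolved here as package defaults:

- **Duality transform.** Negation is the default; `1/(1+f)` is available
  for comparison. Both are strictly decreasing, so the fitness argmin is
  the objective argmax; negation needs no domain restriction.
- **"Uniform crossover probability of 0.5"** is read as a pair-level
  crossover probability Pc = 0.5 with the per-bit swap probability fixed at
  1/2; the alternative reading (every pair mixed, 0.5 per bit) is available
  via `per_bit_crossover=True`.
- **Elitism** defaults to on, which makes the per-generation best history
  monotone (asserted in tests); a flag disables it for a plain generational
  GA.
- **Seeding.** One `numpy` generator per run; sweep replicates derive
  child seeds from (base seed, value index, replicate index) via spawned
  `SeedSequence`s, so parametric studies are reproducible run-to-run.

With these settings the GA reliably reaches the certified maximum of the
packaged quadratic to within the 10-bit discretization gap (observed
spread over 40 seeds: 6.4573–6.4621 U/mL against a certificate of
6.46207 U/mL); occasional premature convergence at the study's low
mutation rate is why results are best quoted as the best over a few seeds.

## The packaged study fixture, and its internal inconsistency

The 33-run design/response table ships verbatim as printed in the original
study, including its printed predictions and R-studentized residuals as
reference columns (`load_study_fixture()`; a 32-row variant dropping the
last duplicated centre row matches the published ANOVA total df of 31 —
the source tables are ambiguous between the two, so both are exposed).

Refitting this table does **not** reproduce the published coefficient
table, R² = 96.6 %, or the published ANOVA. This is not a numerical or
convention issue; the printed table is provably inconsistent with the
printed model:

- The printed predicted column has SSE = 0.732 against the printed
  responses, while the OLS minimum on the printed 33×21 model matrix is
  1.844. OLS minimizes SSE over all linear combinations of those columns,
  and the printed model is such a combination, so no fit of the printed
  table can yield the printed predictions.
- Rows printed with identical levels carry different printed predictions
  (3.528 / 3.522 / 3.492 at the centre point), so the printed predictions
  cannot be any function of the printed levels.
- Several printed predictions instead equal the published polynomial
  evaluated at *other* design points (e.g. a row printed at the centre
  whose prediction matches the pH-axial point): the level columns of some
  rows were evidently scrambled or mistyped in print relative to the
  design actually analysed.

Following the package's fixture policy, the table is never "repaired" or
regenerated: the refit is the arbiter, and it honestly reports R² = 91.0 %,
adjusted R² = 76.1 %, regression F = 6.09, lack-of-fit F = 8.14 (the
significant lack-of-fit is exactly what row scrambling produces). The
published coefficient set itself is retained as `published_surface()` — it
is internally coherent (it reproduces the printed predictions at the
unscrambled rows, e.g. 3.761 at run 4) and is the correct object for the
optimization stage, which the original study ran on that model. Small
print-level disagreements also exist between the published equation and
the published coefficient table (e.g. −0.28062 vs −0.287 for the
temperature×inoculum interaction); the equation's higher-precision values
are the ones packaged.

## Synthetic data

`rsmga.simulate` draws `y = truth(x) + ε` with i.i.d. homoscedastic
Gaussian ε on any design — exactly the error model the OLS/ANOVA machinery
assumes, with the published coefficient set as the default truth surface.
It emulates the statistical structure of a CCD study (quadratic mean,
constant variance, optional replicate runs); it does not emulate
fermentation kinetics, non-Gaussian or heteroscedastic error, run-order
drift, or model misspecification, so passing recovery tests validate the
estimator under its own assumptions, not the adequacy of a quadratic for
any real broth. The recovery experiment (default 500 replicates on the
33-run design at σ = 0.248, the residual scale of the published fit)
vectorizes all OLS solves against one factorized design matrix and checks
per-coefficient bias, RMSE and 95 % t-interval coverage.

## Numerical choices and problem sizes

- Coding round-trips are exact to 1e−12 relative; replicate detection uses
  exact coded-level equality by default (integer-coded designs), with an
  optional tolerance for continuous synthetic designs.
- Rank deficiency is reported before fitting, naming the collinear
  columns via the QR diagonal.
- Face enumeration solves at most 3^5 = 243 linear systems of size ≤ 5;
  singular faces (flat directions) are skipped — their stationary values,
  when attained, are recovered on lower-dimensional faces.
- Test-suite problem sizes: designs of 9–33 runs, GA populations of
  40–210 with 30–815 generations, 400–500 Monte-Carlo replicates; the full
  suite runs in a few seconds on one CPU.

## Known limitations

- Only face-centred (α = 1) CCDs are generated; rotatable designs,
  Box-Behnken layouts, blocking and deeper fractions are out of scope.
- No model reduction (stepwise/term dropping), transforms of the response,
  or mixed models.
- The GA is single-objective, fixed-budget, bitstring-coded; no adaptive
  rates or real-coded variants.
- Surface grids are exported as tidy CSV for external plotting; no 3-D
  rendering is included.
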