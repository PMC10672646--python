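# Methods

## Model

The package models an NSCLC organoid's cellular ecosystem as four coupled
subpopulations — cancer cells N (PD-L1+), M2-polarized macrophages M2
(CD206+), cancer-associated fibroblasts CAF (αSMA+), and cytotoxic
T cells Tc (CD8+) — with mass-action interactions:

    dN/dt   = γ(1 − N/K)N + q₁·N·M2 + q₂·N·CAF − k·Tc·N
    dM2/dt  = q₃·M2·N + q₄·M2·CAF − δ_M2·M2
    dCAF/dt = q₅·CAF·N + q₆·CAF·M2 − δ_CAF·CAF
    dTc/dt  = q₇·Tc·N − q₈·Tc·M2 − q₉·Tc·CAF − δ_Tc·Tc

Assumptions: well-mixed populations (no spatial structure), deterministic
dynamics, bilinear stimulation/suppression, logistic self-limitation of
the cancer compartment only, and first-order death of the immune/stromal
compartments. Every term carries its own state factor, so the origin is
an equilibrium and the nonnegative orthant is forward-invariant.

### Fixed parameters (defaults, literature-adjusted values)

| parameter | meaning | default | units |
|---|---|---|---|
| γ | cancer-cell growth rate | 0.05 | day⁻¹ |
| K | cancer-cell carrying capacity | 10⁶ | state units |
| q₁ | M2 → cancer stimulation | 4×10⁻⁵ | day⁻¹·unit⁻¹ |
| q₃ | cancer → M2 stimulation | 4×10⁻⁸ | day⁻¹·unit⁻¹ |
| δ_M2 | M2 death rate | 0.2 | day⁻¹ |
| k | per-Tc cancer kill rate | 10⁻³ | day⁻¹·unit⁻¹ |
| δ_Tc | Tc death rate | 0.1 | day⁻¹ |

K is treated as an abundance and q₁, q₃, k as per-cell rates so that every
term of the system has units of abundance per day; the sources print all
of them as day⁻¹, which is dimensionally untenable for K in particular.

### State scale and covariance

The model is covariant under rescaling of the state: if z(t) solves the
system, then c·z(t) solves it with K↦cK and every per-cell rate
(q₁…q₉, k) divided by c, while the pure rates (γ, δ's) are unchanged.
The published magnitudes of the estimated rates (q₂ up to 5×10⁻³
unit⁻¹day⁻¹, q₇ ≈ 10⁻³ unit⁻¹day⁻¹) are therefore only dynamically
plausible for states of order 10–100: applied to raw cell counts in the
tens of thousands they produce rate products of several per day and
finite-time blow-up inside the 21-day culture window (we verified this
numerically). States of order 10–100 are exactly the percentage scale of
a flow-cytometry readout, so the package's "abundance units" are
percent-of-seeded-total: one unit = `total_cells / 100` cells (500 cells
for the default 50,000-cell gel dome). The reader exposes this as
`cells_per_unit`; count tables from 50,000-cell samples are typically
analyzed with `cells_per_unit=500`. Fitting on raw counts is possible but
then the per-cell defaults must be rescaled accordingly.

## Parameter estimation

Eight rates Q = (q₂, q₄, q₅, q₆, δ_CAF, q₇, q₈, q₉) enter the equations
linearly with measured cofactors. For each interval between measurement
days the derivative is collocated by the difference quotient
(Z_{i+1} − Z_i)/Δt = F(Z*), with the mid-interval state Z* interpolated
per component: harmonic mean 2ab/(a+b) when both endpoints are strictly
positive, arithmetic mean (a+b)/2 otherwise ("auto" dispatch; either
formula can be forced globally for sensitivity analysis). Known terms
move to the right-hand side, producing four rows per interval in an
8-column design whose blocks are: N-equation → q₂; M2 → q₄;
CAF → (q₅, q₆, δ_CAF); Tc → (q₇, q₈, q₉). A fit needs at least two
intervals (8 rows); rows are unweighted (ordinary least squares).

Three solvers are provided: `normal_equations` (the textbook
(AᵀA)⁻¹AᵀB, refusing condition numbers beyond 10¹²), `pseudoinverse`
(minimum-norm least squares), and the default `nonnegative`
(scipy NNLS), which enforces the modeling constraint that all rates are
nonnegative instead of clipping after the fact. Diagnostics report the
overall rank, per-block ranks and condition numbers; a lone
three-time-point patient leaves the CAF and Tc blocks with 2 rows for 3
unknowns, which is flagged as rank-deficient rather than silently
resolved. δ_CAF is estimated by default but can be fixed
(`fix_delta_caf`), since external evidence often pins it near 0.1 day⁻¹.
Pooling is either `pooled` (one shared Q across patients, the default —
appropriate when the cohort is assumed to share interaction biology) or
`per_patient`.

### Discretization bias

The one-midpoint collocation is second-order: on an exact trajectory the
residual of the true rates scales as Δt². The bias this leaves in the
estimates at the study's 3-day spacing is a few percent for strongly
informed components and overwhelms components whose terms are small
against their equation's dominant decay (e.g. q₄·M2·CAF against
δ_M2·M2). Halving the spacing reduces every recovery error by ~4×; the
test suite demonstrates sub-1% recovery of all eight rates at 0.125-day
spacing. Practical consequence: with day-7/14/21 designs, point estimates
of the weakly informed rates should be read as order-of-magnitude.

### Identifiability

A component is reported as *identifiable* at a given noise level if its
first-order propagated relative standard error is ≤ 25% — computed by
finite-differencing the unconstrained least-squares solution with respect
to every measured abundance and accumulating independent multiplicative
noise contributions (`estimation.parameter_uncertainty`). With four
patients, eight measurement days and 5% noise, the identifiable set is
typically {q₂, q₇} (sometimes plus δ_CAF): the rates whose terms dominate
their equations.

## Simulation

Forward integration uses SciPy's LSODA (adaptive, stiffness-switching)
with rtol 10⁻⁸ and atol 10⁻⁶ by default (both configurable; closed-form
comparisons over long horizons need atol below the decaying magnitudes).
Output grids are read from the dense interpolant, so refining the grid
never changes values at shared times. Integrator undershoot below zero is
clipped when smaller than 10⁻⁹ × the initial total abundance and is an
error otherwise. Composition fractions divide each compartment by the
four-compartment total (undefined, and an error, at an all-zero state).
Local extrema are interior grid points exceeding both neighbors, refined
by the vertex of the parabola through the three bracketing points;
candidates with prominence below 10⁻⁹ × the component's range are
ignored (round-off jitter on flat stretches), and endpoints are never
reported.

## Synthetic cohorts

The generator emulates the motivating study design: 16 patients by
default, measured on days 7, 14 and 21, seeded at 50,000 cells per
sample. One shared truth vector is drawn uniformly from the published
per-parameter ranges (q₂ ∈ [10⁻⁴, 5×10⁻³], q₄ ∈ [10⁻⁴, 10⁻³],
q₅ ∈ [0, 10⁻⁵], q₆ ∈ [10⁻⁵, 10⁻³], δ_CAF = 0.1, q₇ ∈ [9×10⁻⁴, 1.5×10⁻³],
q₈, q₉ ∈ [0, 10⁻⁵]); per-patient day-0 states are drawn uniformly from
cancer-dominant ranges (N ∈ [35, 55], M2, CAF ∈ [4, 10], Tc ∈ [2, 6]
abundance units — a PD-L1-dominant mix covering roughly half the seeded
cells, the remainder unlabeled). No correlation structure is imposed, as
none is reported. Trajectories are simulated exactly, read at the
measurement days, and each reading is multiplied by independent mean-one
lognormal noise with a configurable coefficient of variation (default
5%) — the positive, heteroscedastic error structure of cytometry
subpopulation counts. Everything is a pure function of the spec and its
seed (separate RNG streams for truth, initial states and noise).

What the generator does **not** emulate: cytometer-level artifacts
(spillover, gating error, doublets), double-labeled cells (e.g.
PD-L1+ macrophages inflating the cancer gate), day-to-day culture
drift, patient-to-patient parameter heterogeneity, and compositional
closure error (real percentages are of acquired events; the written
percentage layout renormalizes to the current four-compartment total).
Passing recovery tests therefore demonstrate the estimator's correctness
under the model's own assumptions, not robustness to these real-data
effects.

## Numerical and design choices

- Column order of the unknowns is fixed to (q₂, q₄, q₅, q₆, δ_CAF, q₇,
  q₈, q₉) everywhere; compartment order is (N, M2, CAF, Tc).
- Harmonic midpoints require strictly positive endpoints; "auto" falls
  back to arithmetic when either endpoint is zero.
- The difference scheme and solver never see NaN: inputs are validated on
  construction of the measurement series and linear system.
- Prediction anchors at each patient's earliest measured state and
  integrates forward; a prediction window extending outside the measured
  span triggers an explicit accuracy warning.
- The scheme-consistency and recovery analyses in `scripts/acceptance.py`
  use 4-patient cohorts, a 0–21-day horizon at 3-day spacing (8 time
  points), 100 noise replicates, 20 random 12×8 systems, and 10⁴ random
  midpoint pairs — sizes chosen so the whole script completes in seconds
  while keeping Monte-Carlo error well below the decision thresholds.

## Known limitations

- Point estimation only: no bootstrap or Bayesian uncertainty beyond the
  linearized standard errors used for identifiability.
- The collocation bias at 3-day spacing (above) caps noiseless recovery
  accuracy at the few-percent level for sparse designs.
- One midpoint per interval; no iterated or gradient-matching refinement.
- Four compartments, no immune-therapy terms, no stochastic dynamics.
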