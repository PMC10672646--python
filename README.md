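# organofit

Estimation of tumor-microenvironment interaction rates from sparse
flow-cytometry time courses of non-small-cell lung cancer (NSCLC)
patient-derived tumor organoids (PDTOs), and prediction of how the
organoid's cell composition evolves between measurement days.

It is written for computational and systems biologists who have
per-sample subpopulation measurements at a handful of time points
(e.g. days 7, 14 and 21 of organoid culture) and want a mechanistic,
interpretable forecast of the culture's cellular makeup.

## The model

Four interacting subpopulations are tracked, each identified by a
cytometry biomarker: cancer cells *N* (PD-L1+), M2-polarized
tumor-associated macrophages *M2* (CD206+), cancer-associated
fibroblasts *CAF* (αSMA+), and cytotoxic T cells *Tc* (CD8+):

    dN/dt   = γ(1 − N/K)N + q₁·N·M2 + q₂·N·CAF − k·Tc·N
    dM2/dt  = q₃·M2·N + q₄·M2·CAF − δ_M2·M2
    dCAF/dt = q₅·CAF·N + q₆·CAF·M2 − δ_CAF·CAF
    dTc/dt  = q₇·Tc·N − q₈·Tc·M2 − q₉·Tc·CAF − δ_Tc·Tc

Seven rates (γ, K, q₁, q₃, δ_M2, k, δ_Tc) are fixed from the literature.
The remaining eight — Q = (q₂, q₄, q₅, q₆, δ_CAF, q₇, q₈, q₉) — enter the
equations *linearly* with measurable cofactors. Collocating each
measurement interval with a difference quotient,

    (Z_{i+1} − Z_i)/(t_{i+1} − t_i) = F(Z_{i+1/2}),

with the mid-interval state interpolated per component (harmonic mean for
strictly positive endpoints, arithmetic otherwise), every interval yields
four linear rows, and the stacked overdetermined system **A**Q = **B**
(8 columns; ≥ 8 rows, i.e. ≥ 2 intervals) is solved by least squares —
by default non-negative least squares, since all rates are rates.
The fitted model is then integrated forward (adaptive, stiffness-switching
solver) from each patient's earliest measured state to forecast
composition fractions and detect interior extrema (e.g. a subpopulation
that rises and peaks between measurement days).

Everything is exposed both as plain functions (`assemble`, `solve`,
`fit`, `simulate`, …) and as a scikit-learn-style estimator,
`TumorCompositionModel`, with `fit`/`predict`, `get_params`/`set_params`
and trailing-underscore fitted attributes.

## Worked example

Generate a synthetic 4-patient cohort measured on days 7/14/21 with 5%
measurement noise and a known ground truth, then fit and predict:

    organofit synth --patients 4 --noise-cv 0.05 --seed 42 \
        --out cohort.csv --truth-out truth.json
    organofit predict --input cohort.csv --cells-per-unit 500 --out run --no-plots

(`--cells-per-unit 500` analyzes the 50,000-cell samples in
percent-of-seeded units, the scale the default literature rates are
calibrated for; the model is scale-covariant, see `docs/methods.md`.)

The run prints the parameter provenance log and writes a report bundle
(`params.json`, `summary.json`, `trajectories.csv`, `extrema.csv`,
`run.log`, per-patient plots). For this seed it reports

    fitted: {'delta_CAF': 0.105633, 'q2': 0.003795, 'q4': 0.0, 'q5': 0.0,
             'q6': 0.0, 'q7': 0.001519, 'q8': 0.0, 'q9': 0.0}
    truth : {'delta_CAF': 0.1, 'q2': 0.003892, 'q4': 0.000495, 'q5': 9e-06,
             'q6': 0.0007, 'q7': 0.001485, 'q8': 8e-06, 'q9': 8e-06}

Reading: the three rates this sparse design can identify — CAF→cancer
stimulation q₂, cancer→Tc stimulation q₇ and the CAF death rate δ_CAF —
are recovered within a few percent of the generating truth despite the
noise; the weakly-informed rates (q₄, q₅, q₆, q₈, q₉, whose terms are
small against their equations' dominant decay) are clamped to the
constraint boundary at zero rather than reported as spurious values.
`extrema.csv` lists interior turning points of each compartment inside
the day 7→14 prediction window, and `summary.json` carries the predicted
composition fractions (for patient P01 at day 14: 92.7% PD-L1+, 5.5%
CD8+, 1.4% αSMA+, 0.4% CD206+).

The same pipeline runs on real spreadsheets: CSV or Excel with columns
`patient_id, day, n_cells, m2_cells, caf_cells, tc_cells` (counts) or
`patient_id, day, pdl1_pct, cd206_pct, asma_pct, cd8_pct, total_cells`
(percentages, converted through the per-sample total on read).

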