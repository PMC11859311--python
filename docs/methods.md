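# Methods

This note records the mathematical model, numerical choices and default
parameters behind `skinperm`, together with the rationale for each decision.

## 1. Membrane transport model

The simulator treats percutaneous transport as one-dimensional diffusion
through a single homogeneous membrane (an idealised stratum corneum) of
thickness *h* (cm), diffusivity *D* (cm²/h) and vehicle/membrane partition
coefficient *K*, between an infinite-dose donor at constant concentration
*C* (µg/mL) and a perfect-sink receptor. Under these boundary conditions
(c(0, t) = K·C, c(h, t) = 0, c(x, 0) = 0) the cumulative amount permeated per
unit area is the classical time-lag series

Q(t) = K·h·C·[ D·t/h² − 1/6 − (2/π²) Σₙ₌₁^∞ ((−1)ⁿ/n²)·exp(−D·n²·π²·t/h²) ].

Derived quantities: steady-state flux J_ss = K·D·C/h, lag time
T_lag = h²/(6D), permeability coefficient P = J_ss/C.

**Series truncation.** Terms are added until the next term's magnitude
prefactor falls below 1e−12 relative to the leading scale, with a hard cap of
10 000 terms. At t ≥ T_lag/10 a handful of terms suffice; the cap only guards
pathological inputs (t → 0, where Q → 0 anyway).

**Assumptions (and what the generator does not emulate):** infinite dose
(donor depletion is not modelled), perfect sink (receptor back-pressure
neglected — justified because the draw-and-replace protocol keeps receptor
concentrations far below donor levels), homogeneous single-layer membrane
(no SC/epidermis bilayer, no appendageal shunts), constant D and K (no
concentration-dependent enhancer kinetics within a run; enhancement enters as
between-arm parameter changes), isothermal operation at the protocol
temperature (32 °C default).

## 2. Independent numerical oracle

To verify the series solution with mathematics that shares none of its code
path, `finite_difference_cumulative_amount` solves the same PDE by
Crank–Nicolson on 2 000 spatial nodes with Dirichlet boundaries, computes the
exit flux −D·∂c/∂x|ₓ₌ₕ with a second-order one-sided difference, and
integrates it by the trapezoid rule. The time step is set by
`n_steps_per_unit_tau = 80 000` steps per unit of dimensionless time
τ = D·t/h² (minimum 2 000 steps). This resolution was chosen by measured
convergence: at τ = 1/60 (one tenth of the lag time, the hardest point, where
Q is small and the series is stiff) the relative deviation is ≈5 × 10⁻⁴,
versus ≈3 × 10⁻³ at a quarter of that resolution. The two solutions agree to
better than 0.1% across a (D, h, K) grid spanning lag times from minutes to
hours.

## 3. Draw-and-replace sampling and its correction

The simulated protocol mirrors a Franz-cell run: at each sample time the
receptor (volume V = 4 mL) is mixed, a volume V_s = 2 mL is withdrawn and
replaced by fresh medium. The simulator keeps a truth ledger of pre-draw and
post-draw concentrations and cumulative removed mass. Between draws the
receptor gains mass A·(Q(tᵢ) − Q(tᵢ₋₁)) where A = 1.77 cm² is the diffusional
area.

The analysis layer applies the standard replacement correction

Qᵢ = ( V·Cᵢ + V_s·Σ_{j<i} Cⱼ ) / A,

which inverts the dilution *exactly* (algebraically, V·Cᵢ equals the mass
present minus everything previously removed), and the test suite holds the
noiseless round trip to rtol 1e−12.

A consequence worth noting: corrected Q is guaranteed non-decreasing only
when each concentration satisfies Cᵢ ≥ (1 − V_s/V)·Cᵢ₋₁ — i.e. it is at least
the post-draw residue of the previous sample. Every physical experiment
satisfies this; arbitrary concentration vectors need not, and the
monotonicity test generates physically consistent series accordingly.

## 4. Noise model

Measured concentrations are pre-draw truth times (1 + CV·ε), ε ~ N(0, 1)
i.i.d., floored at zero. The default CV = 3% reflects routine HPLC assay
repeatability for receptor-fluid analysis. All replicates of a run are drawn
from one `numpy.random.default_rng(seed)` stream in a fixed
replicate-then-time order, so results are bit-reproducible for a given seed
and every derived child seed stays below 2³¹.

## 5. Flux and lag estimation

J_ss and T_lag come from ordinary least squares on the *terminal linear
portion* of Q(t): the longest terminal window of at least `min_points = 3`
samples whose linear fit reaches R² ≥ `r2_threshold`, searched from the full
profile downwards so the longest acceptable window wins. T_lag is the
time-axis intercept −b/m; a non-positive slope raises `FluxEstimationError`;
a negative intercept is reported with a `negative_lag` flag; if no window
reaches the threshold the terminal `min_points` window is used and flagged
`window_forced` rather than silently accepted.

**Threshold rationale.** The default is **R² ≥ 0.9999**, deliberately strict.
With hourly sampling over 8 h and lag times of 1–2.5 h, the early curved
portion of a diffusion profile still fits a straight line with R² ≈ 0.996, so
a lax threshold (e.g. 0.99) accepts the full curved window and biases J_ss
low and T_lag low by tens of percent even without noise. At 0.9999 the
noiseless fit recovers J_ss within ~1% and T_lag within ~5%, and under 3%
assay noise the median errors are ≈2.5% (J_ss) and ≈9% (T_lag) — measured
over 1 200 seeded replicate fits spanning T_lag = 0.5–2.5 h.

## 6. Partition, enhancement ratios and uncertainty

The SC/vehicle partition coefficient is K = C_SC/C_vehicle with the field's
conventional mixed units (µg/g over µg/mL; no density correction). The
partition simulator enforces two-compartment mass balance
C_veh = total/(K·m_SC + V_veh) before applying multiplicative noise, using a
default SC specimen mass of 10 mg.

Enhancement ratios (QER, PER, KER) are one operation — treated mean over
control mean — and their standard deviations use the first-order propagation
σ = ratio·√((σ_t/t)² + (σ_c/c)²), which is adequate when both CVs are below
~20%, as they are for all packaged group means. Control arms are reported as
exactly 1.0.

## 7. QSPR layer

Linear models are fitted by statsmodels OLS. `multiple_r` is √(1 − SSE/SST);
`p_value` is the overall F-test. The fitter refuses rank-deficient designs
(`CollinearityError`) and constant responses (`DegenerateFitError`), and
*warns* — rather than refuses — when fewer than 3 residual degrees of freedom
remain, because small-panel fits (5 drugs, 2 predictors) are a legitimate
exploratory use whose p-values simply deserve scepticism. Response surfaces
are evaluated on rectangular grids of two predictors.

Synthetic enhancement panels draw descriptors uniformly over ranges covering
the packaged drugs (PSA 60–270 Å², HBD 2–10, Δδ 4–27 MPa^½), generate
KER/PER from descriptor models and QER from the linear form
β₁·KER + β₂·PER + β₀ with additive Gaussian noise, flooring all ratios at
1e−3. Default generating coefficients (0.434, 0.346, 0.703) are the packaged
reference response surface. Recovery is verified noiselessly to 1e−8 and, at
noise SD 0.05, to within 2 Monte-Carlo standard errors over 200 seeds.

## 8. Biophysical deltas and the Einstein fit

FTIR peak-area decreases are 100·(1 − treated/control), rounded to 2 d.p. to
match standard reporting; band shifts are treated − control (negative =
red-shift, i.e. toward lower wavenumber). The Einstein fit estimates D from
the terminal half (`fit_fraction = 0.5`) of an MSD curve via
MSD = 2·dim·D·t, using the terminal slope to avoid short-time ballistic or
binning artefacts; random-walk generation uses Gaussian steps with
per-coordinate variance 2·D·Δt so the relation holds exactly in expectation
for dim ∈ {1, 2, 3}.

## 9. Demonstration pipeline defaults

The packaged five-drug pipeline anchors each control arm to the reference
group means: membrane thickness is fixed at h = 0.03 cm (a stratum-corneum
scale chosen so that D = h²/(6·T_lag) lands in a physically plausible
10⁻⁵–10⁻⁴ cm²/h range), D follows from the published lag time and K from the
published flux. Enhancer arms scale the membrane partition coefficient by the
target PER (leaving D, hence T_lag, unchanged — consistent with a
partitioning-dominated enhancement mechanism), scale the SC/vehicle partition
experiment by the target KER, and use the published treated donor
concentrations. Defaults: 4 replicates, CV 3%, hourly sampling 1–8 h,
`min_points = 3`, `r2_threshold = 0.9999`. Outputs are tidy CSVs plus a
`summary.json` whose content is byte-identical for identical seeds.
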