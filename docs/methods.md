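# Methods

## Models

cellphenofit calibrates six canonical models of cell population dynamics
to live / dead / total cell-count time series. All rates are in h⁻¹,
populations in cells (or optical-density units treated as proportional
counts), and time in hours, measured from the first observation.

| model | equations | parameters |
|---|---|---|
| `live` | d[Live]/dt = r·[Live] | r (net growth rate), Live(0) |
| `live_logistic` | d[Live]/dt = r·(1 − [Live]/L_cap)·[Live] | r, L_cap, Live(0) |
| `live_dead` | d[Live]/dt = (b − d)·[Live]; d[Dead]/dt = d·[Live] − c·[Dead] | b, d, c, Live(0), Dead(0) |
| `live_dead_logistic` | as `live_dead` with b·(1 − [Live]/L_cap) birth | b, d, c, L_cap, Live(0), Dead(0) |
| `total` | d[Total]/dt = r·[Total] | r, Total(0) |
| `total_logistic` | d[Total]/dt = r·(1 − [Total]/T_cap)·[Total] | r, T_cap, Total(0) |

The net growth rate r = birth − death may be negative (shrinking
cultures); the mechanistic rates b (birth), d (death) and c (clearance
of dead cells — degradation, or loss of recognition by cell-detection
software) are constrained ≥ 0. Initial populations are fitted
parameters, initialised at the first observed value, so measurement
noise at t₀ does not anchor the fit. The population doubling time is
ln 2 / r.

All models except `live_dead_logistic` are evaluated in closed form.
The `live_dead` dead compartment is the linear response to the live
exponential, `Dead(t) = D₀e^(−ct) + d·L₀·(e^((b−d)t) − e^(−ct))/(b−d+c)`,
with the resonant case |b − d + c| < 1e−12 h⁻¹ handled by its analytic
limit `d·L₀·t·e^(−ct)`. The logistic closed form is evaluated as
`cap·N₀ / (N₀ + (cap − N₀)e^(−rt))`, which avoids catastrophic
cancellation when N₀ ≫ cap. `live_dead_logistic` is integrated with
adaptive RK45 at rtol 1e−8 and atol 1e−6 cells, two orders tighter than
the 1e−6 agreement the test suite demands against independent
integrations. For a shrinking culture started above its carrying
capacity the logistic equation diverges in finite time; such corners are
inadmissible inputs and the fitter guards against them by capping
non-finite residuals.

## Fitting

Replicates of one observable must share a time grid (to 1e−6 h; no
interpolation, no smoothing — robustness to sparse data is a design
goal). They are collapsed to per-time-point means with sample standard
deviations σᵢ, and models are fitted to the means by
Levenberg–Marquardt (lmfit) minimisation of

    WSSE = Σᵢ (1/σᵢ) · (Dataᵢ − Simᵢ)² / Dataᵢ

This deliberately unusual weight — 1/σ rather than 1/σ², plus division
by the data value — is the package's defining objective and is kept
exactly in this form rather than normalised to a conventional χ²
weighting. Points with σᵢ = 0 or a single replicate get unit weight with
a logged warning; points with Dataᵢ = 0 are excluded from WSSE and MAPE
(the weight is undefined there) with a warning. Fitting pooled raw
replicates instead of means is not supported.

Fit quality is summarised by

* MAPE = (1/N)·Σ 100·|Dataᵢ − Simᵢ|/Dataᵢ — average percent deviation
  per point, and
* reduced chi-square χ²ν = WSSE/(N_data − N_parameters) — the same
  objective penalised for model complexity, to discourage overfitting.

Models are ranked ascending by either metric (both are always
reported); ties break towards fewer parameters, then model name.
Parameter uncertainty is SEMᵢ = sqrt(χ²ν·Cov(i,i)) with the unscaled
covariance from the minimiser, and confidence intervals are
estimate ± z·SEM with the normal quantile (1.96 at 95 %) by default, or
Student's t on request (`df` argument): the exact multiplier convention
behind historically printed intervals of this kind is not recoverable,
so the plain z convention was chosen and made configurable.

A model with n parameters needs at least n data points (summed over its
observables, after zero-exclusion) to be fitted; with exactly n points
the fit is exact interpolation and is reported without χ²ν or SEM. Note
that at N_data = n + 1 the χ²ν estimate has a single degree of freedom
and the resulting SEM is itself noisy; SEM values become trustworthy as
degrees of freedom grow.

### Optimiser start and determinism

Starting values are deterministic and scale-aware: the net rate from a
log-linear regression on positive means, caps at 2× the maximum
observation, initial populations at the first observation, clearance at
0.01 h⁻¹, death from the dead-cell accumulation divided by the
trapezoid-integrated live count (falling back to 10 % of the net-rate
magnitude). Rates are bounded in [0, 10] h⁻¹ (net rates in [−10, 10]),
caps in (0, 10⁶ × max observation], initial populations in
[0, 100 × max observation].

For the two-compartment models a plain LMA run from these heuristics can
stall in the narrow curved valley of the (birth, death) pair — the live
data pin only their difference. The fitter therefore uses a staged
initialisation: (1) fit the live compartment alone (net rate, initial
live count; the live compartment of the logistic two-compartment model
is itself a logistic curve with an effective capacity L_cap·(1 − d/b)),
(2) fit the dead compartment alone with the live solution held fixed,
(3) release all parameters for a joint polish, restarting the minimiser
from its own solution until the objective stops improving (at most 3
restarts). Every step is deterministic — no random multistart — so fits
are bit-reproducible for identical input. The ODE-backed
`live_dead_logistic` uses standard MINPACK tolerances and a 2000-
evaluation cap (its carrying capacity is nearly flat on pre-confluent
data and the tight tolerances used elsewhere would buy nothing but
runtime); all closed-form models use xtol = ftol = 1e−12.

### Model selection

Models are selected automatically from the observables present and
their sizes: live counts alone select `live` (≥ 2 points) and
`live_logistic` (≥ 3); when dead counts are also present, the
death-describing models and the total-count models (on the derived
Live + Dead series) are added, each subject to the same ≥ n-points
rule. Without viability data, death-describing models are never
offered.

## Synthetic high-content screen

The generator emulates a two-drug screen on a simulated cell line:
5 doses × 5 biological replicates per condition, live and dead counts,
multiplicative Gaussian noise with CV 10 % applied independently per
well and time point (clipped at zero), seeded and bit-reproducible.
Ground truth is returned and serialised (CSV) next to the dataset so
recovery is auditable.

Dose responses are Hill curves, Hill(x) = xⁿ/(ec50ⁿ + xⁿ) with n = 1
and ec50 = 1 by default, acting on the birth–death model rates:

* **cytostatic** (drug_A): birth = b₀·(1 − E·Hill(x)), death constant;
  E = 1 by default, so the net rate falls steeply and crosses zero —
  at the top dose the culture shrinks.
* **cytotoxic** (drug_B): death = d₀·(1 + E·Hill(x)), birth constant;
  E = 2 by default, so the net rate falls only shallowly while the
  death rate triples.

This reproduces the classic attribution trap: judged by net rate alone,
the cytostatic drug looks like the killer; only the birth/death
decomposition from live+dead fits identifies the mechanisms correctly.

Defaults: baseline birth 0.04 h⁻¹ (≈ 17 h division time), baseline death
0.01 h⁻¹, clearance 0.01 h⁻¹ (dead cells degrade over ~4 days), 1000
live + 50 dead cells seeded per well, counts every 12 h for 72 h. The
sampling grid was chosen by a Fisher-information (linearised
standard-error) analysis of the design: with counts only at 0/48/72 h —
the typical grid of a manual staining assay — the free-clearance
five-parameter fit leaves the death rate with a 30–70 % standard error
for any realistic truth, because three dead-compartment parameters then
exactly interpolate three dead time points. Automated HCS platforms
image far more often than manual assays; at 12-h sampling the death-rate
standard error drops to 7–10 % and all three rate classes are
recoverable to ≲ 15 % mean error at 10 % noise. A 0/48/72 h grid remains
one `ScreenDesign(timepoints=...)` away.

What the generator does *not* emulate: count discreteness and detection
thresholds, well-to-well systematic (plate-position) effects, pipetting
error correlated across time points, pharmacokinetics or time-varying
dosing, and resistance dynamics. Passing recovery tests therefore show
that the *estimator* is unbiased and well-conditioned under honest
relative noise — not that real screens are free of systematic error.

## Input format

A single workbook (XLSX; CSV bundle fallback): one `Data_<Observable>`
sheet per observable (column 1 time, one column per replicate), a
`Conditions` sheet mapping replicate columns to condition labels and
environment variables (drug, dose, ...), and `Metadata`/`User`
key–value sheets. Accepted time units: h (default), min, day — converted
to hours on load. Parsing never silently coerces text; every failure is
reported with sheet/row/column coordinates. XLSX numeric cells carry 16
significant digits (one ulp short of exact binary round trip — far below
measurement precision); the CSV bundle round-trips floats bit-exactly.
Written XLSX files have pinned zip timestamps and document properties,
so identical datasets produce byte-identical files.

Sub-sampling for sparsity experiments keeps the points nearest to
t₀ + k·interval within the native span — anchored at the first point,
truncated at the last, deterministic and seedless. (Published sample
counts for such thinning, e.g. 7 samples at a 3-h interval from 95
points at 0.25 h, imply a truncation convention that was never stated;
this rule yields 8 and the discrepancy is documented rather than
hidden.)

## Reporting

Reports are self-contained local HTML: an index ranking all fitted
models per condition by both metrics, one page per (condition, model)
with parameter tables (value, SEM, CI, meaning) and layperson model
descriptions, growth-curve figures (linear, log-linear and
black-and-white variants; PNG+SVG by default, PNG/JPG/SVG/EPS/PDF on
request), dose–response panels (net, birth, death vs dose with SEM
bars), parameter tables as CSV and XLSX, LaTeX fragments of the model
equations, and a phenotype XML record per condition
(see `docs/phenotype_xml.md`; a deliberately minimal schema, left as an
extension point towards full digital-cell-line standards). All plotted
numbers are read from the fit results — nothing is recomputed at the
reporting layer. Output is byte-deterministic given identical inputs;
wall-clock state is confined to the single provenance timestamp, which
callers can pin.

## Problem sizes used in the checks

The shipped verification suite uses: 100 randomised parameter sets for
the closed-form/ODE cross-check; 10-point grids for noiseless
self-recovery of all six models; 20 seeds of the full default screen
(10 conditions × 5 replicates × 7 time points) for noisy recovery; and
95-point dense series thinned to 48/24/8/4/3/2 points for the sparsity
ladder. The acceptance script fits one full screen realisation and two
3-replicate cultures per run.

## Known limitations

* The WSSE weight is not a proper likelihood; SEM and CI inherit its
  convention and should be read as relative, not calibrated, uncertainty.
* Clearance is weakly identified on short assays; its estimate is only
  meaningful when dead counts visibly saturate or decline.
* One environment factor per analysis (drug × dose); crossed factors are
  parsed but not plotted sensibly.
* No Gompertz or cell-cycle-compartment models, no pharmacodynamics, no
  bootstrap/cross-validation/global optimisation.
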