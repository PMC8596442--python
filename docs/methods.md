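# Methods

## Transwell permeability model

The transport model is passive two-compartment diffusion: donor and
receiver chambers of volumes `V_D`, `V_R` (cm³) exchange solute across a
monolayer of area `A` (cm²) at rate `Papp·A·(C_D − C_R)`. It assumes a
single passive pathway (no carrier saturation or active efflux term), a
well-mixed chamber on each side, no solute loss to binding or metabolism,
and negligible monolayer volume. The relaxation solution

    C_R(t) = Ceq + (C_R0 − Ceq)·exp(−Papp·A·(1/V_R + 1/V_D)·t)

with `Ceq = M_tot/(V_D + V_R)` is exact under those assumptions.

Two estimators are provided and selected automatically:

* **Sink regression** (`estimate_papp_sink`): ordinary least squares of the
  cumulative receiver amount `Q(t)` on time; `Papp = slope/(A·C0)`. Valid
  while back-diffusion is negligible. The intercept is left free so a
  nonzero initial receiver signal is absorbed instead of biasing the slope.
* **Non-sink relaxation fit** (`fit_papp_nonsink`): bounded single-parameter
  least squares of the relaxation curve against replacement-corrected
  concentrations `C_R*(t) = Q(t)/V_R`.

`select_papp` applies the conventional 10% rule: sink regression while
`max C_R ≤ 0.10·C0` (boundary inclusive — the rule speaks of *exceeding*
the threshold), relaxation fit above it. The rule reads the *measured*
receiver concentrations; the first analysis driver documents that under
heavy sampling dilution the trigger can under-fire while the sink line is
already curved, and that the relaxation fit remains accurate in every
regime — users with long courses should prefer `fit_papp_nonsink`
directly.

### Sampling-replacement correction

Each sampling event removes `V_S·C_R` of mass and restores the volume with
blank medium. `cumulative_transported` adds the withdrawn mass back
(`Q(t_k) = C_R(t_k)·V_R + Σ_{j<k} C_R(t_j)·V_S`); `compute_facum` instead
discounts the carried-over receiver concentration by `f = 1 − V_S/V_R`.
The fraction-transported series is made dimensionless by dividing each
interval's transported mass by the interval-mean donor mass
(`mean C_D·V_D`); a raw per-area variant (divide by `A·mean C_D`) is
available behind the `per_area` flag for users who want the
chromatogram-style unnormalized series. When the donor series is
unmeasured it is reconstructed by mass balance,
`C_D(t_k) = (M_tot − Q(t_k))/V_D`.

Feeding `C_R* = Q/V_R` to the relaxation model is exact for the cumulative
mass but slightly approximate for the dynamics (withdrawal lowers the
driving receiver concentration, so later transport is marginally faster
than the no-sampling curve). With the default geometry and 100-µL samples
the residual bias on the fitted Papp is below 1% (driver 01 tabulates it);
with `V_S = 0` the fit recovers the generating Papp to machine precision.

### Numerical choices

* Non-sink fit: `scipy.optimize.least_squares`, one parameter bounded to
  `[0, 1]` cm/s, initialized at the sink estimate floored at 1e-9 cm/s,
  `xtol = 1e-14`, at most 500 function evaluations, no random restarts —
  the fit is deterministic. Data sitting entirely at the equilibrium
  concentration are rejected as unidentifiable (any Papp fits them).
* Degenerate `R²` handling: a zero-variance response with zero residuals
  reports 1, with nonzero residuals 0.
* Report rounding is decimal half-up at 2 d.p. (1 d.p. for molar ratios),
  applied only at the presentation layer; JSON reports keep full precision.

## Geometry and unit defaults

Defaults mirror a 12-well transwell glucose assay: insert diameter 12 mm
(`A = 1.13 cm²`, overridable — `π·0.6² = 1.131`), `V_D = 0.5` mL donor,
`V_R = 1.5` mL receiver, `V_S = 0.1` mL samples at 0/30/60/90/120 min,
donor glucose 50 mmol/L. Internally everything is cm/s, cm², cm³ and
seconds; CSV inputs may declare `time_unit=min` and are converted on read.
Papp is reported in 10⁻⁶ cm/s in tabular output.

## Inhibition statistics

The uptake and enzyme assays share the window-normalized form
`100·(AC − AS)/(AC − AB)`; it is affine-invariant (common shifts and
positive rescalings of the three absorbances cancel), exactly 0 at
`AS = AC` and exactly 100 at `AS = AB`. Negative values are reported as-is
— they indicate promotion rather than inhibition of uptake. The
radical-scavenging form is the control-relative decrease
`100·(AC − (AS − AS0))/AC` with an optional sample-background well `AS0`;
whether a background or substrate-blank correction applies to a given
protocol is assay-specific, so both variants are exposed
(`background_corrected=`) and neither is asserted as canonical. Technical
replicates are averaged per role before the formula; the SD of the percent
value is first-order error propagation through the formula's gradient. No
sigmoidal dose-response fitting is attempted: `summarize_dose_response`
reports the maximum, the Spearman monotonicity sign, and a linearly
interpolated 50%-inhibition dose only when the series actually crosses 50%.

## Composition

Yield, retention and protein-removal are ratio statistics
(`100·product/input`, `100·(before − after)/before`). GC molar ratios use
pure area normalization by default — `mole_i ∝ area_i` relative to a
reference sugar — because that is the stated convention for the
hydrolysate chromatograms this supports; per-sugar response factors are
accepted for calibrated detectors. Unnamed peaks are assigned to the
nearest standard retention time within ±0.3 min and unmatched peaks are
returned to the caller, never dropped silently.

## Metabolic indices

HOMA-IR uses the Matthews formulation `FBG·INS/22.5` with FBG in mmol/L
and insulin in mIU/L; the unit contract is strict because a mg/dL glucose
input would silently inflate the index ~18-fold. Fasting-glucose reduction
is computed against the disease-model group mean at the matched timepoint
(treatment-vs-disease contrast, not vs baseline); the reference is an
explicit argument so callers can select a different convention. Group
summaries are arithmetic means with sample SD (n−1).

## Synthetic data

The simulators define the package's verifiable study conditions:

* **Transport**: exact exponential relaxation per inter-sample interval
  (not ODE stepping), so noiseless recovery is testable at machine
  precision; an independent fine-tolerance ODE integration exists in the
  test suite as a cross-check. Sampling events withdraw `V_S·C_R` and
  refill with blank medium; a hidden ledger (donor, receiver, withdrawn
  mass) conserves `M_tot` exactly at every event. Measurement noise is
  multiplicative Gaussian (CV-parameterized) truncated at zero —
  concentration readouts have scale-proportional error; this is a modelling
  choice of the generator, not a claim about any particular instrument.
* **Plates**: `AS` is the convex combination `AC·(1 − p/100) + AB·(p/100)`
  plus optional additive noise, so `p = 0` and `p = 100` reproduce the
  control and blank absorbances exactly in floating point and interior
  levels round-trip to ~1e-13 of a percent.
* **Panels**: independent Gaussian draws per analyte truncated at zero,
  four groups of n = 8 by default. The generating conditions are fixed
  once: disease-model fasting glucose 23.05 ± 5.03 mmol/L; treated-group
  means 15.20 / 14.32 mmol/L (embodying 34.06% / 37.87% reductions versus
  the model mean); LDL/HDL group means at ratios 0.13 / 0.169 / 0.1184 /
  0.044 with HDL near 2–2.6 mmol/L; insulin, TC, TG and GSP at
  field-realistic rodent scales (e.g. model insulin 15 mIU/L, TC
  6.5 mmol/L) since only their qualitative group ordering is documented.

A single integer seed spawns independent substreams
(`numpy.random.SeedSequence`), so identical seeds give bit-identical
outputs across all three simulators.

What the simulators deliberately do **not** emulate: carrier-mediated or
paracellular transport, monolayer integrity drift (TEER), plate-position
effects, correlated analytes within an animal, or longitudinal trajectories.
Passing tests therefore demonstrate correctness of the computations under
the stated generative model, not biological validity of any particular
dataset.

## Problem sizes

Desk-scale throughout, chosen as the package's own verification budget:
8-point courses for the relaxation fits, 200 seeded replicates for noisy
recovery and for panel-mean recovery, 500 randomized configurations for
the conservation sweep, n = 8 per group (the study size) for panels with
200 replicate studies when a Monte Carlo expectation is reported. The full
test suite runs in a few seconds.

## Known limitations

* The sink/non-sink trigger uses measured (post-dilution) receiver
  concentrations; see the note above on under-firing.
* The relaxation fit assumes constant total in-play mass between events;
  heavy sampling (`V_S` approaching `V_R`) degrades the corrected-fit
  accuracy.
* `summarize_dose_response` interpolates the first 50% crossing only; a
  non-monotone series recrossing 50% reports the earliest dose.
* Replicate SD propagation is first-order and treats roles as independent.
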