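# Methods

## The physiological model

The glucose-insulin system is the established ICU minimal-model family:
plasma glucose `G` is cleared by a non-insulin pathway (`pG`, which also
represents suppression of endogenous glucose production as glycemia rises)
and by insulin action `SI·G·Q/(1+alphaG·Q)`, and is fed by gut glucose
appearance, IV dextrose, and net endogenous production `EGPmax − CNS`
scaled by the distribution volume `VG`. Plasma insulin `I` has saturable
clearance (`n`, `alphaI`), exogenous appearance `uex/VI`, and basal
endogenous secretion `IB` that is exponentially suppressed by exogenous
infusion (`exp(−kI·uex)`). The interstitial compartment `Q` first-order
lags `I` with rate `k`. Enteral carbohydrate passes through a
two-compartment gut model (`d1`, `d2`).

Two textual ambiguities in this model family are resolved explicitly and
kept configurable:

* the glucose appearance terms are grouped as `(P(t)+EGPmax−CNS)/VG`, the
  standard form for this family;
* `IB` is an appearance rate per unit insulin distribution volume
  (mU/L/min), which makes the insulin equation dimensionally consistent;
  a total-rate convention (mU/min, divided by `VI` at load) is selectable
  via `ib_units` in the parameter file;
* the suppression factor uses the same instantaneous infusion rate `uex(t)`
  that appears in the appearance term (no filtered/total-dose variant);
* CNS uptake is a constant drain; it is not saturated at low glucose.

### Population constants

No constant is hard-coded in computation paths; all are read from
`vtrial/data/default_params.yaml`. Defaults are literature-typical values
for this model family: `pG` 0.006 /min, `alphaG` 1/65 L/mU, `alphaI`
0.0017 L/mU, `n` 0.16 /min, `k` 0.0542 /min, `EGPmax` 1.16 mmol/min,
`CNS` 0.30 mmol/min, `VG` 13.3 L, `VI` 3.15 L, `IB` 1.9 mU/L/min, `kI`
0.0017 min/mU, `d1` 0.0347 /min, `d2` 0.0069 /min. These give an
insulin-free fasting equilibrium of `(EGPmax−CNS)/(pG·VG) ≈ 10.8` mmol/L —
a plausibly hyperglycemic ICU baseline — and, at a typical `SI` of
3×10⁻⁴ L/(mU·min) with 0.5 mmol/min feed and 2 U/h insulin, a controlled
equilibrium near 5–6 mmol/L. Internal units: minutes, mmol/L, mU/L;
insulin protocol rates convert at 1 U/h = 1000/60 mU/min; glucose mass at
0.18016 g/mmol; BG at 18.016 mg/dL per mmol/L.

## Numerical integration

Inputs (insulin rate, feed, `SI`) are piecewise constant, so the ODE is
smooth within segments and integration restarts at every breakpoint —
inputs are never averaged across a discontinuity. The default integrator is
fixed-step classical RK4 with `dt = 0.25 min` (0.5 min in the
identification and trial hot paths). At these rate constants (fastest
eigenvalue ≈ `n` = 0.16/min) the local error is far below every tolerance
used here: halving the step changes a 480-min endpoint by < 10⁻⁶ relative,
and the result agrees with scipy's adaptive LSODA to ~10⁻⁷ relative
(both are tested). RK4 was preferred over an adaptive solver because
per-interval root-finding requires ~10⁵ short segment solves per cohort
and adaptive-solver overhead dominates at this segment length; LSODA
remains available via `method="lsoda"` and serves as the independent
cross-check. The inner loop is optionally JIT-compiled with numba;
semantics are identical without it.

Negative excursions of `I`, `Q`, `P1`, `P2` (integration noise near zero)
are clipped at 0; `G ≤ 0` aborts the patient's simulation as nonphysical
(reported per patient, not fatal for a cohort). IV glucose boluses are
instantaneous state increments of `mmol/VG` on `G`.

## SI identification

For each inter-measurement interval, one constant `SI` is found such that
the forward-simulated BG at the interval-end measurement matches the
measured value; the simulation state is continuous across intervals. The
map `SI → BG_end` is strictly decreasing (tested on random states), so the
root is unique; Brent's method runs on a warm bracket around the previous
interval's value. Default search bounds are [10⁻⁸, 10⁻²] L/(mU·min);
intervals whose target cannot be bracketed are clamped at the violated
bound with a recorded status (`clamped-low`/`clamped-high`) and a logged
warning, never an exception. Initial conditions at record start: `G` from
the first BG measurement, `I = Q` at the insulin-subsystem equilibrium for
the first recorded infusion rate, gut compartments at equilibrium for the
first recorded feed rate.

With 2- or 4-hourly measurements a single constant spans the whole
interval; the interval length is retained as provenance so the stochastic
module can restrict itself to 1–2-hourly data.

Fit error is `|G_sim − BG|/BG × 100` at each measurement of the
profile-driven simulation. The 1-hour forward prediction error holds the
SI of the interval ending at (or covering) each hour boundary, simulates
one hour ahead with the recorded inputs, and compares against the
measurement at the horizon or a linear estimate between bracketing
measurements up to ~2 h apart; the first identified interval has no prior
SI and is excluded, and horizons with neither a measurement nor a bracket
are skipped and counted.

## Protocol engine

Protocols are declarative band tables: a starting table (absolute rate at
the first measurement) and a maintenance table (increments, target
no-change, halve, stop, stop + 10 g IV glucose rescue + physician call).
Bands are lower-inclusive, upper-exclusive `[lo, hi)` because the
published tables reuse endpoints; partitions are validated at load so
runtime lookups cannot fail. Hypoglycemic bands force hourly measurements
until BG exceeds 80 mg/dL (4.44 mmol/L). Measurement timing otherwise:
hourly outside the target band; 2-hourly in target when the relative
change from the previous measurement is under 50%; the 4-hourly escalation
ships in two interpretations behind a config switch — `literal` (BG below
half the highest BG of the last 4 h, the published wording, default) and
`sustained` (in target throughout the last 4 h with limited variation),
because the literal wording is clinically counter-intuitive and the intent
is not guessed. The 50% comparison uses the previous measurement (the
alternative reading, "the value 2 h ago", is not implemented). After a
stop, insulin resumes through the maintenance table from rate 0; the
starting table applies only at the first measurement.

## Trial engine

A virtual patient is the identified (or synthetic) `SI(t)`, the patient's
own retained nutrition schedule (nutrition was clinician-driven, not
protocol-driven, so it travels with the patient across protocols), initial
BG and stay length. The engine alternates protocol decisions at
measurement times with model integration between them. Timing modes:
`per_protocol` (the protocol's 1/2/4-h rules schedule measurements) and
`replayed` (the source record's timestamps are reused; requires a
record-derived patient). Sensor noise is off by default — protocols are
followed exactly as instructed — with optional multiplicative Gaussian
noise under a seed for robustness studies. The terminal interval is
truncated at stay end, where a final sample is logged; summaries use all
logged samples. Insulin-rate and glucose-rate per-patient medians are
time-weighted over piecewise-constant segments; glucose rate counts
nutrition (boluses are logged separately in the intervention log).

## Stochastic SI model

Consecutive-interval pairs `(SI_n, SI_{n+1})`, restricted to intervals of
≤ 2 h on both sides (a 2-hourly interval contributes one transition;
4-hourly data are excluded), feed a conditional kernel density
`p(SI_{n+1} | SI_n)` on a log-spaced grid (default 200 points over
[10⁻⁵, 3×10⁻³]; `SI` spans orders of magnitude). Kernels are Gaussian
with bandwidth proportional to the `SI` value — variability in this
parameter is multiplicative — with the proportionality constant chosen by
leave-one-out conditional pseudo-likelihood on the fitting data (or fixed
by the caller). Rows are normalized to integrate to 1; per-row log-weights
are max-shifted before exponentiation so conditioning points far from the
data degrade gracefully to the nearest datum's kernel instead of
underflowing. Percentile bands (5/25/50/75/95) invert each row's
cumulative-trapezoid CDF; sampling is inverse-CDF. Cohort comparisons
report band differences over the clinically dense central range
0.01–0.8 ×10⁻³ L/(mU·min), where such comparisons are supported by data.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset: initial BG lognormal with median 6.6 and IQR
[5.6, 8.6] mmol/L (typical of mixed ICU admissions); initial `SI`
lognormal with median 3×10⁻⁴ L/(mU·min) and log-sd 0.55, placing ~90% of
values inside the clinically dense 0.01–0.8 ×10⁻³ range; hour-to-hour `SI`
variability as a multiplicative lognormal random walk with 10% hourly
step CV (clipped to [2×10⁻⁵, 2×10⁻³]), or transitions drawn from a fitted
stochastic model; patient-constant nutrition drawn uniformly from
0.1–1.0 mmol/min (the observed clinical range of carbohydrate
administration); 72-h stays. Records are produced by actually running the
generating protocol in closed loop, so measurement cadence, insulin logs
and BG values are mutually consistent and schema-identical to clinical
input; every draw is reproducible from the config seed, and the generating
truth is retained.

Two deliberate design choices:

* **Truth `SI` steps on the measurement grid.** A k-hour
  inter-measurement interval receives one multiplicative step with
  variance scaled by k. Hourly-scale variability statistics are preserved,
  and the truth is exactly representable by per-interval identification,
  so recovery tests assert exactness rather than an aggregation artifact.
  The corollary is that a patient's realized `SI` step times depend on
  their measurement cadence, which couples (weakly) to the treating
  protocol.
* **Records begin at insulin equilibrium for the first commanded rate**,
  matching identification's initial-state convention, so the first
  interval is as recoverable as the rest.

What the generator does *not* emulate: measurement noise and nurse timing
jitter are off by default (both available as options); nutrition
interruptions, demographic covariates, occult carbohydrate sources, and
sensor artifacts are absent. Passing the recovery and consistency tests
therefore demonstrates the pipeline's internal correctness under the
model's own assumptions — not robustness to real-data pathologies, which
clinical fit/prediction errors must establish separately.

## Validation analytics

Self-validation re-simulates a cohort's own protocol on its derived
virtual patients in both timing modes (per-protocol and replayed);
residuals against the source records reflect model error plus, in the
per-protocol arm, compliance to measurement timing. Cross-validation
simulates the *other* arm's protocol; agreement tests the core assumption
that `SI(t)` is independent of the treatment used to identify it.
Analytics are pooled and per-patient-median BG CDFs, median [IQR] summary
tables (time-weighted rate medians per patient, then cohort quantiles with
linear interpolation between order statistics), fractional patient-days
for measurement frequency, and the compliance fraction (actual
measurements as a percentage of per-protocol-specified opportunities).

On noise-free synthetic cohorts, self-validation is exact by construction.
The cross-vs-self median-BG gap on matched n = 100 cohorts is a stochastic
quantity with sampling SD around 3%; the acceptance suite therefore
asserts its median over three fixed replicate seeds, which estimates the
systematic consistency component rather than one draw's luck. Problem
sizes used by the test and acceptance suites — 50 patients × 72 h for
recovery, 100 per arm × 72 h for validation — were chosen as the smallest
cohorts at which these cohort-level statistics are stable.

## Known limitations

* Population constants are fixed per cohort; real inter-patient spread in
  `IB`, `kI` or `EGPmax` surfaces as `SI` misattribution, most visible at
  low insulin doses.
* No subcutaneous insulin kinetics, sensor dynamics, weight-scaled
  volumes, or nutrition-modulating protocols.
* The literal 4-hourly timing rule is implemented as printed; if the
  original intent differed, measurement-frequency summaries shift
  accordingly (the `sustained` switch bounds the effect).
* Identification requires ≥ 2 BG measurements and recovers at most one
  `SI` value per inter-measurement interval; 4-hourly data yield
  correspondingly coarse profiles and are excluded from variability
  fitting.
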