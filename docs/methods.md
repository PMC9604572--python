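# Methods

## Scope and intent

`clvsim` couples three components — a PID + rules norepinephrine controller,
a synthetic surgical-patient model, and a per-case/cohort scoring suite —
so that a systolic-pressure closed loop can be run, stressed and scored
end-to-end on a laptop. The controller and the metric definitions are the
substantive artifacts; the patient model is a deliberately simple stand-in
whose job is to present the controller with realistic pressure dynamics,
not to reproduce any clinical cohort quantitatively.

## Controller

**Form.** Velocity (incremental) PID on the SAP error `e = target − SAP`:

    Δu_k = Kp(e_k − e_{k−1}) + Ki e_k dt + Kd (e_k − 2e_{k−1} + e_{k−2})/dt

applied as `u_k = u_{k−1} + Δu_k` after the safety layer. The velocity form
was chosen because the integrator then lives implicitly in the commanded
rate: clamping the rate to `[0, u_max]` and limiting per-cycle changes is
inherently anti-windup, with no separate integrator-reset logic to audit.
Above-band pressures drive the same law with negative error; pump-inactive
time emerges as `u = 0` rather than from a distinct off state.

**Safety layer** (in order): (1) if the pressure signal is flagged invalid
and `hold_on_invalid` is set, the previous rate is held and the error
history is frozen; (2) `Δu` is clipped to `[−step_down_max, +step_up_max]`;
(3) the resulting rate is clamped to `[0, rate_max]`.

**Defaults and units.** `Kp = 0.1 µg/min per mmHg`, `Ki = 0.01 µg/min per
mmHg·s`, `Kd = 0`, cycle `dt_control = 10 s`, `rate_max = 80 µg/min`,
`step_up_max = 2` and `step_down_max = 4 µg/min` per cycle,
`rate_epsilon = 0.05 µg/min` (the threshold below which a cycle-to-cycle
rate difference is not counted as a "modification"). These are this
package's own tuning: chosen so that, against the default patient, the loop
adjusts its rate a handful of times per minute and rejects a 25-mmHg
hypotensive step back into the band within a few minutes. Derivative action
is off by default: the measured SAP is noisy, and differentiating it buys
little phase lead at the frequencies the PK and effect-site lags dominate.

**Known limitation — monotonicity.** "A uniformly lower pressure stream
never receives a lower rate" holds in the regime where no safety rule
engages (there the velocity form telescopes exactly to a positional PID,
which is monotone in the error history). It is *not* a theorem of the full
rule set: a stream that saturates `step_up_max` retains a large previous
error, so a subsequent pressure recovery produces a more negative
proportional increment than an otherwise-identical milder stream, and the
ordering can transiently invert. The property tests therefore assert
monotonicity on streams verified not to engage any limit, and bound-safety
(rate and step limits) unconditionally on randomized streams.

## Patient model

**PK.** One-compartment infusion kinetics with distribution volume
`vd = 10 L` and elimination `k_elim = ln 2 / 2.5 min⁻¹` (plasma half-life
2.5 min, in the range reported for norepinephrine), integrated by explicit
Euler at 1 s. Steady state under constant infusion is
`Cp* = rate/(vd·k_elim)` in ng/mL for rate in µg/min; the 1-s Euler solution
is within 1% of the analytic transient. An effect-site compartment
equilibrates at `ke0 = 2 min⁻¹`.

**PD.** Sigmoid Emax: `ΔSAP = Emax·Ce^γ/(EC50^γ + Ce^γ)` with
`Emax = 65 mmHg`, `EC50 = 10 ng/mL`, `γ = 1.5`. The parameter set was
chosen jointly with the fixed controller gains: a linear analysis of the
loop (integral-gain crossover against the PK pole at `1/216 s⁻¹` and the
effect-site pole) bounds the stable local plant gain near
~2 mmHg/(µg/min); the default set keeps the local Hill-slope gain inside
that bound over the whole operating range while leaving the maximal effect
comfortably above the worst pressure deficit the cohort generator produces
(no chronic saturation). A steeper/more potent plant (e.g. EC50 of a few
ng/mL with γ = 2) rings at these gains.

**Baseline and disturbances.** The unsupported (anesthetized) baseline SAP
follows an Ornstein–Uhlenbeck process around `sap_baseline = 112 mmHg`
(time constant 300 s, stationary SD 5 mmHg), using the exact discretization
`b′ = μ + (b − μ)e^{−dt/τ} + σ√(1 − e^{−2dt/τ})·z` so both the
deterministic decay and the stationary variance are step-size exact.
Scheduled insults add a step or linear-ramp offset (negative = hypotensive)
for their duration, emulating fluid shifts and vascular compression;
overlapping insults sum.

**Measurement.** The monitor sees `SAP + N(0, σ)` with `σ = 2 mmHg`,
flagged invalid with probability 0.02 per sample (arterial-line damping or
flushing); MAP is a linear surrogate `0.65·SAP + 10`, capped at `0.95·SAP`
so MAP < SAP holds even in deep hypotension. The MAP surrogate exists only
to feed the secondary MAP < 65 mmHg endpoint and is knowingly crude.

**Clocks.** Three explicit grids: 1-s plant integration, 10-s controller
cycle, 20-s recording grid (the cadence at which clinical hemodynamic
platforms log averaged values). The emitted case series lives on the
recording grid; the controller-side command record is kept alongside it.

**Cohort generator.** `make_cohort(n, seed)` draws per-patient parameters
from documented ranges (`clvsim.patient.COHORT_RANGES`): preoperative SAP
~ N(130, 6) mmHg — centered on the preoperative median of the cohort this
testbed emulates — times an anesthesia depression factor U(0.85, 0.93);
Emax ~ N(65, 8) clipped to [50, 85]; EC50 log-normal around 10 ng/mL;
half-life U(2, 3) min; insult onsets from a 2/h Poisson process with
magnitudes U(−25, −8) mmHg over U(600, 1500) s, 70% ramps. The ranges were
sized so worst-case deficits (standing deficit plus insult) stay inside
per-patient pressor authority; wider anesthetic depression or deeper
insults push patients into Emax saturation and produce chronic under-band
time unlike the tightly-controlled system being emulated. One master seed
spawns independent substreams per case, so cohorts are reproducible and
cases independent.

**What the simulator does not capture:** baroreflex and autonomic
compensation, interaction with anesthetic depth and fluid therapy,
beat-to-beat SAP variability (only the 20-s grid is modeled), pump latency
and drug dead-volume, and any saturation of venous return. Passing the
closed-loop benchmarks therefore shows the controller logic is sound
against plausible dynamics — not that clinical performance is guaranteed.

## Endpoints

Per case, from the recorded series (invalid samples are excluded from
metric denominators; the clock keeps running):

* **Band time**: sample-weighted % under / in / above the band; a sample on
  a band edge counts in-band (the band is printed as "between 117 and
  143"); the three fractions sum to 100 before rounding.
* **MAP < 65 mmHg**: strict inequality, % of valid samples.
* **Pump activity**: % of samples with rate > 0.
* **Rate modifications/min**: consecutive recorded samples differing by
  more than `rate_epsilon`, normalized by the elapsed span. The 20-s
  recording grid caps this at 3/min, so the simulator also reports the
  controller's own command-cycle counter (`SimResult.rate_changes_per_min`),
  which sees every commanded change; whether "modifications" should be
  counted at the pump or the controller is a genuine ambiguity and both are
  exposed.
* **Dose**: each sample owns one recording interval, so total dose is
  `Σ rate·dt/60` µg and mean rate is the per-sample mean.
* **Varvel metrics** from `PE_i = 100(SAP_i − target)/target`: MDPE =
  median PE, MDAPE = median |PE|, wobble = median |PE − MDPE|, divergence =
  OLS slope of |PE| vs time, reported in %/h (configurable to %/min). MDPE
  is computed even where only MDAPE/wobble/divergence are of primary
  interest, because wobble is defined relative to MDPE.

Note the two duration conventions (interval-owning for dose, first-to-last
span for rate changes): each matches the natural reading of its endpoint —
an infusion runs for the whole interval a sample represents, while changes
can only be observed between samples.

## Cohort aggregation

Endpoints aggregate as median with 25th–75th percentiles: midpoint median
for even n, quartiles by linear interpolation between order statistics (the
method is named in the summary metadata — published quartile rows are not
always reproducible under any single convention, so only medians should be
treated as method-robust). Presentation rounding is half-up to one decimal
(doses to whole µg): required because 92.35 → 92.4 and 4.65 → 4.7 under
half-up but not under banker's rounding.

The packaged 12-case table reproduces its published median row under this
pipeline, with one caveat: the published summary row for pump-active time
(95.3%) is inconsistent with the median of its own per-case column; the
recomputed value (94.55 → 94.6) matches the figure the study text itself
reports, and `reproduce_table2` returns the recomputed value.

## Numerical choices and degenerate inputs

* Empty series, all-invalid series, and single-sample rate-change queries
  raise `UndefinedMetricError` rather than returning NaN.
* Case CSVs are written at full float precision and read back with the
  round-trip float parser, so write→read is bit-exact.
* `band_bounds` uses the symmetric form `target ± target·fraction`, which
  is exact in floating point for the default (117/143) band.
* The Hill function is evaluated as `Emax·(C^γ/(EC50^γ + C^γ))` so that
  `pd_effect(EC50) = Emax/2` holds exactly.
* Concentrations are floored at zero after each Euler step; commanded rates
  are clamped after each rule application, so neither can go negative.

## Benchmark problem sizes

The closed-loop efficacy benchmark simulates 12 patients × 4 h at the 1-s
internal step (≈170 k plant steps per arm, closed plus open loop), which
completes in seconds; the controller safety envelope is exercised over 10⁴
randomized cycles. These sizes give stable medians across seeds (checked on
eight seeds during design) while keeping the whole suite fast.
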