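# Methods

This note documents the models, estimators, numerical choices and known
limitations of `breathmech`. Units throughout: pressure cmH₂O, flow L/s,
volume L, elastance cmH₂O/L, resistance cmH₂O·s/L, time s.

## Model and estimators

All three estimators derive from the single-compartment equation
`P_aw = R_rs·Q + E_rs·V + P0`.

**Expiratory time-constant.** Passive expiration at constant airway
pressure reduces the model to `dQ/dt + (E/R)·Q = 0`, hence
`Q(t) = Q0·e^(−Kt)` with `K = E/R = 1/τ`. Per breath, `(Q0, K)` minimise
the flow-domain sum of squares via Levenberg–Marquardt (`scipy
least_squares`, analytic Jacobian, tolerances 1e-10, 200 evaluations). The
objective is deliberately *not* log-transformed: a log fit reweights
residuals toward the small flows late in expiration. The log-linear
regression of `ln Q` on `t` (samples clipped at 1e-4 L/s) supplies the
initial guess and serves as an independent cross-check in the tests.
Fitting both parameters jointly, with the clock starting at the sample of
peak expiratory-flow magnitude, suppresses the valve-opening transient; for
an ideal exponential the choice of clock origin shifts only Q0, never K.
The fit window ends where `|Q − Q_eq|` has shrunk to 5 % of
`|Q_peak − Q_eq|`, with `Q_eq` the median over the final 10 % of the
expiratory span — this accommodates the near-constant end-expiratory flow
that the expiratory valve's resistance produces. Fits with `K ≤ 0`, failed
convergence, or fewer than `min_samples` (5) points are flagged and
excluded from trend statistics; every exclusion is counted in the run
report. Expiratory pressure is never used by this estimator.

**Static (EIP) mechanics.** `PIP` is the raw maximum pressure over
inspiration (ventilator-display convention, no smoothing); `Pplat` is the
median over the final third of the pause; `PEEP` is measured as the median
pressure over the final quarter of the previous expiration (so the tool
runs on waveform-only input; the simulator also emits the set PEEP for
cross-checks); `Vt` is the trapezoidal integral of flow over inspiration;
the flow denominator of the resistance formula is the mean inspiratory flow
`Vt / T_insp`, which equals the set flow for a square profile. A drift
between the early-pause and late-pause median pressure beyond
`max(0.3 cmH₂O, 3σ̂_P/√n)` raises the `pplat_unsettled` flag — a pause too
short for pressure to settle makes `E_static` an overestimate. (σ̂ here and
below is a robust noise scale: 1.4826·median|ΔP|/√2.) Because `PIP` is a
raw maximum, heavy pressure noise biases it (and hence `R_static`) upward
by extreme-value statistics; this is a property of the two-point method
itself, not of the implementation.

**Integral-based identification.** For every sample `t_i` of the
inspiratory span the model is integrated from inspiration onset:
`∫P = R·∫Q + E·∫V + P0·t_i`, `V(t) = ∫Q`, and the stacked system is solved
for `(R, E, P0)` by linear least squares. Integration acts as a low-pass
filter, which is where the method's noise robustness comes from — and,
precisely stated, that advantage is against *high-frequency /
difference-correlated* noise. Under exactly white pressure noise both this
method and a point-wise regression of `P` on `(Q, V, 1)` are linear
estimators, so the point-wise OLS is the Gauss–Markov efficiency bound and
the integral method matches it to within a few percent; under
difference-correlated noise it is about twice as accurate (both facts are
asserted by the test suite, with the point-wise variant kept as
`pointwise_fit` for the comparison). The span includes the end-inspiratory
pause by default: under exactly constant square flow the inspiration-only
design is rank-deficient (`∫Q` is collinear with the `P0·t` column), so the
zero-flow pause rows are what make `R` and `P0` separately identifiable.
Estimates outside `E ∈ (0, 200]`, `R ∈ (0, 100]`, or from designs with
condition number above 1e8, are flagged and excluded from trends.

**Metrics.** The per-breath fitting error is the median over samples of
`100·|modelled − measured|/|measured|` (flow for the expiratory model
against the fit window; reconstructed inspiratory pressure for the two
validators). Samples with `|measured|` below 1 % of the window peak are
excluded (a peak-normalised mode is available via config). Phase summaries
are median [IQR] over breaths (type-7 linear-interpolation quantiles, so
results are bit-reproducible); pooling at breath level weights long and
short breaths equally (an all-samples pooling is a config option). Trend
agreement is the squared Pearson correlation of per-breath pairs, with
flagged breaths excluded pairwise; `scale_for_trend` provides the
through-origin least-squares factor used only to overlay K on an elastance
axis in plots and exports.

## Breath segmentation

Detection runs on a boxcar-smoothed copy of the flow (window 7 samples);
fitting always uses raw samples. Inspiration onsets come from hysteresis
thresholding (rise through `q_on`, re-armed below `q_off`), with three
robustness measures: thresholds are taken per sign of flow (peak expiratory
flow `E·Vt/R` can exceed the set inspiratory flow several-fold, so a shared
peak would mask inspiration); thresholds never drop below 4σ̂ (2σ̂ for
`q_off`) of the smoothed noise; and a candidate onset must *persist* — the
mean of the next 0.3 s of raw flow must stay above `q_on`, which rejects
noise bumps in the pause or expiratory tail (they sit next to zero or
negative flow, so their window mean collapses). Phase boundaries are then
refined to half-amplitude crossings of the smoothed signal, referenced to
the local pre-edge level; a centred boxcar crosses the midpoint of a step
at the edge sample, which locates boundaries to ±1 sample without
sacrificing noise robustness. The expiratory fitting clock starts at the
sample of peak expiratory-flow magnitude. An end-inspiratory pause is
accepted when the structural gap between inspiration end and expiratory
onset spans ≥ 3 samples *and* its median smoothed |flow| is below
`max(q_zero, 3σ̂/√w)`. Leading and trailing partial cycles are dropped; a
final breath is kept only if its expiration has decayed below the
expiratory onset threshold by the record's end (slow lungs, `K ≲ 1`/s, may
therefore lose their last breath — by design, since that expiration is
genuinely incomplete). Indices are 0-based half-open spans; segmentation
uses flow only and is exactly invariant to pressure offsets.

## The simulator

`simulate_breath` generates volume-controlled square-flow breaths:
constant inspiratory flow `Q = Vt/T_insp` with `P = R·Q + E·V + PEEP`
(piecewise-linear pressure), a zero-flow pause at the plateau pressure
`E·Vt_delivered + PEEP`, and a passive expiration with flow magnitude
`(E·Vt_delivered/R)·e^(−(E/R)t)`. Valve transitions fall exactly on sample
instants and the delivered volume is `Q·(n_insp−1)·Δt` (valve closes at the
last inspiratory sample), so the emitted discrete waveform satisfies the
model identities exactly and closed-loop recovery is exact to machine
precision — the basis of the exactness tests. Per-breath volume is rebased
to zero at inspiration onset; the residual volume a truncated real
expiration would carry into the next breath is not modelled.

Measurement artefacts are additive and individually switchable: a slow
exponential valve-tail flow (default 0.02 L/s, τ = 5 s — producing the long
near-constant end-expiratory flow the truncation rule exists for; a full
valve ODE is out of scope), an expiratory pressure trace collapsing to just
above PEEP (default 1 cmH₂O, τ = 0.3 s; physiologically uninformative, as
it is measured downstream of the valve), optional first-order plateau
settling (default 0 = ideal plateau; nonzero values exist solely to
exercise the short-pause failure mode), and white Gaussian noise per
channel with σ a fraction (default 5 %) of that channel's per-breath peak.
Seeds are mandatory; identical (scenario, seed) pairs are bit-identical.

Scenario factories reproduce the three experimental phases: a healthy
staircase recruitment manoeuvre (PEEP 5–10–15–20–15–10–5 cmH₂O), disease
progression at constant PEEP 5 with a slow-then-rapid sigmoid elastance
rise 20→60 (and a variable-resistance variant, R rising 5→10 earlier in
the progression, under which `K = E/R` transiently *falls* while the lung
stiffens — the decoupling that makes constant resistance a prerequisite for
reading K as elastance), and the diseased-state staircase with a convex
`E(PEEP)` (quadratic, minimum at PEEP* = 15) plus a multiplicative
hysteresis factor `h ≤ 1` on the descending limb (the lung stays more
compliant after recruitment). Defaults were chosen once as plausible
porcine values — fs 50 Hz, 20 breaths/min, T_insp 1 s, EIP 0.3 s, Vt 0.4 L,
healthy E 20 / R 5, ARDS-staircase base E 40 / R 8, h 0.9 — the source
recordings' acquisition rate and mechanics ranges are not published, so
fidelity of these defaults to the original animals is unknowable; every
value is configurable. `paper_scale_suite` sizes a full validation run at
three subjects × three phases ≈ 6860 breaths, which simulates and analyses
in well under a minute on one CPU.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: multi-compartment (bi-exponential) expiration,
spontaneous breathing effort, cardiogenic oscillations, secretions or
coughs, leaks, drifting sensors, and correlated (non-white) noise. The
single-compartment generative model is the same family the estimators
assume, so closed-loop exactness demonstrates correctness of the
implementation, not adequacy of the model for a given patient.

## Numerical choices

* **Volume accumulation.** Inside the integral-based fit, `V = ∫Q` uses a
  backward-rectangle rule by default. For square-flow ventilation whose
  valve transitions fall on sample instants, the rectangle rule reproduces
  the ideal ventilator's volume exactly (plateau volume = delivered Vt),
  whereas the trapezoid rule smears each step by half a sample and makes
  the inspiratory estimators inconsistent with the static identities at the
  O(Δt) level. On constant-flow segments the two rules agree exactly; a
  `trapezoid` option is provided. The outer integrals of the stacked system
  are always trapezoidal — their rule is immaterial to consistency because
  integration is linear.
* **Degenerate inputs.** All-zero flow → segmentation error; zero-flow
  inspiration → rank-deficient design → estimator error; constant
  expiratory flow → truncation degenerates to a flagged `min_samples`
  prefix; empty mechanics tables refuse to write.
* **Tie/failure policy.** Optimizer failure or `K ≤ 0` flags the breath;
  flags never silently drop data — the run report reconciles
  `detected = clean + flagged`.
* **Precision.** Tables are written with 12 significant digits and
  round-trip; quantiles are type-7.

## Known limitations

* `R_static` inherits the extreme-value bias of a raw-maximum PIP under
  heavy pressure noise (several % at σ_P = 5 % of PIP).
* Per-breath PEEP is measured from end-expiratory pressure; when an
  expiratory pressure artefact is present this is biased high by a few
  hundredths of cmH₂O.
* Breaths whose expiration is much longer than the configured expiratory
  time (K ≲ 1/s at 20 breaths/min) never reach equilibrium; their
  truncation window covers the whole span and the final breath of a record
  may be dropped as incomplete.
* The integral method's `< 3 %` elastance accuracy holds for pressure-noise
  levels of a few tenths of cmH₂O; with flow noise at 5 % of the
  *expiratory* peak (25 % of the inspiratory flow) its noise floor is
  ≈ 3 % median relative error.
* No spontaneous-breathing support: expiration is assumed fully passive.
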