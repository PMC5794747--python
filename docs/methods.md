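# Methods

## Scope and design

`navclamp` treats a channel variant as an *empirical* parameter set
(`VariantParams`): the Boltzmann midpoints/slopes of steady-state
activation and inactivation, the −10 mV fast-inactivation time constant,
the single-exponential fast-recovery time constant, the
double-exponential kernels of slow-inactivation entry and recovery (after
4-s and 30-s conditioning), a peak current density target, and an
Arrhenius energy of activation.  The forward model is descriptive, not
mechanistic: it is built so that simulating the five study protocols and
re-fitting the traces returns exactly the parameters that generated them.
That closure property is what makes the packaged tables, the simulator
and the fitting chain mutually consistent, and it is what the test suite
leans on.

## Forward model

**Gates.** Open probability is m·h·s with a single effective activation
gate (exponent 1, configurable).  A Hodgkin–Huxley m³ scheme would break
closure: the packaged activation parameters are Boltzmann fits of
normalized peak conductance, so the model uses that curve directly as
m∞(V).

**Step waveform.** The current during a depolarizing step is a rise with
time constant τ_m (0.1 ms at 22 °C, Arrhenius-scaled; activation kinetics
are not part of the parameter set and only need to be fast) to a peak of
g·(V−E_Na)·m∞(V)·h₀·s₀, followed by an *exact* single-exponential decay
toward the pedestal-adjusted steady-state availability.  The peak is
snapped to the sample grid (10 kHz).  A literal m(t)·h(t) product
envelope was measured to bias the re-fitted decay τ by ~3% (rise
contamination) and to wobble sampled peak conductance by up to ~3%
(grid-phase dependence of the peak), violating closure; the piecewise
waveform removes both at the cost of a slope kink at the peak, which no
downstream measurement looks at.

**h relaxation across epochs.** The h gate relaxes toward
C + (1−C)·h∞(V) with an effective time constant blending entry and
recovery rates, 1/τ_eff = w/τ_rec + (1−w)/τ_entry(V).  The weight w is a
falling sigmoid at the inactivation midpoint with half the SSI slope —
sharp enough that τ_eff equals the measured recovery constant at the
holding potentials and the measured entry τ_h at test potentials to
better than 0.05%.  The entry limb is evaluated no lower than −50 mV
(the calibrated range); physically τ_h(V) is bell-shaped and turns over
below the activation range, and without the cap a 500-ms SSI prepulse
would fail to equilibrate at 10 °C.

**τ_h(V) shape.** Only the −10 mV anchors are tabulated.  The shape
floor + amp·exp(−V/15 mV) (floor 0.2 ms) is a generator choice, *not*
data-derived; the amplitude is computed from the anchor so that
τ_h(−10 mV, 22 °C) is exact.  All τ_h anchors are referenced at 22 °C;
other temperatures are reached via the variant's Arrhenius law.

**Slow inactivation.** Represented by the fitted kernels, not a Markov
scheme (only kernel parameters are reported).  Entry:
y0 + A_f·e^(−t/τf) + A_s·e^(−t/τs) with A_s = 1 − y0 − A_f.  Amplitudes
are labelled by the time constant they multiply.  The residual
availability y0 at infinite conditioning is unreported; 0.25 is used for
all variants (a typical residual for NaV1.4 after 30-s depolarization).
Recovery kernels are selected by conditioning duration (4-s / 30-s sets,
parameters interpolated linearly in log conditioning time in between,
clamped outside).  In the executor, slow-protocol test-pulse availability
*is* the kernel value: the published kernels were fitted to measured
test/control ratios, which already fold in fast-gate recovery during the
short interpulse intervals, so re-modelling those would double-count and
break closure.

**Reversal potential.** Nernst from the recording solutions
(150 mM Na⁺ out / 35 mM in): +37.0 mV at 22 °C, temperature-dependent,
overridable.

**Pedestal.** C = 0 by default (no persistent current was observed);
setting C > 0 leaves a persistent fraction of the peak at the end of the
step and raises the window-current floor.

## Protocols

Five programs, digitized at 0.1 ms: the I–V family (−140…+60 mV,
10-mV steps, 50 ms, holding −140 mV; 21 sweeps), steady-state
inactivation (500-ms prepulse −140…−30 mV, 10-ms test at −10 mV),
fast recovery (40-ms conditioning at −10 mV, intervals 0.1–4000 ms at
−140 mV, 20-ms test), slow entry (conditioning 1 ms–30 s at −10 mV from
−120 mV, 20-ms interpulse, 5-ms test) and slow recovery (4-s or 30-s
conditioning, intervals 0.5 ms–10 s).  Variable intervals are log-spaced
at 10 points per decade (counts are not stated anywhere; configurable).
Only the test epoch of the long protocols is recorded.  State fully
resets between sweeps (inter-sweep interval 5 s at holding is assumed
sufficient for complete recovery).  Series resistance, capacitance
transients, leak subtraction and the 5-kHz analog filter are not
emulated.

## Synthetic cohorts

A cell draws: capacitance lognormal (median 15 pF, σ=0.3), additive
jitter N(0, 1 mV) on both midpoints, multiplicative N(1, 5%) on slope
factors and N(1, 10%) on all time constants, and a mean-one lognormal
(σ=0.15) scatter on gmax around the value that puts the expected −10 mV
peak density (as measured from the −140 mV holding) at the variant's
target.  Recording noise is i.i.d. Gaussian, σ = 10 pA per sample.
The capacitance distribution, jitter magnitudes and noise σ are
plumbing choices tuned to give group SEMs of the same order as the
reported cohorts; true cell-to-cell variance components are unavailable,
so SEM matching is approximate by design.  Cohort sizes default to the
reported I–V cohort (10/18/18 cells for WT/R1451C/R1451L).  What passing
tests on these cohorts show is that the fitting chain is unbiased and
correctly propagates this *idealized* variability; they cannot certify
behaviour under rundown, seal drift, endogenous currents or
series-resistance artifacts, which the generator does not model.

## Fitting

All fits use `scipy.optimize.curve_fit` (trust-region reflective, with
bounds), initialized heuristically — half-maximum crossing and 25–75%
width for Boltzmanns, log-linear tail regression for decay τ, geometric
spread of the sampled range for multi-exponentials — with up to three
perturbed restarts before raising a diagnostic `FitError` carrying the
attempted starts.  The Boltzmann is fitted with a free scale so
normalization by the observed maximum (which is not the asymptote) does
not bias V½ or k.  The decay window runs from the first post-peak sample
at or below 95% of the peak to the end of the step, excluding the
activation rise; traces are peak-normalized internally, so fits are
invariant to amplitude rescaling.  SSI fractions are normalized to the
maximal peak across prepulses; recovery and entry fractions to the
maximal test-pulse peak.  Conductance points within 10 mV of E_Na are
excluded from G–V fits (vanishing driving force).  Reported slope-factor
signs follow the table convention: negative for activation, positive
for inactivation (internally both are positive canonical slopes plus a
direction flag — the mapping is bijective).

## Derived statistics

The window metric is the trapezoid *area* of the probability curve on a
0.1 mV grid over −150…+50 mV with C = 0; the area ratio reproduces the
published ~5-fold increase for R1451C (computed: 4.94) and gives 7.47
for R1451L against the published "7-fold" (the peak-ratio alternative,
available via `metric="peak"`, gives 3.5/3.9 and is clearly not the
published metric).  Midpoint shifts are reported to one decimal,
percentage reductions rounded to integers, matching report conventions.
Arrhenius energies come from OLS of ln(1/τ) on 1/T(K), Ea = −slope·R;
slope comparison between groups is the interaction term of a pooled
linear model ln rate ~ (1/T)·group (the regression form of ANCOVA
slope-homogeneity), with 1/T centred and rescaled for conditioning.
Group comparisons use two-sided unpaired equal-variance t-tests with no
multiple-testing correction, flagged at 0.05/0.01/0.001.  SEM is
sd/√n (n = 1 reports SEM as unavailable).

## Known discrepancies and limitations

- Direct evaluation of the R1451L inactivation Boltzmann at −85 mV gives
  32.7% availability (67% inactivated), whereas the source text says
  "about 60%"; the package computes the closed-form value.
- The printed entry equation pairs A_slow with τ_fast; the tabulated
  A_fast values (6–10%) are physically the small fast-component
  amplitudes, and the package labels amplitudes by their time constant.
- The 10 °C parameter sets carry over the 22 °C density targets and
  slow-inactivation kernels, which were not re-measured at 10 °C.
- The single-exponential fast-recovery constant at 10 °C is tabulated
  under a τ_slow heading; it is treated as the same quantity as the
  22 °C recovery τ.
- Gating-pore (omega) currents, stochastic single-channel gating and
  muscle-fiber action-potential consequences (myotonia simulation) are
  out of scope.

## Problem sizes

Default test and acceptance runs use the study protocol sizes (21-sweep
I–V, 12-sweep SSI, ~40-sweep recovery/entry curves at 10 points per
decade), cohorts of 9–10 cells and 20 replicate cohorts for coverage
checks; a full run of the suite plus the acceptance script completes in
well under a minute.
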