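# navclamp

Whole-cell voltage-clamp simulation and analysis for NaV1.4 gating
variants.

Substitutions of the R1451 arginine in the domain-IV voltage sensor of
the skeletal-muscle sodium channel NaV1.4 (R1451C, R1451L) cause a
spectrum of muscle channelopathies — paramyotonia congenita and periodic
paralyses.  Their electrophysiological fingerprint is a set of empirical
gating parameters measured by whole-cell patch clamp: Boltzmann midpoints
and slopes of steady-state activation and inactivation, exponential time
constants of fast- and slow-inactivation kinetics, peak current
densities, and Arrhenius energies of activation.  `navclamp` packages
those parameter sets (wild type, R1451C, R1451L at 22 °C and 10 °C),
an empirical forward model and protocol simulator that reproduces them,
the fitting chain that extracts them from sweep data, and the derived
statistics used to compare variants.  It is aimed at channel
biophysicists who want a testable, reproducible reference implementation
of this analysis pipeline, and at method developers who need realistic
synthetic patch-clamp cohorts with known ground truth.

## The model in brief

Steady-state activation and availability are Boltzmann functions

    G/Gmax(V)  = 1 / (1 + exp((V½ − V)/k))          (activation, k < 0 as reported)
    I/Imax(V)  = 1 / (1 + exp((V − V½)/k))          (availability, k > 0)

Fast-inactivation decay at a step potential is single-exponential with a
voltage-dependent τ_h anchored at −10 mV; recovery time courses follow

    I/Imax(t) = A_fast (1 − e^(−t/τ_fast)) [+ A_slow (1 − e^(−t/τ_slow))]

and entry into slow inactivation follows

    I/Imax(t) = y0 + A_fast e^(−t/τ_fast) + A_slow e^(−t/τ_slow).

Every time constant scales with temperature as
τ(T) = τ_ref · exp((Ea/R)(1/T − 1/T_ref)) with R = 1.987×10⁻³
kcal·mol⁻¹·K⁻¹.  The window current — the sustained open probability
where activation and availability overlap — is

    P(V) = 1/(1 + e^((V½ₐ − V)/kₐ)) · ((1 − C)/(1 + e^((V − V½ᵢ)/kᵢ)) + C)

with pedestal C = 0 (no persistent current).  See `docs/methods.md` for
assumptions and numerical choices.

## Worked example

```python
import navclamp as nv
from navclamp import protocol_engine as pe, trace_analysis as ta, derived_stats as ds

wt = nv.load_variant("WT", 22.0)
l  = nv.load_variant("R1451L", 22.0)
e_na = nv.nernst_sodium(22.0)          # +37.0 mV from 150/35 mM Na+

# simulate the I-V family and re-fit the conductance-voltage curve
iv = ta.analyze_iv(pe.run(wt, pe.build_iv(), 22.0, 120.0, e_na), 15.0, e_na)
print(round(iv["gv_fit"].v12, 4), round(iv["gv_fit"].k, 4))  # -27.5 -5.8
print(round(iv["tau_h"], 4))              # 0.46  (ms, decay at -10 mV)

# window-current fold change of the mutant
w_wt = ds.window_curve((wt.act_v12, wt.act_k), (wt.inact_v12, wt.inact_k))
w_l  = ds.window_curve((l.act_v12, l.act_k), (l.inact_v12, l.inact_k))
print(round(ds.window_fold_change(w_l, w_wt), 2))   # 7.47

# availability of the mutant at a -85 mV resting potential
print(round(nv.h_inf(-85.0, l), 3))       # 0.327 -> ~2/3 inactivated
```

The numbers printed are the fitted activation midpoint and slope (mV),
the fast-inactivation time constant at −10 mV (ms), the fold increase of
the mutant window-current area relative to wild type, and the fraction
of R1451L channels still available at a typical resting potential —
the loss-of-function signature that underlies the paralytic phenotype.

A command-line pipeline wraps the same functions:

```
navclamp simulate --seed 1 --outdir cohort/    # synthetic cells + manifest
navclamp analyze cohort/                       # per-cell fits + summary tables
navclamp compare cohort/summary.json           # shifts, reductions, window folds
navclamp report                                # desk report from packaged tables
```

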