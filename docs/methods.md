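# Methods

## The channel model

`hergkin` models the rapid delayed-rectifier potassium current I_Kr carried
by hERG (Kv11.1) channels with an Ohmic expression

    I_Kr = g_Kr · O · (V − E_K),        [µS · mV = nA]

where `g_Kr` is the maximal whole-cell conductance, `O` the open
probability, `V` the membrane voltage and `E_K` the Nernst potassium
reversal potential, E_K = (RT/zF)·ln([K]o/[K]i) with z = 1.  Gating
factorizes into a three-state activation chain and an independent
Hodgkin–Huxley availability ("h") gate describing fast C-type inactivation:

    C2a ⇌ C1a ⇌ Oa        (activation; occupancies sum to 1)
    ḣ = (h∞ − h)/τh,  h∞ = ah/(ah+bh),  τh = 1/(ah+bh)
    O = Oa · h

The six voltage-dependent transition rates are single exponentials in V,
parameterized by twelve kinetic parameters (odd-indexed prefactors in ms⁻¹,
even-indexed voltage slopes in mV⁻¹):

    a1 = p1·e^{+p2·V}   (C2a→C1a)      b1 = p3·e^{−p4·V}   (C1a→C2a)
    a2 = p9·e^{+p10·V}  (C1a→Oa)       b2 = p11·e^{−p12·V} (Oa→C1a)
    bh = p5·e^{+p6·V}   (inactivation) ah = p7·e^{−p8·V}   (recovery)

This factorized system is exactly equivalent to a six-state Markov chain on
{C2, C1, O} × {available, inactivated}, with the activation rates on the
horizontal transitions of both layers and (bh, ah) on every vertical
transition; the package carries both formulations and asserts their
equivalence numerically (`simulate_markov` exists solely as that oracle).

The sign/pairing convention above (forward rates growing with
depolarization, backward and recovery rates with hyperpolarization) is the
conventional one for this model family and is corroborated by the bundled
fitted values: it reproduces a recovery-from-inactivation time constant of
≈1.55 ms at −90 mV and an h-gate midpoint (ah = bh) of ≈ −33 mV for the WT
set, both consistent with the measured biophysics the sets were fitted to.
The four bundled parameter sets (WT, WT+RPR, R56Q, R56Q+RPR) describe
wild-type and the LQTS2-associated fast-deactivating R56Q variant, each
without and with the type I activator RPR260243, and are only meaningful
under this rate mapping.

A plausibility band constrains every rate to [10⁻⁷, 10³] ms⁻¹ over
V ∈ [−120, +60] mV during validation and inference; violations are rejected
(or penalized during optimization), never clipped.  Rate evaluation guards
the exponent at ±700 and raises a named overflow error rather than
returning infinities.

Units throughout: time ms, voltage mV, rates ms⁻¹, conductance µS, current
nA, temperature K, concentrations mM.

## Simulation

At fixed voltage the gating system is linear and time-invariant, so on step
segments (and the piecewise-constant sub-steps of sampled waveforms) the
state is propagated with the exact 2×2 matrix exponential of the reduced
activation system (spectral decomposition, with a defective-eigenvalue
branch) plus the closed-form h relaxation.  Ramp segments are integrated
with LSODA at absolute/relative tolerances of 10⁻⁸.  The integrator is
restarted at every segment boundary, so voltage discontinuities are never
smeared; the state is continuous across boundaries.  An all-ODE path
(`method="ode"`) exists as a cross-check of the exact propagator and is used
by the closed-form acceptance checks.  Default output sampling is 0.1 ms
(the 10-kHz acquisition rate of the experiments the model family targets);
each sweep starts from the steady state at the (offset-corrected) holding
potential, the infinite-hold limit of "minimum time allowing full channel
closure" between sweeps.

Outward current is positive; with E_K ≈ −93 mV a tail at −110 mV is inward.
The per-cell voltage offset enters as V = V_cmd − V_off for the channel; a
configured linear leak g_leak·(V_cmd − E_leak) sees the raw command voltage
(it is a seal property, not a membrane one).

## Voltage protocols

Built-in protocols reproduce the characterization suite: square activation
protocols (250-ms steps from −100 to +60 mV with −110 mV tails at ambient
temperature; shortened 1,500-ms steps from −50 to +40 mV with −40 mV tails
at physiological temperature), the deactivation/fully-activated-IV protocol
(+40 mV for 250 ms, 750-ms tails), the inactivation protocol (+20 mV
prepulse, 800-ms repolarizing steps from −140 to +40 mV in 30-mV steps),
premature-stimulation protocols (40-ms steps to 0 mV at coupling intervals
of −80…380 ms from 90% repolarization of a stylized action potential),
stylized-AP pacing trains, and a calibration staircase.

The stylized AP is not numerically specified by the experiments it imitates;
the default is an instantaneous upstroke to +40 mV, a 50-ms ramp to +20 mV,
and a 300-ms linear repolarization to −100 mV (APD-like duration 350 ms,
90%-repolarization anchor at 315 ms), fully user-configurable.

The staircase step table is configuration, not contract.  The bundled
default (~19 s) was designed by explicit Fisher-information analysis at the
study noise level so that all identifiable kinetic parameters of all four
bundled sets are well constrained by a single sweep: reference and
activation pulses, ascending and descending 500-ms treads over −120…+40 mV,
deactivation probes at −50/−80/−110 mV with 0-mV re-activation pulses, and a
paired-pulse "gap" block (variable-length hyperpolarized gaps followed by
brief re-depolarizations) that separates occupancy of the two closed states.
A longer table with better-conditioned slow-deactivation information was
deliberately preferred over a shorter one.

The bundled complex action-potential train (`complex_ap_synthetic.csv`,
equal to `build_complex_ap_train()`) is a synthetic stand-in: a
deterministic ~6-s sequence of action potentials of varying duration, a
premature depolarization, an EAD-like secondary depolarization and a
rapid-pacing burst.  The experimentally used waveform is figure-only and is
not reproduced.

## Synthetic three-sweep recordings

`synth` emulates the blocker-subtraction design: each synthetic cell is
"recorded" three times over the same protocol suite — control, after
activator wash-in (activator kinetics, same conductance), and after full
blocker wash-in.  The blocker sweep is modeled as complete channel block
(leak + noise only), so subtracting it from the other sweeps isolates
channel current exactly when rundown is off.  Endogenous currents are
folded into the linear leak.  Noise is iid Gaussian, white at the output
sampling rate (no anti-aliasing-filter emulation — a documented
simplification; real 4-kHz-filtered records have correlated samples, so
passing tests here do not bound the effect of noise correlation on real
data).  Kinetics are shared across cells; conductance and voltage offset
are per-cell.  The reported "measured" reversal potential is E_K + V_off,
as an experimenter reading tail-current zero crossings against command
voltage would obtain.  Optional rundown scales the conductance continuously
along the recording clock (default off; no magnitude is established for it,
and the subtraction residual it leaves is asserted, not corrected).

Study-condition defaults: three cells per construct with the reported
per-cell conductances (WT: 0.0847/0.0705/0.123 µS; R56Q:
0.0796/0.103/0.0433 µS), offsets uniform in ±2 mV, noise sd 2% of each
cell's own peak staircase current, staircase sampled at 0.1 ms, small leak
(0.005 µS to 0 mV).

## Joint inference

The noise model I_data = I_model + ε, ε ~ N(0, σ²), makes the MLE a
least-squares fit; the per-trace log-likelihood is −Σ(residual²) up to
constants, σ profiles out of the argmax and is reported post hoc from
residual variance.  Across a cohort the likelihood sums control and
activator trace terms per cell with: shared control kinetics, shared
activator kinetics, cell-specific conductances (unchanged by the activator),
and per-cell voltage offsets fixed beforehand from V_off = E_K,measured −
E_K.  For N cells the joint problem has 12 + 12 + N parameters (27 at the
three-cell design).

Numerics: prefactors are log-transformed (bounds [ln 10⁻⁷, ln 10³]), slopes
natural-scale in [0, 0.4] mV⁻¹, conductances in (0, 10] µS; the rate
plausibility band is enforced by a smooth log-distance penalty plus final
rejection.  Because the current is linear in g, each cell's conductance is
profiled in closed form during the search.  The optimizer is a multi-start
global-then-local strategy: per start, each 12-parameter condition block is
fitted with CMA-ES (own minimal implementation, `_cmaes.py`) on a
20×-subsampled grid and refined with bounded trust-region least squares on a
10×-subsampled grid; candidates additionally mix the best control and best
activator blocks across starts and cross-seed each block once from the other
block's best solution (activator kinetics are a perturbation of control
kinetics; this reliably escapes a recurring activator-side local optimum);
finally the best candidates are polished on the full-resolution joint
24+N-parameter problem with a structured Jacobian (finite differences per
condition block, analytic conductance columns).  Ten random starts
(log-uniform prefactors, uniform slopes, per-rate plausibility rejection)
are the default.  All of this is configuration; the contract is parameter
recovery on synthetic cohorts, which the acceptance suite measures.

Recovery is judged through the transition rates, the identifiable objects:
for each rate, max over V ∈ [−120, 60] mV of |ln(r̂(V)/r_true(V))|.  This
absorbs the strong anticorrelation between prefactor and slope errors and
is well defined for slopes that are statistically indistinguishable from
zero (e.g. the near-zero C1→C2 slope of the WT control set, ~10⁻⁷ mV⁻¹).

### Known structural non-identifiability

The WT+RPR set has a2, b2 prefactors of ~621 and ~210 ms⁻¹: the open ⇌ C1
transition equilibrates in microseconds, far below any realistic sampling
interval, so only the ratio a2/b2 (and the slow chain dynamics it induces)
is identifiable — the common scale of the pair is a flat likelihood ridge.
No experiment of this class can recover those two rates individually; the
acceptance suite reports the resulting error honestly rather than
restricting the comparison.  All other rates of all four sets are
identifiable under the bundled staircase at the study noise level (checked
by Fisher analysis and by recovery runs).

## Biomarkers

All fits blank the first 1 ms after each voltage step (capacitive-transient
convention kept identical for synthetic data), configurable.

* Deactivation: two-term exponential fits of tail decay with multi-start
  (8 jittered starts from log-linear initial guesses), τ ordering enforced
  by relabeling, degenerate fits flagged (amplitude ratio < 10⁻³ or τ ratio
  < 1.2).
* G–V: peak tail magnitudes normalized to the per-recording maximum, fitted
  with y = scale/(1+exp((V½−V)/k)); positive k = activation, negative k =
  inactivation.
* Whole-cell conductance: OLS slope of the fully activated I–V over
  −140…−110 mV.
* Rectification: R = I/(G·n·(V_t−E_rev)) with the activation variable n at
  +40 mV taken from the same cell's G–V Boltzmann fit; points within 5 mV of
  E_rev are masked.  Known bias: the tail-peak readout races deactivation
  against recovery at strongly negative voltages, so the fitted midpoint of
  R(V) sits depolarized (≈ −20 mV for the WT set) of the closed-form h-gate
  midpoint (≈ −33 mV); tests therefore compare against the identical
  procedure applied to noise-free open probabilities.
* Protective currents: single-exponential fits during the 40-ms premature
  step, extrapolated to the step onset (option: end of blanking), normalized
  to whole-cell conductance; non-decaying fits fall back to the in-step
  maximum and are flagged.
* AP-clamp metrics: peak outward current within the first 20 ms after the
  upstroke of the analyzed beat (Peak_transient), peak outward current over
  the remainder of the waveform (Peak_resurgent), and the command voltage at
  the resurgent peak; normalization by whole-cell conductance or peak tail
  current; ties break toward earlier times.
* Reversal potential: linear interpolation of the zero crossing of the
  instantaneous tail I–V; an error if the currents do not change sign.

### Phenotype notes

At equal conductance the simulations reproduce the qualitative biology of
deactivation-limited protection: the fast-deactivating variant passes about
half the protective current at a 100-ms coupling interval and peaks at more
negative coupling intervals; switching to activator kinetics restores the
ratio toward unity; the activator boosts the early transient current
several-fold while changing the resurgent peak by far less than two-fold.
One direction does not emerge at 1-Hz pacing of the stylized AP: after a
~650-ms diastole both WT and R56Q deactivate essentially completely, so the
next upstroke's early transient is dominated by fresh activation in both
and their ratio stays near unity rather than far below it.  The
memory-carried transient distinction requires much shorter diastoles than
the stylized waveform provides; the acceptance suite reports the measured
1-Hz ratio as is.

## Pipeline and export

`run_characterization` chains generate → subtract → fit (staircase only) →
predict the held-out activation/inactivation/complex-AP protocols →
biomarker phenotyping, writing tidy CSVs, a text summary and a manifest
with a configuration hash; fixed seeds give byte-identical tables.
Staircase-repeat quality control uses drift = RMS(first−repeat)/RMS(first)
with threshold 0.10; the pipeline removes the known synthetic noise
contribution from the drift so the check reflects instability only.
`export_model` writes the twelve parameters plus the six rate expressions
and the current equation as a self-contained JSON or plain-text description
for embedding the fitted channel in external action-potential simulators
(whole-cell AP simulation itself is out of scope).

## Problem sizes and determinism

Default test-scale problem sizes: staircase recordings of 188,500 samples
per trace (0.1-ms sampling, ~19-s protocol), three cells, two conditions →
~1.13 million residuals in the joint fit; validation protocols at 1–2 ms
sampling.  The acceptance recovery runs take a few minutes per construct on
one core.  All randomness (cohort draws, optimizer starts, noise) flows
from explicit integer seeds; repeated runs are bit-identical.

## Limitations

* White noise at the output rate; no filter, amplifier, series-resistance or
  capacitive-artifact emulation (the subtraction design the data emulate
  removed these experimentally).
* No temperature scaling of rates (separate parameter sets stand in for
  temperature/condition differences), no state-dependent drug block, no
  stochastic single-channel simulation.
* Rundown is generated (optionally) but never corrected for, matching the
  analysis limitation it emulates.
* Conclusions from passing tests are about the model and procedures, not
  about biological recordings: the generator's cells are exactly the model
  plus white noise, so recovery results bound estimator and optimizer
  error, not model misspecification.
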