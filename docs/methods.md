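# Methods

## The circuit model

The model captures the control of APC/C–CDH1 activity during exit from
quiescence as an incoherent feedforward loop. A single mitogen input `S`
drives two arms with first-order relaxation kinetics and Hill-function
couplings: a fast arm (mTOR, which phosphorylates CDH1 and thereby
inactivates the APC/C) and a delayed arm (a protein phosphatase PP that
reverses the phosphorylation). Phosphorylated CDH1 (`pCDH1`) represses
APC/C activity; geminin, a canonical APC/C substrate, integrates APC/C
activity and stands in for the degron biosensor used in live-cell
imaging.

All five state variables are dimensionless activities/levels confined to
[0, 1]; every drive term is a Hill fraction in [0, 1] and every equation
relaxes toward its drive, so the unit cube is forward-invariant. Default
parameters are the model's standard calibration (`k1=0.2, n1=1, τ_mTOR=0.5;
k2=0.2, n2=1, τ_PP=0.5; k3=0.3, n3=1, τ_pCDH1=0.5; k4=0.2, n4=2,
τ_APC=0.5; k5=0.8, n5=1; k6=0.4, n6=3, τ_GEMININ=0.3`), the default
stimulus is `S = 3`, and the phosphatase drive is held at zero until 4 h
after stimulation — the empirical delay at which control and
phosphatase-inhibited biosensor traces begin to diverge.

Time is in hours: with a 4-h phosphatase delay these τ's produce the
observed 1–6 h pulse, which pins down the unit; we document this as an
assumption.

The default initial state is the standard quiescent condition
(`mTOR=PP=pCDH1=0, APC=1, GEMININ=0`). Note `GEMININ=0` is slightly below
the quiescent fixed point `k6^n6/(k6^n6+1) ≈ 0.0602`, so even
unstimulated runs show a small initial geminin rise with timescale
`τ_GEMININ`; the convention is kept as the package
default rather than silently replaced with the fixed point.

### Perturbation scenarios

* **Rapamycin** zeroes the mTOR *drive* from the addition time; existing
  mTOR activity relaxes to zero with `τ_mTOR`. Rationale: the drug blocks
  kinase activation, it does not destroy existing activity. An
  instant-clamp variant (`rapamycin_clamp=True`), which sets the activity
  itself to zero at the addition time, is exposed for users who prefer
  the sharper abstraction.
* **Pan-phosphatase inhibitor** zeroes the PP drive from the addition
  time; with the default onset at t=0 the phosphatase arm never acts and
  APC/C inactivation becomes sustained.
* **CDH1(T129A)** (dominant-negative, non-phosphorylatable) forces the
  pCDH1 drive to zero for all time; the APC/C then never inactivates.

The phosphatase onset is a hard step; no smoothing is applied. One deliberate generalization: the PP
drive uses the *effective* mitogen level (zero before `mitogen_onset`)
rather than the raw `S`, so a hypothetical late mitogen onset cannot
produce phosphatase drive before mitogens exist. Under the default
`mitogen_onset=0` used everywhere this is identical to the
plain-`S` form of the equations.

### Numerics

`simulate()` integrates with LSODA (`scipy.integrate.solve_ivp`,
`rtol=1e-8`, `atol=1e-10`), *segmented at every drive discontinuity*
(mitogen onset, PP onset, drug additions) so the solver never steps
across a switch; within a segment the right-hand side is smooth. Output
is sampled from the dense solution onto a uniform grid (0.05 h for
model-only runs; 0.2 h — the imaging cadence — when feeding the trace
generator). Solver failure raises with the solver's diagnostic message
rather than returning truncated output.

`reference_simulate()` is an independently written fixed-step classical
RK4 integrator (default `dt=1e-4` h) sharing only the model right-hand
side. It exists to cross-check the adaptive path; across the full
scenario matrix the two agree to sup-norm ≤ 1e-4 over [0, 12] h (measured
≈ 1e-8).

`steady_state()` exploits the feedforward structure: the fixed point is
unique and obtained by forward substitution of each drive at the upstream
fixed point. It matches the t=200 h integration limit to < 1e-6.

Hill functions return exactly 0 (activating) / 1 (inhibitory) at `x=0`,
avoiding `0**n` edge cases for non-integer coefficients, and saturate
gracefully on ratio overflow.

## Synthetic single-cell traces

The generator emulates live-cell imaging of this system: epithelial
cells starved into quiescence, stimulated at t=0, imaged every 12 min
(0.2 h) for 24 h (the validation populations that only need the pulse and
its aftermath use 8–12 h windows).

Two reporter modes, because the model's GEMININ variable and the physical
biosensor are different objects:

* `model_direct` emits the model GEMININ series scaled per cell — the
  right choice for comparing population medians with model output. MG132
  cannot be represented here (the proteasome acts downstream of the
  modelled drive), and requesting it raises a configuration error.
* `reporter_mechanics` integrates `dG/dt = s − d·APC(t)·G`: constitutive
  synthesis `s` (default 1 AU/h), degradation proportional to APC/C
  activity (`d` = 1/h at full activity), initial level `s/d` (the
  quiescent quasi-steady state). APC/C activity is held piecewise-constant
  at its left-grid value within each 0.2 h sampling interval, and each
  interval is solved exactly for the linear ODE, splitting at the MG132
  time when it falls inside an interval. After MG132 the degradation term
  is zero, so the accumulation slope equals `s` exactly — the property
  the slope-ratio analytics exploit.

Heterogeneity and noise (both are package choices): per-cell synthesis and degradation scales are
lognormal with mean 1 and CV 0.15 — fluorescence scale factors are
positive and right-skewed — and measurement noise is multiplicative
Gaussian with sd 0.05 of the signal, truncated at zero. CDK2 traces are a
phenomenological saturating ramp from a quiescent level (0.5) toward a
cycling plateau (1.5) beginning at a truncated-normal onset (mean 6 h,
sd 2 h, clipped to [0, 16] h, rate 1/h); quiescent cells stay flat. These
choices reproduce the qualitative look of experimentally observed
single-cell traces;
they deliberately omit photobleaching, tracking errors, mitosis/lineage
events and background structure, so passing recovery tests demonstrates
estimator correctness under the stated noise model, not robustness to
every imaging artifact.

Randomness: one root seed; each cell's generator is an independent
substream keyed by `(seed, cell_index)` (`numpy` `SeedSequence` spawn
keys), so identical configs are byte-reproducible and growing `n_cells`
never reshuffles earlier cells.

## Trace analytics

* **Slope fits** are ordinary least squares over half-open windows
  `[start, end)` (adjacent windows partition the grid). The pre-MG132
  accumulation window defaults to [1, 5) h after stimulation — after the
  biosensor has accumulated above background but before the G1/S switch;
  the full 1–6 h interval over which the reporter transiently accumulates
  is treated as the pulse span, not the fit window. The post-MG132 window
  opens 0.5 h after MG132 (equilibration gap) and spans 2 h — a documented
  package default.
* **Percent inactivation** is `100·(1 − slope_pre/slope_post)`, the
  per-cell *paired* form (same cell before and after MG132); it is
  undefined when the post slope is not positive, which signals a failed
  MG132 reference rather than a zero. A population-mean variant can be
  assembled from the per-cell `SlopeFit`s if needed.
* **Transient vs sustained**: traces are smoothed with a 5-sample moving
  median; a trace is `none` when peak − baseline falls below
  `min_prominence` (default 3× a robust noise scale, 1.4826·MAD of first
  differences /√2), `transient` when the peak is interior and the
  terminal level has decayed to within `terminal_fraction` (default 0.5)
  of the rise, else `sustained`. The thresholds are configurable package
  defaults; on the synthetic populations they recover scenario ground
  truth essentially perfectly.
* **Median traces** are pointwise across cells on the exact shared grid
  (no interpolation; a grid mismatch is an error). For even cell counts
  the lower middle value is taken — every reported value is an observed
  one and the result is bit-reproducible.
* **Divergence time** is the earliest grid time where |a−b| ≥ ε holds for
  `sustain_points` (default 3) consecutive samples, with ε defaulting to
  5 % of the control median's dynamic range. With the default 4 h
  phosphatase onset the control/inhibitor medians diverge at 4.4–4.6 h:
  detection lags onset because the signal must propagate through the
  pCDH1 → APC/C → geminin cascade and then clear the threshold.
* **Cycling classification** calls a CDK2 trace cycling iff activity
  stays ≥ threshold (default 1.0, halfway between the quiescent level and
  plateau) for 3 consecutive samples; the sustain rule rejects
  single-sample noise spikes.

No hypothesis-testing machinery is included: the package reports
estimates and fractions, not p-values.

## Validation strategy and problem sizes

Every quantitative claim is checked against an independent oracle: the
RK4 reference for the solver, closed forms for the reporter mechanics and
steady states, long-horizon integration for fixed points, and generator
truth labels for the estimator/classifier recovery runs. Validation
populations use 100–500 cells at CV 0.15 / noise sd 0.05 over 8–24 h
windows — sizes comparable to the imaged fields of view in this kind of
experiment and large enough that binomial/OLS sampling error is well
below the asserted tolerances. The whole suite, including the acceptance
recomputation, runs in well under a minute on one CPU.

## Known limitations

* The model keeps the mTOR drive constant after stimulation; a measured
  slight rise of mTOR activity between 3 and 7 h is not modelled, and no
  model term exists for CDH1(T129D) co-expression.
* No parameter fitting to experimental traces, no stochastic
  (Langevin/Gillespie) variant, no glycolysis/PFKFB3 node.
* Trace-level emulation assumes background subtraction and illumination
  correction have already happened upstream; pixel-level effects are out
  of scope.
* The percent-inactivation statistic is reported exactly as defined by
  the slope-ratio formula; its mapping onto a mechanistic "fraction of
  APC/C molecules inhibited" holds only near the quiescent quasi-steady
  state of the reporter.
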