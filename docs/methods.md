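# Methods

## The single-bond model

A receptor–ligand bond held under constant tension F is assigned the hazard

    k(F, t) = k(F, 0) / (1 + a(F) · t)

with two parameters: the initial off-rate k(F, 0) (s⁻¹) and the bond
strengthening rate a(F) (s⁻¹). Integrating the hazard gives the survival
curve S(t) = (1 + a t)^(−k₀/a); a = 0 recovers a memoryless exponential
bond. The model is a deliberate minimal description of bond maturation: it
replaces multi-state energy-landscape kinetics (which need many rate
constants) with a single aging parameter, and it is meant for times of
order 1/k₀ — it says nothing about the millisecond-scale encounter complex.
Both parameters are assumed to depend on force exponentially (Bell form),
v(F) = v(0)·exp(σF), fitted by ordinary least squares of ln v on F. The
model is unit-agnostic: the flow-chamber path works in seconds, and a
force-free dataset in per-minute units can use the same functions with the
caller converting units.

Survival-curve fitting minimizes the mean squared difference between the
logarithms of predicted and observed survival (log-MSD) over a fixed grid
of 19 times: 0 and (1.25^i − 1)/10 for i = 1…18, i.e. log-spaced from
25 ms to 5.45 s. Log spacing weights the early, information-rich part of
the curve; grid points where the observed survival is ≤ 0 are excluded
(the log is undefined and the empirical estimate carries no usable
information there). The fit is unweighted across grid points. The
optimizer is a coarse log-spaced grid over (k₀, a) ∈ [10⁻³, 50]²
(strengthening rate 0 included) followed by Nelder–Mead refinement;
the objective is smooth and two-dimensional, so this is reliable and fast.

### Left-truncated (conditional) fitting

Arrest detection imposes a floor on observable durations (below). Fitting
the *absolute* renormalized curve is unreliable when the true curve is
steep: the linear early-count extrapolation used for renormalization
undercounts a convex early segment by up to a factor ~1.8 at the steepest
condition studied here, which scales the whole curve and biases both
parameters. `fit_bond_law(..., condition_at=floor)` therefore fits the
survival *conditional on exceeding the floor*, comparing
S(t)/S(floor) with the empirical curve of detected events on grid times
≥ floor. This removes the truncation bias entirely; the price is weaker
identifiability (see Limitations). The linear extrapolation remains the
estimator for true arrest counts and binding frequencies, matching how
flow-chamber frequencies are reported.

## Hydrodynamics

A sphere of radius a = 2250 nm held near a wall in simple shear experiences
drag F = 6πμa²·f*·G and torque Γ = 4πμa³·t*·G, with contact-limit
wall-correction constants f* = 1.7005 and t* = 0.9440 (the gap dependence
at h ≈ 25 nm is ignored; these constants reproduce the working values
0.904/0.855 pN·s and 1.62 pN to three significant figures). Torque and drag
combine into bond tension through the lever arm: T = (F + Γ/a)·√(a/2L) for
a tether of length L (68 nm for the monomeric ligand chain, 76 nm for the
dimeric one). Viscosity defaults to 1.0·10⁻³ Pa·s (aqueous buffer) and
temperature to 298 K; the thermal-force control is insensitive to ±5 K.
The unbound bead translates at u_p ≈ 0.54·a·G (1.215 µm/s per s⁻¹ with the
default radius). The freely-jointed-chain controls use stiffness
s = 3kT/(4l²) with link length l = 15 nm and mean Brownian force
⟨F⟩ = √(2skT/π) ≈ 0.19 pN, two orders below the flow forces — thermal
loading of the bond is negligible.

The tether model carries two length scales on purpose: the lever length L
enters only the tension formula, and the FJC link length enters only the
stiffness/thermal-force controls; the two are not forced to be consistent
because they parameterize different approximations of the same chain.

## Arrest observation

A bead is *arrested* when its displacement over the following 200 ms window
stays below 0.5 µm. Maximal runs of qualifying frames form events; the
apparent duration (first to last qualifying frame) underestimates the true
one, which the standard correction d_true = d_app + δt − 2δx/u_p restores.
Runs that reach the end of a record are flagged right-censored and handled
by Kaplan–Meier risk-set reduction when building survival curves.
Uncertainties are binomial per curve point, √(s(1−s)/N), and Poisson for
binding frequencies, √(N)/L.

The detection window makes arrests shorter than δt − 2δx/u_p (110–175 ms
at the shear rates studied) invisible. True arrest counts are estimated by
linear extrapolation of the surviving count over observable times ≤ 0.5 s
to time zero.

Nonspecific arrests (control beads carrying an irrelevant antibody) are
removed as a mixture component: s_spec = (s_obs − p_ns·s_ns)/(1 − p_ns),
clamped to [0, 1]. p_ns is the nonspecific share of *detected* events — in
an experiment it comes from the ratio of detected binding frequencies — so
the identity is exact on curves of detected events under a common window.

## Divalent attachment simulation

An attachment holds one or two bonds; each bond has its own age clock, and
its hazard is evaluated from the bond law at its own age (a newly formed
second bond starts unstrengthened). Three parameter sets are used: full
force, half force (from the Bell regressions evaluated at F/2), and zero
force (the Bell intercepts). Load rules:

* sharing ON — both bonds of a pair use half-force parameters; when one
  ruptures, the survivor switches to full-force parameters keeping its age;
* sharing OFF — the elder bond carries full force and the younger is
  unloaded; after any rupture the survivor carries full force, keeping its
  age.

Time is advanced in fixed steps (default dt = 1 ms): each existing bond
ruptures with probability k·dt; then, if exactly one bond existed at the
step start and survived it, a second bond forms with probability k_r·dt.
The fixed within-step order (ruptures, then rebinding) makes runs
reproducible; the ordering bias is below Monte Carlo error at dt = 1 ms,
verified by dt-halving and by agreement (within 0.003 at n = 40,000) with
the analytic three-state Markov chain when strengthening is disabled. The
scheme raises an error if k·dt ≥ 1. Survival curves average 5,000
replicates by default. k_r is load-independent and constant in time; its
force dependence is an *output* of fitting per condition, not a model
input.

k_r fitting is a grid search (log-spaced 0.05–50 s⁻¹, 25 points, one local
refinement pass between the best point's neighbours), with every candidate
simulated under a common seed and scored by log-MSD against the observed
curve. The mechanism decomposition re-simulates the all-on configuration
with force sharing off, rebinding off (k_r = 0) or strengthening off (all
a = 0), identical seed policy, and reports 5-s survival for each variant.

## Synthetic data generator

The generator emulates the study regime: three wall shear rates (10.3,
18.5, 30.9 s⁻¹) with monomer bond laws (0.519, 1.171), (1.277, 2.270),
(4.934, 6.126) s⁻¹ at tensions 8.80/15.84/26.4 pN; a detected nonspecific
fraction p_ns = 0.22; nonspecific bond laws chosen (strengthening rate
2 s⁻¹, k₀ solved) to reproduce first-500-ms mean off-rates of 2.53, 1.74
and 1.75 s⁻¹ — rates that do *not* rise with force, descriptively emulating
the catch-bond-like behaviour of nonspecific arrests without modelling it.
Default 1,000 events per condition (the order of the real per-condition
counts) and a binding frequency of 1 mm⁻¹. Specific monomer durations are
drawn by analytic inversion of the survival curve; dimer durations by the
Monte Carlo; events below the detection floor are discarded and redrawn
within their component, so mixture labels refer to detected events exactly
as p_ns does. Labels are returned separately from the arrest tables and
never enter the analysis path. Trajectories are uniform translation at u_p
with 40-nm Gaussian positional noise at 20-ms frames and planted arrests at
exponential spacing.

What the generator does **not** emulate: bead-height Brownian motion and
velocity fluctuation, pixelation/optical noise beyond Gaussian jitter,
within-slide correlation of specific and nonspecific frequencies, tether
elasticity, and any force dependence of the rebinding rate. Passing
end-to-end tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to these real-data features.

## Numerical choices

* Survival and sampling use log1p/expm1 forms, stable for a → 0; a below
  10⁻¹² is treated as exactly zero.
* Empirical curves are step functions evaluated at the last stored time ≤ t.
* fit_bell with all forces equal returns slope 0 and the geometric mean
  (defined behaviour for the force-free single-condition case).
* Degenerate inputs raise ValueError: non-positive rates, u outside (0, 1],
  negative times, p_ns ≥ 1, empty duration lists, unsorted trajectories,
  dt·rate ≥ 1.
* Problem sizes: simulation-based checks use 5,000 replicates (20,000 for
  the rebinding-recovery reference curve), matching the scale at which the
  Monte Carlo error is a few tenths of a percent of survival.

## Limitations

* (k₀, a) are strongly correlated when the early curve is hidden by the
  detection window: at the steepest condition the conditional fit's
  sampling SD is ~15% per parameter at ~1,500 events (pure specific) and
  up to ~40% after nonspecific subtraction at p_ns = 0.22. Replicated
  experiments or larger event counts are needed for tight per-condition
  estimates at high force.
* The simulator supports at most two bonds and no spatial model of
  receptor topography; force sharing is all-or-none.
* The strengthening law is empirical; its parameters should not be
  over-interpreted structurally, and extrapolation beyond ~[0, 35 pN] and
  beyond the seconds timescale is unsupported.
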