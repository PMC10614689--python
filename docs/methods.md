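# Methods

## Scientific setting

Intact IgG antibodies barely cross the blood-brain barrier (BBB).
Transcranial low-intensity focused ultrasound (FUS) with circulating
microbubbles opens the barrier transiently, letting an intravenously
injected radiolabelled antibody enter the brain for a few minutes before
the barrier reseals.  In a glioblastoma setting this enables immunoPET
imaging of PD-L1 with an anti-PD-L1 IgG1 ("C4") and an engineered
FcRn-binding-deficient (H310A/H435Q) mutant of the same antibody, whose
abolished neonatal-Fc-receptor recycling shortens its plasma half-life
and changes its transport across the barrier.

This package implements the kinetic analysis of such experiments:
fitting plasma and brain time-activity curves (TACs), comparing model
orders, and simulating dose-normalised tumour exposure.  It ships no
animal data; a synthetic-cohort generator with the study's acquisition
design provides the validation surface.

## Plasma model

A bicompartmental model with first-order elimination from the central
compartment.  After a bolus dose D the plasma concentration is

    C_p(t) = A e^(-αt) + B e^(-βt)

with hybrid rates α ≥ β the roots of λ² − (k10+k12+k21)λ + k10·k21 = 0,
A = (D/Vc)(α − k21)/(α − β), B = (D/Vc)(k21 − β)/(α − β), so that
A + B = D/Vc exactly.  Derived quantities: initial/terminal half-lives
ln2/α and ln2/β, peripheral volume Vp = Vc·k12/k21, and
AUC(0→∞) = D/(Vc·k10) by mass balance.  The repeated-root corner
(k12 = 0, k10 = k21) uses the confluent limiting form.

Image-derived whole-blood curves (left-ventricle VOI, %ID/cc) are
converted to plasma with a fixed blood:plasma ratio of 0.55 (IgG is
restricted to serum) before fitting.  Fits use frame mid-times,
weighted least squares, and seeded multistart (16 log-uniform starts in
Vc ∈ [0.5, 5] mL, rates ∈ [1e-4, 1] h⁻¹).  Each subject's plasma
parameters are frozen and reused as the input function for all of that
subject's brain regions, so regional estimates share one input.

Cohort summaries average per-subject estimates.  Note that macro
quantities are nonlinear in the micro-constants, so the mean of
individual terminal half-lives is not ln2/β evaluated at the mean
micro-constants; the package documents and tests this distinction
rather than hiding it.

## Tissue models with a transient entry window

The brain models are standard 1- and 2-tissue compartment models whose
plasma→tissue entry clearance is piecewise in time:

    k_in(t) = K_FUS  for t ≤ t_FUS   (barrier open after sonication)
    k_in(t) = K1     for t > t_FUS   (barrier resealed)

K_FUS *replaces* K1 during the window (it is not added to it): K1 is
the influx of the resealed barrier, and the open-barrier transfer is a
distinct, perfusion-dependent process.  Efflux k2 is constant — FUS
modifies entry, not clearance — and for tumour regions k3/k4 exchange
the free/non-specific pool with a specifically (PD-L1-) bound pool:

    dC_free/dt = k_in(t)·C_p − (k2 + k3)·C_free + k4·C_spec
    dC_spec/dt = k3·C_free − k4·C_spec

with zero initial conditions.  The modeled PET signal is

    C_total = (1 − vB)(C_free + C_spec) + vB·C_blood,   C_blood = 0.55·C_p.

The time origin is the injection; the ~1.7 min gap between the end of
sonication and injection is absorbed into the estimated t_FUS rather
than modelled separately.  Tissue density is taken as 1 g/cc so %ID/cc
and %ID/g are interchangeable.  Because the system is linear in dose,
fits are done in %ID units (dose = 100) and conversions to µg/mL use
the injected protein dose (activity / specific activity × 150 µg/nmol).

Two independent solution routes exist and are cross-checked to < 1e-6
relative error in the tests:

* numeric — stiff-capable adaptive integration (LSODA, rtol 1e-8,
  atol 1e-10) with a hard solver restart at t_FUS so the discontinuity
  is handled exactly;
* analytic — the 2×2 tissue rate matrix is diagonalised and each mode
  convolved with the biexponential input in closed form, piecewise
  across t_FUS.  Confluent rate collisions (k2 equal to a plasma hybrid
  rate) use the t·e^(−kt) limit; the measure-zero defective corner
  k3 = 0, k2 = k4 is broken by a relative 1e-9 nudge of k4.

The analytic route also powers estimation, where speed matters.

## Estimation

Observed frame values are compared with the *frame-averaged* model
signal (mean of C_total over each frame interval), not the mid-time
sample; frames straddling t_FUS are split at the discontinuity so the
average is exact for the piecewise-smooth curve (5-point Gauss-Legendre
per piece).  On slowly varying segments the two differ by < 0.5%, but
the early 30-s frames are far from stationary.

Weighting.  Three schemes are available: frame-duration, uniform, and
inverse-variance from the curve's reported per-frame SDs.  The default
("auto") is inverse variance whenever SDs accompany the data, falling
back to duration weights otherwise.  This choice matters: with the
PET-like heteroscedastic noise the generator produces, duration weights
are far from the efficient weighting and inflate the sampling error of
K1 and k2 several-fold in recovery experiments, while inverse-variance
weighting keeps median recovery bias near 10%.

Bounds are one order of magnitude around typical estimates
(K_FUS, K1 ∈ [0, 2] mL/h/g; t_FUS ∈ [0, 1] h; k2, k3 ∈ [0, 5] h⁻¹;
k4 ∈ [0, 1] h⁻¹; vB ∈ [0, 0.2]).  The t_FUS/K_FUS-vs-K1 separation
creates local minima, so fits use seeded multistart (32 by default; the
simulation harnesses use 8, which pilot comparisons against 64 starts
showed finds the same optima on these problems).  Standard errors come
from the local Jacobian; fits flag parameters at bounds, t_FUS at its
upper bound, and poorly constrained windows (fewer than 3 frames inside
[0, t_FUS]).

Model order is selected by the least-squares AIC,
n·ln(wSSR/n) + 2p; only ΔAIC between models fitted to identical
data/weights is meaningful.  Group statistics follow the study
conventions: two-factor ANOVA (format × region) with Bonferroni-adjusted
pairwise t-tests for tissue parameters, plain two-sample t-tests for
plasma parameters.

An identifiability caveat the package surfaces honestly: at realistic
single-subject noise, t_FUS is weakly identified — the likelihood can
prefer a long window with inflated K1/k2 (their ratio stays pinned by
the late quasi-equilibrium).  Per-subject maximum-likelihood estimates
of t_FUS are therefore heavy-tailed, and k2/K1 recovery should be
judged on cohort medians, not single fits.  A shared-t_FUS joint fit
across regions is scientifically attractive (barrier closure is a
property of the animal) but does not help when regional windows truly
differ, and is not the default.

## Synthetic cohorts

The generator emulates the study design: subject-level parameters drawn
independently per parameter from lognormals moment-matched to the
packaged cohort means/SDs (positivity without truncation); TACs are
frame-averaged model output on the acquisition schedule — 24 dynamic
frames totalling exactly 3600 s (3×30, 5×60, 5×120, 3×180, 3×240,
4×300, 1×150 s) plus five 20-min statics centred at 5, 22, 46, 70 and
168 h — with zero-mean Gaussian noise of SD = scale·√(value/Δt)
(Poisson-count heritage).  The default scale 0.05 gives late-static CVs
of ≈ 4-8% and early 30-s-frame CVs of ≈ 20-40%, the order of magnitude
of small-animal dynamic PET.  Negative noisy values are floored at zero
and the flooring rate reported (< 1% at the default scale).  Sham
subjects are generated with the entry window disabled (influx = K1 from
t = 0), not with K_FUS = K1: unsonicated animals have no open-window
phase at all.

What the generator does *not* emulate — and hence what passing recovery
tests cannot certify about real data: inter-parameter correlations
within an animal (all draws independent), partial-volume and spill-over
effects, motion, reconstruction artefacts, and any tumour growth
between injection and the late scans.

## Exposure analysis

The dose-normalised tumour simulation uses the two-tissue model at the
cohort-mean plasma and tumour ("PET-enhanced, without pre-existing
T1w-MRI contrast enhancement", i.e. intact-BBB tumour) parameters,
normalised to a 70 µg dose on a dense grid (5-s steps over the first
hour, 3-min steps to 168 h, t_FUS included exactly).  The reported PET
signal is C_free + C_spec: the vascular term is excluded from the
simulated signal, matching the decomposition into non-specific plus
specific binding (a flag re-includes it for sensitivity checks).  AUC
is trapezoidal on that grid (grid-refinement stable to < 0.1%); the
specific-binding dominance time is the earliest grid time with
C_spec > C_free, infinite when never crossed.

## Numerical and design choices

* Observation times: mid-times for plasma fits, frame averages for
  tissue fits (default, with the mid-time difference documented above).
* Multistart seeds: all randomness flows from explicit integer seeds;
  identical seeds reproduce identical datasets, fits and manifests.
* Degenerate inputs: flat blood curves and all-zero TACs are fitted but
  flagged (bound/identifiability flags) rather than silently returned.
* Problem sizes in the validation suite: recovery uses four replicate
  cohorts of n = 8 (pooled medians of per-subject signed relative
  errors; single-cohort medians are heavy-tailed, see above), ordering
  and model-selection experiments use 50 seeded replicates each.
* The harness fits with 8 multistarts (see above) to keep the full
  validation suite fast while reaching the same optima.

## Known limitations

* No population (mixed-effects) modelling; per-subject fits with cohort
  averaging only.
* Standard errors are local (Jacobian-based); no profile-likelihood or
  bootstrap intervals.
* t_FUS identifiability at single-subject noise is weak (above); real
  analyses should pool regions or animals before interpreting it.
* The exact observation equation of the original analysis (placement of
  the vascular term, blood vs plasma in it) is not published in the
  main text; the convention here (vB on whole blood, signal excluding
  the vascular term for the exposure simulation) reproduces the
  published exposure AUCs to ≈ 1%.
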