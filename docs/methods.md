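# Methods

This note documents the models implemented in `egfrptp`, the choices made
where the design was genuinely open, and what the synthetic-data studies do
and do not demonstrate.

## The EGFR-PTP reaction network

The core model (`egfrptp.reaction_models`) tracks three species at the
plasma membrane: ligandless phosphorylated EGFR monomers `[EGFRp]`,
phosphorylated ligand-bound dimers `[EGF-EGFRp]`, and the active fraction
`[PTPa]` of an ectopically expressed protein tyrosine phosphatase. With the
conservation relations (total receptor `[EGFR]_T`, total liganded receptor
`[EGF-EGFR]_T`, total phosphatase `[PTP]_T`) the dynamics are

```
d[EGFRp]/dt    = ([EGFR]_T − [EGF-EGFR]_T − [EGFRp]) ·
                 (α1·([EGFR]_T − [EGF-EGFR]_T − [EGFRp]) + α2·[EGFRp] + α3·[EGF-EGFRp])
                 − [EGFRp]·(γ·[PTPa] + [PTPe])
d[EGF-EGFRp]/dt = k5·([EGF-EGFR]_T/2 − [EGF-EGFRp]) − [EGF-EGFRp]·(γ·[PTPa] + [PTPe])
d[PTPa]/dt      = k1·([PTP]_T − [PTPa]) − k2·[PTPa]
                  − k3·[PTPa]·P + k4·([PTP]_T − [PTPa])·P
```

with `P = 2·[EGF-EGFRp] + [EGFRp]` the total phosphorylation. Phosphorylation
of ligandless monomers is autocatalytic: driven by free monomers (α1,
basal), by phosphorylated monomers (α2) and by phosphorylated liganded
dimers (α3). The aggregate endogenous phosphatase activity
`[PTPe] = c + 1/(a + b·P)` is active only when no ectopic phosphatase
dominates (`γ = 0`); with ectopic expression (`γ > 0`) it is set to zero.
Three topologies restrict the PTP coupling: *double-negative* (k3 > 0,
k4 = 0; phospho-EGFR inactivates the PTP — the toggle switch),
*negative feedback* (k3 = 0, k4 > 0; phospho-EGFR activates the PTP) and
*negative regulation* (k3 = k4 = 0; constant PTP activity).

**Units.** Time in minutes; concentrations in arbitrary units normalised to
`egfr_total = 1`. No absolute parameter values are published for this
model, so the defaults (α1 = 0.001, α2 = α3 = 1, γ = 1, k1 = 1, k2 = 0.1,
k3 = 5, k5 = 2) were chosen by numerical exploration to place the system in
the qualitative regime the biology requires: a bistable tongue in the
(PTP/EGFR expression ratio, liganded fraction) plane spanning ratios
~1.25–2.05, irreversible (the high state persists at zero ligand) below
ratio ~1.85, a reversible hysteresis window (liganded fraction ~0.03–0.07)
at ratio 1.9, and monostable behaviour past the cusp. These defaults are
fixed package constants, not fitted quantities.

**PTPN2 extension.** A slow ER phosphatase variable `[PTPN2a]` with
`d[PTPN2a]/dt = ε·(k4*·[EGFRp]·([PTPN2]_T − [PTPN2a]) − k2*·[PTPN2a])` and
an extra dephosphorylation term `γ1·[PTPN2a]` closes a delayed negative
feedback. ε = 0.005 keeps this loop roughly two orders of magnitude slower
than the phosphorylation cycle. Both phospho-species are PTPN2 substrates
by default (`ptpn2_acts_on_dimer`), with a flag to restrict it to monomers;
the published description leaves this open and the symmetric choice matches
the substrate chemistry. With γ1 = 0.6, k4* = 20, k2* = 15 the three
pulse-train regimes appear as a function of the PTP/EGFR ratio alone:
trapped at 1.35, biphasic at 1.5, tracking at 2.5 (`REGIME_RATIOS`). Below
~1.25 the resting system is pre-activated (monostable high), the state a
strong phosphatase knockdown produces.

**Numerics.** Trajectories use the implicit BDF integrator with analytic
Jacobian, rtol 1e-8 / atol 1e-10 (the extended system is stiff by
construction); inputs with declared breakpoints are integrated
segment-wise so discontinuities are never stepped over. Steady states are
found two ways: a multi-start Newton iteration on the full system
(`steady_state`, with Jacobian-eigenvalue stability labels; zero real parts
within 1e-9 are "marginal"), and a fast reduction (`steady_states_reduced`)
that exploits the fact that at steady state both phospho-species see the
same total dephosphorylation activity D — given D everything else is closed
form, so fixed points are roots of a scalar self-consistency map in D,
located by a dense scan plus Brent refinement. The test suite checks both
routes against a third, independent parametrisation (a scan over total
phosphorylation P).

**Pulse-train classification.** The published description of the three
regimes is qualitative, so the classifier uses fixed documented thresholds:
*trapped* if the terminal phosphorylated fraction exceeds 50% of the
resting upper branch; *tracking* if before every pulse the response has
returned to within 5% of baseline (relative to the peak excursion);
*biphasic* otherwise.

## Bifurcation analysis

`egfrptp.bifurcation` re-implements the continuation analysis natively:
pseudo-arclength predictor–corrector continuation of steady-state branches
(tangent from the SVD null space of the augmented Jacobian, Newton
correction orthogonal to the tangent, step halving on failure with a floor
of 1e-5 of the control range), fold detection where the control parameter
reverses along the branch (parabolic refinement through the bracketing
points), two-parameter bistability maps from fixed-point multiplicity, and
quasi-static hysteresis sweeps that follow the nearest branch adiabatically.
The PTP/EGFR "expression ratio" axis is implemented as `ptp_total/egfr_total`
scaling. Hopf/limit-cycle detection is out of scope — the network has no
oscillatory regime in the parameter ranges of interest.

## Trafficking, binding and reactivity closed forms

`egfrptp.compartment_kinetics` implements:

* **Relative PTP reactivity** `k_PTPx·[PTPx]/k_EGFR = 1/f_ptpx − 1/f_ctr`
  from paired phospho-fractions. Note the minus sign: the ectopic activity
  is the excess of the perturbed steady state over the endogenous background
  measured in control cells; the subtraction of the two steady-state
  expressions forces the difference form.
* **Two-compartment recycling**: PM fraction relaxing exponentially from
  `f0` at `t0` (default 5 min, the end of the stimulation pulse) toward
  `k_rec/(k_rec + k_in)` with rate `k_in + k_rec`.
* **Ligand-depletion binding**: the physical root of the binding quadratic,
  with the receptor-number term folded into a single molar depletion
  coefficient; it reduces to the hyperbola `L/(L + K_D)` as depletion → 0.
  Doses convert from ng/ml with a conjugate molar mass of 7381 g/mol,
  back-derived from the printed dose range equivalence (600 ng/ml = 81.29 nM).

The printed cohort-average half-life (4.32 min) is not consistent with
ln2/(k_in + k_rec) at the printed average rates (1.28 min) — a per-cell
averaging artefact; the package reports per-trace half-lives and averages
those, and no test asserts the printed half-life.

## Inference

`egfrptp.inference` provides an adaptive Metropolis–Hastings sampler
(Haario-style: random-walk proposals whose covariance is replaced, after a
warm-up of 1000 steps and every 100 steps thereafter, by the empirical
chain covariance scaled by 2.38²/d; flat priors on bounded boxes;
reproducible under a seed). Dose-response fitting pools per-cell
(liganded fraction, phosphorylated fraction) points under an iid additive
Gaussian residual model, with rate constants free on a log10 scale in
[−4, 2]: the three α's, k2, k5 and the topology coupling (k3 or k4). k5
must stay free — fixing it breaks the steady-state time-scale degeneracy
artificially and the model can then fail to fit its own curves. γ, k1,
`ptp_total` and `egfr_total` are fixed at 1 because only products with
these scales are identifiable from steady-state data. Point estimates come
from multi-start trust-region least squares; `AIC = n·ln(RSS/n) + 2k`
(Gaussian profile likelihood; small-sample AICc behind a flag); optional
MCMC around the optimum (proposal seeded with the linearised covariance)
yields credible intervals. Individual rate constants sit on a time-scale
ridge; only ratios (e.g. α2/α3) and the predicted curve are identifiable,
and the tests check exactly those.

**Topology identifiability.** Negative-feedback steady-state dose responses
are structurally near-degenerate with negative regulation on this read-out:
for every negative-feedback parameter set we examined (including strong
homeostatic clamps and mildly non-monotone curves) the negative-regulation
model family reproduces the noiseless curve to RMS < 0.003 — far below the
per-point standard error of a 20-cell cohort at 5% noise — so AIC correctly
prefers the smaller model on such data. The dynamic (trafficking-mediated)
signature of the feedback, not the steady-state curve, is what identifies
it in practice. The topology-recovery simulation study therefore generates
cohorts from the two identifiable topologies (double-negative, with its
bistable jump placed inside the sampled liganded range, and negative
regulation) while always fitting all three.

Other fitters: nonlinear least squares for K_D (internally rescaled to O(1)
because sub-nanomolar magnitudes stall bounded optimisers; CI from the
linearised covariance), per-trace recycling fits with cohort averages and
t-based CIs, and the specific-activity pipeline (Mann–Whitney gate at
p < 0.05 against control, MAD outlier removal at ±3 MAD — with MAD = 0 the
window collapses onto the median, so constant samples pass unchanged while
lone outliers are removed — exponential fit `α = c + A·e^(−k·x)` with
control cells at expression 0, activity = k·A, linear-slope fallback for
weak dependence).

## FLIM phasor global analysis

`egfrptp.flim_phasor` reduces each pixel's decay to its first-harmonic
Fourier coefficients (g, s). Phasors from raw photon arrival times are
exact in expectation (wrapping at the pulse period leaves the first
harmonic unchanged); histogram and homodyne phase-stack readers are also
provided, the latter as a least-squares sinusoid fit which handles permuted
phase orders. Calibration divides by the complex ratio measured/ideal of a
reference of known lifetime. The global analysis fits an intensity-weighted
total-least-squares line through the pixel cloud (TLS because shot noise
perturbs both coordinates), intersects it with the universal semicircle
`(g−½)² + s² = ¼` to obtain τ_D (longer) and τ_DA (shorter), and converts
each pixel's normalised projection along the chord (photon fraction f) to
the molecular FRET fraction via the relative brightness q = τ_DA/τ_D:
`α = f/(f + (1−f)·q)`, assuming equal radiative rates. Pixels under 100
photons are masked. Defaults: ω = 2π·40 MHz (TCSPC first harmonic);
2π·79.2 MHz selectable for widefield.

## Spatial-temporal maps and fold-change statistics

`egfrptp.stm` assigns every in-cell pixel the normalised radial coordinate
`r = r_PM/(r_PM + r_NM)` from Euclidean distance transforms of the cell and
nucleus masks (nucleus excluded; a nucleus touching the cell boundary is an
error). Observables are averaged in 10 half-open radial bins `[i/10,
(i+1)/10)` (last closed); ratio observables use the ratio of bin means, not
the mean of pixel ratios. Profiles are optionally divided by the whole-cell
mean, averaged across cells per time point, and stacked into maps carrying
per-bin mean/SD/n.

The phosphorylation fold change between control and perturbed maps assumes
log-normal per-bin data: batch means and SDs are converted to log-space
parameters, differenced on the orientation set by the perturbation mode
(knockdown: perturbed/control; overexpression: control/perturbed), combined
across batches by inverse-variance (Gaussian product) weighting, and tested
against zero with a one-sided Welch t-test whose degrees of freedom
propagate through Welch–Satterthwaite at both stages. The reported PFC is
the median (geometric-mean) back-transform `exp(μ)` with a log-normal
dispersion `exp(μ)·sqrt(exp(σ²)−1)`: the median makes self-comparison
identically 1 and mode inversion exact, which the mean back-transform
`exp(μ+σ²/2)` would not. Independent tests combine via the
product-of-uniforms rule `k·Σ_{i<n}(−ln k)^i/i!` with `k = Π p_i`. The
screen statistic for the FRET fraction computes per-replicate median ratios
gated by a two-sided Kolmogorov–Smirnov test; the aggregate is the mean
over significant replicates if more than half are significant, else 1.
Cells whose phosphatase expression saturates dephosphorylation are excluded
by a documented gate: predicted response sensitivity (relative to zero
expression, `(f/f_ctr)²`) below 20%.

## Synthetic data: what it emulates, what it does not

All generators (`egfrptp.synthetic_data`) are bit-reproducible under a seed
and return their ground truth. Defaults are the study conditions: 20-cell
dose-response cohorts on the printed dose series {2.5, 7.2, 16.4, 34.75,
71.6, 145.6, 294.4, 593.4} ng/ml plus an unstimulated point, K_D = 762 pM
for the dose→liganded mapping, 20% log-normal cell-to-cell scatter on rate
constants, additive Gaussian measurement noise (5% of the fraction scale),
forward dose sweeps; recycling traces on a 1-min grid over 5–35 min at
k_in = 0.31, k_rec = 0.23 per minute; FLIM pixels with exactly the
requested photon count per pixel drawn from the two-exponential mixture;
radial scenes as noisy profiles of r over elliptical masks; pulse
experiments sampled at 1-min intervals with first-order liganded-receptor
depletion (0.2/min) after each washout. The generators do not emulate
point-spread functions, bleaching, drift, segmentation errors, or
non-radial cell geometry — passing round-trip tests therefore demonstrates
correctness of the estimators under the stated statistical model, not
robustness to imaging artefacts.

## Problem sizes used by the default test run

The acceptance-level studies run at desk scale: 50 dose-response cohorts
(20 cells each) for topology recovery, 50×50 grids for the bistability
maps, 16×16-pixel FLIM fields at 10⁴ photons/pixel, 8-cell two-batch STM
cohorts on 101×101 scenes, 17 noisy replicates per pulse-train regime, and
10⁶-draw Monte-Carlo checks for the combined p-value. These sizes were
chosen so the full suite completes comfortably on a single CPU while
keeping Monte-Carlo error well inside the asserted margins.
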