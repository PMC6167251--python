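# egfrptp

Tools for analysing the collective activation dynamics of the epidermal
growth factor receptor (EGFR) and its protein tyrosine phosphatases (PTPs).

At low growth-factor doses most phosphorylated EGFR is ligandless:
liganded dimers ignite autocatalytic phosphorylation of monomers, which is
opposed by PTPs. Mutual inhibition between EGFR and a receptor-like
phosphatase (phospho-EGFR inactivates the PTP; the PTP dephosphorylates
EGFR) forms a toggle switch whose behaviour depends on where the cell sits
in the (PTP/EGFR expression ratio, liganded fraction) plane — from
irreversibly trapped activation through reversible hysteresis to graded
monostable responses. This package implements, and connects with fitting
and statistics machinery, the models used to study that system:

* **Reaction models** — the generalized EGFR–PTP ODE system with three
  coupling topologies (double-negative, negative feedback, negative
  regulation), an extension with a slow ER-phosphatase (PTPN2) feedback,
  stiff time-course simulation, steady-state solvers and pulse-train
  protocols with trapped/biphasic/tracking regime classification.
* **Bifurcation** — pseudo-arclength continuation, saddle-node (fold)
  detection, two-parameter bistability maps and quasi-static hysteresis
  sweeps.
* **Compartment kinetics** — closed forms for relative PTP reactivity from
  phospho-fractions, two-compartment receptor recycling
  (PM fraction → k_rec/(k_rec+k_in)), and equilibrium ligand binding with
  ligand depletion (K_D with a receptor-depletion correction).
* **Inference** — adaptive Metropolis–Hastings sampling, Gaussian-likelihood
  dose-response fits per topology with AIC model discrimination, K_D and
  recycling-rate least-squares fits, exponential specific-activity fits
  with a Mann–Whitney gate, MAD outlier removal.
* **FLIM phasor analysis** — per-pixel first-harmonic phasors, reference
  calibration, global lifetime pair (τ_D, τ_DA) from the line/semicircle
  intersection, per-pixel FRET fraction α by projection.
* **Spatial-temporal maps** — normalised plasma-membrane→nuclear-membrane
  radial coordinate, 10-bin radial profiles, phosphorylation fold-change
  (PFC) statistics with log-normal batch combination, combined p values,
  and the CA-FLIM screen statistic.
* **Synthetic data** — seeded generators for every input above, each
  returning its ground truth.

See `docs/methods.md` for the model equations, parameter conventions and
design choices.

## Worked example

Simulate a train of four 5-minute EGF pulses (30-minute period) with the
network organised close to the bistable region, then refit trafficking
rates from synthetic recovery traces:

```python
import numpy as np
from egfrptp.reaction_models import PulseProtocol, regime_preset, simulate_pulse_train
from egfrptp.inference import fit_recycling
from egfrptp.synthetic_data import synth_recycling_traces

traj, regime = simulate_pulse_train(regime_preset("biphasic"), PulseProtocol())
print(f"regime: {regime}; peak pEGFR {traj.pegfr.max():.3f}; "
      f"pre-pulse pEGFR {traj.pegfr[np.searchsorted(traj.times, 30.0) - 1]:.3f}")

traces, truth = synth_recycling_traces(k_in=0.31, k_rec=0.23, f0=0.2,
                                       noise_sd=0.02, n_traces=14, seed=1)
fit = fit_recycling(traces)
print(f"k_in  {fit['k_in']:.3f} /min  (truth {truth['k_in']})")
print(f"k_rec {fit['k_rec']:.3f} /min  (truth {truth['k_rec']})")
print(f"steady-state PM fraction {fit['pm_fraction_from_mean_rates']:.2f}")
```

prints

```
regime: biphasic; peak pEGFR 0.797; pre-pulse pEGFR 0.224
k_in  0.299 /min  (truth 0.31)
k_rec 0.221 /min  (truth 0.23)
steady-state PM fraction 0.42
```

The phosphorylation response peaks near 0.8 during each pulse and has only
relaxed partway (0.22) when the next pulse arrives — the biphasic signature
of a system poised near the bistable boundary. The refitted trafficking
rates recover the generating values, implying that roughly 0.4 of the
ligandless receptor pool sits at the plasma membrane at steady state.

Workflows are also exposed on the command line:

```sh
egfrptp simulate --seed 0 --out out/sim           # pulse-train trajectory
egfrptp bifurcation --seed 0 --out out/bif        # bistable region + hysteresis
egfrptp fit-dose-response --seed 0 --out out/fit  # topology fits + AIC table
```

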