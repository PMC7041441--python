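# fretbudget

**How many photons do you need to measure FRET to a given precision?**

`fretbudget` computes photon-normalized precision bounds for the two most
common quantitative FRET imaging modalities and turns them into concrete
photon budgets:

* **Three-cube sensitized-emission FRET (seFRET).** Donor-excited donor
  (I<sup>DD</sup>), donor-excited acceptor (I<sup>DA</sup>) and
  acceptor-excited acceptor (I<sup>AA</sup>) images are unmixed into the
  crosstalk-corrected signal
  cFRET = I<sup>DA</sup> − DER·I<sup>DD</sup> − AER·I<sup>AA</sup>
  and the apparent efficiencies
  dFRET = η·cFRET/(I<sup>DD</sup> + η·cFRET) (estimating f<sub>D</sub>E) and
  aFRET = ε·cFRET/I<sup>AA</sup> (estimating f<sub>A</sub>E).
  For Poisson channel counts the package computes the precision of these
  estimators analytically — by first-order error propagation, cross-checked
  against the Cramér-Rao bound from the Fisher information matrix of the
  three-parameter Poisson channel model (the two coincide because the
  plug-in estimator is the exact MLE).

* **TCSPC FLIM.** FRET quenches the donor lifetime from τ₀ to τ₀(1−E). For
  a binned, periodically excited double-exponential decay with known τ₀,
  unknown quenched-component fraction f and unknown quenched lifetime
  (optionally an unknown uniform background), the package computes the
  multinomial Cramér-Rao lower bound for Ê numerically.

All bounds are reported as the normalized precision **σ̃**, defined by
σ = σ̃·N<sub>P</sub><sup>−1/2</sup> for N<sub>P</sub> detected photons, so a
single number characterizes the photon economy of a configuration
independently of exposure. The photon budget for a target standard
deviation σ is then **N<sub>D</sub> = σ̃²/σ²**. Poisson/multinomial
Monte-Carlo simulation (replicated three-cube acquisitions, simulated decay
histograms with maximum-likelihood fitting) validates every analytic bound.

Intended users: microscopists designing FRET/FLIM assays who need to trade
off acquisition time, photodamage and biochemical resolution.

## Worked example

A sample where half the donors interact (f_D = 0.5, f_A = 1) at E = 50%,
measured on an ideal three-cube system (no crosstalk) and on a confocal
CFP-YFP system (AER = 0.60, DER = 0.42, η = 0.52, ε = 6.3):

```python
from fretbudget import (SamplePopulation, delta_sigma, photon_budget,
                        TcspcModel, make_irf, tcspc_crlb_sigma,
                        molecular_to_photon_fraction)
from fretbudget.sefret_core import SYSTEM_CONFOCAL

pop = SamplePopulation.from_fractions(efficiency=0.5, f_d=0.5, f_a=1.0)
for sys, label in [(None, "ideal"), (SYSTEM_CONFOCAL, "confocal")]:
    for which in ("dfret", "afret"):
        res = delta_sigma(pop, sys, which=which) if sys else delta_sigma(pop, which=which)
        print(f"{label:9s} {which}: sigma_tilde={res.sigma_tilde:.3f} "
              f"N_D(sigma=0.05)={photon_budget(res.sigma_tilde, 0.05)}")

model = TcspcModel(tau0_ns=3.0, rep_rate_hz=80e6, n_bins=256, irf=make_irf("dirac"))
f_ph = molecular_to_photon_fraction(0.98, 0.75)
print(f"TCSPC E=75%, 98% interacting: sigma_tilde="
      f"{tcspc_crlb_sigma(model, f_ph, 0.75).sigma_tilde:.3f}")
```

prints

```
ideal     dfret: sigma_tilde=0.530 N_D(sigma=0.05)=112
ideal     afret: sigma_tilde=1.500 N_D(sigma=0.05)=900
confocal  dfret: sigma_tilde=3.570 N_D(sigma=0.05)=5097
confocal  afret: sigma_tilde=9.457 N_D(sigma=0.05)=35777
TCSPC E=75%, 98% interacting: sigma_tilde=0.355
```

Reading: on the ideal system, ~112 detected photons suffice to pin the
apparent efficiency f_D·E = 0.25 down to ±0.05 with the donor-normalized
estimator, while the acceptor-normalized estimator needs ~900; realistic
confocal crosstalk inflates those budgets by more than an order of
magnitude. The equivalent TCSPC measurement of this high-f_D sample needs
only σ̃²/σ² ≈ 50 donor photons.

## Command line

```bash
fretbudget budget --sigma-tilde 3 --sigma 0.05          # -> 3600
fretbudget sigma-sefret --fd 0.5 --e 0.5                # single bound
fretbudget sigma-sefret --fd 0.5 --n-points 128 --out curve.csv
fretbudget sigma-tcspc --tau0-ns 3 --fd 0.98 --e 0.75
fretbudget simulate --e 0.5 --fd 0.5 --reps 10000 --seed 1
fretbudget synth-image scene.tif --e 0.4 --der 0.42 --aer 0.6 --seed 5
fretbudget unmix scene.tif --der 0.42 --aer 0.6 --out maps
fretbudget calibrate donor.tif acceptor.tif
fretbudget validate --seed 7 --reps 10000
fretbudget table1 --out cases.csv
```

Every flag can also be given in a flat YAML config (`--config run.yaml`);
explicit flags win. CSV outputs come with a JSON sidecar echoing the full
parameter set.

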