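# porcycle

Kinetic and spectroscopic analysis of the photocycle of light-dependent
protochlorophyllide oxidoreductase (POR), the enzyme that reduces
protochlorophyllide (Pchlide) to chlorophyllide using NADPH after
absorbing a photon.  The package is written for spectroscopists and enzyme
kineticists who characterize POR active-site variants and need a tested,
scriptable replacement for the usual chain of one-off analysis steps:

* **Global target analysis** of time-resolved difference-absorbance
  matrices ΔA(t, λ): compartmental photocycle models (sequential chains
  and the branched wild-type scheme), solved analytically with Gaussian
  instrument-response convolution, fitted by **variable projection** —
  the species-associated difference spectra (SADS) are the exact linear
  least-squares solution at every step of the nonlinear search over rates,
  so the optimizer only sees the kinetic parameters.
* **Preprocessing** of pump-probe data: pre-excitation background
  subtraction, spectral chirp correction, and merging of a fast
  (~1 ps–2.6 ns, 0.2 ps resolution) and a slow (~0.5 ns–2 μs, 0.5 ns
  resolution) instrument window by scaling on the ground-state bleach.
* **696 nm flash-photolysis transients**: the intermediate band at 696 nm
  reports on hydride transfer from NADPH (formation, `k_hydride`) and the
  subsequent proton transfer (decay, `k_proton`); the package fits both
  windowed single-exponential phases and the full biexponential
  intermediate time course
  `ΔA(t) = A·k₁/(k₁−k₂)·(e^(−k₂t) − e^(−k₁t))`.
* **Equilibrium and steady-state models**: tight-binding (Morrison)
  quadratic and hyperbolic K_d fits for NADPH/Pchlide titrations, and
  initial-rate k_cat from progress curves.
* A fully seeded **synthetic-data generator** standing in for the
  instruments, with every ground truth embedded in the output metadata —
  all fits can be validated end to end by parameter recovery.

The branched wild-type model routes the intramolecular charge-transfer
(ICT) excited state of Pchlide into a non-catalytic limb (60%, solvated
ICT decaying to ground/triplet) and a catalytic limb (40%, reactive ICT
converting to the 696 nm hydride-transfer intermediate, which persists in
the observation window).  See `docs/methods.md` for the model, parameter
conventions and numerical choices.

## Worked example

Simulate the wild-type ternary-complex measurement on both instrument
windows at 1% noise, merge, and fit the branched target model:

```sh
$ printf 'seed: 7\nsimulate:\n  preset: wildtype_branched\n  noise: 0.01\n' > wt.yaml
$ porcycle run wt.yaml --out wtout
{
  "fit_global": {
    "converged": true,
    "lifetimes_s": {
      "branch": 2.5221370775593297e-11,
      "intermediate_formation": 4.923013177367838e-07,
      "solvated_decay": 3.56046116923987e-09
    },
    ...
  },
  "merge": { "n_times": 214, "n_wavelengths": 64, "scale": 1.030696862749484 }
}
```

The fitted `intermediate_formation` lifetime, 492 ns, recovers the
generating 500 ns within 1.6% despite the perturbed starting guesses; the
`branch` (25 ps) and `solvated_decay` (3.5 ns) stages are likewise
recovered.  The merge scale (1.03) is the fixed factor matching the slow
window's bleach amplitude to the fast window's.

The same recovery from Python, for a single 696 nm transient:

```python
>>> from porcycle import simulate_flash_transient, fit_phase_rates
>>> from porcycle.synthetic import NoiseSpec
>>> from porcycle.transient_fit import default_windows
>>> tr = simulate_flash_transient(2.21e6, 2.72e4, 102.0,
...                               noise=NoiseSpec(0.01, seed=1, relative=True))
>>> fit = fit_phase_rates(tr, *default_windows(2.21e6, tr.times[-1]))
```

prints (via the `fit-transient` CLI, equivalently):

```
k_hydride = 2.192e+06 +/- 9.2e+03 s^-1
k_proton  = 2.731e+04 +/- 1.5e+02 s^-1
amplitude = 102.2 +/- 0.2 mAbs
```

i.e. the generating wild-type rates (2.21×10⁶ and 2.72×10⁴ s⁻¹) and the
102 mAbs plateau amplitude, each within about 1%.

Other entry points: `porcycle simulate ta|transient|titration`,
`porcycle preprocess`, `porcycle merge`, `porcycle fit-global`,
`porcycle fit-transient`, `porcycle fit-binding`, `porcycle fit-kcat`.

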