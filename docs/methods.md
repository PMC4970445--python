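# Methods

## Kinetic models

All kinetics are first-order compartmental: `dp/dt = K p`, with the column
convention `K[i, j]` (i ≠ j) the per-second flow j → i and the diagonal
the negative total outflow.  Losses to the ground state are implicit
(diagonal outflow exceeding the credited inflows); `with_ground_sink()`
routes them to an explicit terminal compartment when exact population
conservation is wanted (tests rely on this).

**Sequential chain.**  `build_sequential_scheme([τ1, …, τn])` gives the
Glotaran-style evolution model: species i decays with `1/τi` into species
i+1, and the last species decays to ground with `1/τn`.  Passing
`terminal_persists=True` (or a trailing `inf` lifetime) instead freezes
the last species for the duration of the experiment — the appropriate
model when a photoproduct outlives the observation window.

**Branched wild-type photocycle.**  After excitation, the intramolecular
charge-transfer state of Pchlide (`S_ICT`) partitions with catalytic
fraction f (default 0.4): fraction 1−f forms a solvated ICT state that is
lost to ground/triplet, fraction f forms a reactive ICT state that
converts to the 696 nm hydride-transfer intermediate `I696`, which
persists.  An explicit `ground` sink collects the non-catalytic loss.  The
branching is implemented as two outflows `f·k_branch` and
`(1−f)·k_branch` from `S_ICT`.  Only f and the ~500 ns formation lifetime
of `I696` are anchored to measurements; the remaining stage rates are
generator conventions, chosen on the timescales the two instrument
windows resolve:

| stage | default | meaning |
| --- | --- | --- |
| `branch` | 4×10¹⁰ s⁻¹ (25 ps) | partitioning out of S_ICT |
| `solvated_decay` | 2.86×10⁸ s⁻¹ (3.5 ns) | solvated-ICT loss to ground/triplet |
| `intermediate_formation` | 2×10⁶ s⁻¹ (500 ns) | reactive ICT → I696 (hydride transfer) |

`flux_fraction` integrates the entry flux into a compartment analytically
(solving `K_TT x = −p0` on the transient sub-system), so the 60/40 split
is checked exactly rather than by quadrature.

## Population solver

Populations are obtained by eigendecomposition; each eigenmode
`exp(λt)·θ(t)` convolved with a Gaussian IRF of width σ is the
exponentially modified Gaussian, evaluated in the scaled-complementary-
error-function form `0.5·erfcx(b)·exp(−Δt²/2σ²)` with
`b = −(Δt/σ + λσ)/√2`, which cannot overflow on the rising side.  For
`b < 0` (times well past the IRF) the identity
`0.5·erfcx(b)·exp(−Δt²/2σ²) = exp(λΔt + λ²σ²/2) − 0.5·erfcx(−b)·exp(−Δt²/2σ²)`
is used instead, whose leading term is the plain exponential; its exponent
is bounded above by 0 in that branch, so neither term overflows.  Complex
eigenvalues (schemes with cycles) go through the Faddeeva function.
Repeated eigenvalues are harmless when the eigenvector matrix remains
well conditioned (e.g. two independent terminal compartments); only a
*defective* rate matrix (condition number > 1e10 with coincident
eigenvalues) triggers a documented 1e-6 relative diagonal jitter with a
warning, and if that fails the solver falls back to adaptive ODE
integration (flagged in the result metadata).  The analytic solution is
verified against `solve_ivp` on 100 random schemes (rates spanning
10³–10¹² s⁻¹) to < 1e-6, and against direct quadrature of the IRF
convolution.

Merged datasets carry a per-time-point IRF width (0.2 ps for the fast
rows, 0.5 ns for the slow rows), and the solver accepts that array so one
global fit models both resolutions consistently.

## Global fitting

`fit_target` optimizes the free rates on a log scale (positivity by
construction; rates span nine decades) with trust-region-reflective least
squares.  At every objective evaluation the SADS are solved exactly by
linear least squares given the concentration matrix (variable
projection), so the returned residual is orthogonal to the span of the
concentrations by construction.  Ground-state sinks are "dark" — excluded
from the SADS solve, since a difference spectrum is zero at the ground
state by definition.  Standard errors come from the linearized covariance
of the projected residual at the optimum (`s²(JᵀJ)⁻¹` with the
finite-difference Jacobian over log-rates, delta-method back to rates and
lifetimes); a 20-replicate calibration test checks that reported errors
match the empirical spread within a factor of two.  A concentration
matrix with condition number > 1e8 at the optimum raises a degenerate-
model error naming the colliding lifetimes.  Weights are uniform per
point by default; per-time-point weights are accepted.  The 60/40 branch
fraction is fixed by default and can be freed explicitly.

`estimate_component_count` counts singular values above the analytic
noise floor `σ·(√n_t + √n_λ)` — the expected largest singular value of a
pure-noise matrix of that shape — never below the numerical rank floor
`s₁·max(n_t, n_λ)·ε`.  When σ is unknown it is replaced by a multiplier
(default 5) on the median singular value, and an optional cross-check
runs nested sequential fits, keeping an extra component only if it
improves the rmse by more than 2%.

## Transient fitting at 696 nm

The windowed method mirrors routine flash-photolysis practice: a single
exponential on each phase, decay first.  The formation-window model is
multiplied by the already-determined slow decay,
`a·(1−e^(−k(t−t0)))·e^(−k₂(t−t0))`; because the exact intermediate time
course factors as `A·k₁/(k₁−k₂)·e^(−k₂t)·(1−e^(−(k₁−k₂)t))`, this makes
the windowed estimates exact on noiseless data (`k₁ = k + k₂`) rather
than biased by the finite phase separation.  The reported amplitude is
the extrapolated plateau A (what a biexponential fit would report), not
the raw peak — the peak undershoots A by `1−(k₂/k₁)^{k₂/(k₁−k₂)}`, about
5% at the wild-type rate ratio of 81.  Default windows from a hydride-
rate guess k: formation `[t0, 5/k]`, decay `[20/k, end]`.  A formation
window without a net rise raises a phase-separation error pointing at the
biexponential method, which fits the full two-rate form directly and is
used as the cross-check (the two agree within 3% whenever k₁/k₂ ≥ 20).

## Equilibrium and steady state

Bound fraction under ligand depletion uses the Morrison tight-binding
quadratic, evaluated cancellation-free (discriminant as
`(E−L)² + 2K_d(E+L) + K_d²`, small root in rationalized form), so the
stoichiometric limit is exact to machine precision.  K_d is fitted on a
log scale with free offset and span; the hyperbolic model
`offset + s·L/(K_d+L)` serves the weak-binding regime and agrees with the
quadratic within 5% whenever E ≤ K_d/50.  k_cat is the slope of the
earliest points covering a configurable fraction (default 10%) of the
total signal change, converted through the extinction×pathlength factor
and divided by total enzyme.

The transcribed reference table (wild type + 16 variants: k_cat, both
K_d values, transfer rates, 696 nm amplitudes, with the five
photochemistry-impaired variants' rates marked not determined) is the
single source of simulation ground truths.

## Synthetic data

Difference spectra are sums of Gaussian bands; every excited compartment
carries the ground-state bleach at 642 nm (σ 12 nm, negative) plus a
broad positive excited-state absorption in the 475–560 nm region, and
`I696` carries its positive marker band at 696 nm (σ 14 nm).  Only the
642 and 696 nm centers are anchored to measured features; widths,
amplitudes and the ESA placements are documented conventions, so
spectral-shape agreement with any real dataset is explicitly not a claim
— passing recovery tests shows the *kinetic* analysis is correct, not
that the generator reproduces real POR spectra.  Other idealizations: no
spectral evolution within a compartment, no coherent artifacts around
t0, additive white Gaussian noise (default 1% of peak |ΔA|), and exact
wavelength registration between the two instrument windows.

Instrument presets: fast window, 120 log-spaced points over 1 ps–2.6 ns
(plus 6 pre-excitation points) with a 0.2 ps Gaussian IRF; slow window,
110 points over 0.5 ns–2 μs with a 0.5 ns IRF; both 64 wavelengths over
475–725 nm.  These sizes keep a full simulate→merge→fit cycle well under
a second while leaving every kinetic stage resolved by at least one
window.  The photochemistry-deficient variant preset is a three-step
sequential decay (4 ps solvation, 2 ns triplet formation, 1.5 μs triplet
relaxation) with no band near 696 nm.

Titration fixtures use 10 log-spaced ligand points over 0.05–20×K_d with
2% noise.  The macromolecule default is 10 nM: with enzyme far above K_d
the curve collapses onto the stoichiometric limit and carries almost no
K_d information (a 60-seed check at E = 100 nM showed ~24% scatter on a
21 nM K_d, versus ~8% at 10 nM), while ligand depletion at the low end of
the series still requires the quadratic model.  Pchlide-scale fixtures
(μM K_d) use 50 nM enzyme, the weak-binding regime.

## Merging fast and slow windows

The slow matrix is scaled by the ratio of mean bleach amplitudes over a
configurable band × window (defaults 630–650 nm × 0.6–2.4 ns), with the
slow band profile interpolated onto the fast sample times in log time so
unequal sampling densities do not bias the ratio; fast data win inside
the overlap, and slow points are kept beyond the last fast time.  Because
the slow instrument's 0.5 ns IRF genuinely broadens sub-ns kinetics
inside the overlap, the estimated factor on simulated wild-type data sits
~3% above 1 even without noise; this is a real property of
bleach-matching, absorbed into the fixed factor; it shifts recovered
lifetimes by about a percent, less than the statistical scatter at the
default 1% noise level.  Tests that require
exact self-consistency pass the known factor explicitly ("ideal
merging").  Chirp handling is correction-only: coefficients must be
supplied (the generator knows its own injected polynomial); estimating
chirp from solvent response is out of scope.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed and identical seeds give
bit-identical outputs.  Fits are deterministic given data and guesses.
Default problem sizes (214×64 merged matrices, 600-point transients,
10-point titrations) are chosen so the whole test suite runs in seconds;
they match the sampling density of the emulated instruments, not their
raw shot counts.

## Known limitations

No confluent closed form for exactly repeated defective eigenvalues
(jitter instead); linearized standard errors only (no profiling;
bootstrap is available for binding fits); no anisotropy, temperature
dependence, multi-wavelength flash photolysis, or lifetime-density
analysis; IRF center/width are fixed, not fitted.
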