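# Methods

## Model and assumptions

The package treats a swollen gel as a three-term thermodynamic system,
Π_tot(φ) = Π_elast + Π_mix + Π_ion, under the standard assumptions of that
decomposition: the elastic, mixing and ionic free-energy contributions are
separable and additive; the network is a Gaussian affine network so that
Π_elast = −G_s with G_s ∝ φ^(1/3); the mixing pressure is described by the
two-coefficient virial expansion (RT/V₁)(A₂φ² + A₃φ³), equivalently by the
Flory–Huggins form with concentration-independent χ₀, χ₁; and the ionic term
is ideal Donnan (unit activity coefficients, no counter-ion condensation, no
explicit electrostatics). Divalent-salt effects enter only through the
empirical dependence of A₂ and A₃ on salt concentration — shear-modulus
measurements across salt conditions show no change in cross-link density, so
no ion-bridging cross-links are modelled.

Truncation at A₃ is deliberate: higher virial coefficients are not
identifiable from deswelling data over φ ≈ 0.01–0.2, and the two-coefficient
form is what the virial-sign-inversion analysis needs. `VirialModel` is
linear in (φ², φ³) rather than a nonlinear fit of the Flory–Huggins form;
linearity makes the covariance exact and the coefficients are the quantities
of interest anyway.

## Conventions that required a decision

* **Stability of equilibria.** A root of Π_tot(φ) = 0 is classified stable
  when dΠ_tot/dφ > 0. A gel compressed slightly above φ_eq then has
  positive swelling pressure and re-swells; equivalently the osmotic modulus
  K_os = φ ∂Π/∂φ is positive, which is the thermodynamic stability
  criterion. This also guarantees M_os > 0 (with the elastic derivative
  included) at every reported stable equilibrium.
* **Longitudinal modulus.** The default is
  M_os = φ ∂Π_mix/∂φ + (4/3)G_s = (RT/V₁)(2A₂φ² + 3A₃φ³) + (4/3)G_s,
  evaluated with the exact analytic derivative of the virial mixing
  pressure; forms of this quantity in the literature are sometimes printed
  with an extra power of φ, which is dimensionally inconsistent with
  φ ∂Π/∂φ and treated here as a typographical slip. Whether the derivative
  of the *elastic* pressure belongs in φ ∂Π_sw/∂φ is ambiguous next to the
  separate (4/3)G_s term; the default keeps the mixing derivative only, and
  `include_elastic_derivative=True` adds φ ∂(−G_s)/∂φ = −G_s/3 (turning
  (4/3)G_s into G_s). Both conventions are tested.
* **Virial fits are to the virial expression.** Reports of least-squares
  fits of deswelling data occasionally cross-reference the Donnan sum; the
  object actually fitted here (and the only one that yields A₂, A₃) is the
  virial form of Π_mix.
* **Shear-modulus uncertainty.** G_s is the slope of the no-intercept
  regression of σ on (Λ − Λ⁻²) — the model is exact at zero strain, so no
  intercept is estimated. Its standard error uses the HC3 sandwich
  estimator because compression stresses carry multiplicative
  (percent-level) instrument error; a homoscedastic residual-variance
  estimate understates the uncertainty by roughly a factor two for
  realistic strain ranges. The default compression window is
  0.7 < Λ ≤ 1, the range over which the classical relation is validated;
  it is overridable.
* **Elastic scaling exponent is a report, not a constraint.** The log–log
  fit of G_s(φ) reports a p-value for the classical exponent 1/3 and a
  rejection flag; deviations at high swelling (finite chain extensibility)
  are expected, so nothing is enforced.

## Donnan solver

Ideal Donnan partitioning gives c_j^gel = c_j^sol·y^(z_j) with a single
ratio y for all mobile species. Gel electroneutrality with anionic fixed
charge c_f(φ) = f·φ/v_m (f effective charges per monomer, v_m the monomer
molar volume, default 3×10⁻⁵ m³/mol for a vinyl backbone) is a strictly
increasing scalar equation in y, solved by Brent bisection in log y to
machine tolerance. The solver reduces to the 1:1-salt closed form
Π_ion = RT(√(c_f² + 4c_s²) − 2c_s) to ~1e−14 relative, and to the
counter-ion ideal-gas limit RT·c_f as c_s → 0. Mixed NaCl/CaCl₂ baths are
supported through the generic valence sum.

## Equilibrium swelling and volume transition

Roots of Π_tot(φ) = 0 are located by a sign-change scan on a 400-node
log-spaced grid over [1e−4, 0.99] (equilibrium swelling degrees span
decades, so a linear grid would waste resolution), refined by Brent's method
to relative tolerance ~1e−12. No root is reported as an empty list with a
"fully swollen / no equilibrium" meaning, not an exception — a network-free
model with repulsive virials genuinely has no finite equilibrium.

The transition scan follows the swollen branch by continuation: at each
control value (salt concentration or temperature) the stable root nearest
the previous branch point in log φ is selected. A transition is declared
where the branch disappears or the swelling degree 1/φ drops by more than a
threshold factor (default 2) between adjacent grid points; with a model
factory available the critical control value is refined by bisection on the
branch-loss condition to 1e−3 relative. Hysteresis is not modelled beyond
this one-directional continuation.

## SANS fitting

The two-component intensity model is fitted by bounded Levenberg–Marquardt
(lmfit), with weights 1/dI when uncertainties are present, otherwise
log-space residuals (uniform relative weighting). All parameters are bounded
nonnegative and the power-law exponent is restricted to m ∈ [2, 5], the
physically meaningful surface-scattering range. Initial guesses are derived
deterministically from the data — plateau level from the upper-q half,
power-law slope from the lowest-q points, crossover length from the
geometric mid-q — and a small multistart grid (amplitude ×{1,3}, slope
variants) protects against local minima; the best χ² start wins, and
per-start diagnostics are attached to any total failure. Fits are
reproducible by construction. Instrumental resolution smearing is not
modelled: profiles are assumed fully reduced.

The osmotic amplitude is defined in exactly one place:
I₀ = Δρ²·k_BT·φ²/M_os, with Δρ² in cm⁻⁴, k_BT in J and M_os in Pa, giving
cm⁻¹ through the 10⁶ cm³/m³ factor. The consistency check compares the
fitted and osmotic amplitudes symmetrically, passing iff
|log(ratio)| ≤ log(1 + tolerance) with a default tolerance of 0.5
(factor 1.5), the level at which macroscopic osmotic measurements and
absolute-calibrated SANS can be expected to agree.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure of the three experiment
types: deswelling curves on a 15-point log grid over φ = 0.01–0.2 with 5%
relative Gaussian noise (the stated repeatability of swelling-pressure
measurements); compression series over 0.7 < Λ < 1; SANS profiles on 60
log-spaced points over the instrument range q = 0.003–0.15 Å⁻¹. Scenario
sweeps use affine laws A_i(x) = a + b·x in the control variable — the
minimal family reproducing both the near-linear A₂(T) of neutral gels and
the monotone A₃(c) collapse of polyelectrolytes. Defaults: elastic
reference C = 10 kPa at φ_ref = 0.05 (typical of the measured moduli);
polyelectrolyte preset A₂ = 0.05 − 0.005c, A₃ = 0.3 − 0.36c over
c = 0–2 mM CaCl₂, placing the A₃ zero crossing at 0.83 mM and the branch
collapse at 1.80 mM; neutral preset A₂ = 0.252 − 0.0008·T over 290–320 K
(sign change inside the grid) with A₃ = 0.05 fixed; bottlebrush preset
keeps A₃ > 0 throughout. Preset validation rejects law/preset
combinations that break these signatures.

Randomness is split per operation: each generator draws from
`SeedSequence(seed, spawn_key=(stream_id, index))` with fixed stream ids,
so adding one generator call never perturbs the draws of another, and
identical configurations are byte-identical.

What the generators do **not** emulate: instrument smearing, incoherent
background, correlated noise, gel-to-gel preparation variability,
concentration-dependent χ parameters, counter-ion condensation, or the
kinetics of swelling. Passing round-trip tests therefore demonstrates the
correctness and statistical calibration of the estimators under the stated
noise model, not robustness to systematic errors real instruments add.

## Degenerate inputs and edge cases

Readers reject malformed tables with line numbers rather than coercing;
unsorted q is an error unless sorting is requested. Fits require minimum
information (≥3 distinct φ for virials, ≥8 points spanning a q decade for
SANS, ≥2 compression points with at least one Λ ≠ 1) and raise on
rank-deficient designs. All-zero mixing pressures yield A₂ = A₃ = 0 with
zero residual. Negative Π_mix after decomposition is allowed — it is
physical near collapse.

## Known limitations

* The fixed-charge fraction per monomer is a user parameter; it is not
  derivable from synthesis conditions within the package.
* The two-coefficient virial form cannot represent re-entrant behaviour at
  high φ (the ln(1−φ) repulsion is truncated away), so collapsed-branch
  equilibria are outside its domain; the transition is detected as branch
  loss, not as coexistence.
* Absolute-scale comparison of fitted SANS parameters to specific published
  gel profiles requires the contrast factor and per-sample parameters,
  which must be supplied by the user; the built-in consistency scenario is
  synthetic and self-consistent by construction.
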