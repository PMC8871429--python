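"""Thermodynamics of gel swelling: mixing, ionic and elastic osmotic pressures.

The swelling pressure of a gel is treated as the sum of three contributions,

    Pi_tot(phi) = Pi_elast + Pi_mix + Pi_ion,

where ``phi`` is the polymer volume fraction.  The mixing term is modelled
either by the Flory-Huggins expression or by its virial expansion

    Pi_mix = (RT/V1) (A2 phi^2 + A3 phi^3),

with dimensionless second and third osmotic virial coefficients ``A2`` and
``A3`` and solvent molar volume ``V1``.  The elastic term follows classical
rubber elasticity, Pi_elast = -G_s with G_s ∝ phi^(1/3), and the ionic term
is the ideal Donnan pressure of mobile ions partitioned between gel and bath.

The module provides the forward model (:class:`GelModel`), the inverse
problem (:class:`VirialModel` / :class:`VirialResults`, statsmodels-style),
the Donnan solver, equilibrium-swelling root finding and the detection of
salt- or temperature-induced volume transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import constants as _const
from scipy.optimize import brentq

__all__ = [
    "SolventSpec",
    "WATER_25C",
    "OsmoticCurve",
    "ChiParameters",
    "IonicCondition",
    "GelModel",
    "VirialModel",
    "VirialResults",
    "EquilibriumRoot",
    "TransitionResult",
    "mixing_pressure_virial",
    "mixing_pressure_flory_huggins",
    "chi_to_virial",
    "virial_to_chi",
    "donnan_pressure",
    "decompose_swelling_pressure",
    "fit_virial_coefficients",
    "swelling_pressure",
    "solve_equilibrium_swelling",
    "longitudinal_modulus",
    "detect_volume_transition",
]

R_GAS = _const.R          # J / (mol K)
K_BOLTZMANN = _const.k    # J / K


@dataclass(frozen=True)
class SolventSpec:
    """Solvent and temperature defining the osmotic pressure scale RT/V1.

    Parameters
    ----------
    V1 : float
        Molar volume of the solvent in m^3/mol.
    T : float
        Absolute temperature in K.
    """

    V1: float = 1.805e-5
    T: float = 298.15

    def __post_init__(self) -> None:
        if self.V1 <= 0:
            raise ValueError(f"V1 must be positive, got {self.V1}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")

    @property
    def pressure_scale(self) -> float:
        """RT/V1 in Pa — the natural unit of the mixing pressure."""
        return R_GAS * self.T / self.V1

    @property
    def kT(self) -> float:
        """Thermal energy k_B T in J."""
        return K_BOLTZMANN * self.T


#: Water at 25 degC (V1 = 1.805e-5 m^3/mol).
WATER_25C = SolventSpec()

_PRESSURE_KINDS = ("total", "swelling", "mixing")


@dataclass
class OsmoticCurve:
    """One deswelling series: polymer volume fraction vs osmotic pressure.

    ``pressure_kind`` distinguishes the raw swelling pressure ("total" or the
    synonymous "swelling") from the mixing contribution obtained after
    subtracting the elastic and ionic terms.
    """

    phi: np.ndarray
    pressure: np.ndarray
    pressure_kind: str = "total"
    condition: dict = field(default_factory=dict)
    uncertainty: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.pressure_kind not in _PRESSURE_KINDS:
            raise ValueError(
                f"pressure_kind must be one of {_PRESSURE_KINDS}, got {self.pressure_kind!r}"
            )
        if self.phi.shape != self.pressure.shape:
            raise ValueError("phi and pressure must have the same shape")
        if np.any(self.phi <= 0) or np.any(self.phi >= 1):
            raise ValueError("volume fractions must lie strictly in (0, 1)")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.shape != self.phi.shape:
                raise ValueError("uncertainty must match phi in shape")
            if np.any(self.uncertainty < 0):
                raise ValueError("uncertainties must be nonnegative")

    def __len__(self) -> int:
        return self.phi.size


@dataclass(frozen=True)
class ChiParameters:
    """Flory interaction parameters chi0 (phi^2 term) and chi1 (phi^3 term)."""

    chi0: float
    chi1: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.chi0) and math.isfinite(self.chi1)):
            raise ValueError("chi parameters must be finite")


def _validate_phi(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise ValueError("phi must lie strictly in (0, 1)")
    return phi


def mixing_pressure_virial(phi, A2: float, A3: float,
                           solvent: SolventSpec = WATER_25C):
    """Virial form of the mixing pressure, (RT/V1)(A2 phi^2 + A3 phi^3), in Pa."""
    phi = _validate_phi(phi)
    return solvent.pressure_scale * (A2 * phi**2 + A3 * phi**3)


def mixing_pressure_flory_huggins(phi, chi: ChiParameters,
                                  solvent: SolventSpec = WATER_25C):
    """Flory-Huggins mixing pressure, -(RT/V1)[ln(1-phi) + phi + chi0 phi^2 + chi1 phi^3]."""
    phi = _validate_phi(phi)
    return -solvent.pressure_scale * (
        np.log1p(-phi) + phi + chi.chi0 * phi**2 + chi.chi1 * phi**3
    )


def chi_to_virial(chi: ChiParameters) -> tuple[float, float]:
    """Map Flory parameters to osmotic virial coefficients.

    Expanding -ln(1-phi) - phi = phi^2/2 + phi^3/3 + ... gives
    A2 = 1/2 - chi0 and A3 = 1/3 - chi1.
    """
    return 0.5 - chi.chi0, 1.0 / 3.0 - chi.chi1


def virial_to_chi(A2: float, A3: float) -> ChiParameters:
    """Inverse of :func:`chi_to_virial`."""
    return ChiParameters(chi0=0.5 - A2, chi1=1.0 / 3.0 - A3)


# ---------------------------------------------------------------------------
# Ionic (Donnan) pressure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonicCondition:
    """External salt composition and fixed-charge density of the network.

    ``salt_external`` lists mobile-ion species as (label, valence, bath
    concentration in mol/m^3); the bath must be electroneutral.  The fixed
    charge on the network is anionic (carboxylate, sulfonate, phosphate) with
    ``fixed_charge_per_monomer`` effective charges per monomer; its molar
    concentration at volume fraction phi is

        c_f(phi) = fixed_charge_per_monomer * phi / monomer_molar_volume.
    """

    salt_external: tuple  # of (label, z, c_sol [mol/m^3])
    fixed_charge_per_monomer: float = 0.0
    monomer_molar_volume: float = 3.0e-5  # m^3/mol, generic vinyl monomer

    def __post_init__(self) -> None:
        salts = tuple((str(lbl), int(z), float(c)) for lbl, z, c in self.salt_external)
        object.__setattr__(self, "salt_external", salts)
        for lbl, z, c in salts:
            if c < 0:
                raise ValueError(f"negative concentration for ion {lbl!r}")
            if z == 0:
                raise ValueError(f"ion {lbl!r} has zero valence")
        net = sum(z * c for _, z, c in salts)
        tot = sum(abs(z) * c for _, z, c in salts)
        if tot > 0 and abs(net) > 1e-9 * tot:
            raise ValueError(
                f"external solution is not electroneutral (net charge {net} mol/m^3)"
            )
        if self.fixed_charge_per_monomer < 0:
            raise ValueError("fixed_charge_per_monomer must be >= 0")
        if self.monomer_molar_volume <= 0:
            raise ValueError("monomer_molar_volume must be positive")

    @classmethod
    def from_salts(cls, c_nacl: float = 0.0, c_cacl2: float = 0.0,
                   fixed_charge_per_monomer: float = 0.0,
                   monomer_molar_volume: float = 3.0e-5) -> "IonicCondition":
        """Convenience constructor for NaCl + CaCl2 baths (mol/m^3 == mM)."""
        salts = []
        if c_nacl > 0 or c_cacl2 > 0:
            salts = [
                ("Na+", +1, c_nacl),
                ("Ca2+", +2, c_cacl2),
                ("Cl-", -1, c_nacl + 2.0 * c_cacl2),
            ]
        return cls(tuple(salts), fixed_charge_per_monomer, monomer_molar_volume)

    def fixed_charge_concentration(self, phi) -> np.ndarray:
        return self.fixed_charge_per_monomer * np.asarray(phi, float) / self.monomer_molar_volume


def _donnan_ratio(ions: IonicCondition, c_f: float) -> float:
    """Solve gel electroneutrality for the Donnan ratio y.

    Ideal Donnan partitioning gives c_j^gel = c_j^sol * y^(z_j) for every
    mobile species with a single ratio y (equal salt chemical potentials).
    Gel electroneutrality with anionic fixed charge c_f reads

        g(y) = sum_j z_j c_j^sol y^(z_j) - c_f = 0.

    g is strictly increasing in y, so the root is unique.
    """
    salts = ions.salt_external
    if not salts or all(c == 0 for _, _, c in salts):
        if c_f > 0:
            raise ValueError("fixed charge present but no mobile ions to neutralise it")
        return 1.0

    def g(log_y: float) -> float:
        y = math.exp(log_y)
        return sum(z * c * y**z for _, z, c in salts) - c_f

    lo, hi = 0.0, 0.0
    step = 1.0
    while g(lo) > 0:
        lo -= step
        step *= 2
        if lo < -700:  # pragma: no cover - defensive
            raise ArithmeticError("Donnan ratio bracketing failed (lo)")
    step = 1.0
    while g(hi) < 0:
        hi += step
        step *= 2
        if hi > 700:  # pragma: no cover - defensive
            raise ArithmeticError("Donnan ratio bracketing failed (hi)")
    if lo == hi:
        return math.exp(lo)
    log_y = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    return math.exp(log_y)


def donnan_pressure(phi, ions: Optional[IonicCondition],
                    solvent: SolventSpec = WATER_25C):
    """Ideal Donnan osmotic pressure Pi_ion = RT * sum_j (c_j^gel - c_j^sol), Pa.

    Vectorised over ``phi``.  With no fixed charge every ion partitions
    equally and the pressure vanishes; in the salt-free limit the counter-ions
    behave as an ideal gas, Pi_ion -> RT * c_f(phi).
    """
    phi = _validate_phi(phi)
    scalar = phi.ndim == 0
    phi = np.atleast_1d(phi)
    if ions is None:
        out = np.zeros_like(phi)
        return float(out[0]) if scalar else out
    rt = R_GAS * solvent.T
    c_sol_total = sum(c for _, _, c in ions.salt_external)
    out = np.empty_like(phi)
    for i, p in enumerate(phi):
        c_f = float(ions.fixed_charge_concentration(p))
        if not ions.salt_external or all(c == 0 for _, _, c in ions.salt_external):
            out[i] = rt * c_f  # pure counter-ion ideal-gas pressure
            continue
        y = _donnan_ratio(ions, c_f)
        # Electroneutrality sum_j z_j c_j^gel = c_f already places the mobile
        # counter-ions of the fixed charge inside the y-weighted sum.
        c_gel_total = sum(c * y**z for _, z, c in ions.salt_external)
        out[i] = rt * (c_gel_total - c_sol_total)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Forward gel model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumRoot:
    """A root of Pi_tot(phi) = 0 with its stability classification."""

    phi: float
    stable: bool
    dPi_dphi: float

    @property
    def swelling_degree(self) -> float:
        return 1.0 / self.phi


@dataclass(frozen=True)
class GelModel:
    """Forward model Pi_tot(phi) = Pi_mix + Pi_elast + Pi_ion for one gel.

    Parameters
    ----------
    A2, A3 : float
        Dimensionless osmotic virial coefficients of the mixing pressure.
    elastic_C : float
        Shear modulus (Pa) at the reference volume fraction ``phi_ref``;
        the modulus scales as G_s(phi) = C (phi/phi_ref)^(1/3) and enters
        the swelling pressure as Pi_elast = -G_s.
    phi_ref : float
        Reference volume fraction of the elastic scaling law.
    ions : IonicCondition, optional
        Mobile-ion composition; omit for neutral gels or salt-dominated
        conditions where the Donnan term is negligible.
    solvent : SolventSpec
        Sets the RT/V1 pressure scale.
    """

    A2: float
    A3: float
    elastic_C: float = 0.0
    phi_ref: float = 0.05
    ions: Optional[IonicCondition] = None
    solvent: SolventSpec = WATER_25C

    def __post_init__(self) -> None:
        if self.elastic_C < 0:
            raise ValueError("elastic_C must be >= 0")
        if not (0 < self.phi_ref < 1):
            raise ValueError("phi_ref must lie in (0, 1)")

    def shear_modulus(self, phi):
        phi = _validate_phi(phi)
        return self.elastic_C * (phi / self.phi_ref) ** (1.0 / 3.0)

    def mixing_pressure(self, phi):
        return mixing_pressure_virial(phi, self.A2, self.A3, self.solvent)

    def elastic_pressure(self, phi):
        return -self.shear_modulus(phi)

    def ionic_pressure(self, phi):
        return donnan_pressure(phi, self.ions, self.solvent)

    def swelling_pressure(self, phi):
        return (self.mixing_pressure(phi) + self.elastic_pressure(phi)
                + self.ionic_pressure(phi))

    def longitudinal_modulus(self, phi, include_elastic_derivative: bool = False):
        return longitudinal_modulus(phi, (self.A2, self.A3), self.shear_modulus(phi),
                                    self.solvent,
                                    include_elastic_derivative=include_elastic_derivative)

    def equilibrium(self, phi_min: float = 1e-4, phi_max: float = 0.99,
                    n_grid: int = 400) -> list[EquilibriumRoot]:
        return solve_equilibrium_swelling(self, phi_min=phi_min, phi_max=phi_max,
                                          n_grid=n_grid)


def swelling_pressure(phi, model: GelModel):
    """Total swelling pressure Pi_tot(phi) of ``model`` in Pa."""
    return model.swelling_pressure(phi)


def elasticity_scaling_modulus(phi, C: float, phi_ref: float):
    """Rubber-elasticity modulus scaling G_s(phi) = C (phi/phi_ref)^(1/3), Pa."""
    phi = _validate_phi(phi)
    return C * (phi / phi_ref) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Decomposition and virial fitting
# ---------------------------------------------------------------------------

def decompose_swelling_pressure(curve: OsmoticCurve, G_s,
                                ions: Optional[IonicCondition] = None,
                                solvent: SolventSpec = WATER_25C) -> OsmoticCurve:
    """Extract the mixing pressure from a measured swelling-pressure curve.

    Pi_mix(phi_i) = Pi_tot(phi_i) + G_s(phi_i) - Pi_ion(phi_i).

    Parameters
    ----------
    curve : OsmoticCurve
        Measured series with ``pressure_kind`` "total" (or "swelling").
    G_s : float, array_like, callable or (C, phi_ref) tuple
        Shear modulus per point: a scalar applied to every point, an array
        matching the curve, a callable G_s(phi), or the elastic scaling law
        as a (C, phi_ref) pair.
    ions : IonicCondition, optional
        If given, the ideal Donnan pressure is subtracted as well.
    """
    if curve.pressure_kind not in ("total", "swelling"):
        raise ValueError(
            f"expected a total/swelling-pressure curve, got {curve.pressure_kind!r}"
        )
    phi = curve.phi
    if G_s is None:
        raise ValueError("shear modulus G_s is required for decomposition")
    if callable(G_s):
        g = np.asarray(G_s(phi), dtype=float)
        provenance = "callable"
    elif isinstance(G_s, tuple) and len(G_s) == 2 and np.isscalar(G_s[0]):
        C, phi_ref = G_s
        g = elasticity_scaling_modulus(phi, float(C), float(phi_ref))
        provenance = f"scaling(C={float(C):g} Pa, phi_ref={float(phi_ref):g})"
    else:
        g = np.broadcast_to(np.asarray(G_s, dtype=float), phi.shape).copy()
        provenance = "per-point"
    pi_ion = donnan_pressure(phi, ions, solvent) if ions is not None else np.zeros_like(phi)
    mixing = curve.pressure + g - pi_ion
    meta = dict(curve.metadata)
    meta["decomposition"] = {
        "G_s": provenance,
        "ionic": "donnan" if ions is not None else "none",
    }
    return OsmoticCurve(
        phi=phi.copy(), pressure=mixing, pressure_kind="mixing",
        condition=dict(curve.condition),
        uncertainty=None if curve.uncertainty is None else curve.uncertainty.copy(),
        metadata=meta,
    )


class VirialModel:
    """Weighted linear model for the osmotic virial coefficients.

    The reduced mixing pressure Pi_mix V1/(RT) is regressed on the basis
    (phi^2, phi^3) with no intercept; the coefficients are A2 and A3.
    Weights come from the curve's uncertainty column when present
    (1/sigma^2), otherwise the fit is unweighted.
    """

    def __init__(self, curve: OsmoticCurve, solvent: SolventSpec = WATER_25C):
        if curve.pressure_kind != "mixing":
            raise ValueError("VirialModel expects a mixing-pressure curve; "
                             "use decompose_swelling_pressure first")
        if len(curve) < 3:
            raise ValueError("need at least 3 points to fit (A2, A3)")
        if np.unique(curve.phi).size < 2:
            raise ValueError("rank-deficient design: all phi values equal")
        self.curve = curve
        self.solvent = solvent

    @classmethod
    def from_dataframe(cls, df, phi_col: str = "phi", pressure_col: str = "pressure_Pa",
                       uncertainty_col: Optional[str] = "uncertainty_Pa",
                       solvent: SolventSpec = WATER_25C) -> "VirialModel":
        unc = None
        if uncertainty_col is not None and uncertainty_col in df:
            unc = df[uncertainty_col].to_numpy(dtype=float)
        curve = OsmoticCurve(df[phi_col].to_numpy(dtype=float),
                             df[pressure_col].to_numpy(dtype=float),
                             pressure_kind="mixing", uncertainty=unc)
        return cls(curve, solvent=solvent)

    def fit(self) -> "VirialResults":
        phi = self.curve.phi
        scale = self.solvent.pressure_scale
        y = self.curve.pressure / scale
        X = np.column_stack([phi**2, phi**3])
        if self.curve.uncertainty is not None and np.all(self.curve.uncertainty > 0):
            sigma = self.curve.uncertainty / scale
            w = 1.0 / sigma
            Xw, yw = X * w[:, None], y * w
            known_sigma = True
        else:
            Xw, yw = X, y
            known_sigma = False
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < 2:
            raise np.linalg.LinAlgError("rank-deficient virial design matrix")
        resid = y - X @ beta
        n, p = len(y), 2
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        if known_sigma:
            # Uncertainties supplied: covariance in reduced units is (X' W X)^-1.
            cov = xtx_inv
        else:
            dof = max(n - p, 1)
            s2 = float(resid @ resid) / dof
            cov = xtx_inv * s2
        return VirialResults(
            A2=float(beta[0]), A3=float(beta[1]), cov_params=cov,
            scale=scale, n_points=n,
            residual_rms=float(np.sqrt(np.mean((resid * scale) ** 2))),
            model=self,
        )


@dataclass
class VirialResults:
    """Fitted osmotic virial coefficients and their uncertainties.

    ``cov_params`` is the 2x2 covariance of (A2, A3) in the dimensionless
    reduced-pressure units; ``scale`` is RT/V1 in Pa.
    """

    A2: float
    A3: float
    cov_params: np.ndarray
    scale: float
    n_points: int
    residual_rms: float
    model: Optional[VirialModel] = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.A2, self.A3])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (A2, A3)."""
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        p = self.params
        return np.column_stack([p - z * se, p + z * se])

    def predict(self, phi) -> np.ndarray:
        phi = _validate_phi(np.asarray(phi, float))
        return self.scale * (self.A2 * phi**2 + self.A3 * phi**3)

    def summary(self) -> str:
        se = self.bse
        ci = self.conf_int()
        lines = [
            "Osmotic virial fit  Pi_mix = (RT/V1)(A2 phi^2 + A3 phi^3)",
            f"  pressure scale RT/V1 : {self.scale:.4e} Pa",
            f"  n points             : {self.n_points}",
            f"  residual rms         : {self.residual_rms:.4g} Pa",
            f"  A2 = {self.A2:+.5g}  (se {se[0]:.2g}, 95% CI [{ci[0,0]:+.4g}, {ci[0,1]:+.4g}])",
            f"  A3 = {self.A3:+.5g}  (se {se[1]:.2g}, 95% CI [{ci[1,0]:+.4g}, {ci[1,1]:+.4g}])",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "A2": self.A2, "A3": self.A3,
            "cov_params": np.asarray(self.cov_params).tolist(),
            "scale_Pa": self.scale, "n_points": self.n_points,
            "residual_rms_Pa": self.residual_rms,
        }


def fit_virial_coefficients(curve: OsmoticCurve,
                            solvent: SolventSpec = WATER_25C) -> VirialResults:
    """Fit (A2, A3) to a mixing-pressure curve; see :class:`VirialModel`."""
    return VirialModel(curve, solvent=solvent).fit()


# ---------------------------------------------------------------------------
# Equilibrium swelling and volume transition
# ---------------------------------------------------------------------------

def _dpi_dphi(model: GelModel, phi: float) -> float:
    h = 1e-6 * phi
    lo = max(phi - h, 1e-12)
    hi = min(phi + h, 1.0 - 1e-12)
    return float((model.swelling_pressure(hi) - model.swelling_pressure(lo)) / (hi - lo))


def solve_equilibrium_swelling(model: GelModel, phi_min: float = 1e-4,
                               phi_max: float = 0.99,
                               n_grid: int = 400) -> list[EquilibriumRoot]:
    """All roots of Pi_tot(phi) = 0 on [phi_min, phi_max].

    A sign-change scan on a log-spaced grid (equilibria span decades of
    swelling degree) is refined by Brent bisection to relative tolerance
    ~1e-12 in phi.  Roots are classified stable when dPi_tot/dphi > 0
    (equivalently K_os = phi dPi/dphi > 0: a gel compressed above phi_eq has
    positive swelling pressure and re-swells).  An empty list means the gel
    has no equilibrium in range (e.g. it swells without bound when the
    network is absent and A2, A3 > 0).
    """
    if not (0 < phi_min < phi_max < 1):
        raise ValueError("need 0 < phi_min < phi_max < 1")
    grid = np.logspace(np.log10(phi_min), np.log10(phi_max), n_grid)
    f = np.asarray(model.swelling_pressure(grid), dtype=float)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = f[i], f[i + 1]
        if fa == 0.0:
            if not roots or abs(a - roots[-1]) > 1e-12 * a:
                roots.append(float(a))
            continue
        if fa * fb < 0:
            r = brentq(lambda p: float(model.swelling_pressure(p)), a, b,
                       xtol=1e-300, rtol=1e-12, maxiter=200)
            roots.append(float(r))
    if len(f) and f[-1] == 0.0:
        roots.append(float(grid[-1]))
    out = []
    for r in roots:
        d = _dpi_dphi(model, r)
        out.append(EquilibriumRoot(phi=r, stable=d > 0, dPi_dphi=d))
    return out


def longitudinal_modulus(phi, virials, G_s, solvent: SolventSpec = WATER_25C,
                         include_elastic_derivative: bool = False):
    """Longitudinal osmotic modulus M_os in Pa.

    Default convention:

        M_os = phi dPi_mix/dphi + (4/3) G_s
             = (RT/V1)(2 A2 phi^2 + 3 A3 phi^3) + (4/3) G_s,

    the analytic derivative of the virial mixing pressure plus the shear
    contribution.  With ``include_elastic_derivative=True`` the derivative of
    the elastic pressure is kept as well: phi d(-G_s(phi))/dphi = -G_s/3 for
    G_s ∝ phi^(1/3), giving M_os = (RT/V1)(2A2 phi^2 + 3A3 phi^3) + G_s.
    """
    phi = _validate_phi(phi)
    if hasattr(virials, "A2"):
        A2, A3 = float(virials.A2), float(virials.A3)
    else:
        A2, A3 = (float(v) for v in virials)
    G_s = np.asarray(G_s, dtype=float)
    if np.any(G_s < 0):
        raise ValueError("G_s must be >= 0")
    mix = solvent.pressure_scale * (2.0 * A2 * phi**2 + 3.0 * A3 * phi**3)
    if include_elastic_derivative:
        return mix + G_s
    return mix + (4.0 / 3.0) * G_s


@dataclass
class TransitionResult:
    """Swollen-branch continuation over a control grid and the detected jump."""

    control_grid: np.ndarray
    phi_eq: np.ndarray                  # NaN where the swollen branch is lost
    c_critical: Optional[float]
    jump_ratio: Optional[float]
    jump_threshold: float

    @property
    def transition_detected(self) -> bool:
        return self.c_critical is not None

    @property
    def swelling_degree(self) -> np.ndarray:
        return 1.0 / self.phi_eq


def _branch_root(model: GelModel, phi_prev: Optional[float],
                 phi_min: float, phi_max: float) -> Optional[float]:
    roots = [r for r in solve_equilibrium_swelling(model, phi_min, phi_max) if r.stable]
    if not roots:
        return None
    if phi_prev is None:
        return min(r.phi for r in roots)  # most swollen branch
    return min((r.phi for r in roots), key=lambda p: abs(math.log(p / phi_prev)))


def detect_volume_transition(control_grid: Sequence[float],
                             models: Optional[Sequence[GelModel]] = None,
                             model_fn: Optional[Callable[[float], GelModel]] = None,
                             jump_threshold: float = 2.0,
                             phi_min: float = 1e-4, phi_max: float = 0.99,
                             refine_rtol: float = 1e-3) -> TransitionResult:
    """Follow the swollen equilibrium branch over a control grid.

    At each control value the stable root nearest (in log phi) to the
    previous branch point is taken.  A volume transition is declared where
    the branch disappears or the swelling degree 1/phi drops by more than
    ``jump_threshold`` between adjacent grid points.  When ``model_fn`` is
    supplied the critical control value is refined by bisection on the
    branch-loss condition to relative tolerance ``refine_rtol``.
    """
    control = np.asarray(control_grid, dtype=float)
    if control.size < 4:
        raise ValueError("need at least 4 control values")
    if np.any(np.diff(control) <= 0):
        raise ValueError("control grid must be strictly increasing")
    if models is None:
        if model_fn is None:
            raise ValueError("provide models or model_fn")
        models = [model_fn(c) for c in control]
    if len(models) != control.size:
        raise ValueError("models and control grid lengths differ")

    phi_eq = np.full(control.size, np.nan)
    prev: Optional[float] = None
    c_critical: Optional[float] = None
    jump_ratio: Optional[float] = None
    i_break: Optional[int] = None
    for i, m in enumerate(models):
        root = _branch_root(m, prev, phi_min, phi_max)
        if root is None:
            if prev is None:
                raise ValueError(
                    f"no stable equilibrium at the first control value {control[i]:g}"
                )
            i_break = i
            jump_ratio = math.inf
            break
        if prev is not None and (prev / root) < 1.0 / jump_threshold:
            # 1/phi dropped by more than the threshold factor
            i_break = i
            jump_ratio = (1.0 / prev) / (1.0 / root)
            phi_eq[i] = root
            break
        phi_eq[i] = root
        prev = root

    if i_break is not None:
        lo, hi = control[i_break - 1], control[i_break]
        if model_fn is not None and prev is not None:
            phi_ok = prev

            def branch_lost(c: float) -> bool:
                r = _branch_root(model_fn(c), phi_ok, phi_min, phi_max)
                return r is None or (phi_ok / r) < 1.0 / jump_threshold

            while (hi - lo) > refine_rtol * max(abs(hi), abs(lo)):
                mid = 0.5 * (lo + hi)
                if branch_lost(mid):
                    hi = mid
                else:
                    lo = mid
            c_critical = 0.5 * (lo + hi)
        else:
            c_critical = 0.5 * (lo + hi)
    return TransitionResult(control_grid=control, phi_eq=phi_eq,
                            c_critical=c_critical, jump_ratio=jump_ratio,
                            jump_threshold=jump_threshold)
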