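"""Small-angle neutron scattering models for polymer gels.

The scattering response of a swollen gel is decomposed into a dynamic part
from thermodynamic concentration fluctuations and a static part from frozen
large-scale structure:

    I(q) = I_os(q) + I_x(q)
         = I0 (1 + qL)^-1 (1 + q^2 R^2)^-1  +  A q^-m,

where the dynamic amplitude I0 = Delta-rho^2 k_B T phi^2 / M_os is set by the
longitudinal osmotic modulus M_os, L is the linear-segment length, R the
effective chain cross-section, and the power law (m = 4 for smooth
interfaces, Porod scattering) captures the low-q excess.  For structureless
semi-dilute systems the dynamic part reduces to an Ornstein-Zernike shape
I0 (1 + q^2 xi^2)^-1 with correlation length xi.

Units follow SANS practice: q in 1/Angstrom, I in 1/cm, contrast in 1/cm^4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import lmfit

from .osmotics import SolventSpec, WATER_25C

__all__ = [
    "SANSProfile",
    "SANSFitResult",
    "SANSModel",
    "ConsistencyReport",
    "oz_intensity",
    "rod_oz_intensity",
    "power_law_intensity",
    "total_intensity",
    "fit_sans_profile",
    "osmotic_amplitude",
    "consistency_check",
    "DEFAULT_Q_RANGE",
]

#: Instrument q-range (1/Angstrom) used by generators and default fit masks.
DEFAULT_Q_RANGE = (0.003, 0.15)

# J = Pa m^3 and intensities are per cm: 1 m^3 = 1e6 cm^3.
_M3_TO_CM3 = 1.0e6


@dataclass
class SANSProfile:
    """A reduced SANS profile: q (1/A), absolute intensity I (1/cm), dI (1/cm)."""

    q: np.ndarray
    I: np.ndarray
    dI: Optional[np.ndarray] = None
    contrast: Optional[float] = None      # Delta-rho^2, 1/cm^4
    phi: Optional[float] = None
    condition: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.shape != self.I.shape:
            raise ValueError("q and I must have the same shape")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.dI is not None:
            self.dI = np.asarray(self.dI, dtype=float)
            if self.dI.shape != self.q.shape:
                raise ValueError("dI must match q in shape")
            if np.any(self.dI < 0):
                raise ValueError("dI must be nonnegative")
            if np.any(self.I[self.dI == 0] < 0):
                raise ValueError("negative intensity with zero uncertainty")

    def __len__(self) -> int:
        return self.q.size

    def masked(self, q_min: float = -np.inf, q_max: float = np.inf) -> "SANSProfile":
        keep = (self.q >= q_min) & (self.q <= q_max)
        return SANSProfile(self.q[keep], self.I[keep],
                           None if self.dI is None else self.dI[keep],
                           self.contrast, self.phi,
                           dict(self.condition), dict(self.metadata))


def oz_intensity(q, amplitude: float, xi: float):
    """Ornstein-Zernike line shape amplitude / (1 + q^2 xi^2), 1/cm."""
    q = np.asarray(q, dtype=float)
    if amplitude < 0 or xi < 0:
        raise ValueError("amplitude and xi must be >= 0")
    return amplitude / (1.0 + q**2 * xi**2)


def rod_oz_intensity(q, amplitude: float, L: float, R: float):
    """Dynamic intensity of linear segments, amplitude (1+qL)^-1 (1+q^2R^2)^-1."""
    q = np.asarray(q, dtype=float)
    if amplitude < 0 or L < 0 or R < 0:
        raise ValueError("amplitude, L and R must be >= 0")
    return amplitude / ((1.0 + q * L) * (1.0 + q**2 * R**2))


def power_law_intensity(q, A: float, m: float):
    """Static low-q excess A q^-m (Porod: m = 4 for smooth interfaces)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0 for the power-law term")
    if A < 0:
        raise ValueError("A must be >= 0")
    if not (2.0 <= m <= 5.0):
        raise ValueError("power-law exponent m must lie in [2, 5]")
    return A * q ** (-m)


@dataclass
class SANSFitResult:
    """Parameters of the two-component intensity model.

    ``variant`` selects the dynamic term: "rod" uses (L, R); "oz" uses the
    correlation length xi.  Amplitudes in 1/cm, lengths in Angstrom,
    A in cm^-1 A^-m.
    """

    dyn_amplitude: float
    A: float
    m: float
    L: Optional[float] = None
    R: Optional[float] = None
    xi: Optional[float] = None
    variant: str = "rod"
    cov_params: Optional[np.ndarray] = None
    stderr: Optional[dict] = None
    chi2_reduced: Optional[float] = None
    n_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant not in ("rod", "oz"):
            raise ValueError("variant must be 'rod' or 'oz'")
        if self.variant == "rod" and (self.L is None or self.R is None):
            raise ValueError("rod variant requires L and R")
        if self.variant == "oz" and self.xi is None:
            raise ValueError("oz variant requires xi")
        for name in ("dyn_amplitude", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (2.0 <= self.m <= 5.0):
            raise ValueError("m must lie in [2, 5]")

    @property
    def param_names(self) -> tuple:
        if self.variant == "rod":
            return ("dyn_amplitude", "L", "R", "A", "m")
        return ("dyn_amplitude", "xi", "A", "m")

    @property
    def params(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.param_names])

    def dynamic(self, q):
        if self.variant == "rod":
            return rod_oz_intensity(q, self.dyn_amplitude, self.L, self.R)
        return oz_intensity(q, self.dyn_amplitude, self.xi)

    def static(self, q):
        if self.A == 0:
            return np.zeros_like(np.asarray(q, dtype=float))
        return power_law_intensity(q, self.A, self.m)

    def predict(self, q):
        return self.dynamic(q) + self.static(q)

    def summary(self) -> str:
        se = self.stderr or {}
        lines = [f"SANS fit  I(q) = I_os(q) + A q^-m   [{self.variant} variant]"]
        for n in self.param_names:
            s = f"  {n:13s}: {getattr(self, n):.6g}"
            if n in se:
                s += f"  (se {se[n]:.3g})"
            lines.append(s)
        if self.chi2_reduced is not None:
            lines.append(f"  reduced chi^2 : {self.chi2_reduced:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {n: float(getattr(self, n)) for n in self.param_names}
        d["variant"] = self.variant
        if self.chi2_reduced is not None:
            d["chi2_reduced"] = float(self.chi2_reduced)
        if self.stderr:
            d["stderr"] = {k: float(v) for k, v in self.stderr.items()}
        return d


def total_intensity(q, params: SANSFitResult):
    """Two-component model intensity at q; see :class:`SANSFitResult`."""
    return params.predict(q)


class SANSModel:
    """Weighted nonlinear least squares for the two-component SANS model.

    Weights are 1/dI when uncertainties are present and positive; otherwise
    residuals are taken in log space (equivalent to uniform relative
    weighting).  All parameters are bounded nonnegative with m in [2, 5], and
    a small deterministic multistart grid of data-derived initial guesses
    protects against local minima.
    """

    def __init__(self, profile: SANSProfile, variant: str = "rod",
                 q_min: Optional[float] = None, q_max: Optional[float] = None):
        if variant not in ("rod", "oz"):
            raise ValueError("variant must be 'rod' or 'oz'")
        if q_min is not None or q_max is not None:
            profile = profile.masked(q_min if q_min is not None else -np.inf,
                                     q_max if q_max is not None else np.inf)
        if len(profile) < 8:
            raise ValueError("need at least 8 points to fit the SANS model")
        if profile.q[-1] / profile.q[0] < 10.0:
            raise ValueError("q range must span at least one decade")
        self.profile = profile
        self.variant = variant

    # -- initial guesses -------------------------------------------------
    def _starts(self) -> list[dict]:
        q, I = self.profile.q, self.profile.I
        n = len(q)
        pos = I[I > 0]
        floor = float(pos.min()) * 1e-3 if pos.size else 1e-12
        Isafe = np.clip(I, floor, None)
        # plateau (dynamic) level from the upper-q half
        plateau = float(np.median(Isafe[n // 2:]))
        # low-q slope for the static power law
        k = max(3, n // 8)
        slope = float(np.polyfit(np.log(q[:k]), np.log(Isafe[:k]), 1)[0])
        m0 = float(np.clip(-slope, 2.0, 5.0))
        A0 = float(Isafe[0] * q[0] ** m0)
        # crossover of the dynamic term: qL ~ 1 near mid-range
        L0 = 1.0 / float(np.sqrt(q[0] * q[-1]))
        starts = []
        for amp_f in (1.0, 3.0):
            for m_s in (m0, 4.0 if abs(m0 - 4.0) > 0.25 else 3.0):
                base = {"dyn_amplitude": plateau * amp_f,
                        "A": A0 * (0.5 if m_s != m0 else 1.0), "m": m_s}
                if self.variant == "rod":
                    base.update({"L": L0, "R": L0 / 10.0})
                else:
                    base.update({"xi": L0})
                starts.append(base)
        return starts

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        p = {k: params[k].value for k in params}
        if self.variant == "rod":
            model = (rod_oz_intensity(self.profile.q, p["dyn_amplitude"], p["L"], p["R"])
                     + p["A"] * self.profile.q ** (-p["m"]))
        else:
            model = (oz_intensity(self.profile.q, p["dyn_amplitude"], p["xi"])
                     + p["A"] * self.profile.q ** (-p["m"]))
        if self._weights is not None:
            return (model - self.profile.I) * self._weights
        floor = 1e-300
        return np.log(np.clip(model, floor, None)) - np.log(np.clip(self.profile.I, floor, None))

    def fit(self) -> SANSFitResult:
        dI = self.profile.dI
        if dI is not None and np.all(dI > 0):
            self._weights = 1.0 / dI
        else:
            self._weights = None
        best = None
        diagnostics = []
        for start in self._starts():
            params = lmfit.Parameters()
            for name, val in start.items():
                if name == "m":
                    params.add("m", value=val, min=2.0, max=5.0)
                else:
                    params.add(name, value=max(val, 1e-12), min=0.0)
            try:
                res = lmfit.minimize(self._residual, params, method="leastsq",
                                     nan_policy="raise")
            except Exception as exc:  # keep per-start diagnostics
                diagnostics.append((start, repr(exc)))
                continue
            if not res.success:
                diagnostics.append((start, res.message))
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError(
                "SANS fit failed to converge from any start; per-start diagnostics: "
                + "; ".join(f"{s} -> {msg}" for s, msg in diagnostics)
            )
        p = best.params
        names = (("dyn_amplitude", "L", "R", "A", "m") if self.variant == "rod"
                 else ("dyn_amplitude", "xi", "A", "m"))
        stderr = {n: p[n].stderr for n in names if p[n].stderr is not None}
        cov = best.covar if best.covar is not None else None
        nfree = max(best.ndata - best.nvarys, 1)
        kwargs = {n: float(p[n].value) for n in names}
        return SANSFitResult(variant=self.variant, cov_params=cov, stderr=stderr,
                             chi2_reduced=float(best.chisqr) / nfree,
                             n_points=best.ndata, **kwargs)


def fit_sans_profile(profile: SANSProfile, variant: str = "rod",
                     q_min: Optional[float] = None,
                     q_max: Optional[float] = None) -> SANSFitResult:
    """Fit the two-component model to a profile; see :class:`SANSModel`."""
    return SANSModel(profile, variant=variant, q_min=q_min, q_max=q_max).fit()


def osmotic_amplitude(phi: float, M_os: float, contrast: float,
                      solvent: SolventSpec = WATER_25C) -> float:
    """Dynamic scattering amplitude predicted from osmotic measurements.

    I_os(q -> 0) = Delta-rho^2 k_B T phi^2 / M_os in 1/cm, with the contrast
    Delta-rho^2 in 1/cm^4, M_os in Pa and k_B T in J.  Dimensionally
    cm^-4 * J / Pa = cm^-4 m^3 = 1e6 cm^-1, hence the 1e6 cm^3/m^3 factor.
    """
    if M_os <= 0:
        raise ValueError(
            f"M_os must be positive (thermodynamically stable), got {M_os:g} Pa"
        )
    if contrast <= 0:
        raise ValueError("contrast Delta-rho^2 must be positive")
    if not (0 < phi < 1):
        raise ValueError("phi must lie in (0, 1)")
    return contrast * solvent.kT * _M3_TO_CM3 * phi**2 / M_os


@dataclass
class ConsistencyReport:
    """Comparison of the SANS dynamic amplitude with the osmotic prediction."""

    sans_amplitude: float     # 1/cm, from the SANS fit
    osmotic_amplitude: float  # 1/cm, Delta-rho^2 k_B T phi^2 / M_os
    ratio: float
    tolerance: float
    passed: bool

    def summary(self) -> str:
        verdict = "CONSISTENT" if self.passed else "INCONSISTENT"
        return (
            "Osmotic vs SANS consistency\n"
            f"  SANS dynamic amplitude    : {self.sans_amplitude:.4g} 1/cm\n"
            f"  osmotic phi^2/M_os value  : {self.osmotic_amplitude:.4g} 1/cm\n"
            f"  ratio (SANS/osmotic)      : {self.ratio:.4g}\n"
            f"  tolerance (factor)        : {1.0 + self.tolerance:.3g}\n"
            f"  verdict                   : {verdict}"
        )

    def to_dict(self) -> dict:
        return {"sans_amplitude": self.sans_amplitude,
                "osmotic_amplitude": self.osmotic_amplitude,
                "ratio": self.ratio, "tolerance": self.tolerance,
                "passed": self.passed}


def consistency_check(fit: "SANSFitResult | float", osmotic: float,
                      tolerance: float = 0.5) -> ConsistencyReport:
    """Check whether SANS and osmotic amplitudes agree within a factor 1+tol.

    The comparison is symmetric in the two amplitudes: it passes iff
    |log(ratio)| <= log(1 + tolerance).
    """
    sans = fit.dyn_amplitude if isinstance(fit, SANSFitResult) else float(fit)
    if sans <= 0 or osmotic <= 0:
        raise ValueError("both amplitudes must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ratio = sans / osmotic
    passed = abs(math.log(ratio)) <= math.log1p(tolerance)
    return ConsistencyReport(sans_amplitude=sans, osmotic_amplitude=osmotic,
                             ratio=ratio, tolerance=tolerance, passed=passed)
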