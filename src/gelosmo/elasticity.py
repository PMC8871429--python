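"""Rubber elasticity of swollen networks: shear modulus and its phi-scaling.

Uniaxial compression of a gel cylinder obeys, in the classical (Gaussian,
affine) network theory,

    sigma = G_s (Lambda - Lambda^-2),

with nominal stress sigma (force per undeformed cross-section) and
deformation ratio Lambda = L/L0.  The same theory predicts the osmotic
contribution of the network, Pi_elast = -A RT nu phi^(1/3) = -G_s, i.e. a
shear modulus scaling as phi^(1/3) with swelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .osmotics import _validate_phi

__all__ = [
    "StressStrainSeries",
    "ShearModulusModel",
    "ShearModulusFit",
    "ElasticScalingModel",
    "ElasticScalingFit",
    "fit_shear_modulus",
    "elastic_pressure",
    "fit_elasticity_scaling",
]


@dataclass
class StressStrainSeries:
    """Uniaxial compression series (Lambda_i, sigma_i) for one gel specimen."""

    lam: np.ndarray      # deformation ratio L/L0, dimensionless
    sigma: np.ndarray    # nominal stress, Pa
    condition: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.lam.shape != self.sigma.shape:
            raise ValueError("lam and sigma must have the same shape")
        if self.lam.size < 2:
            raise ValueError("need at least 2 points")
        if np.any(self.lam <= 0):
            raise ValueError("deformation ratios must be positive")

    def __len__(self) -> int:
        return self.lam.size


@dataclass
class ShearModulusFit:
    """Result of the no-intercept regression sigma = G_s (Lambda - Lambda^-2)."""

    G_s: float            # Pa
    stderr: float         # Pa
    n_points: int
    residual_rms: float   # Pa

    @property
    def params(self) -> np.ndarray:
        return np.array([self.G_s])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.stderr])

    def summary(self) -> str:
        return (
            "Shear modulus fit  sigma = G_s (Lambda - Lambda^-2)\n"
            f"  G_s          : {self.G_s:.6g} Pa  (se {self.stderr:.3g} Pa)\n"
            f"  n points     : {self.n_points}\n"
            f"  residual rms : {self.residual_rms:.4g} Pa"
        )

    def to_dict(self) -> dict:
        return {"G_s_Pa": self.G_s, "stderr_Pa": self.stderr,
                "n_points": self.n_points, "residual_rms_Pa": self.residual_rms}


class ShearModulusModel:
    """No-intercept least-squares model for the shear modulus.

    The regression is forced through (Lambda=1, sigma=0) because the neo-
    Hookean law is exact at zero strain.  ``lambda_window`` restricts the
    points used to the compression range where the classical relation was
    validated (default 0.7 < Lambda <= 1); pass ``None`` to use all points.
    """

    def __init__(self, series: StressStrainSeries,
                 lambda_window: Optional[tuple[float, float]] = (0.7, 1.0)):
        self.series = series
        lam, sig = series.lam, series.sigma
        if lambda_window is not None:
            lo, hi = lambda_window
            keep = (lam > lo) & (lam <= hi)
            if keep.sum() < 2:
                raise ValueError(
                    f"fewer than 2 points inside lambda window ({lo}, {hi}]"
                )
            lam, sig = lam[keep], sig[keep]
        self.lam = lam
        self.sigma = sig

    def fit(self) -> ShearModulusFit:
        x = self.lam - self.lam**-2
        if np.all(x == 0):
            raise ValueError("degenerate design: all Lambda equal 1 (no strain)")
        sxx = float(x @ x)
        g = float(x @ self.sigma) / sxx
        resid = self.sigma - g * x
        n = x.size
        # HC3 sandwich variance: compression errors are typically relative
        # (instrument %-level), so per-point residual variances differ and a
        # homoscedastic estimate would understate the uncertainty.
        lever = x**2 / sxx
        infl = resid / np.clip(1.0 - lever, 1e-6, None)
        var = float(x**2 @ infl**2) / sxx**2
        return ShearModulusFit(
            G_s=g, stderr=math.sqrt(var), n_points=n,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )


def fit_shear_modulus(series: StressStrainSeries,
                      lambda_window: Optional[tuple[float, float]] = None
                      ) -> ShearModulusFit:
    """Fit G_s to a compression series (all points unless a window is given)."""
    return ShearModulusModel(series, lambda_window=lambda_window).fit()


def elastic_pressure(G_s) -> float:
    """Elastic contribution to the swelling pressure, Pi_elast = -G_s (Pa)."""
    G_s = np.asarray(G_s, dtype=float)
    if np.any(G_s < 0):
        raise ValueError("G_s must be >= 0")
    out = -G_s
    return float(out) if out.ndim == 0 else out


@dataclass
class ElasticScalingFit:
    """Power-law fit G_s = prefactor * phi^exponent on log-log axes.

    ``classical_pvalue`` tests the Gaussian-network exponent 1/3;
    ``classical_rejected`` flags rejection at the 95% level.  Deviations are
    expected at high swelling where chain finite extensibility sets in, so
    the comparison is reported, never enforced.
    """

    prefactor: float        # Pa (modulus at phi = 1 by extrapolation)
    exponent: float
    cov_params: np.ndarray  # 2x2 covariance of (log prefactor, exponent)
    n_points: int
    classical_pvalue: float
    classical_rejected: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.prefactor, self.exponent])

    @property
    def exponent_stderr(self) -> float:
        return float(np.sqrt(self.cov_params[1, 1]))

    def predict(self, phi) -> np.ndarray:
        phi = _validate_phi(np.asarray(phi, float))
        return self.prefactor * phi**self.exponent

    def summary(self) -> str:
        return (
            "Elastic scaling fit  G_s = prefactor * phi^exponent\n"
            f"  prefactor : {self.prefactor:.6g} Pa\n"
            f"  exponent  : {self.exponent:.6g}  (se {self.exponent_stderr:.3g})\n"
            f"  classical exponent 1/3 {'rejected' if self.classical_rejected else 'not rejected'}"
            f" at 95% (p = {self.classical_pvalue:.3g})"
        )

    def to_dict(self) -> dict:
        return {"prefactor_Pa": self.prefactor, "exponent": self.exponent,
                "exponent_stderr": self.exponent_stderr,
                "n_points": self.n_points,
                "classical_pvalue": self.classical_pvalue,
                "classical_rejected": self.classical_rejected}


class ElasticScalingModel:
    """Log-log linear model for the swelling dependence of the shear modulus."""

    def __init__(self, phi: Sequence[float], G_s: Sequence[float]):
        phi = np.asarray(phi, dtype=float)
        G_s = np.asarray(G_s, dtype=float)
        if phi.shape != G_s.shape:
            raise ValueError("phi and G_s must have the same shape")
        if phi.size < 3:
            raise ValueError("need at least 3 (phi, G_s) points")
        if np.any(phi <= 0) or np.any(G_s <= 0):
            raise ValueError("phi and G_s must be positive for a log-log fit")
        self.phi = phi
        self.G_s = G_s

    def fit(self) -> ElasticScalingFit:
        x = np.log(self.phi)
        y = np.log(self.G_s)
        X = np.column_stack([np.ones_like(x), x])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        n = x.size
        dof = max(n - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = np.linalg.inv(X.T @ X) * s2
        exponent = float(beta[1])
        se = math.sqrt(max(cov[1, 1], 0.0))
        if se > 0 and n > 2:
            tstat = (exponent - 1.0 / 3.0) / se
            pval = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
        else:
            # exact (noiseless) data: exponent either equals 1/3 or it does not
            pval = 1.0 if abs(exponent - 1.0 / 3.0) < 1e-8 else 0.0
        return ElasticScalingFit(
            prefactor=float(np.exp(beta[0])), exponent=exponent,
            cov_params=cov, n_points=n,
            classical_pvalue=pval, classical_rejected=pval < 0.05,
        )


def fit_elasticity_scaling(points) -> ElasticScalingFit:
    """Fit G_s(phi) = prefactor * phi^exponent to (phi, G_s) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (phi, G_s)")
    return ElasticScalingModel(pts[:, 0], pts[:, 1]).fit()
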