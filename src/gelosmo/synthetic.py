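"""Synthetic experiments with known ground truth.

Generators for every input the analysis consumes: uniaxial stress-strain
series, osmotic deswelling curves, salt/temperature sweeps of gel models
with affine A2/A3 laws, and reduced SANS profiles.  Every generated object
carries its generating parameters in ``metadata["truth"]`` so round-trip
recovery can be asserted exactly.

Scenario presets emulate the qualitative patterns of the three gel families
studied osmotically:

* ``polyelectrolyte_salt_sweep`` — divalent salt weakly depresses A2 (which
  stays positive) while A3 crosses zero inside the grid; past the crossing
  the swollen branch is eventually lost (salt-induced volume transition).
* ``neutral_temperature_sweep`` — A2 varies nearly linearly with temperature
  and may change sign; A3 stays small and positive; no transition.
* ``bottlebrush_salt_sweep`` — side-chain grafting inhibits the A3 sign
  change; A3 stays positive over the same salt range and the collapse is
  suppressed.

Randomness: every operation draws from its own stream, derived from the
configuration seed as ``SeedSequence(seed, spawn_key=(STREAM_ID, index))``,
so adding one generator call never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .elasticity import StressStrainSeries
from .osmotics import (GelModel, OsmoticCurve, SolventSpec, WATER_25C)
from .scattering import DEFAULT_Q_RANGE, SANSFitResult, SANSProfile

__all__ = [
    "NoiseModel",
    "ScenarioConfig",
    "SweepCondition",
    "ConfigurationError",
    "generate_stress_strain",
    "generate_deswelling_series",
    "generate_salt_sweep",
    "generate_sans_profile",
    "polyelectrolyte_salt_sweep",
    "neutral_temperature_sweep",
    "bottlebrush_salt_sweep",
    "default_phi_grid",
    "default_lambda_grid",
    "default_q_grid",
    "PAA_LIKE_SANS_TRUTH",
]

# fixed stream identifiers of the seed-splitting rule
_STREAMS = {
    "stress_strain": 11,
    "deswelling": 23,
    "salt_sweep": 37,
    "sans": 53,
}


class ConfigurationError(ValueError):
    """A scenario preset and its A2/A3 laws are mutually inconsistent."""


def _stream_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], index))
    )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise, additive or relative to the signal.

    ``scale`` is the standard deviation: in signal units for
    ``additive_gaussian``, dimensionless for ``relative_gaussian``.
    Identical (kind, scale, seed) always reproduces identical samples.
    """

    kind: str = "relative_gaussian"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "relative_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(kind="additive_gaussian", scale=0.0, seed=0)

    def sigma(self, signal: np.ndarray) -> np.ndarray:
        """Per-point noise standard deviation for a clean signal."""
        signal = np.asarray(signal, dtype=float)
        if self.kind == "additive_gaussian":
            return np.full_like(signal, self.scale)
        return self.scale * np.abs(signal)

    def sample(self, signal: np.ndarray,
               rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Noise realisation for a clean signal (uses own seed unless rng given)."""
        signal = np.asarray(signal, dtype=float)
        if self.scale == 0:
            return np.zeros_like(signal)
        if rng is None:
            rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, 1.0, size=signal.shape) * self.sigma(signal)


def default_lambda_grid(n: int = 10) -> np.ndarray:
    """Compression grid inside the validated range 0.7 < Lambda < 1."""
    return np.linspace(0.72, 0.98, n)


def default_phi_grid(n: int = 15, lo: float = 0.01, hi: float = 0.2) -> np.ndarray:
    """Log-spaced deswelling grid over the experimentally covered phi range."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def default_q_grid(n: int = 60) -> np.ndarray:
    """Log-spaced q grid spanning the instrument range 0.003-0.15 1/A."""
    return np.logspace(np.log10(DEFAULT_Q_RANGE[0]), np.log10(DEFAULT_Q_RANGE[1]), n)


def generate_stress_strain(G_s: float, lambda_grid: Sequence[float],
                           noise: NoiseModel = NoiseModel.off(),
                           rng: Optional[np.random.Generator] = None
                           ) -> StressStrainSeries:
    """Uniaxial compression series sigma = G_s (Lambda - Lambda^-2) + noise."""
    if G_s <= 0:
        raise ValueError("G_s must be positive")
    lam = np.asarray(lambda_grid, dtype=float)
    if np.any(lam <= 0) or np.any(lam > 1):
        raise ValueError("deformation ratios must lie in (0, 1]")
    clean = G_s * (lam - lam**-2)
    if rng is None:
        rng = _stream_rng(noise.seed, "stress_strain")
    sigma = clean + noise.sample(clean, rng)
    return StressStrainSeries(
        lam=lam, sigma=sigma,
        metadata={"truth": {"G_s_Pa": float(G_s)}, "noise": noise},
    )


def generate_deswelling_series(model: GelModel, phi_grid: Sequence[float],
                               noise: NoiseModel = NoiseModel.off(),
                               condition: Optional[dict] = None,
                               rng: Optional[np.random.Generator] = None
                               ) -> OsmoticCurve:
    """Total swelling pressure Pi_tot(phi) + noise for one gel model.

    The returned curve carries the noiseless mixing pressure, the elastic
    scaling and the generating virials in ``metadata["truth"]``; the
    uncertainty column holds the nominal per-point noise s.d.
    """
    phi = np.asarray(phi_grid, dtype=float)
    clean = np.asarray(model.swelling_pressure(phi), dtype=float)
    if rng is None:
        rng = _stream_rng(noise.seed, "deswelling")
    pressure = clean + noise.sample(clean, rng)
    sigma = noise.sigma(clean)
    return OsmoticCurve(
        phi=phi, pressure=pressure, pressure_kind="total",
        condition=dict(condition or {}),
        uncertainty=sigma if np.any(sigma > 0) else None,
        metadata={"truth": {
            "A2": model.A2, "A3": model.A3,
            "elastic_C_Pa": model.elastic_C, "phi_ref": model.phi_ref,
            "Pi_mix_Pa": np.asarray(model.mixing_pressure(phi), dtype=float),
            "Pi_tot_Pa": clean,
        }, "noise": noise},
    )


# ---------------------------------------------------------------------------
# Scenario sweeps
# ---------------------------------------------------------------------------

_SCENARIO_KINDS = ("polyelectrolyte_salt_sweep", "neutral_temperature_sweep",
                   "bottlebrush_salt_sweep")


def _affine(law: tuple[float, float], x: np.ndarray) -> np.ndarray:
    return law[0] + law[1] * x


def _sign_changes(values: np.ndarray) -> int:
    s = np.sign(values)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


@dataclass(frozen=True)
class ScenarioConfig:
    """Recipe for a synthetic sweep of gel models over a control variable.

    The virial laws are affine in the control variable (salt concentration in
    mol/m^3 or temperature in K): A_i(x) = intercept + slope * x.  The
    elastic reference modulus ``elastic_C`` (Pa at ``phi_ref``) is held fixed
    across the sweep, matching the observation that the added salt does not
    alter the network cross-link density.
    """

    scenario_kind: str
    A2_law: tuple[float, float]
    A3_law: tuple[float, float]
    control_grid: tuple[float, ...]
    elastic_C: float = 10_000.0
    phi_ref: float = 0.05
    solvent: SolventSpec = WATER_25C
    noise_rel: float = 0.05
    seed: int = 0
    phi_grid: tuple[float, ...] = tuple(default_phi_grid())

    def __post_init__(self) -> None:
        if self.scenario_kind not in _SCENARIO_KINDS:
            raise ConfigurationError(f"unknown scenario kind {self.scenario_kind!r}")
        grid = np.asarray(self.control_grid, dtype=float)
        if grid.size < 4 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("control_grid must be strictly increasing, >= 4 values")
        if self.noise_rel < 0:
            raise ConfigurationError("noise_rel must be >= 0")
        if not (0 < self.phi_ref < 1):
            raise ConfigurationError("phi_ref must lie in (0, 1)")
        if self.elastic_C < 0:
            raise ConfigurationError("elastic_C must be >= 0")
        a2 = _affine(self.A2_law, grid)
        a3 = _affine(self.A3_law, grid)
        if self.scenario_kind == "polyelectrolyte_salt_sweep":
            if np.any(a2 <= 0):
                raise ConfigurationError(
                    "polyelectrolyte preset requires A2 > 0 across the grid")
            if _sign_changes(a3) != 1:
                raise ConfigurationError(
                    "polyelectrolyte preset requires exactly one A3 sign change inside the grid")
        elif self.scenario_kind == "neutral_temperature_sweep":
            if self.A3_law[1] != 0 or self.A3_law[0] <= 0:
                raise ConfigurationError(
                    "neutral preset requires a constant positive A3")
        elif self.scenario_kind == "bottlebrush_salt_sweep":
            if np.any(a3 <= 0):
                raise ConfigurationError(
                    "bottlebrush preset requires A3 > 0 across the grid")

    @property
    def control(self) -> np.ndarray:
        return np.asarray(self.control_grid, dtype=float)

    def virials_at(self, x: float) -> tuple[float, float]:
        return float(_affine(self.A2_law, np.asarray(x))), \
            float(_affine(self.A3_law, np.asarray(x)))

    def gel_model(self, x: float) -> GelModel:
        A2, A3 = self.virials_at(x)
        return GelModel(A2=A2, A3=A3, elastic_C=self.elastic_C,
                        phi_ref=self.phi_ref, solvent=self.solvent)

    def noise(self) -> NoiseModel:
        if self.noise_rel == 0:
            return NoiseModel.off()
        return NoiseModel(kind="relative_gaussian", scale=self.noise_rel,
                          seed=self.seed)


def polyelectrolyte_salt_sweep(noise_rel: float = 0.05, seed: int = 0,
                               **overrides) -> ScenarioConfig:
    """Divalent-salt sweep of a linear polyelectrolyte gel (CaCl2 in mol/m^3)."""
    defaults = dict(
        scenario_kind="polyelectrolyte_salt_sweep",
        A2_law=(0.05, -0.005), A3_law=(0.3, -0.36),
        control_grid=tuple(np.linspace(0.0, 2.0, 9)),
    )
    defaults.update(overrides)
    return ScenarioConfig(noise_rel=noise_rel, seed=seed, **defaults)


def neutral_temperature_sweep(noise_rel: float = 0.05, seed: int = 0,
                              **overrides) -> ScenarioConfig:
    """Temperature sweep of a neutral gel: A2 crosses zero, A3 small positive."""
    defaults = dict(
        scenario_kind="neutral_temperature_sweep",
        A2_law=(0.252, -0.0008), A3_law=(0.05, 0.0),
        control_grid=tuple(np.linspace(290.0, 320.0, 7)),
    )
    defaults.update(overrides)
    return ScenarioConfig(noise_rel=noise_rel, seed=seed, **defaults)


def bottlebrush_salt_sweep(noise_rel: float = 0.05, seed: int = 0,
                           **overrides) -> ScenarioConfig:
    """Salt sweep of a bottlebrush polyelectrolyte: A3 stays positive."""
    defaults = dict(
        scenario_kind="bottlebrush_salt_sweep",
        A2_law=(0.04, -0.0025), A3_law=(0.25, -0.05),
        control_grid=tuple(np.linspace(0.0, 2.0, 9)),
    )
    defaults.update(overrides)
    return ScenarioConfig(noise_rel=noise_rel, seed=seed, **defaults)


@dataclass
class SweepCondition:
    """One condition of a sweep: control value, noisy curve, modulus info."""

    control: float
    curve: OsmoticCurve
    G_s: np.ndarray                 # per-point shear modulus along the curve, Pa
    elastic: tuple[float, float]    # (C, phi_ref) scaling behind G_s
    truth: dict                     # generating A2, A3


def generate_salt_sweep(config: ScenarioConfig) -> list[SweepCondition]:
    """Deswelling curves for every control value of a scenario sweep."""
    noise = config.noise()
    out = []
    control_name = ("T_K" if config.scenario_kind == "neutral_temperature_sweep"
                    else "c_CaCl2_mM")
    for i, x in enumerate(config.control):
        model = config.gel_model(float(x))
        rng = _stream_rng(config.seed, "salt_sweep", i)
        curve = generate_deswelling_series(
            model, np.asarray(config.phi_grid), noise,
            condition={control_name: float(x)}, rng=rng)
        out.append(SweepCondition(
            control=float(x), curve=curve,
            G_s=np.asarray(model.shear_modulus(curve.phi), dtype=float),
            elastic=(config.elastic_C, config.phi_ref),
            truth={"A2": model.A2, "A3": model.A3},
        ))
    return out


# ---------------------------------------------------------------------------
# SANS profiles
# ---------------------------------------------------------------------------

#: PAA-gel-like ground truth for the two-component model: a ~10 cm^-1
#: dynamic plateau with L = 50 A, R = 5 A, and a Porod (m = 4) low-q upturn
#: reaching ~100 cm^-1 at the lower end of the instrument range.
PAA_LIKE_SANS_TRUTH = SANSFitResult(dyn_amplitude=10.0, L=50.0, R=5.0,
                                    A=1.0e-8, m=4.0, variant="rod")


def generate_sans_profile(truth: SANSFitResult, q_grid: Sequence[float],
                          noise: NoiseModel = NoiseModel.off(),
                          contrast: Optional[float] = None,
                          phi: Optional[float] = None,
                          rng: Optional[np.random.Generator] = None
                          ) -> SANSProfile:
    """Reduced SANS profile I(q) = model(q) + noise with stored ground truth.

    The uncertainty column holds the nominal noise s.d. (flat for additive
    noise, proportional to I for relative noise); with noise off a uniform
    1%-of-plateau uncertainty is recorded so weighted fits stay defined.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive (power law diverges at 0)")
    clean = np.asarray(truth.predict(q), dtype=float)
    if rng is None:
        rng = _stream_rng(noise.seed, "sans")
    I = clean + noise.sample(clean, rng)
    dI = noise.sigma(clean)
    if not np.any(dI > 0):
        dI = np.full_like(clean, 0.01 * max(truth.dyn_amplitude, clean.max() * 1e-3))
    return SANSProfile(
        q=q, I=I, dI=dI, contrast=contrast, phi=phi,
        metadata={"truth": truth.to_dict(), "noise": noise},
    )
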