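"""Muscle stem-cell lineage dynamics, chemotherapy coupling, and tumour growth.

Healthy muscle is modelled as two volume compartments (mm^3): satellite
(stem) cells S and differentiated muscle fibres M.  Stem cells divide
symmetrically, self-renewing with probability p(M) and differentiating with
probability 1 - p(M):

    dS/dt = (2 p(M) - 1) nu(M) S
    dM/dt = 2 (1 - p(M)) nu(M) S - d0 M

with saturating feedback p(M) = p0 + p1/(1 + M/m) and
nu(M) = nu0 + nu1/(1 + M/m) that downregulates self-renewal and
proliferation as the muscle approaches its homeostatic size.  Lean mass in
grams is density*(S + M) with density = 0.002 g/mm^3.

Chemotherapy enters as a cubic suppression of successful proliferation and
differentiation by the tau-day average tissue exposure y:

    factor(y) = 1 - (y / Rd)^3

multiplying both division terms; Rd (ug/ml) is the exposure threshold at
which net turnover stalls.  The factor is deliberately not clamped below
zero: exposures beyond Rd drive net loss, which is what produces the
strongly nonlinear dose response.

Tumour burden follows an exponential-linear growth law with a log-kill
term proportional to tissue drug concentration:

    dT/dt = mu0 T (1 + (mu0 T / mu1)^eta)^(-1/eta) - kappa C2 T.

The tumour is not coupled back to the host (no cancer-induced cachexia).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MuscleParams",
    "ChemoEffect",
    "TumourParams",
    "HostState",
    "renewal_probability",
    "proliferation_rate",
    "chemo_factor",
    "muscle_derivatives",
    "lean_mass",
    "healthy_equilibrium",
    "tumour_derivative",
    "initial_state",
    "aged_params",
]


@dataclass(frozen=True)
class MuscleParams:
    """Lineage-model parameters.

    p0, p1 : base and perturbation self-renewal probability (dimensionless);
    nu0, nu1 : base and perturbation proliferation rates (1/day);
    d0 : muscle-fibre death rate (1/day); m : half-saturation volume (mm^3);
    density : lean-mass conversion factor (g/mm^3).
    """

    p0: float = 0.479
    p1: float = 0.133
    nu0: float = 0.087
    nu1: float = 5.591
    d0: float = 0.05
    m: float = 1000.0
    density: float = 0.002

    def __post_init__(self) -> None:
        for name in ("nu0", "nu1", "d0", "m", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"muscle parameter {name} must be positive")
        if not 0 < self.p0 < 0.5 < self.p0 + self.p1 <= 1:
            raise ValueError(
                "self-renewal probabilities must satisfy 0 < p0 < 0.5 < p0 + p1 <= 1"
            )


@dataclass(frozen=True)
class ChemoEffect:
    """Pharmacodynamic coupling: threshold Rd (ug/ml), exposure window tau (days).

    The suppression exponent is cubic by construction (the dose separation
    in the calibration data is approximately cubic; linear and quadratic
    forms cannot reproduce it).
    """

    Rd: float = 6.8
    tau: float = 8.0
    exponent: int = 3

    def __post_init__(self) -> None:
        if self.Rd <= 0 or self.tau <= 0:
            raise ValueError("Rd and tau must be positive")


@dataclass(frozen=True)
class TumourParams:
    """Exponential-linear tumour growth with concentration-proportional kill.

    mu0 (1/day) exponential rate, mu1 (mm^3/day) linear rate, eta transition
    sharpness, kappa (ml/(ug day)) kill efficacy, T0 (mm^3) initial volume.
    """

    mu0: float = 0.446
    mu1: float = 116.0
    eta: float = 20.0
    kappa: float = 0.13
    T0: float = 10.0

    def __post_init__(self) -> None:
        for name in ("mu0", "mu1", "eta", "kappa", "T0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"tumour parameter {name} must be positive")


@dataclass(frozen=True)
class HostState:
    """Satellite-cell and muscle-fibre volumes (mm^3)."""

    S: float
    M: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.M < 0:
            raise ValueError("compartment volumes must be non-negative")


def renewal_probability(M, mp: MuscleParams):
    """Self-renewal probability p(M) = p0 + p1/(1 + M/m); decreasing in M."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("muscle volume must be non-negative")
    return mp.p0 + mp.p1 / (1.0 + M / mp.m)


def proliferation_rate(M, mp: MuscleParams):
    """Proliferation rate nu(M) = nu0 + nu1/(1 + M/m) in 1/day; decreasing in M."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("muscle volume must be non-negative")
    return mp.nu0 + mp.nu1 / (1.0 + M / mp.m)


def chemo_factor(y, Rd: float):
    """Cubic suppression multiplier 1 - (y/Rd)^3; negative above threshold."""
    y = np.asarray(y, dtype=float)
    return 1.0 - (y / Rd) ** 3


def muscle_derivatives(
    state: HostState, y: float, mp: MuscleParams, ce: ChemoEffect
) -> tuple[float, float]:
    """(dS/dt, dM/dt) in mm^3/day under exposure y; reduces to the healthy
    field at y = 0."""
    p = renewal_probability(state.M, mp)
    nu = proliferation_rate(state.M, mp)
    f = chemo_factor(y, ce.Rd)
    dS = f * (2.0 * p - 1.0) * nu * state.S
    dM = f * 2.0 * (1.0 - p) * nu * state.S - mp.d0 * state.M
    return float(dS), float(dM)


def lean_mass(state: HostState, mp: MuscleParams) -> float:
    """Lean mass in grams: density * (S + M)."""
    return mp.density * (state.S + state.M)


def healthy_equilibrium(mp: MuscleParams) -> HostState:
    """Unique positive equilibrium of the healthy system, in closed form.

    At equilibrium dS/dt = 0 with S > 0 forces p(M*) = 1/2, so
    M* = m*(p1/(1/2 - p0) - 1); dM/dt = 0 then gives
    S* = d0*M*/nu(M*).  Requires p0 < 1/2 < p0 + p1.
    """
    if not mp.p0 < 0.5 < mp.p0 + mp.p1:
        raise ValueError("no positive equilibrium: need p0 < 1/2 < p0 + p1")
    M_star = mp.m * (mp.p1 / (0.5 - mp.p0) - 1.0)
    if M_star <= 0:
        raise ValueError("no positive equilibrium for these parameters")
    S_star = mp.d0 * M_star / proliferation_rate(M_star, mp)
    return HostState(S=float(S_star), M=float(M_star))


def tumour_derivative(T, C2, tp: TumourParams):
    """dT/dt in mm^3/day for the exponential-linear model with drug kill."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("tumour volume must be non-negative")
    growth = tp.mu0 * T * (1.0 + (tp.mu0 * T / tp.mu1) ** tp.eta) ** (-1.0 / tp.eta)
    return growth - tp.kappa * np.asarray(C2, dtype=float) * T


def initial_state(lean_mass_g: float, stem_ratio: float, mp: MuscleParams) -> HostState:
    """Host state with the requested lean mass and stem ratio S/M.

    Inverts lean mass = density*(S + M) with S = stem_ratio*M, so the
    round trip through :func:`lean_mass` is exact.
    """
    if lean_mass_g <= 0 or stem_ratio <= 0:
        raise ValueError("lean mass and stem ratio must be positive")
    M = lean_mass_g / (mp.density * (1.0 + stem_ratio))
    return HostState(S=stem_ratio * M, M=M)


def aged_params(mp: MuscleParams, scale: float = 0.98) -> MuscleParams:
    """Age-degraded parameters: the self-renewal perturbation p1 is scaled down.

    Models the age-related decay in stem-cell viability; a 2% reduction
    shifts the homeostatic lean mass down by about 2.5%.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    return replace(mp, p1=scale * mp.p1)
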