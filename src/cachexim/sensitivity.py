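"""Dynamic local sensitivity analysis of the lean-mass response.

For a parameter rho with nominal value r, the sensitivity coefficient at
time t_i is the one-sided finite difference

    S(t_i) = [LM(t_i; (1 + eps) r) - LM(t_i; r)] / (eps r)

and the relative (dimensionless) coefficient is
S_rel(t_i) = S(t_i) * r / LM(t_i; r), with eps = 1e-5 by default.  The
minus direction uses the backward difference
[LM(t_i; r) - LM(t_i; (1 - eps) r)] / (eps r) so both directions estimate
the same derivative.  Because the chemotherapy effect is transient, the
coefficients are dynamic: they grow during treatment and decay after the
last dose.

Both perturbed and nominal lean-mass series are computed on the shared
fixed-step RK4 discretisation (:mod:`cachexim._fast`), so the finite
difference is not contaminated by adaptive-stepping noise.  The tau window
is perturbed continuously here (non-integer tau is well defined in the
moving average) even though fitting restricts tau to integers.

Tumour-only parameters are excluded from the all-parameter scan: the
tumour equation is not coupled back to the lean-mass equations, so their
lean-mass sensitivity is identically zero (asserted for kappa in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._fast import DEFAULT_STEP, exposure_cubed_substeps, integrate_muscle
from .coupled import HostTrajectory, Scenario, run
from .pharmacokinetics import PKSolution

__all__ = [
    "SensitivitySettings",
    "SensitivitySeries",
    "PerturbationPair",
    "LEAN_MASS_PARAMETERS",
    "perturb_scenario",
    "sensitivity_series",
    "perturbation_run",
    "all_param_sensitivity",
]

#: Parameters that can influence lean mass: PK rates and volumes, the
#: muscle-lineage parameters, and the two pharmacodynamic constants.
LEAN_MASS_PARAMETERS = (
    "k10", "k12", "k21", "V1", "V2",
    "p0", "p1", "nu0", "nu1", "d0", "m",
    "Rd", "tau",
)
_TUMOUR_PARAMETERS = ("mu0", "mu1", "eta", "kappa", "T0")
_PK_FIELDS = ("k10", "k12", "k21", "V1", "V2")
_MUSCLE_FIELDS = ("p0", "p1", "nu0", "nu1", "d0", "m", "density")
_CHEMO_FIELDS = ("Rd", "tau")


def _get_param(scenario: Scenario, name: str) -> float:
    if name in _PK_FIELDS:
        return getattr(scenario.pk, name)
    if name in _MUSCLE_FIELDS:
        return getattr(scenario.mp, name)
    if name in _CHEMO_FIELDS:
        return getattr(scenario.ce, name)
    if name in _TUMOUR_PARAMETERS:
        if scenario.tp is None:
            raise KeyError(f"scenario has no tumour; parameter {name!r} unaddressable")
        return getattr(scenario.tp, name)
    raise KeyError(f"unknown parameter {name!r}")


def perturb_scenario(scenario: Scenario, name: str, factor: float) -> Scenario:
    """A copy of ``scenario`` with the named parameter multiplied by ``factor``."""
    value = _get_param(scenario, name) * factor
    if name in _PK_FIELDS:
        return replace(scenario, pk=replace(scenario.pk, **{name: value}))
    if name in _MUSCLE_FIELDS:
        return replace(scenario, mp=replace(scenario.mp, **{name: value}))
    if name in _CHEMO_FIELDS:
        return replace(scenario, ce=replace(scenario.ce, **{name: value}))
    return replace(scenario, tp=replace(scenario.tp, **{name: value}))


@dataclass(frozen=True)
class SensitivitySettings:
    """eps: finite-difference fraction; direction: 'plus' or 'minus';
    display_perturbation: fraction for the +/-10% trajectory comparison."""

    eps: float = 1e-5
    direction: str = "plus"
    display_perturbation: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.eps < self.display_perturbation:
            raise ValueError("need 0 < eps << display_perturbation")
        if self.direction not in ("plus", "minus"):
            raise ValueError("direction must be 'plus' or 'minus'")


@dataclass
class SensitivitySeries:
    """Dynamic sensitivity of lean mass to one parameter.

    ``S`` is in grams per parameter unit; ``S_rel`` is dimensionless and
    satisfies S_rel = S * rho / LM pointwise.
    """

    parameter: str
    times: np.ndarray
    S: np.ndarray
    S_rel: np.ndarray
    eps: float
    nominal: float

    def peak_abs_rel(self) -> float:
        return float(np.max(np.abs(self.S_rel)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "time_days": self.times,
                "S_g_per_unit": self.S,
                "S_rel": self.S_rel,
            }
        )


def _lean_series(scenario: Scenario, days: np.ndarray, h: float) -> np.ndarray:
    """Lean mass at the given (integer-multiple-of-h) days via fixed-step RK4."""
    pk = scenario.effective_pk
    mp = scenario.effective_mp
    host0 = scenario.initial_host
    t_end = float(days[-1])
    sol = PKSolution(pk, scenario.schedule, max(t_end, scenario.t_end))
    ycube = exposure_cubed_substeps(sol, scenario.ce.tau, t_end, h)
    steps = np.rint(days / h).astype(int)
    S, M = integrate_muscle(
        ycube, scenario.ce.Rd ** -3.0, mp, host0.S, host0.M, h, steps
    )
    return mp.density * (S + M)


def sensitivity_series(
    scenario: Scenario,
    parameter: str,
    settings: SensitivitySettings | None = None,
    day_step: float = 1.0,
    h: float = DEFAULT_STEP,
) -> SensitivitySeries:
    """Finite-difference sensitivity of lean mass on a daily output grid."""
    settings = settings or SensitivitySettings()
    rho = _get_param(scenario, parameter)
    if rho == 0:
        raise ValueError(f"parameter {parameter!r} has zero nominal value")
    days = np.arange(0.0, scenario.t_end + day_step / 2, day_step)

    if parameter in _TUMOUR_PARAMETERS:
        # Not coupled into the lean-mass equations: exactly zero.
        lm = _lean_series(scenario, days, h)
        zeros = np.zeros_like(days)
        return SensitivitySeries(parameter, days, zeros, zeros, settings.eps, rho)

    lm = _lean_series(scenario, days, h)
    eps = settings.eps
    if settings.direction == "plus":
        lm_pert = _lean_series(perturb_scenario(scenario, parameter, 1.0 + eps), days, h)
        S = (lm_pert - lm) / (eps * rho)
    else:
        lm_pert = _lean_series(perturb_scenario(scenario, parameter, 1.0 - eps), days, h)
        S = (lm - lm_pert) / (eps * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        S_rel = np.where(lm > 0, S * rho / lm, 0.0)
    return SensitivitySeries(parameter, days, S, S_rel, eps, rho)


@dataclass
class PerturbationPair:
    """Nominal and +/-fraction trajectories for one parameter."""

    parameter: str
    fraction: float
    nominal: HostTrajectory
    increased: HostTrajectory
    decreased: HostTrajectory


def perturbation_run(
    scenario: Scenario, parameter: str, fraction: float = 0.10
) -> PerturbationPair:
    """Full simulations at (1 +/- fraction) * rho alongside the nominal run."""
    nominal = run(scenario)
    up = run(perturb_scenario(scenario, parameter, 1.0 + fraction)) if fraction else nominal
    down = run(perturb_scenario(scenario, parameter, 1.0 - fraction)) if fraction else nominal
    return PerturbationPair(parameter, fraction, nominal, up, down)


def all_param_sensitivity(
    scenario: Scenario,
    parameters: tuple[str, ...] = LEAN_MASS_PARAMETERS,
    settings: SensitivitySettings | None = None,
    **kwargs,
) -> dict[str, SensitivitySeries]:
    """Sensitivity series for every listed lean-mass parameter.

    Tumour-only parameters are rejected: they cannot affect lean mass.
    """
    if not parameters:
        raise ValueError("parameter list must be non-empty")
    bad = [p for p in parameters if p in _TUMOUR_PARAMETERS]
    if bad:
        raise ValueError(f"tumour-only parameters excluded from the lean-mass scan: {bad}")
    return {
        p: sensitivity_series(scenario, p, settings=settings, **kwargs)
        for p in parameters
    }
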