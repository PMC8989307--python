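"""Synthetic dose-response datasets with the structure of the calibration data.

The model was calibrated to lean-mass curves extrapolated from body-weight
measurements in mice dosed with 5-FU on a daily or 5-on/2-off schedule
(doses 14-35 and 24-60 mg/kg respectively, 28 treatment days, 56-day
observation, initial body weight 25 g of which ~40% is lean mass).  Those
digitized curves are not deposited anywhere, so this module generates
datasets of identical shape from the model itself at known (tau, Rd) plus
additive Gaussian measurement noise — which is exactly what the fitting
pipeline needs for end-to-end parameter-recovery experiments.

The generator emits one mean series per dose arm (the calibration curves
are per-arm means); it makes no claim about the real experiment's
between-animal variance, digitization artifacts, or the mortality observed
in the high-dose arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupled import Scenario, run
from .fitting import FAMILY_BUILDERS, DoseResponseDataset, FitTemplate
from .tissue import ChemoEffect, HostState, initial_state

__all__ = ["SyntheticConfig", "generate", "default_configs"]

#: Initial body weight (g) and lean fraction emulating the source experiment.
BODY_WEIGHT_G = 25.0
LEAN_FRACTION = 0.40
#: Stem ratio of the young growth-phase host used at treatment start.
YOUNG_STEM_RATIO = 267.5 / 4732.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one schedule family's dataset.

    ``dose_arms`` in mg/kg with 0 denoting the untreated control arm;
    ``noise_sd`` is the additive Gaussian measurement noise on lean mass in
    grams; observations fall every ``cadence`` days over ``horizon`` days.
    """

    family: str = "daily"
    dose_arms: tuple[float, ...] = (0.0, 14.0, 17.0, 20.0, 24.0, 29.0, 35.0)
    true_tau: float = 8.0
    true_Rd: float = 6.8
    noise_sd: float = 0.2
    cadence: float = 2.0
    horizon: float = 56.0
    seed: int = 0
    body_weight_emulation: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if len(set(self.dose_arms)) != len(self.dose_arms):
            raise ValueError("dose arms must be distinct")
        if self.family not in FAMILY_BUILDERS:
            raise KeyError(f"unknown schedule family {self.family!r}")


def default_configs(
    noise_sd: float = 0.2, seed: int = 0
) -> tuple[SyntheticConfig, SyntheticConfig]:
    """The two standard families: daily 14-35 mg/kg and 5-on/2-off 24-60 mg/kg."""
    daily = SyntheticConfig(
        family="daily",
        dose_arms=(0.0, 14.0, 17.0, 20.0, 24.0, 29.0, 35.0),
        noise_sd=noise_sd,
        seed=seed,
    )
    five_two = SyntheticConfig(
        family="5on2off",
        dose_arms=(0.0, 24.0, 35.0, 42.0, 50.0, 60.0),
        noise_sd=noise_sd,
        seed=seed + 1,
    )
    return daily, five_two


def _initial_host(config: SyntheticConfig, template: FitTemplate) -> HostState:
    if config.body_weight_emulation:
        lean0 = BODY_WEIGHT_G * LEAN_FRACTION
        return initial_state(lean0, YOUNG_STEM_RATIO, template.mp)
    return template.host0


def generate(
    config: SyntheticConfig, template: FitTemplate | None = None
) -> DoseResponseDataset:
    """Simulate every dose arm at the true (tau, Rd) and add observation noise.

    Deterministic in ``config.seed``: identical configs yield identical
    datasets.  The control arm is the zero-dose simulation of the same host.
    """
    template = template or FitTemplate()
    host0 = _initial_host(config, template)
    ce = ChemoEffect(Rd=config.true_Rd, tau=config.true_tau)
    days = np.arange(0.0, config.horizon + config.cadence / 2, config.cadence)
    rng = np.random.default_rng(config.seed)

    builder = FAMILY_BUILDERS[config.family]
    arms: dict[float, np.ndarray] = {}
    for dose in sorted(config.dose_arms):
        schedule = builder(dose) if dose > 0 else builder(1.0).empty()
        scenario = Scenario(
            schedule=schedule, pk=template.pk, mp=template.mp, ce=ce,
            host0=host0, t_end=config.horizon,
        )
        traj = run(scenario)
        lean = np.interp(days, traj.times, traj.lean)
        if config.noise_sd > 0:
            lean = lean + rng.normal(0.0, config.noise_sd, size=lean.shape)
        arms[float(dose)] = np.column_stack([days, lean])
    return DoseResponseDataset(family=config.family, arms=arms)
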