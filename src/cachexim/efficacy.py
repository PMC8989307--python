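"""Treatment-effect curves and AUC-based therapeutic-efficacy scores.

Treatment effects are normalised by each trajectory's own initial values —
the quantities known at clinical presentation — not by an untreated
control:

    lean_fraction(t)   = LM(t) / LM(0)
    tumour_fraction(t) = T(t) / T(0)
    ITE(t)             = lean_fraction(t) / tumour_fraction(t)

(instantaneous therapeutic efficacy: large when lean mass is preserved and
the tumour shrinks).  A single score per schedule comes from areas under
the normalised curves relative to a reference regimen (conventionally the
24 mg/kg daily schedule, the most lean-sparing standard):

    lean_auc_ratio   = AUC(lean_fraction) / AUC(reference lean_fraction)
    tumour_auc_ratio = AUC(tumour_fraction) / AUC(reference tumour_fraction)
    total_te         = lean_auc_ratio / tumour_auc_ratio

Higher total_te is better.  The metric carries no toxicity penalty, so
high-dose schedules must be interpreted with care.  A control-relative
lean-mass reduction is provided as a separate diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupled import HostTrajectory

__all__ = [
    "EfficacyCurves",
    "EfficacyScores",
    "treatment_effect_curves",
    "auc",
    "scores",
    "score_table",
    "control_relative_reduction",
]


@dataclass
class EfficacyCurves:
    """Normalised treatment-effect series; tumour parts None without a tumour."""

    times: np.ndarray
    lean_fraction: np.ndarray
    tumour_fraction: np.ndarray | None
    ite: np.ndarray | None


@dataclass(frozen=True)
class EfficacyScores:
    label: str
    lean_auc_ratio: float
    tumour_auc_ratio: float
    total_te: float
    reference: str
    window: tuple[float, float]


def treatment_effect_curves(traj: HostTrajectory) -> EfficacyCurves:
    """Normalise lean mass and tumour volume by their t = 0 values."""
    if traj.lean[0] <= 0:
        raise ValueError("initial lean mass must be positive")
    lean_fraction = traj.lean / traj.lean[0]
    tumour_fraction = ite = None
    if traj.T is not None:
        if traj.T[0] <= 0:
            raise ValueError("initial tumour volume must be positive")
        tumour_fraction = traj.T / traj.T[0]
        ite = lean_fraction / tumour_fraction
    return EfficacyCurves(traj.times, lean_fraction, tumour_fraction, ite)


def auc(times: np.ndarray, series: np.ndarray, window: tuple[float, float]) -> float:
    """Trapezoidal area under ``series`` over ``window`` (days).

    Window endpoints may fall between grid points; the series is
    interpolated linearly there.
    """
    start, end = window
    if not (times[0] <= start < end <= times[-1]):
        raise ValueError(f"window {window} not contained in the time grid")
    inside = (times > start) & (times < end)
    t = np.concatenate([[start], times[inside], [end]])
    v = np.concatenate(
        [[np.interp(start, times, series)], series[inside], [np.interp(end, times, series)]]
    )
    return float(np.trapezoid(v, t))


def scores(
    treated: HostTrajectory,
    reference: HostTrajectory,
    window: tuple[float, float],
    label: str = "treated",
    reference_label: str = "reference",
) -> EfficacyScores:
    """AUC ratios and total therapeutic efficacy of a schedule vs a reference."""
    tc = treatment_effect_curves(treated)
    rc = treatment_effect_curves(reference)
    if tc.tumour_fraction is None or rc.tumour_fraction is None:
        raise ValueError("both trajectories need a tumour series for efficacy scores")
    lean_ratio = auc(tc.times, tc.lean_fraction, window) / auc(
        rc.times, rc.lean_fraction, window
    )
    tumour_ratio = auc(tc.times, tc.tumour_fraction, window) / auc(
        rc.times, rc.tumour_fraction, window
    )
    return EfficacyScores(
        label=label,
        lean_auc_ratio=float(lean_ratio),
        tumour_auc_ratio=float(tumour_ratio),
        total_te=float(lean_ratio / tumour_ratio),
        reference=reference_label,
        window=window,
    )


def score_table(
    trajectories: dict[str, HostTrajectory],
    reference_label: str,
    window: tuple[float, float] = (0.0, 56.0),
) -> pd.DataFrame:
    """Score every trajectory against the named reference; one row each."""
    if reference_label not in trajectories:
        raise KeyError(f"reference {reference_label!r} missing from trajectories")
    ref = trajectories[reference_label]
    rows = []
    for label, traj in trajectories.items():
        s = scores(traj, ref, window, label=label, reference_label=reference_label)
        rows.append(
            {
                "schedule": label,
                "lean_auc_ratio": s.lean_auc_ratio,
                "tumour_auc_ratio": s.tumour_auc_ratio,
                "total_te": s.total_te,
                "is_reference": label == reference_label,
            }
        )
    return pd.DataFrame(rows)


def control_relative_reduction(
    treated: HostTrajectory, control: HostTrajectory, day: float
) -> float:
    """Percent lean-mass deficit vs the time-matched untreated control."""
    lm_t = treated.at_day(day)["lean"]
    lm_c = control.at_day(day)["lean"]
    return 100.0 * (1.0 - lm_t / lm_c)
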