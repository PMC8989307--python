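"""Fixed-step RK4 backend for the muscle stage, vectorised over parameter grids.

The grid search over (tau, Rd) needs on the order of 10^4 muscle-stage
solves; an adaptive solver per grid point is far too slow.  Because the
exposure y_tau(t) is an exogenous forcing (exact, from the closed-form PK
solution) and Rd enters only through the multiplier 1 - y^3/Rd^3, the whole
(tau, Rd) grid can be advanced in lock-step by one classic RK4 recursion on
arrays: y^3 is precomputed at every RK4 substage time per tau, and Rd^-3 is
a broadcast axis.  The fixed step also makes finite-difference parameter
sensitivities clean, since perturbed and nominal runs share the identical
discretisation.

Accuracy is set by the step (default 0.005 day); the adaptive LSODA path in
:mod:`cachexim.coupled` is the independent oracle for this backend.
"""

from __future__ import annotations

import numpy as np

from .pharmacokinetics import PKSolution
from .tissue import MuscleParams

#: Default RK4 step in days.
DEFAULT_STEP = 0.005


def substep_times(t_end: float, h: float) -> tuple[np.ndarray, int]:
    """Times 0, h/2, h, 3h/2, ... t_end covering every RK4 substage.

    Returns the (2*n_steps + 1,) time array and the step count.
    """
    n_steps = int(round(t_end / h))
    return np.linspace(0.0, t_end, 2 * n_steps + 1), n_steps


def exposure_cubed_substeps(
    sol: PKSolution, tau: float, t_end: float, h: float
) -> np.ndarray:
    """y_tau(t)^3 evaluated exactly at every RK4 substage time."""
    times, _ = substep_times(t_end, h)
    return sol.exposure(times, tau) ** 3


def integrate_muscle(
    ycube: np.ndarray,
    inv_rd3: np.ndarray | float,
    mp: MuscleParams,
    S0: float,
    M0: float,
    h: float,
    sample_steps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance (S, M) with RK4 over a broadcast (tau-grid, Rd-grid) stack.

    ``ycube`` holds y^3 at substage times with shape (..., 2*n_steps + 1);
    leading axes enumerate exposure variants (e.g. tau values).  ``inv_rd3``
    (= Rd^-3) broadcasts against those leading axes.  Returns S and M at the
    requested step indices, shaped broadcast_shape + (len(sample_steps),).
    """
    n_steps = (ycube.shape[-1] - 1) // 2
    shape = np.broadcast_shapes(ycube.shape[:-1], np.shape(inv_rd3))
    inv_rd3 = np.asarray(inv_rd3, dtype=float)
    S = np.full(shape, float(S0))
    M = np.full(shape, float(M0))

    p0, p1, nu0, nu1, d0, m = mp.p0, mp.p1, mp.nu0, mp.nu1, mp.d0, mp.m

    def rates(S, M, f):
        denom = 1.0 + M / m
        p = p0 + p1 / denom
        nu = nu0 + nu1 / denom
        nuS = nu * S
        dS = f * (2.0 * p - 1.0) * nuS
        dM = f * (2.0 * (1.0 - p)) * nuS - d0 * M
        return dS, dM

    sample_steps = np.asarray(sample_steps, dtype=int)
    n_out = sample_steps.size
    S_out = np.empty(shape + (n_out,))
    M_out = np.empty(shape + (n_out,))
    out_pos = 0
    if n_out and sample_steps[0] == 0:
        S_out[..., 0] = S
        M_out[..., 0] = M
        out_pos = 1

    half = h / 2.0
    sixth = h / 6.0
    for i in range(n_steps):
        f_a = 1.0 - ycube[..., 2 * i] * inv_rd3
        f_b = 1.0 - ycube[..., 2 * i + 1] * inv_rd3
        f_c = 1.0 - ycube[..., 2 * i + 2] * inv_rd3
        k1S, k1M = rates(S, M, f_a)
        k2S, k2M = rates(S + half * k1S, M + half * k1M, f_b)
        k3S, k3M = rates(S + half * k2S, M + half * k2M, f_b)
        k4S, k4M = rates(S + h * k3S, M + h * k3M, f_c)
        S = S + sixth * (k1S + 2.0 * (k2S + k3S) + k4S)
        M = M + sixth * (k1M + 2.0 * (k2M + k3M) + k4M)
        if out_pos < n_out and sample_steps[out_pos] == i + 1:
            S_out[..., out_pos] = S
            M_out[..., out_pos] = M
            out_pos += 1
    if out_pos != n_out:
        raise ValueError("sample_steps must be sorted step indices within the run")
    return S_out, M_out


def lean_mass_at_days(
    sol: PKSolution,
    tau_values: np.ndarray,
    rd_values: np.ndarray,
    mp: MuscleParams,
    S0: float,
    M0: float,
    days: np.ndarray,
    h: float = DEFAULT_STEP,
) -> np.ndarray:
    """Lean mass (g) at the given days for a full (tau, Rd) grid.

    One schedule/dose (one PK solution) at a time; returns an array of shape
    (len(tau_values), len(rd_values), len(days)).  The requested days must
    be representable on the step grid.
    """
    days = np.asarray(days, dtype=float)
    steps = days / h
    sample_steps = np.rint(steps).astype(int)
    if np.max(np.abs(steps - sample_steps)) > 1e-9:
        raise ValueError("observation days must be multiples of the RK4 step")
    t_end = float(days[-1])
    ycube = np.stack(
        [exposure_cubed_substeps(sol, tau, t_end, h) for tau in np.atleast_1d(tau_values)]
    )[:, None, :]
    inv_rd3 = np.atleast_1d(rd_values).astype(float) ** -3.0
    S, M = integrate_muscle(ycube, inv_rd3, mp, S0, M0, h, sample_steps)
    return mp.density * (S + M)
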