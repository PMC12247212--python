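"""Shared fixtures and the independent ODE oracle.

The oracle integrates the 1:1 mass-action rate equation
dR/dt = k_on*C(t)*(R_max - R) - k_off*R numerically, segment by segment
with piecewise-constant analyte concentration, and is used to validate the
closed-form piecewise model it knows nothing about.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.integrate import solve_ivp

from blifit import (
    AssaySchedule,
    KineticParameters,
    StepKind,
    default_schedule,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

NM = 1e-9


def ode_trace(
    times: np.ndarray,
    schedule: AssaySchedule,
    params: KineticParameters,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> np.ndarray:
    """Numerically integrated standard-model trace at the given times.

    Piecewise-constant C(t): the analyte concentration of the current
    association well, zero in dissociation steps.  R(0) = 0.
    """
    times = np.asarray(times, dtype=float)
    segments = []
    t = 0.0
    for step in schedule.kinetic_steps:
        c = step.concentration if step.kind is StepKind.ASSOCIATION else 0.0
        segments.append((t, t + step.duration, c))
        t += step.duration

    out = np.empty_like(times)
    r0 = 0.0
    for t_start, t_end, c in segments:
        if t_end == segments[-1][1]:  # last segment keeps its right edge
            sel = times >= t_start - 1e-12
        else:
            sel = (times >= t_start - 1e-12) & (times < t_end - 1e-12)
        ts = times[sel]
        if ts.size and abs(ts[-1] - t_end) < 1e-12:
            t_eval = ts
        else:
            t_eval = np.append(ts, t_end)
        sol = solve_ivp(
            lambda _t, r, c=c: params.k_on * c * (params.r_max - r[0])
            - params.k_off * r[0],
            (t_start, t_end),
            [r0],
            t_eval=np.clip(t_eval, t_start, t_end),
            rtol=rtol,
            atol=atol,
            method="LSODA",
        )
        out[sel] = sol.y[0][: ts.size]
        r0 = float(sol.y[0][-1])
    return out


@pytest.fixture(scope="session")
def five_well_schedule() -> AssaySchedule:
    """Routine 5-well design: 25–400 nM, 300→100 s dwells, 30 s minis,
    600 s final dissociation."""
    return default_schedule([25 * NM, 50 * NM, 100 * NM, 200 * NM, 400 * NM])


@pytest.fixture(scope="session")
def mid_nanomolar_params() -> KineticParameters:
    """Mid-nanomolar truth (K_D ~= 48.7 nM), typical nanobody rates."""
    return KineticParameters(k_on=2.3e5, k_off=1.12e-2, r_max=0.14)
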