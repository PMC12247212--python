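"""Closed-form piecewise 1:1 binding models for single-cycle kinetics.

A single-cycle sensorgram is described segment by segment on the continuous
assay clock.  Within an association well at analyte concentration ``C`` the
response relaxes exponentially towards the equilibrium level

    R_eq = R_max * k_on*C / (k_on*C + k_off)

at observed rate ``k_on*C + k_off``; within a dissociation step it decays
exponentially at rate ``k_off``.  Segments are chained by forcing the
starting response of each step to equal the ending response of the
previous one, and the trace starts from R = 0 at t = 0 (entry into the
first analyte well).  Only three parameters are global across the whole
trace: k_on, k_off and R_max, with K_D = k_off/k_on.

The partial-dissociation variant lets every dissociation step decay
towards a plateau R_inf instead of zero, either with one free plateau per
dissociation segment (local-plateau parametrisation) or with a single
mobile-fraction parameter phi shared across segments, which pins each
plateau to R_inf = phi * R_start (global-mobile-fraction parametrisation).
phi = 0 recovers the standard model; the upper bound phi <= 0.95 demands
that at least 5% of the signal eventually dissociates — a trace flatter
than that is better explained as a very tight binder.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import DomainError, ModelError, ValidationError
from .schedule import AssaySchedule, StepKind
from .sensorgram import Sensorgram

__all__ = [
    "KineticParameters",
    "PartialDissociationMode",
    "PartialDissociationParameters",
    "SegmentState",
    "PHI_MAX",
    "equilibrium_response",
    "response_association",
    "response_dissociation",
    "response_dissociation_partial",
    "evaluate_trace",
    "predict_trace",
    "dissociation_constant",
]

#: Upper bound on the mobile-fraction parameter: at least 5% of the signal
#: must eventually dissociate for a partial-dissociation fit to be credible.
PHI_MAX = 0.95


@dataclass(frozen=True)
class KineticParameters:
    """1:1 binding rate constants and saturation response.

    k_on in 1/(M s), k_off in 1/s, R_max in nm; all strictly positive.
    """

    k_on: float
    k_off: float
    r_max: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "r_max"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{name} must be finite and strictly positive, got {v!r}"
                )

    @property
    def k_d(self) -> float:
        """Equilibrium dissociation constant K_D = k_off/k_on, molar."""
        return self.k_off / self.k_on


class PartialDissociationMode(str, enum.Enum):
    LOCAL_PLATEAU = "local_plateau"
    GLOBAL_MOBILE_FRACTION = "global_mobile_fraction"


@dataclass(frozen=True)
class PartialDissociationParameters:
    """Partial-dissociation extension of :class:`KineticParameters`.

    In GLOBAL_MOBILE_FRACTION mode the single parameter ``phi`` pins each
    dissociation plateau to ``phi * R_start`` of that segment; in
    LOCAL_PLATEAU mode ``plateaus`` carries one free R_inf (nm) per
    dissociation segment of the schedule, clamped to [0, R_start] when the
    trace is evaluated.
    """

    base: KineticParameters
    mode: PartialDissociationMode = PartialDissociationMode.GLOBAL_MOBILE_FRACTION
    phi: float = 0.0
    plateaus: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode is PartialDissociationMode.GLOBAL_MOBILE_FRACTION:
            if not (0.0 <= self.phi <= PHI_MAX):
                raise ValidationError(
                    f"phi must lie in [0, {PHI_MAX}], got {self.phi!r}"
                )
        else:
            object.__setattr__(self, "plateaus", tuple(float(p) for p in self.plateaus))
            if any(not (math.isfinite(p) and p >= 0) for p in self.plateaus):
                raise ValidationError("plateaus must be finite and >= 0")

    @property
    def k_on(self) -> float:
        return self.base.k_on

    @property
    def k_off(self) -> float:
        return self.base.k_off

    @property
    def r_max(self) -> float:
        return self.base.r_max

    @property
    def k_d(self) -> float:
        return self.base.k_d


ModelParameters = Union[KineticParameters, PartialDissociationParameters]


@dataclass(frozen=True)
class SegmentState:
    """Boundary condition of a segment: its entry time and the response
    propagated from the end of the previous segment."""

    t_start: float
    r_start: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.r_start) or self.r_start < -1e-12:
            raise ValidationError(
                f"segment start response must be finite and >= 0, got {self.r_start!r}"
            )


def equilibrium_response(c: float, params: KineticParameters) -> float:
    """Equilibrium response R_eq = R_max * k_on*C / (k_on*C + k_off).

    Zero at C = 0, approaches R_max as C grows, strictly increasing in C;
    half-saturation at C = K_D.
    """
    if c < 0:
        raise DomainError(f"analyte concentration must be >= 0, got {c!r}")
    kc = params.k_on * c
    return params.r_max * kc / (kc + params.k_off)


def response_association(
    t: float | np.ndarray,
    state: SegmentState,
    c: float,
    params: KineticParameters,
) -> float | np.ndarray:
    """Association-segment response.

    R(t) = R_eq + (R_start - R_eq) * exp(-(k_on*C + k_off)*(t - t_start)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < state.t_start):
        raise DomainError("t must be >= the segment start time")
    if c <= 0:
        raise DomainError(f"association requires C > 0, got {c!r}")
    r_eq = equilibrium_response(c, params)
    k_obs = params.k_on * c + params.k_off
    out = r_eq + (state.r_start - r_eq) * np.exp(-k_obs * (t - state.t_start))
    return float(out) if out.ndim == 0 else out


def response_dissociation(
    t: float | np.ndarray, state: SegmentState, k_off: float
) -> float | np.ndarray:
    """Dissociation-segment response R(t) = R_start * exp(-k_off*(t - t_start))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < state.t_start):
        raise DomainError("t must be >= the segment start time")
    out = state.r_start * np.exp(-k_off * (t - state.t_start))
    return float(out) if out.ndim == 0 else out


def response_dissociation_partial(
    t: float | np.ndarray, state: SegmentState, k_off: float, r_inf: float
) -> float | np.ndarray:
    """Dissociation towards a plateau:
    R(t) = (R_start - R_inf) * exp(-k_off*(t - t_start)) + R_inf.

    With R_inf = 0 this is exactly :func:`response_dissociation`.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < state.t_start):
        raise DomainError("t must be >= the segment start time")
    if r_inf < 0 or r_inf > state.r_start + 1e-12:
        raise DomainError(
            f"plateau R_inf = {r_inf!r} must lie in [0, R_start = {state.r_start!r}]"
        )
    out = (state.r_start - r_inf) * np.exp(-k_off * (t - state.t_start)) + r_inf
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class _Segment:
    kind: StepKind
    state: SegmentState
    t_end: float
    c: float | None  # association concentration, molar
    r_inf: float  # dissociation plateau (0 for the standard model)


def _chain_segments(
    schedule: AssaySchedule, params: ModelParameters
) -> list[_Segment]:
    """Propagate the closed forms across the kinetic steps, forcing each
    segment to start where the previous one ended (exact continuity)."""
    if isinstance(params, PartialDissociationParameters):
        base = params.base
        partial = params
    else:
        base = params
        partial = None

    segments: list[_Segment] = []
    t = 0.0
    r = 0.0  # R_0(t = 0) = 0: the sensor enters the first analyte well bare
    diss_counter = 0
    for step in schedule.kinetic_steps:
        state = SegmentState(t_start=t, r_start=r)
        t_end = t + step.duration
        if step.kind is StepKind.ASSOCIATION:
            seg = _Segment(step.kind, state, t_end, step.concentration, 0.0)
            r = response_association(t_end, state, step.concentration, base)
        else:
            if partial is None:
                r_inf = 0.0
            elif partial.mode is PartialDissociationMode.GLOBAL_MOBILE_FRACTION:
                r_inf = partial.phi * state.r_start
            else:
                if diss_counter >= len(partial.plateaus):
                    raise ModelError(
                        f"local-plateau parameters carry {len(partial.plateaus)} "
                        f"plateaus but the schedule has "
                        f"{schedule.n_dissociation_segments} dissociation segments"
                    )
                # free parameter, clamped to the physically meaningful range
                r_inf = min(max(partial.plateaus[diss_counter], 0.0), state.r_start)
            seg = _Segment(step.kind, state, t_end, None, r_inf)
            r = response_dissociation_partial(t_end, state, base.k_off, r_inf)
            diss_counter += 1
        segments.append(seg)
        t = t_end
    return segments


def evaluate_trace(
    times: np.ndarray, schedule: AssaySchedule, params: ModelParameters
) -> np.ndarray:
    """Evaluate the piecewise model at arbitrary times on the continuous
    clock (t >= 0).  Times beyond the schedule end extrapolate the final
    dissociation; negative times are a domain error (pre-analyte steps are
    not modelled)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < -1e-9):
        raise DomainError("model evaluation requires times on the kinetic clock (>= 0)")
    segments = _chain_segments(schedule, params)
    base = params.base if isinstance(params, PartialDissociationParameters) else params

    boundaries = np.array([seg.t_end for seg in segments[:-1]])
    idx = np.searchsorted(boundaries, times, side="right")
    out = np.empty_like(times)
    for i, seg in enumerate(segments):
        sel = idx == i
        if not np.any(sel):
            continue
        t_sel = np.maximum(times[sel], seg.state.t_start)
        if seg.kind is StepKind.ASSOCIATION:
            out[sel] = response_association(t_sel, seg.state, seg.c, base)
        else:
            out[sel] = response_dissociation_partial(
                t_sel, seg.state, base.k_off, seg.r_inf
            )
    return out


def predict_trace(
    schedule: AssaySchedule,
    params: ModelParameters,
    grid: float = 1.0,
) -> Sensorgram:
    """Predict a noiseless single-cycle sensorgram on a regular grid.

    Samples run from t = 0 (entry into the first analyte well) to the end
    of the final dissociation at ``grid``-second spacing (default 1 s,
    a typical BLI acquisition cadence) and are annotated with their step
    index so the result is compatible with the sensorgram pre-processing
    and fitting machinery.
    """
    if grid <= 0:
        raise DomainError(f"grid spacing must be > 0, got {grid!r}")
    total = schedule.kinetic_duration
    n = int(math.floor(total / grid + 1e-9)) + 1
    times = np.arange(n) * grid
    responses = evaluate_trace(times, schedule, params)

    first = schedule.first_association_index
    starts = np.cumsum([0.0] + [s.duration for s in schedule.kinetic_steps])
    idx = np.searchsorted(starts[1:-1], times, side="right") + first
    return Sensorgram(times=times, responses=responses, step_index=idx.astype(int))


def dissociation_constant(params: KineticParameters) -> float:
    """K_D = k_off / k_on, in molar."""
    return params.k_d
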