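"""Assay-design rules for single-cycle runs.

Encodes the practical design guidance for kinetic titrations: when an
approximate K_D is known, the five-well 1:2 concentration ladder should
span roughly one-half to ten-fold K_D; for very tight (picomolar) binders
a 10x-K_D top concentration would give no measurable signal, so the top
of the ladder is floored at 4 nM — the concentration range actually used
for single-digit-picomolar binders.  The final dissociation is extended
until the expected fractional signal loss reaches about 5%, the minimum
drop needed for a reliable slow k_off, capped at five hours.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ValidationError
from .schedule import AssaySchedule, AssayStep, StepKind
from .simulate import _DWELL_LONGEST, _DWELL_SHORTEST, _MINI_DISSOCIATION_S

__all__ = [
    "concentration_series",
    "final_dissociation_duration",
    "schedule_for_affinity",
]

#: top-of-ladder concentration floor for tight binders, molar (4 nM)
TOP_CONCENTRATION_FLOOR = 4e-9
#: fractional signal drop the final dissociation should reach
MIN_DISSOCIATION_DROP = 0.05
#: hard cap on the final dissociation, seconds (5 h)
FINAL_DISSOCIATION_CAP = 18000.0


def concentration_series(
    k_d: float,
    n_wells: int = 5,
    top_multiple: float = 10.0,
    dilution: float = 2.0,
) -> list[float]:
    """1:``dilution`` analyte ladder (molar, ascending) for a known K_D.

    Top concentration is ``top_multiple * K_D`` but never below the 4 nM
    floor used for picomolar binders; with the defaults the five wells
    span ~0.6x to 10x K_D for nanomolar-and-weaker affinities.
    """
    if not (math.isfinite(k_d) and k_d > 0):
        raise ValidationError(f"K_D must be finite and > 0, got {k_d!r}")
    if n_wells < 1:
        raise ValidationError("need at least one well")
    if dilution <= 1:
        raise ValidationError("dilution factor must exceed 1")
    top = max(top_multiple * k_d, TOP_CONCENTRATION_FLOOR)
    return [top / dilution**i for i in reversed(range(n_wells))]


def final_dissociation_duration(
    k_off: float,
    min_drop: float = MIN_DISSOCIATION_DROP,
    floor: float = 600.0,
    cap: float = FINAL_DISSOCIATION_CAP,
) -> float:
    """Final-dissociation dwell (s) long enough for a ``min_drop``
    fractional signal loss at the expected k_off, within [floor, cap]."""
    if not (math.isfinite(k_off) and k_off > 0):
        raise ValidationError(f"k_off must be finite and > 0, got {k_off!r}")
    t_needed = -math.log(1.0 - min_drop) / k_off
    return float(np.clip(t_needed, floor, cap))


def schedule_for_affinity(
    k_on: float,
    k_off: float,
    n_wells: int = 5,
    top_multiple: float = 10.0,
    dilution: float = 2.0,
) -> AssaySchedule:
    """Design a full single-cycle schedule around an expected affinity.

    Combines :func:`concentration_series` for the analyte ladder, the
    routine tapered association dwells (300 s down to 100 s, lowest to
    highest concentration), 30 s mini-dissociations, and a final
    dissociation extended per :func:`final_dissociation_duration`.
    """
    conc = concentration_series(k_off / k_on, n_wells, top_multiple, dilution)
    if n_wells == 1:
        dwells = [_DWELL_LONGEST]
    else:
        dwells = list(np.linspace(_DWELL_LONGEST, _DWELL_SHORTEST, n_wells))
    steps: list[AssayStep] = []
    for i, (c, d) in enumerate(zip(conc, dwells)):
        steps.append(AssayStep(StepKind.ASSOCIATION, duration=d, concentration=c))
        if i < n_wells - 1:
            steps.append(AssayStep(StepKind.MINI_DISSOCIATION, _MINI_DISSOCIATION_S))
    steps.append(
        AssayStep(StepKind.FINAL_DISSOCIATION, final_dissociation_duration(k_off))
    )
    return AssaySchedule(steps)
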