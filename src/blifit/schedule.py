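"""Assay schedules for single-cycle (kinetic-titration) BLI runs.

A single-cycle run moves one sensor through an ordered sequence of wells:
surface preparation (loading / blocking / baseline), then the kinetic part —
analyte associations at strictly increasing concentrations, separated by
short "mini-dissociation" buffer transfers, and a terminal final
dissociation.  The kinetic part is fitted globally on a continuous clock
that starts (t = 0) when the sensor enters the first analyte well.

Concentrations are stated in nM in config files (the unit figure captions
use) and held in molar internally.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "StepKind",
    "AssayStep",
    "AssaySchedule",
    "read_schedule",
    "write_schedule",
]

NM_PER_MOLAR = 1e9


class StepKind(str, enum.Enum):
    """Kind of assay step; kinetic steps are the last three."""

    LOADING = "loading"
    BLOCKING = "blocking"
    BASELINE = "baseline"
    ASSOCIATION = "association"
    MINI_DISSOCIATION = "mini_dissociation"
    FINAL_DISSOCIATION = "final_dissociation"

    @property
    def is_kinetic(self) -> bool:
        return self in _KINETIC_KINDS

    @property
    def is_dissociation(self) -> bool:
        return self in (StepKind.MINI_DISSOCIATION, StepKind.FINAL_DISSOCIATION)


_KINETIC_KINDS = frozenset(
    {StepKind.ASSOCIATION, StepKind.MINI_DISSOCIATION, StepKind.FINAL_DISSOCIATION}
)


@dataclass(frozen=True)
class AssayStep:
    """One well of the assay.

    Parameters
    ----------
    kind
        Step kind.
    duration
        Dwell time in seconds, strictly positive and finite.
    concentration
        Analyte concentration in molar.  Required exactly when
        ``kind == StepKind.ASSOCIATION``.
    label
        Free-text annotation (well position, sample name, ...).
    """

    kind: StepKind
    duration: float
    concentration: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "duration", float(self.duration))
        if self.concentration is not None:
            object.__setattr__(self, "concentration", float(self.concentration))
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValidationError(
                f"step duration must be positive and finite, got {self.duration!r}"
            )
        if self.kind is StepKind.ASSOCIATION:
            if self.concentration is None:
                raise ValidationError("association step requires a concentration")
            if not (math.isfinite(self.concentration) and self.concentration >= 0):
                raise ValidationError(
                    f"association concentration must be finite and >= 0, "
                    f"got {self.concentration!r}"
                )
        elif self.concentration is not None:
            raise ValidationError(
                f"{self.kind.value} step must not carry a concentration"
            )


@dataclass(frozen=True)
class AssaySchedule:
    """Ordered, validated sequence of assay steps.

    The continuous assay clock starts at 0 when the sensor enters the first
    association well; pre-analyte steps (loading/blocking/baseline) sit at
    negative clock times and are excluded from kinetic fitting.

    Invariants enforced at construction:

    * at least one association; association concentrations strictly increase
      along the schedule (sensors always move from lowest to highest);
    * exactly one final dissociation, and it is the last step;
    * every association except possibly the last is followed by a
      mini-dissociation;
    * pre-analyte steps all precede the first association.
    """

    steps: tuple[AssayStep, ...]

    def __init__(self, steps: Iterable[AssayStep]):
        object.__setattr__(self, "steps", tuple(steps))
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        steps = self.steps
        if not steps:
            raise ValidationError("schedule has no steps")

        assoc_idx = [i for i, s in enumerate(steps) if s.kind is StepKind.ASSOCIATION]
        if not assoc_idx:
            raise ValidationError("schedule has no association step")

        final_idx = [
            i for i, s in enumerate(steps) if s.kind is StepKind.FINAL_DISSOCIATION
        ]
        if len(final_idx) != 1:
            raise ValidationError(
                f"schedule must contain exactly one final dissociation, "
                f"found {len(final_idx)}"
            )
        if final_idx[0] != len(steps) - 1:
            raise ValidationError("final dissociation must be the last step")

        first_assoc = assoc_idx[0]
        for i, s in enumerate(steps[:first_assoc]):
            if s.kind.is_kinetic:
                raise ValidationError(
                    f"kinetic step {s.kind.value} at position {i} precedes the "
                    "first association"
                )
        for i, s in enumerate(steps[first_assoc:], start=first_assoc):
            if not s.kind.is_kinetic:
                raise ValidationError(
                    f"pre-analyte step {s.kind.value} at position {i} follows the "
                    "first association"
                )

        conc = [steps[i].concentration for i in assoc_idx]
        for lo, hi in zip(conc, conc[1:]):
            if not hi > lo:
                raise ValidationError(
                    "association concentrations must strictly increase along the "
                    "schedule (sensors move from lowest to highest concentration); "
                    f"got {lo * NM_PER_MOLAR:g} nM followed by "
                    f"{hi * NM_PER_MOLAR:g} nM"
                )

        # every association except possibly the last is followed by a mini
        for i in assoc_idx[:-1]:
            if steps[i + 1].kind is not StepKind.MINI_DISSOCIATION:
                raise ValidationError(
                    f"association at position {i} must be followed by a "
                    "mini-dissociation"
                )

    # -- derived clock quantities ----------------------------------------

    @property
    def first_association_index(self) -> int:
        for i, s in enumerate(self.steps):
            if s.kind is StepKind.ASSOCIATION:
                return i
        raise ValidationError("schedule has no association step")  # pragma: no cover

    @property
    def pre_kinetic_duration(self) -> float:
        """Total duration of loading/blocking/baseline steps, seconds."""
        return sum(s.duration for s in self.steps[: self.first_association_index])

    @property
    def kinetic_steps(self) -> tuple[AssayStep, ...]:
        return self.steps[self.first_association_index :]

    @property
    def kinetic_duration(self) -> float:
        """Duration of the kinetic part on the continuous clock, seconds."""
        return sum(s.duration for s in self.kinetic_steps)

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.steps)

    def step_start_times(self) -> list[float]:
        """Entry time of every step on the continuous clock (first
        association = 0; pre-analyte steps negative)."""
        starts, t = [], -self.pre_kinetic_duration
        for s in self.steps:
            starts.append(t)
            t += s.duration
        return starts

    @property
    def association_times(self) -> list[float]:
        """t_i: entry time of each association well on the continuous clock."""
        starts = self.step_start_times()
        return [
            starts[i]
            for i, s in enumerate(self.steps)
            if s.kind is StepKind.ASSOCIATION
        ]

    @property
    def t_off(self) -> float:
        """Entry time of the final dissociation on the continuous clock."""
        return self.step_start_times()[-1]

    @property
    def concentrations(self) -> list[float]:
        """Association concentrations in molar, in schedule order."""
        return [
            s.concentration  # type: ignore[misc]
            for s in self.steps
            if s.kind is StepKind.ASSOCIATION
        ]

    @property
    def n_dissociation_segments(self) -> int:
        return sum(1 for s in self.steps if s.kind.is_dissociation)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for s in self.steps:
            d: dict = {"kind": s.kind.value, "duration_s": s.duration}
            if s.concentration is not None:
                d["concentration_nM"] = s.concentration * NM_PER_MOLAR
            if s.label:
                d["label"] = s.label
            out.append(d)
        return {"steps": out}

    @classmethod
    def from_dict(cls, data: dict) -> "AssaySchedule":
        if not isinstance(data, dict) or "steps" not in data:
            raise FormatError("schedule config must be a mapping with a 'steps' key")
        raw = data["steps"]
        if not isinstance(raw, Sequence) or isinstance(raw, (str, bytes)):
            raise FormatError("'steps' must be a sequence of step mappings")
        steps = []
        for i, item in enumerate(raw):
            if not isinstance(item, dict):
                raise FormatError(f"step {i} is not a mapping")
            unknown = set(item) - {"kind", "duration_s", "concentration_nM", "label"}
            if unknown:
                raise FormatError(
                    f"step {i} has unknown keys: {sorted(unknown)}"
                )
            try:
                kind = StepKind(str(item["kind"]).lower())
            except (KeyError, ValueError) as exc:
                raise FormatError(f"step {i} has missing or invalid 'kind'") from exc
            if "duration_s" not in item:
                raise FormatError(f"step {i} lacks 'duration_s'")
            conc_nm = item.get("concentration_nM")
            steps.append(
                AssayStep(
                    kind=kind,
                    duration=float(item["duration_s"]),
                    concentration=None if conc_nm is None else float(conc_nm) / NM_PER_MOLAR,
                    label=str(item.get("label", "")),
                )
            )
        return cls(steps)


def read_schedule(path: str | Path) -> AssaySchedule:
    """Read an :class:`AssaySchedule` from a YAML or JSON config file.

    The config lists ``steps``, each with ``kind``, ``duration_s`` and, for
    association steps, ``concentration_nM`` (converted to molar internally).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"schedule config not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse schedule config {path}: {exc}") from exc
    return AssaySchedule.from_dict(data)


def write_schedule(schedule: AssaySchedule, path: str | Path) -> None:
    """Write a schedule config (YAML or JSON by extension)."""
    path = Path(path)
    data = schedule.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
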