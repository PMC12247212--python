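"""Sensorgram container, CSV I/O and pre-processing.

The native exchange format is a tidy CSV with ``time_s`` and ``response_nm``
columns (extra columns are ignored).  Instrument vendors export many
dialects; converting to this format is the caller's responsibility.

Pre-processing covers the three operations routinely applied before a
global kinetic fit: aligning the trace onto the continuous assay clock,
subtracting a matched reference (control) sensor, and optionally removing
inter-step bulk shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CoverageError,
    FormatError,
    ParseError,
    ValidationError,
)
from .schedule import AssaySchedule

__all__ = [
    "Sensorgram",
    "read_sensorgram_table",
    "write_sensorgram_table",
    "align_to_assay_clock",
    "subtract_reference",
    "correct_interstep_shifts",
]


@dataclass(frozen=True)
class Sensorgram:
    """A biosensor response time series.

    Attributes
    ----------
    times
        Sample times in seconds, strictly increasing.
    responses
        Interference shift in nm, finite, same length as ``times``.
    step_index
        Per-sample index into the schedule's steps, set by
        :func:`align_to_assay_clock` (``-1`` marks samples outside the
        schedule).  ``None`` until aligned.
    label
        Free-text sensor identifier.
    """

    times: np.ndarray
    responses: np.ndarray
    step_index: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        responses = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "responses", responses)
        if times.ndim != 1 or responses.ndim != 1:
            raise ValidationError("times and responses must be 1-D")
        if times.size != responses.size:
            raise ValidationError(
                f"times ({times.size}) and responses ({responses.size}) differ "
                "in length"
            )
        if not np.all(np.isfinite(times)):
            raise ValidationError("times contain non-finite values")
        if not np.all(np.isfinite(responses)):
            raise ValidationError("responses contain non-finite values")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ValidationError(
                f"times must be strictly increasing (violation at sample {bad})"
            )
        if self.step_index is not None:
            si = np.asarray(self.step_index, dtype=int)
            if si.shape != times.shape:
                raise ValidationError("step_index must match times in length")
            object.__setattr__(self, "step_index", si)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def is_aligned(self) -> bool:
        return self.step_index is not None

    def kinetic_mask(self, schedule: AssaySchedule) -> np.ndarray:
        """Boolean mask of samples belonging to kinetic steps
        (association / mini-dissociation / final dissociation)."""
        if self.step_index is None:
            raise ValidationError("sensorgram is not aligned to a schedule")
        kinetic = np.array(
            [s.kind.is_kinetic for s in schedule.steps], dtype=bool
        )
        mask = np.zeros(len(self), dtype=bool)
        valid = self.step_index >= 0
        mask[valid] = kinetic[self.step_index[valid]]
        return mask

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times, "response_nm": self.responses})
        if self.step_index is not None:
            df["step_index"] = self.step_index
        return df


def read_sensorgram_table(
    path: str | Path,
    time_column: str = "time_s",
    response_column: str = "response_nm",
) -> Sensorgram:
    """Read a sensorgram from a tidy CSV table.

    Extra columns are ignored.  At least 4 rows are required — fewer
    samples cannot support any kinetic analysis.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"sensorgram file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (time_column, response_column):
        if col not in df.columns:
            raise FormatError(
                f"column {col!r} not found in {path} "
                f"(available: {list(df.columns)})"
            )
    if len(df) < 4:
        raise FormatError(
            f"{path} has only {len(df)} rows; at least 4 are required"
        )
    values = {}
    for col in (time_column, response_column):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}",
                row=row,
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"missing value in column {col!r} at data row {row}", row=row)
        values[col] = numeric.to_numpy(dtype=float)
    return Sensorgram(
        times=values[time_column],
        responses=values[response_column],
        label=path.stem,
    )


def write_sensorgram_table(sg: Sensorgram, path: str | Path) -> None:
    """Write a sensorgram as tidy CSV at full float precision (round-trip
    safe: times/responses re-read bit-for-bit)."""
    sg.to_frame().to_csv(Path(path), index=False, float_format="%.17g")


def align_to_assay_clock(
    sg: Sensorgram,
    schedule: AssaySchedule,
    boundary_tolerance_samples: int = 1,
) -> Sensorgram:
    """Put a raw trace onto the continuous assay clock.

    The trace is assumed to start when the sensor enters the first scheduled
    step.  Times are shifted so the first sample of the first association
    well sits at t = 0; pre-analyte samples keep negative times and are
    annotated with their (non-kinetic) step index.  Step boundaries are
    taken from the scheduled dwell times, not detected from the data; a
    tolerance of ``boundary_tolerance_samples`` sample intervals absorbs
    acquisition jitter at the end of the run.
    """
    times = sg.times - sg.times[0]
    dt = float(np.median(np.diff(times))) if len(sg) > 1 else 0.0
    tol = boundary_tolerance_samples * dt
    if times[-1] + tol < schedule.total_duration:
        raise CoverageError(
            f"sensorgram spans {times[-1]:.1f} s but the schedule requires "
            f"{schedule.total_duration:.1f} s"
        )

    starts = np.cumsum([0.0] + [s.duration for s in schedule.steps])
    # sample at exactly a boundary time belongs to the later step
    idx = np.searchsorted(starts[1:-1], times, side="right")
    step_index = idx.astype(int)
    step_index[times >= starts[-1] + tol] = -1  # beyond the schedule

    shifted = times - schedule.pre_kinetic_duration
    return Sensorgram(
        times=shifted, responses=sg.responses, step_index=step_index, label=sg.label
    )


def subtract_reference(assay: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Subtract a matched reference (control) sensor trace pointwise.

    Both traces must be aligned to the same schedule.  When the grids
    differ the reference is linearly interpolated onto the assay grid; the
    assay time range must be covered by the reference.
    """
    if not (assay.is_aligned and reference.is_aligned):
        raise ValidationError("both sensorgrams must be aligned before subtraction")
    t0, t1 = assay.times[0], assay.times[-1]
    if reference.times[0] > t0 or reference.times[-1] < t1:
        raise AlignmentError(
            f"reference trace [{reference.times[0]:.2f}, "
            f"{reference.times[-1]:.2f}] s does not cover the assay trace "
            f"[{t0:.2f}, {t1:.2f}] s"
        )
    if assay.times.shape == reference.times.shape and np.array_equal(
        assay.times, reference.times
    ):
        ref_resp = reference.responses
    else:
        ref_resp = np.interp(assay.times, reference.times, reference.responses)
    return replace(assay, responses=assay.responses - ref_resp)


def correct_interstep_shifts(
    sg: Sensorgram, schedule: AssaySchedule
) -> Sensorgram:
    """Remove rigid bulk-shift offsets at kinetic step boundaries.

    Bulk refractive-index differences between wells offset the whole trace
    from a boundary onward without reflecting binding.  Each kinetic
    segment after the first is rigidly shifted so that its first sample
    equals the last sample of the previous kinetic segment; the first
    kinetic segment is never moved.  The operation is idempotent and is
    disabled by default in the fitting pipeline (enable explicitly when a
    control sensor reveals bulk shifts).
    """
    if sg.step_index is None:
        raise ValidationError("sensorgram must be aligned before shift correction")
    kinetic_steps = [
        i for i, s in enumerate(schedule.steps) if s.kind.is_kinetic
    ]
    responses = sg.responses.copy()
    prev_last: float | None = None
    for i in kinetic_steps:
        seg = np.flatnonzero(sg.step_index == i)
        if seg.size == 0:
            continue
        if prev_last is not None:
            # gap measured against the already-corrected previous segment
            responses[seg] -= responses[seg[0]] - prev_last
        prev_last = responses[seg[-1]]
    return replace(sg, responses=responses)
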