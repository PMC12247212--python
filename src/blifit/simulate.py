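"""Synthetic single-cycle sensorgram generator.

Produces the schedules, noiseless/noisy traces, loading-phase traces and
whole fixture plates that exercise the rest of the package without any
instrument data.  The default schedule is the routine single-cycle design
for high-picomolar-to-mid-nanomolar binders: five analyte wells with
association dwell times tapered 300/250/200/150/100 s from lowest to
highest concentration, 30 s mini-dissociation transfers between wells,
and a 600 s final dissociation (1200 s with ``long_final``).

Noise emulates the artefacts a real run can show: iid Gaussian sample
noise (default sigma 0.005 nm, inside the 0.0035–0.018 nm range of fit
RMSEs observed on real traces), optional linear drift, and optional
bulk-refractive shifts injected at step boundaries that accumulate along
the trace (each boundary's offset carries forward, as in real data).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError, ValidationError
from .models import ModelParameters, PartialDissociationParameters, predict_trace
from .schedule import NM_PER_MOLAR, AssaySchedule, AssayStep, StepKind, write_schedule
from .sensorgram import Sensorgram, write_sensorgram_table

__all__ = [
    "NoiseModel",
    "default_schedule",
    "simulate_sensorgram",
    "simulate_loading",
    "make_fixture_plate",
]

#: endpoints of the tapered association dwell times, seconds
_DWELL_LONGEST = 300.0
_DWELL_SHORTEST = 100.0
_MINI_DISSOCIATION_S = 30.0
_FINAL_S = 600.0
_FINAL_LONG_S = 1200.0


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-artefact model for simulated traces.

    sigma: iid Gaussian noise per sample (nm).  drift: linear baseline
    drift (nm/s).  step_shift_sd: SD of the Gaussian bulk offset injected
    at each kinetic step boundary (nm); offsets accumulate along the
    trace.  The seed fixes the full output stream.
    """

    sigma: float = 0.0
    drift: float = 0.0
    step_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.step_shift_sd < 0:
            raise ValidationError("sigma and step_shift_sd must be >= 0")
        if not math.isfinite(self.drift):
            raise ValidationError("drift must be finite")


def default_schedule(
    concentrations: Sequence[float],
    long_final: bool = False,
    labels: Sequence[str] | None = None,
) -> AssaySchedule:
    """Build the routine single-cycle schedule for a concentration series.

    Association dwell times are linearly spaced from 300 s down to 100 s
    across the wells (exactly 300/250/200/150/100 s for five wells):
    low-concentration wells approach steady state slowly and get the long
    dwells.  30 s mini-dissociations separate the wells; the final
    dissociation lasts 600 s, or 1200 s with ``long_final`` to better
    probe slow-dissociating binders.

    Concentrations are in molar and must strictly increase (the sensor
    always moves from lowest to highest).
    """
    conc = [float(c) for c in concentrations]
    if not conc:
        raise ValidationError("at least one analyte concentration is required")
    if any(c <= 0 for c in conc):
        raise ValidationError("analyte concentrations must be strictly positive")
    for lo, hi in zip(conc, conc[1:]):
        if not hi > lo:
            raise ValidationError(
                "analyte concentrations must strictly increase from lowest to "
                f"highest; got {lo * NM_PER_MOLAR:g} nM before {hi * NM_PER_MOLAR:g} nM"
            )
    n = len(conc)
    if n == 1:
        dwells = [_DWELL_LONGEST]
    else:
        dwells = list(np.linspace(_DWELL_LONGEST, _DWELL_SHORTEST, n))
    if labels is None:
        labels = [f"well_{i + 1}" for i in range(n)]

    steps: list[AssayStep] = []
    for i, (c, d) in enumerate(zip(conc, dwells)):
        steps.append(
            AssayStep(StepKind.ASSOCIATION, duration=d, concentration=c,
                      label=str(labels[i]))
        )
        if i < n - 1:
            steps.append(AssayStep(StepKind.MINI_DISSOCIATION, _MINI_DISSOCIATION_S))
    steps.append(
        AssayStep(
            StepKind.FINAL_DISSOCIATION,
            _FINAL_LONG_S if long_final else _FINAL_S,
        )
    )
    return AssaySchedule(steps)


def simulate_sensorgram(
    schedule: AssaySchedule,
    params: ModelParameters,
    noise: NoiseModel = NoiseModel(),
    grid: float = 0.5,
) -> Sensorgram:
    """Simulate one single-cycle trace: analytic prediction plus noise.

    The noiseless part is exactly :func:`blifit.models.predict_trace`;
    on top of it come linear drift (drift * t), cumulative bulk shifts at
    each kinetic step boundary, and iid Gaussian sample noise.  Fully
    reproducible for a given ``noise.seed``.  Default grid 0.5 s/sample
    (BLI-like acquisition cadence).
    """
    clean = predict_trace(schedule, params, grid=grid)
    rng = np.random.default_rng(noise.seed)
    resp = clean.responses.copy()

    resp += noise.drift * clean.times

    if noise.step_shift_sd > 0:
        offset = 0.0
        boundaries = np.flatnonzero(np.diff(clean.step_index) != 0) + 1
        shifts = rng.normal(0.0, noise.step_shift_sd, size=boundaries.size)
        for b, shift in zip(boundaries, shifts):
            offset += shift  # bulk offsets carry forward through the run
            resp[b:] += shift
    if noise.sigma > 0:
        resp += rng.normal(0.0, noise.sigma, size=resp.size)
    return replace(clean, responses=resp)


def simulate_loading(
    binder_concentration: float,
    capture_rate_constant: float,
    r_sat: float,
    duration: float,
    noise: NoiseModel = NoiseModel(),
    grid: float = 0.5,
    label: str = "",
) -> Sensorgram:
    """Simulate a sensor-loading trace under irreversible covalent capture.

    R(t) = R_sat * (1 - exp(-k_capture * C * t)) + noise: pseudo-first-
    order capture whose plateau is set by the pre-loaded capture-site
    density, not by the binder concentration — given enough time every
    sensor attains the same density, only the approach rate differs.
    """
    for name, v in (
        ("binder_concentration", binder_concentration),
        ("capture_rate_constant", capture_rate_constant),
        ("r_sat", r_sat),
        ("duration", duration),
        ("grid", grid),
    ):
        if not (math.isfinite(v) and v > 0):
            raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
    n = int(math.floor(duration / grid + 1e-9)) + 1
    t = np.arange(n) * grid
    k = capture_rate_constant * binder_concentration
    resp = r_sat * (1.0 - np.exp(-k * t))
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        resp = resp + rng.normal(0.0, noise.sigma, size=resp.size)
    if noise.drift != 0.0:
        resp = resp + noise.drift * t
    return Sensorgram(times=t, responses=resp, label=label)


def make_fixture_plate(
    spec: Sequence[tuple[ModelParameters, AssaySchedule, NoiseModel]],
    out_dir: str | Path,
    include_reference: bool = False,
    grid: float = 0.5,
) -> dict:
    """Write a plate of simulated sensorgram CSVs plus schedule configs.

    One CSV per sensor (``sensor_00.csv``, ...), one schedule config per
    sensor (``sensor_00.schedule.yaml``), optionally a ligand-free
    reference trace (``reference.csv``: pure noise/drift around zero,
    sharing the first sensor's schedule), and a ``manifest.json`` listing
    the true generating parameters for test harnesses.  All files
    round-trip through the sensorgram/schedule readers.
    """
    if not spec:
        raise DataError("fixture plate spec is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"sensors": [], "grid_s": grid}
    for i, (params, schedule, noise) in enumerate(spec):
        name = f"sensor_{i:02d}"
        sg = simulate_sensorgram(schedule, params, noise, grid=grid)
        sg = replace(sg, label=name)
        write_sensorgram_table(sg, out_dir / f"{name}.csv")
        write_schedule(schedule, out_dir / f"{name}.schedule.yaml")

        base = params.base if isinstance(params, PartialDissociationParameters) else params
        entry = {
            "label": name,
            "csv": f"{name}.csv",
            "schedule": f"{name}.schedule.yaml",
            "k_on_per_M_per_s": base.k_on,
            "k_off_per_s": base.k_off,
            "K_D_M": base.k_d,
            "R_max_nm": base.r_max,
            "sigma_nm": noise.sigma,
            "drift_nm_per_s": noise.drift,
            "step_shift_sd_nm": noise.step_shift_sd,
            "seed": noise.seed,
        }
        if isinstance(params, PartialDissociationParameters):
            entry["phi"] = params.phi
        manifest["sensors"].append(entry)

    if include_reference:
        _, schedule0, noise0 = spec[0]
        clean = predict_trace(schedule0, spec[0][0], grid=grid)
        rng = np.random.default_rng(noise0.seed + 10_007)
        resp = noise0.drift * clean.times
        if noise0.sigma > 0:
            resp = resp + rng.normal(0.0, noise0.sigma, size=clean.times.size)
        ref = Sensorgram(times=clean.times, responses=resp,
                         step_index=clean.step_index, label="reference")
        write_sensorgram_table(ref, out_dir / "reference.csv")
        manifest["reference"] = {"csv": "reference.csv", "seed": noise0.seed + 10_007}

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
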