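"""Global kinetic fitting of single-cycle sensorgrams.

All kinetic segments (associations, mini-dissociations, final dissociation)
are fitted jointly against the piecewise closed-form model with continuity
enforced by construction, so the standard 1:1 model has only three free
parameters (k_on, k_off, R_max); the partial-dissociation variants add a
single mobile fraction phi or one plateau per dissociation segment.

Rates and R_max are optimised in log10 space with a bounded trust-region
least-squares solver and a small, seeded multistart around a data-driven
initial guess.  Goodness of fit is the degrees-of-freedom-corrected RMSE
sqrt(SS / (N - p)), also reported as a fraction of the fitted response
window.

The module also provides the two auxiliary estimators used in screening
campaigns: steady-state affinity from equilibrium plateaus, and ranking of
binders by expression level from their sensor-loading traces.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.optimize._numdiff import approx_derivative

from .errors import (
    ConvergenceError,
    DataError,
    DofError,
    GuessError,
    UncertaintyError,
    ValidationError,
)
from .models import (
    PHI_MAX,
    KineticParameters,
    ModelParameters,
    PartialDissociationMode,
    PartialDissociationParameters,
    evaluate_trace,
)
from .schedule import AssaySchedule, StepKind
from .sensorgram import Sensorgram

__all__ = [
    "FitModel",
    "FitOptions",
    "FitResult",
    "LoadingEstimate",
    "goodness_of_fit",
    "initial_guess",
    "fit_single_cycle",
    "fit_steady_state",
    "parameter_uncertainty",
    "rank_expression",
    "choose_model",
]

LN10 = math.log(10.0)


class FitModel(str, enum.Enum):
    STANDARD_1_1 = "standard"
    PARTIAL_LOCAL = "partial-local"
    PARTIAL_GLOBAL = "partial-global"


@dataclass(frozen=True)
class FitOptions:
    """Optimiser configuration.

    Default parameter bounds bracket the dynamic range of BLI
    (roughly 10 pM – 1 mM in K_D): k_on in [1e2, 1e8] /M/s,
    k_off in [1e-7, 1] /s, R_max in (0, 10] nm.
    """

    k_on_bounds: tuple[float, float] = (1e2, 1e8)
    k_off_bounds: tuple[float, float] = (1e-7, 1.0)
    r_max_bounds: tuple[float, float] = (1e-6, 10.0)
    n_starts: int = 5
    jitter_decades: float = 1.0  # multistart jitters rates by up to x/÷ 10
    seed: int = 0
    ftol: float = 1e-15
    xtol: float = 1e-15
    gtol: float = 1e-15
    max_nfev: int = 5000
    min_window: float = 1e-6  # nm; traces flatter than this cannot be fitted


@dataclass(frozen=True)
class LoadingEstimate:
    """Mono-exponential capture fit of one sensor-loading trace.

    rank_score equals k_obs: under pseudo-first-order irreversible capture
    the observed loading rate is proportional to the binder concentration
    in the crude sample, so faster loading means higher expression.
    """

    label: str
    k_obs: float
    r_sat: float
    saturated: bool
    rank_score: float
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and math.isfinite(self.k_obs)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a global single-cycle fit."""

    model: FitModel
    params: ModelParameters
    residuals: np.ndarray
    n: int
    p: int
    rmse: float
    rmse_fraction_of_window: float
    converged: bool
    n_evaluations: int
    cost: float
    standard_errors: dict[str, float] | None = None
    segment_rmse: dict[int, float] = field(default_factory=dict)

    @property
    def base(self) -> KineticParameters:
        if isinstance(self.params, PartialDissociationParameters):
            return self.params.base
        return self.params

    def to_dict(self) -> dict:
        """JSON-ready fit report."""
        base = self.base
        out: dict = {
            "model": self.model.value,
            "k_on_per_M_per_s": base.k_on,
            "k_off_per_s": base.k_off,
            "K_D_M": base.k_d,
            "K_D_nM": base.k_d * 1e9,
            "R_max_nm": base.r_max,
            "rmse_nm": self.rmse,
            "rmse_fraction_of_window": self.rmse_fraction_of_window,
            "n_data_points": self.n,
            "n_free_parameters": self.p,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "segment_rmse_nm": {str(k): v for k, v in sorted(self.segment_rmse.items())},
        }
        if isinstance(self.params, PartialDissociationParameters):
            if self.params.mode is PartialDissociationMode.GLOBAL_MOBILE_FRACTION:
                out["phi"] = self.params.phi
            else:
                out["plateaus_nm"] = list(self.params.plateaus)
        if self.standard_errors is not None:
            out["standard_errors"] = dict(self.standard_errors)
        return out


def goodness_of_fit(residuals: Sequence[float] | np.ndarray, p: int) -> float:
    """Degrees-of-freedom-corrected RMSE: sqrt(sum(r^2) / (N - p)).

    N is the total number of fitted data points and p the number of free
    parameters of the model.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n <= p:
        raise DofError(f"need more data points ({n}) than free parameters ({p})")
    return float(np.sqrt(np.sum(r * r) / (n - p)))


# ---------------------------------------------------------------------------
# initial guess


def _noise_sd(responses: np.ndarray) -> float:
    """Robust per-sample noise estimate from first differences."""
    if responses.size < 3:
        return 0.0
    d = np.diff(responses)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / math.sqrt(2.0))


def _segment_samples(
    sg: Sensorgram, schedule: AssaySchedule, kind: StepKind
) -> list[tuple[int, np.ndarray]]:
    """(step index, sample indices) for every step of the given kind."""
    out = []
    for i, step in enumerate(schedule.steps):
        if step.kind is kind:
            sel = np.flatnonzero(sg.step_index == i)
            out.append((i, sel))
    return out


def _observed_rate(t: np.ndarray, r: np.ndarray) -> float:
    """Estimate the exponential-approach rate of one segment by regressing
    dR/dt on R (slope = -k_obs).  Crude but robust to not knowing the
    asymptote; only used for starting values."""
    if t.size < 5:
        return np.nan
    dr = np.gradient(r, t)
    a = np.polyfit(r, dr, 1)[0]
    return -float(a) if a < 0 else np.nan


def initial_guess(
    sg: Sensorgram, schedule: AssaySchedule, options: FitOptions = FitOptions()
) -> KineticParameters:
    """Data-driven starting point for the global fit.

    k_off comes from a log-linear regression on the final dissociation;
    k_on from regressing per-association observed rates k_obs,i on C_i
    (slope = k_on); R_max from the largest observed response divided by
    the occupancy those guesses imply at the top concentration.  All three
    are clamped to the optimiser bounds.
    """
    if sg.step_index is None:
        raise ValidationError("sensorgram must be aligned before fitting")
    mask = sg.kinetic_mask(schedule)
    resp = sg.responses[mask]
    if resp.size < 4:
        raise GuessError("too few kinetic samples to derive a starting point")
    window = float(resp.max() - resp.min())
    noise = _noise_sd(resp)
    if window < options.min_window or (noise > 0 and window < 5.0 * noise):
        raise GuessError(
            f"response window ({window:.3g} nm) is below the noise floor; "
            "check that the sensor produced signal before fitting"
        )

    lo_on, hi_on = options.k_on_bounds
    lo_off, hi_off = options.k_off_bounds
    lo_rm, hi_rm = options.r_max_bounds

    # k_off from the final dissociation
    k_off = math.sqrt(lo_off * hi_off)  # fallback: geometric mid-bound
    final = _segment_samples(sg, schedule, StepKind.FINAL_DISSOCIATION)
    if final:
        _, sel = final[0]
        t, r = sg.times[sel], sg.responses[sel]
        pos = r > max(3.0 * noise, 1e-12)
        if pos.sum() >= 5:
            slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
            if slope < 0:
                k_off = -float(slope)
    k_off = float(np.clip(k_off, lo_off, hi_off))

    # k_on from per-well observed rates vs concentration
    assoc = _segment_samples(sg, schedule, StepKind.ASSOCIATION)
    rates, concs = [], []
    for i, sel in assoc:
        if sel.size < 5:
            continue
        k_obs = _observed_rate(sg.times[sel], sg.responses[sel])
        if np.isfinite(k_obs) and k_obs > 0:
            rates.append(k_obs)
            concs.append(schedule.steps[i].concentration)
    k_on = math.sqrt(lo_on * hi_on)
    if len(rates) >= 2:
        slope = np.polyfit(concs, rates, 1)[0]
        if slope > 0:
            k_on = float(slope)
    elif len(rates) == 1:
        k_on = max((rates[0] - k_off) / concs[0], lo_on)
    k_on = float(np.clip(k_on, lo_on, hi_on))

    # R_max from the top response and the implied occupancy
    c_top = schedule.concentrations[-1]
    occupancy = k_on * c_top / (k_on * c_top + k_off)
    r_max = float(np.clip(resp.max() / max(occupancy, 1e-6), lo_rm, hi_rm))
    return KineticParameters(k_on=k_on, k_off=k_off, r_max=r_max)


# ---------------------------------------------------------------------------
# global fit


def _theta_names(model: FitModel, n_plateaus: int) -> list[str]:
    names = ["k_on", "k_off", "r_max"]
    if model is FitModel.PARTIAL_GLOBAL:
        names.append("phi")
    elif model is FitModel.PARTIAL_LOCAL:
        names += [f"r_inf_{i}" for i in range(n_plateaus)]
    return names


def _params_from_theta(
    theta: np.ndarray, model: FitModel
) -> ModelParameters:
    base = KineticParameters(
        k_on=10.0 ** theta[0], k_off=10.0 ** theta[1], r_max=10.0 ** theta[2]
    )
    if model is FitModel.STANDARD_1_1:
        return base
    if model is FitModel.PARTIAL_GLOBAL:
        return PartialDissociationParameters(
            base=base,
            mode=PartialDissociationMode.GLOBAL_MOBILE_FRACTION,
            phi=float(np.clip(theta[3], 0.0, PHI_MAX)),
        )
    return PartialDissociationParameters(
        base=base,
        mode=PartialDissociationMode.LOCAL_PLATEAU,
        plateaus=tuple(theta[3:]),
    )


def _residual_fn(
    times: np.ndarray,
    obs: np.ndarray,
    schedule: AssaySchedule,
    model: FitModel,
) -> Callable[[np.ndarray], np.ndarray]:
    def residuals(theta: np.ndarray) -> np.ndarray:
        return evaluate_trace(times, schedule, _params_from_theta(theta, model)) - obs

    return residuals


def fit_single_cycle(
    sg: Sensorgram,
    schedule: AssaySchedule,
    model: FitModel = FitModel.STANDARD_1_1,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Globally fit one aligned single-cycle sensorgram.

    Minimises the unweighted squared residuals between the trace and the
    piecewise model over all kinetic segments jointly.  A small seeded
    multistart (``options.n_starts`` starts, rates jittered by up to a
    factor of 10 around :func:`initial_guess`) guards against local
    minima; the best converged start wins.

    Raises
    ------
    DofError
        If there are no residual degrees of freedom.
    ConvergenceError
        If no start converges; carries best-so-far diagnostics.
    """
    if sg.step_index is None:
        raise ValidationError("sensorgram must be aligned before fitting")
    model = FitModel(model)
    mask = sg.kinetic_mask(schedule)
    times = sg.times[mask]
    obs = sg.responses[mask]

    n_plateaus = schedule.n_dissociation_segments
    names = _theta_names(model, n_plateaus)
    n, p = int(obs.size), len(names)
    if n <= p:
        raise DofError(f"N = {n} data points cannot constrain p = {p} parameters")

    guess = initial_guess(sg, schedule, options)
    window = float(obs.max() - obs.min())

    lo = [math.log10(options.k_on_bounds[0]), math.log10(options.k_off_bounds[0]),
          math.log10(options.r_max_bounds[0])]
    hi = [math.log10(options.k_on_bounds[1]), math.log10(options.k_off_bounds[1]),
          math.log10(options.r_max_bounds[1])]
    theta0 = [math.log10(guess.k_on), math.log10(guess.k_off), math.log10(guess.r_max)]
    if model is FitModel.PARTIAL_GLOBAL:
        lo.append(0.0)
        hi.append(PHI_MAX)
        theta0.append(0.1)
    elif model is FitModel.PARTIAL_LOCAL:
        lo += [0.0] * n_plateaus
        hi += [options.r_max_bounds[1]] * n_plateaus
        theta0 += [0.02 * window] * n_plateaus
    lo, hi, theta0 = np.array(lo), np.array(hi), np.array(theta0)

    rng = np.random.default_rng(options.seed)
    starts = [theta0]
    for _ in range(max(options.n_starts - 1, 0)):
        jit = theta0.copy()
        jit[0] += rng.uniform(-options.jitter_decades, options.jitter_decades)
        jit[1] += rng.uniform(-options.jitter_decades, options.jitter_decades)
        jit[2] += rng.uniform(-0.3, 0.3)
        starts.append(np.clip(jit, lo, hi))

    fn = _residual_fn(times, obs, schedule, model)
    best = None
    n_evaluations = 0
    for x0 in starts:
        try:
            res = least_squares(
                fn,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                gtol=options.gtol,
                max_nfev=options.max_nfev,
            )
        except Exception:  # singular steps etc.: try the next start
            continue
        n_evaluations += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None or best.status <= 0:
        raise ConvergenceError(
            "global fit did not converge from any start", best=best
        )

    params = _params_from_theta(best.x, model)
    residuals = best.fun
    rmse = goodness_of_fit(residuals, p)

    seg_rmse: dict[int, float] = {}
    step_idx = sg.step_index[mask]
    for i in np.unique(step_idx):
        sel = step_idx == i
        seg_rmse[int(i)] = float(np.sqrt(np.mean(residuals[sel] ** 2)))

    result = FitResult(
        model=model,
        params=params,
        residuals=residuals,
        n=n,
        p=p,
        rmse=rmse,
        rmse_fraction_of_window=rmse / window,
        converged=True,
        n_evaluations=n_evaluations,
        cost=float(best.cost),
        segment_rmse=seg_rmse,
    )
    try:
        se = parameter_uncertainty(result, sg, schedule)
    except UncertaintyError:
        se = None
    return FitResult(**{**result.__dict__, "standard_errors": se})


def parameter_uncertainty(
    fit: FitResult, sg: Sensorgram, schedule: AssaySchedule
) -> dict[str, float]:
    """Asymptotic per-parameter standard errors of a converged fit.

    Computed from the Jacobian of the model at the optimum scaled by the
    residual variance (covariance = s^2 (J^T J)^-1 with
    s^2 = SS/(N - p)); log-space errors for the rates and R_max are
    propagated back to natural units.  These are approximate single-fit
    errors — replicate experiments remain the gold standard, summarised as
    mean ± SD over independent runs.
    """
    if not fit.converged:
        raise UncertaintyError("uncertainty requires a converged fit")
    mask = sg.kinetic_mask(schedule)
    times, obs = sg.times[mask], sg.responses[mask]
    fn = _residual_fn(times, obs, schedule, fit.model)

    base = fit.base
    theta = [math.log10(base.k_on), math.log10(base.k_off), math.log10(base.r_max)]
    if isinstance(fit.params, PartialDissociationParameters):
        if fit.params.mode is PartialDissociationMode.GLOBAL_MOBILE_FRACTION:
            theta.append(fit.params.phi)
        else:
            theta += list(fit.params.plateaus)
    theta = np.asarray(theta)
    names = _theta_names(fit.model, schedule.n_dissociation_segments)

    jac = approx_derivative(fn, theta, method="2-point")
    jtj = jac.T @ jac
    sv = np.linalg.svd(jtj, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    if not math.isfinite(cond) or cond > 1e14:
        raise UncertaintyError(
            f"Jacobian is ill-conditioned (condition number {cond:.3g})",
            condition_number=cond,
        )
    s2 = float(np.sum(fit.residuals**2)) / (fit.n - fit.p)
    cov = s2 * np.linalg.inv(jtj)
    se_theta = np.sqrt(np.maximum(np.diag(cov), 0.0))

    out: dict[str, float] = {}
    values = [base.k_on, base.k_off, base.r_max]
    for i, name in enumerate(names):
        if i < 3:  # log10-parametrised: SE_x = x ln(10) SE_log10(x)
            out[name] = float(values[i] * LN10 * se_theta[i])
        else:
            out[name] = float(se_theta[i])
    return out


# ---------------------------------------------------------------------------
# steady-state affinity


def fit_steady_state(
    concentrations: Sequence[float] | np.ndarray,
    responses: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Fit R_eq(C) = R_max * C / (C + K_D) to equilibrium plateaus.

    An alternative to kinetic fitting for weak binders, where K_D comes
    from the concentration dependence of steady-state plateaus.  Returns
    ``(K_D, R_max)`` in (molar, nm).  Needs at least 3 concentration
    points; ideally the series brackets K_D (a warning is issued when it
    does not).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size:
        raise DataError("concentrations and responses differ in length")
    if c.size < 3:
        raise DataError(
            f"steady-state fit needs at least 3 concentration points, got {c.size}"
        )
    if np.any(c <= 0):
        raise DataError("concentrations must be strictly positive")

    r_top = float(r.max())
    kd0 = float(np.median(c))
    try:
        popt, _ = curve_fit(
            lambda cc, r_max, kd: r_max * cc / (cc + kd),
            c,
            r,
            p0=[1.05 * r_top, kd0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise DataError(f"steady-state fit failed: {exc}") from exc
    r_max, kd = float(popt[0]), float(popt[1])
    if kd > 50.0 * c.max():
        warnings.warn(
            "steady-state responses are proportional to concentration; "
            "K_D is unidentifiable (no curvature up to the top concentration)",
            stacklevel=2,
        )
        raise DataError(
            "K_D unidentifiable from steady-state data: responses show no "
            "saturation; extend the concentration series"
        )
    if not (c.min() < kd < c.max()):
        warnings.warn(
            f"steady-state series does not bracket the fitted K_D "
            f"({kd * 1e9:.3g} nM); include points above and below K_D",
            stacklevel=2,
        )
    return kd, r_max


# ---------------------------------------------------------------------------
# expression ranking from loading traces


def rank_expression(
    loading_segments: Sequence[Sensorgram],
) -> list[LoadingEstimate]:
    """Rank binders by expression level from their sensor-loading traces.

    Each loading trace is fitted with the pseudo-first-order irreversible
    capture model R(t) = R_sat * (1 - exp(-k_obs t)); since every sensor
    ultimately reaches the same capture density, the observed rate k_obs —
    proportional to binder concentration in the crude sample — ranks
    expression.  Segments already at >= 95% of R_sat are flagged
    saturated (their rate, and hence rank, is less reliable).  Traces that
    cannot be fitted are kept in the output with an error message and
    sorted last.
    """
    estimates: list[LoadingEstimate] = []
    for i, sg in enumerate(loading_segments):
        label = sg.label or f"sensor_{i}"
        t = sg.times - sg.times[0]
        r = sg.responses
        noise = _noise_sd(r)
        window = float(r.max() - r.min())
        if window < max(5.0 * noise, 1e-9):
            warnings.warn(
                f"loading trace {label!r} is flat; cannot estimate capture rate",
                stacklevel=2,
            )
            estimates.append(
                LoadingEstimate(label, math.nan, math.nan, False, math.nan,
                                error="flat trace: no detectable loading signal")
            )
            continue
        # running maximum decline of the smoothed trace flags non-monotonic
        # capture beyond noise (raw white noise alone produces ~severalsigma
        # excursions of the running max over long traces)
        w = min(11, max(3, r.size // 10))
        smooth = np.convolve(r, np.ones(w) / w, mode="valid")
        decline = float(np.max(np.maximum.accumulate(smooth) - smooth))
        if decline > 5.0 * max(noise, 1e-12):
            warnings.warn(
                f"loading trace {label!r} is non-monotone beyond noise "
                f"(max decline {decline:.3g} nm); rank may be unreliable",
                stacklevel=2,
            )
        r_top = float(r.max())
        above = np.flatnonzero(r >= 0.63 * r_top)
        t63 = float(t[above[0]]) if above.size else float(t[-1])
        k0 = 1.0 / max(t63, float(t[1] - t[0]))
        try:
            popt, _ = curve_fit(
                lambda tt, r_sat, k: r_sat * (1.0 - np.exp(-k * tt)),
                t,
                r,
                p0=[r_top * 1.05, k0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
            r_sat, k_obs = float(popt[0]), float(popt[1])
            saturated = r_top >= 0.95 * r_sat
            estimates.append(
                LoadingEstimate(label, k_obs, r_sat, saturated, rank_score=k_obs)
            )
        except RuntimeError as exc:
            warnings.warn(
                f"loading fit failed for {label!r}: {exc}", stacklevel=2
            )
            estimates.append(
                LoadingEstimate(label, math.nan, math.nan, False, math.nan,
                                error=f"capture fit failed: {exc}")
            )
    return sorted(
        estimates,
        key=lambda e: (-e.rank_score if e.ok else math.inf),
    )


# ---------------------------------------------------------------------------
# model selection


def choose_model(
    standard: FitResult,
    partial: FitResult,
    min_rmse_improvement: float = 0.05,
    min_phi: float = 0.02,
) -> FitResult:
    """Parsimony-based choice between a standard and a partial fit.

    The partial-dissociation fit is preferred only when it lowers the RMSE
    by at least ``min_rmse_improvement`` (fractional) and its fitted
    plateau is material (phi >= ``min_phi``, or for local plateaus, the
    largest plateau exceeds ``min_phi`` of the response window).
    """
    if standard.model is not FitModel.STANDARD_1_1:
        raise ValidationError("first argument must be a standard-model fit")
    if not isinstance(partial.params, PartialDissociationParameters):
        raise ValidationError("second argument must be a partial-model fit")
    improvement = (standard.rmse - partial.rmse) / standard.rmse
    if partial.params.mode is PartialDissociationMode.GLOBAL_MOBILE_FRACTION:
        material = partial.params.phi >= min_phi
    else:
        window = standard.rmse / max(standard.rmse_fraction_of_window, 1e-300)
        material = bool(partial.params.plateaus) and (
            max(partial.params.plateaus) >= min_phi * window
        )
    if improvement >= min_rmse_improvement and material:
        return partial
    return standard
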