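"""Summary statistics and rate-constant inference.

A step infusion is applied at t = 0, so the time derivative of a probe
breakthrough curve, normalized to unit area, is the residence-time
distribution (RTD) of solute from the source to that probe. Its first
moment m1 is the average residence time; t95 is the time to reach 95% of
the 40-min reference concentration; the Peclet number compares advection
and diffusion over the source-sink separation.

Because the substrate concentration is far below Km, hydrolysis is first
order and every simulated observable is linear in the infused
concentration; the substrate/internal-standard and
product/internal-standard ratios at the probe outlet therefore calibrate
the rate constant independently of recovery and delivery. The inversion
interpolates a simulated calibration sweep monotonically on log k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import AnalysisError, ConfigurationError
from .transport import BreakthroughCurve

DEFAULT_REFERENCE_TIME = 2400.0  # s, the 40-min steady-state convention
SOURCE_SINK_SEPARATION = 269e-6  # m, characteristic Peclet length


@dataclass
class ResidenceTimeStats:
    distribution_times: np.ndarray  # s
    distribution: np.ndarray        # 1/s, unit area
    first_moment_m1: float          # s
    t95: float | None               # s
    peclet: float | None
    characteristic_length: float    # m
    effective_diffusivity: float    # m^2/s


@dataclass
class RateEstimate:
    k_hat: float                    # 1/s
    interval: tuple[float, float]   # 1/s, propagated measurement CV
    observables_used: tuple[str, ...]
    extrapolated: bool
    sweep: "CalibrationSweep"


class SteadyStateWarning(UserWarning):
    """The curve had not plateaued where a steady value was requested."""


class MonotonicityWarning(UserWarning):
    """A sweep violated its expected monotone trend beyond tolerance."""


def rtd_from_step_response(curve: BreakthroughCurve,
                           smooth_window: int | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Differentiate a step-response breakthrough curve into a unit-area RTD.

    Requires an approached plateau (final tenth of the record varies by
    < 2% of the final value). Optional boxcar smoothing (odd window) tames
    noisy curves; negative lobes are clipped and the area renormalized.
    """
    t = curve.times
    c = curve.concentrations.astype(float)
    if t.size < 5:
        raise AnalysisError("need at least 5 samples to differentiate")
    tail = c[t >= t[-1] - 0.1 * (t[-1] - t[0])]
    c_end = c[-1]
    if c_end <= 0:
        raise AnalysisError("curve never rises above zero")
    if (tail.max() - tail.min()) > 0.02 * c_end:
        raise AnalysisError(
            "no plateau: final 10% of the record varies by "
            f"{(tail.max() - tail.min()) / c_end:.1%} of the final value; "
            "run the simulation longer")
    if smooth_window is not None and smooth_window > 1:
        w = int(smooth_window) | 1
        kernel = np.ones(w) / w
        pad = w // 2
        c = np.convolve(np.pad(c, pad, mode="edge"), kernel, mode="valid")
    f = np.gradient(c, t)
    np.clip(f, 0.0, None, out=f)
    area = np.trapezoid(f, t)
    if area <= 0:
        raise AnalysisError("degenerate distribution (zero area)")
    return t, f / area


def first_moment(times: np.ndarray, distribution: np.ndarray) -> float:
    """m1 = integral t f(t) dt by trapezoidal quadrature of a unit-area f."""
    times = np.asarray(times, float)
    f = np.asarray(distribution, float)
    area = np.trapezoid(f, times)
    if abs(area - 1.0) > 1e-3:
        raise AnalysisError(f"distribution area {area:.4f} is not 1; normalize first")
    return float(np.trapezoid(times * f, times))


def time_to_fraction(curve: BreakthroughCurve, fraction: float = 0.95,
                     t_ref: float = DEFAULT_REFERENCE_TIME) -> float:
    """Earliest time the curve reaches ``fraction`` of its value at
    ``t_ref`` (linear interpolation between samples)."""
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must be in (0, 1]")
    t = curve.times
    c = curve.concentrations
    if t[-1] < t_ref - 1e-9:
        raise AnalysisError(f"curve ends before t_ref = {t_ref:.0f} s")
    target = fraction * float(np.interp(t_ref, t, c))
    if target <= 0:
        return 0.0
    above = c >= target
    if not above.any():
        raise AnalysisError("curve never reaches the requested fraction")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0]) if c[0] >= target else 0.0
    # linear interpolation across the crossing
    t0, t1 = t[i - 1], t[i]
    c0, c1 = c[i - 1], c[i]
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))


def peclet_number(m1: float, length: float = SOURCE_SINK_SEPARATION,
                  d_eff: float = 5.4e-10 / 1.61**2) -> float:
    """Pe = L^2 / (m1 * D_eff): the ratio of the diffusive time over L to
    the observed mean residence time. Defaults: source-sink separation and
    the hindered tissue diffusivity of the internal standard at 37 degC."""
    if m1 <= 0 or length <= 0 or d_eff <= 0:
        raise ConfigurationError("m1, length, d_eff must be > 0")
    return length**2 / (m1 * d_eff)


def residence_time_stats(curve: BreakthroughCurve,
                         t_ref: float = DEFAULT_REFERENCE_TIME,
                         length: float = SOURCE_SINK_SEPARATION,
                         d_eff: float = 5.4e-10 / 1.61**2,
                         smooth_window: int | None = None) -> ResidenceTimeStats:
    """RTD, first moment, t95 and Peclet from one breakthrough curve."""
    t, f = rtd_from_step_response(curve, smooth_window=smooth_window)
    m1 = first_moment(t, f)
    t95 = time_to_fraction(curve, 0.95, min(t_ref, curve.times[-1]))
    return ResidenceTimeStats(
        distribution_times=t, distribution=f, first_moment_m1=m1, t95=t95,
        peclet=peclet_number(m1, length, d_eff),
        characteristic_length=length, effective_diffusivity=d_eff)


def transit_first_moment(upstream: BreakthroughCurve,
                         downstream: BreakthroughCurve,
                         smooth_window: int | None = None) -> float:
    """Mean residence time across a device segment as the difference of the
    two step-response first moments (RTD moments compose additively along
    the flow path, so the segment moment is m1_down - m1_up)."""
    m_up = first_moment(*rtd_from_step_response(upstream,
                                                smooth_window=smooth_window))
    m_down = first_moment(*rtd_from_step_response(downstream,
                                                  smooth_window=smooth_window))
    if m_down <= m_up:
        raise AnalysisError("downstream moment does not exceed upstream; "
                            "curves may be too coarsely sampled")
    return m_down - m_up


def survival_fraction(times: np.ndarray, distribution: np.ndarray,
                      rate_constant: float) -> float:
    """Fraction of a first-order substrate surviving transit with the given
    RTD: integral f(t) exp(-k t) dt (plug flow: exp(-k tau))."""
    if rate_constant < 0:
        raise ConfigurationError("rate constant must be >= 0")
    return float(np.trapezoid(distribution * np.exp(-rate_constant * times),
                              times))


def recovery_ratio(curve: BreakthroughCurve, infused_concentration: float,
                   t_ref: float | None = None) -> float:
    """Detected / infused concentration at the probe outlet.

    Uses the curve value at ``t_ref`` (default: end of record); attaches a
    warning when the curve is not within 5% of plateau over its last tenth.
    """
    if infused_concentration <= 0:
        raise AnalysisError("infused concentration must be > 0 for a recovery ratio")
    t = curve.times
    c = curve.concentrations
    t_ref = float(t[-1]) if t_ref is None else float(t_ref)
    c_ref = float(np.interp(t_ref, t, c))
    tail = c[t >= t_ref - 0.1 * (t_ref - t[0])]
    if c_ref > 0 and (tail.max() - tail.min()) > 0.05 * c_ref:
        warnings.warn("recovery ratio taken before steady state "
                      f"(tail varies {(tail.max() - tail.min()) / c_ref:.1%})",
                      SteadyStateWarning, stacklevel=2)
    return c_ref / infused_concentration


def ratio_curves(result, probe: str, mask_threshold: float = 0.01) -> dict:
    """Per-species concentration ratios to the internal standard at a probe.

    Samples before the internal standard exceeds ``mask_threshold`` of its
    plateau are masked (the ratio is numerically meaningless there).
    Returns {species: masked_array} plus "times".
    """
    standard = [s for s in result.species if s.role == "internal_standard"]
    if not standard:
        raise AnalysisError("no internal standard species in this run")
    is_name = standard[0].name
    c_is = result.curves[(probe, is_name)]
    if c_is.max() <= 0:
        raise AnalysisError("internal standard never arrived at this probe")
    mask = c_is < mask_threshold * c_is.max()
    out = {"times": result.times}
    for s in result.species:
        if s.name == is_name:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mask, np.nan, result.curves[(probe, s.name)]
                             / np.where(mask, np.nan, c_is))
        out[s.name] = np.ma.masked_invalid(ratio)
    return out


# --- calibration sweep and inversion ------------------------------------

@dataclass
class CalibrationSweep:
    """Steady S/IS and P/IS at the probe outlet per rate constant."""
    k_grid: np.ndarray
    s_over_is: np.ndarray
    p_over_is: np.ndarray
    current: float | None = None
    probe: str = "MD_OUTLET"

    def __post_init__(self):
        self.k_grid = np.asarray(self.k_grid, float)
        self.s_over_is = np.asarray(self.s_over_is, float)
        self.p_over_is = np.asarray(self.p_over_is, float)
        if self.k_grid.size < 3:
            raise ConfigurationError("calibration sweep needs >= 3 rate constants")
        if np.any(np.diff(self.k_grid) <= 0):
            raise ConfigurationError("k grid must be sorted ascending")


def sweep_rate_constants(evaluate_ratios, k_grid,
                         current: float | None = None,
                         probe: str = "MD_OUTLET",
                         monotonicity_tolerance: float = 1e-6
                         ) -> CalibrationSweep:
    """Evaluate steady (S/IS, P/IS) over a sorted k grid.

    ``evaluate_ratios(k) -> (s_over_is, p_over_is)`` should reuse the
    k-independent field/flow solution (the flow problem does not depend on
    the reaction). S/IS is checked to be non-increasing in k; violations
    beyond tolerance raise a numerical warning, not an error.
    """
    k_grid = np.asarray(sorted(k_grid), float)
    if k_grid.size < 3:
        raise ConfigurationError("need at least 3 rate constants in the sweep")
    s_vals, p_vals = [], []
    for k in k_grid:
        s, p = evaluate_ratios(float(k))
        s_vals.append(s)
        p_vals.append(p)
    s_vals = np.asarray(s_vals)
    p_vals = np.asarray(p_vals)
    if np.any(np.diff(s_vals) > monotonicity_tolerance * max(1.0, s_vals.max())):
        warnings.warn("S/IS is not monotone non-increasing in k; the grid "
                      "may be under-resolved", MonotonicityWarning, stacklevel=2)
    return CalibrationSweep(k_grid=k_grid, s_over_is=s_vals, p_over_is=p_vals,
                            current=current, probe=probe)


def _interpolants(sweep: CalibrationSweep):
    pos = sweep.k_grid > 0
    logk = np.log10(sweep.k_grid[pos])
    return (logk,
            PchipInterpolator(logk, sweep.s_over_is[pos]),
            PchipInterpolator(logk, sweep.p_over_is[pos]))


def infer_rate_constant(measured: dict, sweep: CalibrationSweep,
                        cv: float = 0.05,
                        quantitation_floor: float = 0.0) -> RateEstimate:
    """Invert measured steady ratios to a first-order rate constant.

    ``measured`` holds "s_over_is" and/or "p_over_is" (scalar or replicate
    array; replicates are combined by geometric mean, consistent with
    multiplicative measurement noise). The estimate minimizes the summed
    squared log-residual of the usable observables along the monotone
    PCHIP interpolants of the sweep on log k. Observables below the
    quantitation floor are dropped. A measurement outside the sweep's range
    flags extrapolation (clamped to the nearest grid edge) rather than
    failing.

    Uncertainty: the stated measurement CV is propagated through the
    inversion by re-inverting at exp(+/-cv)-perturbed observables.
    """
    vals = {}
    for key in ("s_over_is", "p_over_is"):
        v = measured.get(key)
        if v is None:
            continue
        v = np.atleast_1d(np.asarray(v, float))
        v = v[v > 0] if np.any(v > 0) else v
        vals[key] = float(np.exp(np.mean(np.log(v)))) if np.all(v > 0) \
            else float(np.mean(v))
    if not vals:
        raise AnalysisError("no usable observables in the measurement")

    # exact boundary case: unreacted substrate
    if vals.get("s_over_is") is not None and vals["s_over_is"] >= float(
            np.max(sweep.s_over_is)) and "p_over_is" not in vals:
        return RateEstimate(k_hat=0.0, interval=(0.0, float(sweep.k_grid[
            sweep.k_grid > 0][0])), observables_used=("s_over_is",),
            extrapolated=False, sweep=sweep)

    logk, s_itp, p_itp = _interpolants(sweep)
    dense = np.linspace(logk[0], logk[-1], 2048)
    model = {"s_over_is": np.clip(s_itp(dense), 1e-300, None),
             "p_over_is": np.clip(p_itp(dense), 1e-300, None)}

    def invert(obs: dict) -> tuple[float, bool]:
        cost = np.zeros_like(dense)
        used = 0
        extrap = False
        for key, v in obs.items():
            if v <= max(quantitation_floor, 0.0):
                continue
            curve = model[key]
            lo, hi = curve.min(), curve.max()
            if not (lo <= v <= hi):
                extrap = True
            cost += (np.log(v) - np.log(curve))**2
            used += 1
        if used == 0:
            raise AnalysisError("all observables below the quantitation floor")
        return float(10.0 ** dense[int(np.argmin(cost))]), extrap

    k_hat, extrapolated = invert(vals)
    k_lo, k_hi = k_hat, k_hat
    if cv > 0:
        for sign in (+1.0, -1.0):
            pert = {"s_over_is": vals.get("s_over_is", None),
                    "p_over_is": vals.get("p_over_is", None)}
            # S falls with k while P rises: perturb them oppositely for the
            # widest consistent interval
            pert = {k: v * np.exp(sign * cv * (-1 if k == "s_over_is" else 1))
                    for k, v in pert.items() if v is not None}
            k_p, _ = invert(pert)
            k_lo, k_hi = min(k_lo, k_p), max(k_hi, k_p)
    used = tuple(k for k, v in vals.items()
                 if v > max(quantitation_floor, 0.0))
    return RateEstimate(k_hat=k_hat, interval=(k_lo, k_hi),
                        observables_used=used, extrapolated=extrapolated,
                        sweep=sweep)


def measurable_k_range(sweep: CalibrationSweep, floor: float) -> tuple[float, float]:
    """Widest [k_lo, k_hi] over which the rate is quantifiable given a
    relative quantitation floor on the ratio observables.

    The lower edge is where the product first clears the floor (a rate
    distinguishable from zero); the upper edge is where the substrate is
    last quantifiable (distinguishable from complete conversion). PCHIP
    interpolation on log k locates the crossings between grid points.
    """
    logk, s_itp, p_itp = _interpolants(sweep)
    dense = np.linspace(logk[0], logk[-1], 4096)
    p = p_itp(dense)
    s = s_itp(dense)
    p_ok = p >= floor
    s_ok = s >= floor
    if not p_ok.any() or not s_ok.any():
        raise AnalysisError("floor excludes the whole sweep")
    k_lo = 10.0 ** dense[int(np.argmax(p_ok))]
    k_hi = 10.0 ** dense[len(dense) - 1 - int(np.argmax(s_ok[::-1]))]
    return float(k_lo), float(k_hi)
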