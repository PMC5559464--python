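"""Four-parameter logistic description of the baroreflex function curve.

The stimulus-response relation between mean arterial pressure (MAP, the
input) and sympathetic nerve activity (SNA, the output) is modelled by the
sigmoid logistic

    Y(X) = a1 / (1 + exp(a2 * (X - a3))) + a4

with ``a1`` the response range, ``a2`` a (positive) slope coefficient,
``a3`` the centering pressure at which the curve passes through the middle
of its range, and ``a4`` the lower plateau.  With ``a1, a2 > 0`` the curve
is strictly decreasing: SNA falls as pressure rises, the signature of a
negative-feedback reflex.

Derived descriptors follow the standard convention: the threshold pressure
is where the output has dropped 5% of the range below its maximum, the
saturation pressure is where it sits 5% of the range above its minimum, and
the operating range is the interval between them.  The reflex gain |dY/dX|
is maximal at ``a3`` where it equals ``a1 * a2 / 4``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "CurveMetrics",
    "PressureSnaSeries",
    "FitResult",
    "FitOptions",
    "UnidentifiableDataError",
    "evaluate",
    "gain_at",
    "curve_metrics",
    "fit_logistic",
]

# ln(19) solves 1/(1+e^u) = 0.95 (u = -ln 19) and 0.05 (u = +ln 19):
# the 5% threshold/saturation conditions of the logistic.
_LN19 = math.log(19.0)

# |a2*(P-a3)| beyond this would overflow exp(); the curve is flat to machine
# precision there anyway, so we saturate to the plateau value.
_EXP_GUARD = 700.0


class UnidentifiableDataError(ValueError):
    """Raised when a series cannot constrain the four logistic parameters."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the four-parameter logistic baroreflex curve.

    Attributes
    ----------
    a1 : float
        Response range (upper plateau minus lower plateau), a.u., > 0.
    a2 : float
        Slope coefficient, per mmHg, > 0.  Positive ``a2`` gives a
        decreasing curve; the falling sign of the slope is implicit in the
        functional form, not in the stored value.
    a3 : float
        Centering pressure (midpoint of the response range), mmHg.
    a4 : float
        Lower plateau, a.u., >= 0.
    """

    a1: float
    a2: float
    a3: float
    a4: float

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.a1 <= 0:
            raise ValueError(f"a1 (response range) must be > 0, got {self.a1}")
        if self.a2 <= 0:
            raise ValueError(f"a2 (slope coefficient) must be > 0, got {self.a2}")
        if self.a4 < 0:
            raise ValueError(f"a4 (lower plateau) must be >= 0, got {self.a4}")

    @property
    def upper_plateau(self) -> float:
        return self.a1 + self.a4

    @property
    def lower_plateau(self) -> float:
        return self.a4

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a1, self.a2, self.a3, self.a4)


@dataclass(frozen=True)
class CurveMetrics:
    """Derived descriptors of a fitted or specified baroreflex curve."""

    threshold: float          # mmHg, output 5% of range below maximum
    saturation: float         # mmHg, output 5% of range above minimum
    operating_range: float    # mmHg, saturation - threshold
    midpoint_pressure: float  # mmHg, pressure of maximal gain (= a3)
    max_gain: float           # a.u./mmHg, magnitude a1*a2/4
    upper_plateau: float      # a.u.
    lower_plateau: float      # a.u.


@dataclass
class PressureSnaSeries:
    """Paired (pressure, SNA) observations, measured or simulated.

    Pressures in mmHg; SNA in arbitrary units (optionally normalized to 100
    at a stated resting point).  ``time`` (seconds) and a behavioral-state
    ``label`` are optional.
    """

    pressure: np.ndarray
    sna: np.ndarray
    time: Optional[np.ndarray] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.sna = np.asarray(self.sna, dtype=float)
        if self.pressure.shape != self.sna.shape or self.pressure.ndim != 1:
            raise ValueError(
                "pressure and sna must be 1-D arrays of equal length, got "
                f"shapes {self.pressure.shape} and {self.sna.shape}"
            )
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure samples must be finite")
        if not np.all(np.isfinite(self.sna)):
            raise ValueError("sna samples must be finite")
        if np.any(self.sna < 0):
            raise ValueError("sna samples must be non-negative")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != self.pressure.shape:
                raise ValueError("time must match pressure/sna length")

    def __len__(self) -> int:
        return self.pressure.size

    def normalized(self, resting_sna: float) -> "PressureSnaSeries":
        """Return a copy with SNA expressed as percent of ``resting_sna``."""
        if resting_sna <= 0:
            raise ValueError("resting_sna must be positive")
        return PressureSnaSeries(
            pressure=self.pressure.copy(),
            sna=100.0 * self.sna / resting_sna,
            time=None if self.time is None else self.time.copy(),
            label=self.label,
        )


@dataclass(frozen=True)
class FitOptions:
    """Options controlling :func:`fit_logistic`.

    ``n_starts`` multi-starts are jittered around the data-driven initial
    guess with a generator seeded by ``seed``, so a fit is deterministic
    given the series and options.
    """

    n_starts: int = 5
    seed: int = 0
    max_nfev: int = 2000
    min_points: int = 8
    min_pressure_span: float = 20.0   # mmHg
    min_sna_range: float = 1e-8       # a.u.; below this the data are flat


@dataclass(frozen=True)
class FitResult:
    params: LogisticParams
    residual_sd: float
    r_squared: float
    converged: bool
    n_points: int
    param_se: Optional[tuple[float, float, float, float]] = None


def evaluate(params: LogisticParams, pressure) -> np.ndarray | float:
    """Evaluate the logistic curve at one pressure or a pressure grid.

    Overflow in the exponential is guarded: far outside the operating range
    the exact plateau value is returned.
    """
    p = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure must be finite")
    u = np.clip(params.a2 * (p - params.a3), -_EXP_GUARD, _EXP_GUARD)
    y = params.a1 / (1.0 + np.exp(u)) + params.a4
    return float(y) if np.isscalar(pressure) or p.ndim == 0 else y


def gain_at(params: LogisticParams, pressure) -> np.ndarray | float:
    """Magnitude of the reflex gain |dY/dX| at the given pressure(s).

    Closed form: a1*a2*e^u / (1+e^u)^2 with u = a2*(P - a3); written via
    the numerically symmetric form a1*a2 / (e^{u/2} + e^{-u/2})^2.
    """
    p = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure must be finite")
    u = np.clip(params.a2 * (p - params.a3), -_EXP_GUARD, _EXP_GUARD)
    sech_half = 1.0 / np.cosh(u / 2.0)
    g = params.a1 * params.a2 * 0.25 * sech_half**2
    return float(g) if np.isscalar(pressure) or p.ndim == 0 else g


def curve_metrics(params: LogisticParams) -> CurveMetrics:
    """Derived descriptors of the curve, in closed form.

    Threshold/saturation solve the 5% conditions exactly:
    Y(Thr) = a4 + 0.95*a1  =>  Thr = a3 - ln(19)/a2, and symmetrically
    Y(Sat) = a4 + 0.05*a1  =>  Sat = a3 + ln(19)/a2.
    """
    half_range = _LN19 / params.a2
    return CurveMetrics(
        threshold=params.a3 - half_range,
        saturation=params.a3 + half_range,
        operating_range=2.0 * half_range,
        midpoint_pressure=params.a3,
        max_gain=params.a1 * params.a2 / 4.0,
        upper_plateau=params.a1 + params.a4,
        lower_plateau=params.a4,
    )


def _initial_guess(pressure: np.ndarray, sna: np.ndarray) -> np.ndarray:
    """Data-driven starting point: plateaus from the SNA extremes, midpoint
    from the sample nearest mid-range, slope from a local linear fit there."""
    a4 = float(np.min(sna))
    a1 = float(np.ptp(sna))
    mid = a4 + a1 / 2.0
    i_mid = int(np.argmin(np.abs(sna - mid)))
    a3 = float(pressure[i_mid])

    # local slope around a3 over a +/-10 mmHg window (fall back to global)
    window = np.abs(pressure - a3) <= 10.0
    if window.sum() < 3:
        window = np.ones_like(pressure, dtype=bool)
    slope = np.polyfit(pressure[window], sna[window], 1)[0]
    a2 = max(4.0 * abs(slope) / a1, 1e-4)
    return np.array([a1, a2, a3, a4])


def fit_logistic(series: PressureSnaSeries, options: FitOptions | None = None) -> FitResult:
    """Least-squares fit of the four-parameter logistic to observed data.

    Multi-start bounded optimization (a1, a2 > 0; a4 >= 0), deterministic
    for a fixed series and options.  Raises
    :class:`UnidentifiableDataError` for series that cannot constrain the
    parameters (too few points, too narrow a pressure span, or a flat
    response); returns ``converged=False`` rather than raising if the
    optimizer fails on identifiable data.
    """
    opts = options or FitOptions()
    p = series.pressure
    y = series.sna
    if len(series) < opts.min_points:
        raise UnidentifiableDataError(
            f"need at least {opts.min_points} points, got {len(series)}"
        )
    if np.ptp(p) < opts.min_pressure_span:
        raise UnidentifiableDataError(
            f"pressure span {np.ptp(p):.1f} mmHg is below the "
            f"{opts.min_pressure_span:.0f} mmHg needed to trace the curve"
        )
    if np.ptp(y) < max(opts.min_sna_range, 1e-12):
        raise UnidentifiableDataError("flat SNA response; curve unidentifiable")

    x0 = _initial_guess(p, y)
    rng = np.random.default_rng(opts.seed)
    lower = np.array([1e-9, 1e-9, -np.inf, 0.0])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])

    def residuals(theta: np.ndarray) -> np.ndarray:
        a1, a2, a3, a4 = theta
        u = np.clip(a2 * (p - a3), -_EXP_GUARD, _EXP_GUARD)
        return a1 / (1.0 + np.exp(u)) + a4 - y

    best = None
    for k in range(max(1, opts.n_starts)):
        if k == 0:
            start = x0.copy()
        else:
            jitter = rng.normal(0.0, [0.15, 0.3, 0.05, 0.15], size=4)
            start = x0 * (1.0 + jitter)
            start[2] = x0[2] + rng.normal(0.0, 5.0)  # a3 jitter in mmHg
        start = np.clip(start, lower, None)
        try:
            sol = least_squares(
                residuals, start, bounds=(lower, upper), max_nfev=opts.max_nfev
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None or not best.success:
        # report the attempt without claiming usable parameters
        fallback = LogisticParams(
            a1=max(x0[0], 1e-6), a2=max(x0[1], 1e-6), a3=x0[2], a4=max(x0[3], 0.0)
        )
        return FitResult(
            params=fallback,
            residual_sd=float("nan"),
            r_squared=0.0,
            converged=False,
            n_points=len(series),
        )

    a1, a2, a3, a4 = best.x
    params = LogisticParams(a1=a1, a2=a2, a3=a3, a4=max(a4, 0.0))
    resid = best.fun
    dof = max(len(series) - 4, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    r_squared = min(max(r_squared, 0.0), 1.0)

    param_se = None
    try:
        jac = best.jac
        cov = np.linalg.inv(jac.T @ jac) * residual_sd**2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        param_se = tuple(float(s) for s in se)
    except np.linalg.LinAlgError:
        pass

    return FitResult(
        params=params,
        residual_sd=residual_sd,
        r_squared=r_squared,
        converged=True,
        n_points=len(series),
        param_se=param_se,
    )
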