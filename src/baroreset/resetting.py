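"""Comparison of baroreflex curves between behavioral states.

Resetting of the reflex between a rest curve and a behavioral-state curve
is summarised by four descriptor deltas (state minus rest) and classified
into four types, numbered to match the circuit mechanism that produces
each effect:

    1  lateral shift of the operating range   (delta midpoint pressure)
    2  change in maximum gain                 (delta max gain)
    3  change in the upper plateau            (delta upper plateau)
    4  change in the lower plateau            (delta lower plateau)

The module also inverts the forward circuit model: given a rest series and
a state series, it estimates the modulatory set (m1..m4) whose simulated
curve best explains the state data, after verifying that the unmodulated
circuit explains the rest data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .circuit import CircuitParams, ModulatorySet, stage_activities
from .logistic import CurveMetrics, FitResult, PressureSnaSeries, curve_metrics

__all__ = [
    "ResettingDelta",
    "ClassificationTolerances",
    "InferenceResult",
    "BaselineMismatchError",
    "compare_fits",
    "classify_resetting",
    "infer_mechanisms",
]


class BaselineMismatchError(ValueError):
    """Rest data are poorly explained by the unmodulated circuit."""


@dataclass(frozen=True)
class ClassificationTolerances:
    """Magnitude a descriptor delta must exceed to count as resetting.

    Defaults are 5% of the rest curve's corresponding descriptor (built
    with :meth:`from_rest_metrics`); all must be strictly positive.
    """

    midpoint: float = 5.0       # mmHg
    max_gain: float = 0.125     # a.u./mmHg
    upper_plateau: float = 5.0  # a.u.
    lower_plateau: float = 5.0  # a.u.

    def __post_init__(self) -> None:
        for name in ("midpoint", "max_gain", "upper_plateau", "lower_plateau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"tolerance {name} must be strictly positive")

    @classmethod
    def from_rest_metrics(cls, rest: CurveMetrics) -> "ClassificationTolerances":
        y_range = rest.upper_plateau - rest.lower_plateau
        return cls(
            midpoint=5.0,
            max_gain=0.05 * rest.max_gain,
            upper_plateau=0.05 * y_range,
            lower_plateau=0.05 * y_range,
        )


@dataclass(frozen=True)
class ResettingDelta:
    """State-minus-rest differences in the fitted curve descriptors."""

    d_midpoint: float        # mmHg
    d_max_gain: float        # a.u./mmHg
    d_upper_plateau: float   # a.u.
    d_lower_plateau: float   # a.u.
    types_present: frozenset[int] = field(default_factory=frozenset)


def compare_fits(rest: FitResult, state: FitResult) -> ResettingDelta:
    """Descriptor deltas between two converged fits, classified with
    tolerances scaled to the rest curve."""
    if not rest.converged or not state.converged:
        raise ValueError("both fits must have converged before comparison")
    mr = curve_metrics(rest.params)
    ms = curve_metrics(state.params)
    delta = ResettingDelta(
        d_midpoint=ms.midpoint_pressure - mr.midpoint_pressure,
        d_max_gain=ms.max_gain - mr.max_gain,
        d_upper_plateau=ms.upper_plateau - mr.upper_plateau,
        d_lower_plateau=ms.lower_plateau - mr.lower_plateau,
    )
    types = classify_resetting(delta, ClassificationTolerances.from_rest_metrics(mr))
    return ResettingDelta(
        d_midpoint=delta.d_midpoint,
        d_max_gain=delta.d_max_gain,
        d_upper_plateau=delta.d_upper_plateau,
        d_lower_plateau=delta.d_lower_plateau,
        types_present=types,
    )


def classify_resetting(
    delta: ResettingDelta, tolerances: ClassificationTolerances | None = None
) -> frozenset[int]:
    """Resetting types whose descriptor exceeds its tolerance in magnitude."""
    tol = tolerances or ClassificationTolerances()
    present = set()
    if abs(delta.d_midpoint) > tol.midpoint:
        present.add(1)
    if abs(delta.d_max_gain) > tol.max_gain:
        present.add(2)
    if abs(delta.d_upper_plateau) > tol.upper_plateau:
        present.add(3)
    if abs(delta.d_lower_plateau) > tol.lower_plateau:
        present.add(4)
    return frozenset(present)


@dataclass(frozen=True)
class InferenceResult:
    mods: ModulatorySet
    residual_sd: float
    r_squared: float
    baseline_r_squared: float
    n_starts: int


def _series_r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot <= 0:
        return 0.0
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def infer_mechanisms(
    rest_series: PressureSnaSeries,
    state_series: PressureSnaSeries,
    circuit: CircuitParams,
    seed: int = 0,
    n_starts: int = 5,
    baseline_r2_min: float = 0.9,
) -> InferenceResult:
    """Estimate the modulatory set that maps the circuit onto state data.

    The rest series calibrates nothing; it verifies that the unmodulated
    circuit (mods = 0) already explains the rest data (r^2 >= 0.9), i.e.
    that the shared circuit is the right baseline.  The state modulations
    are then found by multi-start least squares on the state series, in a
    transformed space (log(1 + m2); identity for m1, m3, m4) that respects
    admissibility, with bounds keeping m3 within the circuit's admissible
    range and m4 non-negative.  Deterministic for a given seed.
    """
    zero = ModulatorySet()
    baseline_pred = stage_activities(circuit, zero, rest_series.pressure).sna
    baseline_r2 = _series_r_squared(rest_series.sna, baseline_pred)
    if baseline_r2 < baseline_r2_min:
        raise BaselineMismatchError(
            f"rest data are poorly explained by the unmodulated circuit "
            f"(r^2 = {baseline_r2:.3f} < {baseline_r2_min}); recalibrate the "
            "circuit constants before inferring mechanisms"
        )

    p = state_series.pressure
    y = state_series.sna

    # theta = (m1, log(1+m2), m3, m4)
    def residuals(theta: np.ndarray) -> np.ndarray:
        m1, z2, m3, m4 = theta
        mods = ModulatorySet(m1=m1, m2=math.expm1(z2), m3=m3, m4=max(m4, 0.0))
        return stage_activities(circuit, mods, p).sna - y

    lower = np.array([-0.45, math.log(0.05), -circuit.tonic_drive + 1e-6, 0.0])
    upper = np.array([0.45, math.log(4.0), circuit.max_m3, np.inf])

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        if k == 0:
            start = np.array([0.0, 0.0, 0.0, 0.0])
        else:
            start = np.array(
                [
                    rng.uniform(-0.3, 0.3),
                    rng.uniform(math.log(0.3), math.log(2.5)),
                    rng.uniform(-0.5 * circuit.tonic_drive, circuit.max_m3),
                    rng.uniform(0.0, 0.3 * circuit.output_scale),
                ]
            )
        start = np.clip(start, lower, np.where(np.isfinite(upper), upper, start))
        try:
            sol = least_squares(residuals, start, bounds=(lower, upper), max_nfev=3000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise RuntimeError("mechanism inference failed from every start")

    m1, z2, m3, m4 = best.x
    mods = ModulatorySet(m1=float(m1), m2=float(math.expm1(z2)),
                         m3=float(m3), m4=float(max(m4, 0.0)))
    pred = stage_activities(circuit, mods, p).sna
    resid = y - pred
    dof = max(y.size - 4, 1)
    return InferenceResult(
        mods=mods,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        r_squared=_series_r_squared(y, pred),
        baseline_r_squared=baseline_r2,
        n_starts=n_starts,
    )
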