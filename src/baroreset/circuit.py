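"""Static four-stage circuit model of the sympathetic baroreflex arc.

The pathway NTS -> CVLM -> RVLM -> IML turns rising arterial pressure into
falling sympathetic vasomotor outflow:

* baroreceptor afferent activity rises sigmoidally with pressure,
* second-order NTS neurons relay it (sigmoid on net drive),
* GABAergic CVLM interneurons are excited by the NTS,
* RVLM premotor neurons carry a tonic excitatory drive and are inhibited by
  the CVLM (rectified at zero -- firing rates cannot be negative),
* spinal IML preganglionic output (SNA) scales the RVLM activity.

Four modulatory inputs from higher centers and/or peripheral receptors act
at one stage each and reset the reflex curve in four distinct ways:

    m1  inhibition of the NTS relay          -> lateral (rightward) shift
    m2  facilitation of the NTS->CVLM input  -> steeper slope (higher gain)
    m3  excitation of RVLM premotor neurons  -> higher upper plateau
    m4  baroreflex-independent IML drive     -> both plateaus raised equally

Reference composition, with pressure P:

    a    = sigmoid(k_a * (P - p_a))            afferent activity in [0, 1]
    n    = sigmoid(k_n * (a - theta_n - m1))   NTS relay in [0, 1]
    c    = (1 + m2) * n                        CVLM activity
    r    = max(0, d0 + m3 - w * c)             RVLM activity
    sna  = max(0, s0 * r + m4)                 sympathetic output, a.u.

The inhibitory weight must satisfy w >= d0 + m3 for every admissible m3 so
that full CVLM activation can silence the RVLM, pinning the lower plateau
of the curve at m4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .logistic import PressureSnaSeries

__all__ = [
    "CircuitParams",
    "ModulatorySet",
    "StageActivities",
    "DEFAULT_CIRCUIT",
    "PRESET_STATES",
    "stage_activities",
    "simulate_curve",
    "preset_state",
    "default_pressure_grid",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700.0, 700.0)))


@dataclass(frozen=True)
class CircuitParams:
    """Fixed constants of the circuit.

    Attributes
    ----------
    afferent_slope : float
        k_a, per mmHg, > 0. Steepness of the baroreceptor afferent sigmoid.
    afferent_midpoint : float
        p_a, mmHg. Pressure of half-maximal afferent activity.
    nts_slope : float
        k_n, dimensionless, > 0. Steepness of the NTS relay sigmoid.
    nts_threshold : float
        theta_n in (0, 1). Afferent level at which the unmodulated NTS
        relay is half active.
    inhibitory_weight : float
        w > 0. Strength of CVLM inhibition onto the RVLM.
    tonic_drive : float
        d0 > 0. Tonic excitatory input to RVLM premotor neurons present
        even at rest.
    output_scale : float
        s0 > 0, a.u. RVLM-to-SNA scaling.
    max_m3 : float
        Largest admissible RVLM modulation; w >= d0 + max_m3 is enforced so
        the lower plateau stays pinned at m4.
    """

    afferent_slope: float = 0.06
    afferent_midpoint: float = 115.0
    nts_slope: float = 10.0
    nts_threshold: float = 0.5
    inhibitory_weight: float = 1.5
    tonic_drive: float = 1.0
    output_scale: float = 100.0
    max_m3: float = 0.5

    def __post_init__(self) -> None:
        checks = {
            "afferent_slope": self.afferent_slope > 0,
            "nts_slope": self.nts_slope > 0,
            "nts_threshold": 0.0 < self.nts_threshold < 1.0,
            "inhibitory_weight": self.inhibitory_weight > 0,
            "tonic_drive": self.tonic_drive > 0,
            "output_scale": self.output_scale > 0,
        }
        for name, ok in checks.items():
            v = getattr(self, name)
            if not (ok and math.isfinite(v)):
                raise ValueError(f"invalid circuit constant {name}={v!r}")
        if not math.isfinite(self.afferent_midpoint):
            raise ValueError("afferent_midpoint must be finite")
        if self.inhibitory_weight < self.tonic_drive + self.max_m3:
            raise ValueError(
                "inhibitory_weight must be >= tonic_drive + max_m3 "
                f"({self.inhibitory_weight} < {self.tonic_drive + self.max_m3}): "
                "full CVLM activation must be able to silence the RVLM"
            )


@dataclass(frozen=True)
class ModulatorySet:
    """The four behavioral modulations acting on the circuit.

    All are signed and finite; ``m4`` (the baroreflex-independent IML
    drive) must be non-negative after output rectification, so it is
    required >= 0 here.  ``m2 >= -1`` keeps the CVLM relay gain
    non-negative.
    """

    m1: float = 0.0  # NTS inhibition, afferent-activity units
    m2: float = 0.0  # CVLM facilitation fraction (0 = none)
    m3: float = 0.0  # RVLM excitatory modulation, drive units
    m4: float = 0.0  # independent IML drive, a.u.

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "m3", "m4"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.m2 < -1.0:
            raise ValueError(f"m2 must be >= -1 (got {self.m2})")
        if self.m4 < 0.0:
            raise ValueError(f"m4 must be >= 0 (got {self.m4})")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.m1, self.m2, self.m3, self.m4)


@dataclass(frozen=True)
class StageActivities:
    """Activity at each stage of the arc for one pressure (or a grid)."""

    afferent: np.ndarray | float  # in [0, 1]
    nts: np.ndarray | float       # in [0, 1]
    cvlm: np.ndarray | float      # >= 0
    rvlm: np.ndarray | float      # >= 0
    sna: np.ndarray | float       # >= 0, a.u.


DEFAULT_CIRCUIT = CircuitParams()

# Behavioral-state presets. Rest switches every modulatory input off (only
# the tonic RVLM drive remains); exercise engages all four mechanisms;
# mental stress engages the NTS and CVLM mechanisms (lateral shift plus
# gain increase); sleep reverses the NTS and RVLM mechanisms, moving the
# curve down and to the left. Magnitudes are package defaults and can be
# overridden per run.
PRESET_STATES: dict[str, ModulatorySet] = {
    "rest": ModulatorySet(0.0, 0.0, 0.0, 0.0),
    "exercise": ModulatorySet(m1=0.15, m2=0.5, m3=0.3, m4=10.0),
    "stress": ModulatorySet(m1=0.20, m2=0.4, m3=0.0, m4=0.0),
    "sleep": ModulatorySet(m1=-0.10, m2=0.0, m3=-0.30, m4=0.0),
}


def default_pressure_grid(
    low: float = 40.0, high: float = 200.0, step: float = 1.0
) -> np.ndarray:
    """Standard analysis grid spanning the full reflex range.

    Covers well past both plateaus of the default circuit so that fitted
    plateau estimates are pinned by data rather than extrapolation.
    """
    return np.arange(low, high + step / 2.0, step)


def preset_state(name: str) -> ModulatorySet:
    """Return the default :class:`ModulatorySet` for a behavioral state."""
    try:
        return PRESET_STATES[name]
    except KeyError:
        valid = ", ".join(sorted(PRESET_STATES))
        raise ValueError(f"unknown state {name!r}; valid states: {valid}") from None


def stage_activities(
    circuit: CircuitParams, mods: ModulatorySet, pressure
) -> StageActivities:
    """Propagate one pressure (or a grid) through the four-stage arc."""
    p = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure must be finite")
    if mods.m3 > circuit.max_m3:
        raise ValueError(
            f"m3={mods.m3} exceeds the circuit's admissible maximum "
            f"{circuit.max_m3}; the lower plateau would no longer be pinned"
        )

    a = _sigmoid(circuit.afferent_slope * (p - circuit.afferent_midpoint))
    n = _sigmoid(circuit.nts_slope * (a - circuit.nts_threshold - mods.m1))
    c = (1.0 + mods.m2) * n
    r = np.maximum(0.0, circuit.tonic_drive + mods.m3 - circuit.inhibitory_weight * c)
    sna = np.maximum(0.0, circuit.output_scale * r + mods.m4)

    scalar = np.isscalar(pressure) or p.ndim == 0
    if scalar:
        return StageActivities(float(a), float(n), float(c), float(r), float(sna))
    return StageActivities(a, n, c, r, sna)


def simulate_curve(
    circuit: CircuitParams, mods: ModulatorySet, pressure_grid, label: str | None = None
) -> PressureSnaSeries:
    """Sample the circuit's noiseless SNA output over an ordered grid."""
    grid = np.asarray(pressure_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("pressure_grid must contain at least two points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("pressure_grid must be strictly increasing")
    acts = stage_activities(circuit, mods, grid)
    return PressureSnaSeries(pressure=grid, sna=acts.sna, label=label)
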