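"""Synthetic modified-Oxford-style data for exercising the toolkit.

The modified Oxford protocol sweeps arterial pressure across the full
operating range of the reflex with vasoactive drugs (a fall to a nadir,
then a rise to a peak) while sympathetic activity is recorded.  The
generator emulates this as a piecewise-linear pressure trajectory fed
through the forward circuit model, with additive Gaussian measurement
noise on the SNA channel only (pressure is treated as measured exactly)
and rectification at zero, since nerve activity cannot be negative.

Every generator is a pure function of its arguments, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import (
    CircuitParams,
    DEFAULT_CIRCUIT,
    ModulatorySet,
    preset_state,
    stage_activities,
)
from .logistic import PressureSnaSeries

__all__ = [
    "RampProtocol",
    "NoiseSpec",
    "generate_oxford_pressures",
    "sample_observations",
    "make_state_dataset",
]


@dataclass(frozen=True)
class RampProtocol:
    """Pressure trajectory of a simulated modified-Oxford run.

    The pressure falls linearly from ``start_pressure`` to ``nadir`` (the
    vasodilator phase), then rises linearly to ``peak`` (the vasoconstrictor
    phase), at ``rate`` mmHg/s, sampled every ``sample_interval`` seconds.
    """

    start_pressure: float = 100.0  # mmHg
    nadir: float = 60.0            # mmHg
    peak: float = 180.0            # mmHg
    rate: float = 1.0              # mmHg/s
    sample_interval: float = 1.0   # s

    def __post_init__(self) -> None:
        if not (self.nadir < self.start_pressure < self.peak):
            raise ValueError(
                "protocol requires nadir < start_pressure < peak, got "
                f"{self.nadir}, {self.start_pressure}, {self.peak}"
            )
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.sample_interval <= 0:
            raise ValueError(f"sample_interval must be > 0, got {self.sample_interval}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise on the SNA channel."""

    sd: float = 0.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")


def generate_oxford_pressures(protocol: RampProtocol) -> np.ndarray:
    """Sampled pressure trajectory start -> nadir -> peak, inclusive ends."""
    down_duration = (protocol.start_pressure - protocol.nadir) / protocol.rate
    up_duration = (protocol.peak - protocol.nadir) / protocol.rate
    total = down_duration + up_duration
    n = int(math.floor(total / protocol.sample_interval + 1e-9)) + 1
    t = np.arange(n) * protocol.sample_interval
    falling = t <= down_duration
    p = np.where(
        falling,
        protocol.start_pressure - protocol.rate * t,
        protocol.nadir + protocol.rate * (t - down_duration),
    )
    return np.clip(p, protocol.nadir, protocol.peak)


def sample_observations(
    circuit: CircuitParams,
    mods: ModulatorySet,
    pressures,
    noise: NoiseSpec = NoiseSpec(),
    label: str | None = None,
) -> PressureSnaSeries:
    """Noisy SNA observations from the forward circuit at given pressures."""
    p = np.asarray(pressures, dtype=float)
    clean = stage_activities(circuit, mods, p).sna
    rng = np.random.default_rng(noise.seed)
    sna = np.maximum(0.0, clean + rng.normal(0.0, noise.sd, size=p.shape))
    return PressureSnaSeries(pressure=p, sna=sna, label=label)


def make_state_dataset(
    states: list[str],
    protocol: RampProtocol = RampProtocol(),
    noise: NoiseSpec = NoiseSpec(),
    circuit: CircuitParams = DEFAULT_CIRCUIT,
) -> dict[str, PressureSnaSeries]:
    """One labeled series per behavioral state, from its preset modulations.

    Per-state seeds are derived deterministically from the base seed and
    the state's position in the list, so a bundle is reproducible while
    states still receive independent noise streams.
    """
    bundle: dict[str, PressureSnaSeries] = {}
    pressures = generate_oxford_pressures(protocol)
    for i, state in enumerate(states):
        mods = preset_state(state)
        state_seed = int(np.random.SeedSequence([noise.seed, i]).generate_state(1)[0])
        # keep derived seeds in signed-int32 range for portability
        state_seed %= 2**31
        bundle[state] = sample_observations(
            circuit,
            mods,
            pressures,
            NoiseSpec(sd=noise.sd, seed=state_seed),
            label=state,
        )
    return bundle
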