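"""Synthetic daily series with known periodic structure.

The generator emulates the profile of a long environmental exposure record
(about 16 years of complete daily values, e.g. fine particulate matter):
a sum of periodic mean components at chosen periods — annual, semi-annual,
tri-annual, weekly and others — of differing amplitudes, an optional slow
linear trend, and serially correlated noise.  The noise is a stationary
AR(1) process initialized from its stationary distribution, so coverage
and power experiments see no burn-in artifacts; its marginal variance is
``noise_sd**2 / (1 - ar1**2)``.

Every simulation returns the exact per-component periodic means as ground
truth, which is what coverage, type-I-error and power studies check the
bootstrap bands against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .series import RegularSeries

__all__ = ["ComponentSpec", "SyntheticSpec", "simulate", "component_values"]

_WAVEFORMS = ("sinusoid", "square", "sawtooth")


@dataclass(frozen=True)
class ComponentSpec:
    """One periodic mean component.

    period is in samples (days) and may be non-integer (harmonics of the
    annual cycle such as 365/2 are not whole days); amplitude is in series
    units; phase in radians.  Square and sawtooth waveforms exist to
    exercise the bandpass filters on periodic means whose harmonics fall
    outside a single band.
    """

    period: float
    amplitude: float
    phase: float = 0.0
    waveform: str = "sinusoid"

    def __post_init__(self) -> None:
        if not np.isfinite(self.period) or self.period < 2:
            raise ValueError(f"period must be finite and >= 2 samples, got {self.period}")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError(f"amplitude must be finite and >= 0, got {self.amplitude}")
        if not np.isfinite(self.phase):
            raise ValueError("phase must be finite")
        if self.waveform not in _WAVEFORMS:
            raise ValueError(f"waveform must be one of {_WAVEFORMS}, got {self.waveform!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one simulated series."""

    n: int
    components: tuple[ComponentSpec, ...] = ()
    noise_sd: float = 0.0
    ar1: float = 0.0
    trend_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.n < 2:
            raise ValueError("n must be >= 2")
        max_p = max((c.period for c in self.components), default=1.0)
        if self.n < 2 * max_p:
            raise ValueError(
                f"series length {self.n} is shorter than two cycles of the "
                f"longest period {max_p}"
            )
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and >= 0")
        if not np.isfinite(self.ar1) or not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must lie strictly inside (-1, 1)")
        if not np.isfinite(self.trend_slope):
            raise ValueError("trend_slope must be finite")


def component_values(comp: ComponentSpec, t: np.ndarray) -> np.ndarray:
    """Deterministic waveform of one component at sample times t."""
    arg = 2.0 * np.pi * t / comp.period + comp.phase
    if comp.waveform == "sinusoid":
        w = np.cos(arg)
    elif comp.waveform == "square":
        w = scipy.signal.square(arg)
    else:
        w = scipy.signal.sawtooth(arg)
    return comp.amplitude * w


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1): x[t] = phi x[t-1] + eps[t], eps ~ N(0, sd^2),
    x[-1] drawn from the stationary law N(0, sd^2/(1-phi^2))."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, size=n)
    x_init = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi))
    if phi == 0.0:
        return eps
    out, _ = scipy.signal.lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x_init]))
    return out


def simulate(spec: SyntheticSpec, start=None):
    """Generate a series and the exact periodic means of its components.

    Returns
    -------
    series : RegularSeries
        trend + sum of components + AR(1) noise; identical seeds give
        bit-identical output.
    ground_truth : dict
        Maps each component's period to its deterministic periodic mean
        over one cycle of the rounded integer period (for an integer
        period this is simply the waveform evaluated at phases 0..p-1).
    """
    t = np.arange(spec.n, dtype=float)
    values = spec.trend_slope * t
    ground_truth: dict[float, np.ndarray] = {}
    for comp in spec.components:
        cv = component_values(comp, t)
        values = values + cv
        p = int(round(comp.period))
        n_cycles = spec.n // p
        if n_cycles < 1:
            raise ValueError(f"series too short for one cycle of period {comp.period}")
        ground_truth[comp.period] = cv[: n_cycles * p].reshape(n_cycles, p).mean(axis=0)
    rng = np.random.default_rng(spec.seed)
    values = values + _ar1_noise(spec.n, spec.noise_sd, spec.ar1, rng)
    return RegularSeries(values, start=start), ground_truth
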