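"""Period-aligned block bootstrap and percentile CI bands for periodic means.

The resampler follows the seasonal block-bootstrap scheme in which every
block has length equal to the period p and starts at a phase-0 position,
so each resampled observation originates from an input position with the
same phase (t mod p).  That preserves the periodic correlation structure:
the periodic mean of a resample is a mean of randomly chosen complete
cycles.  Repeating the draw B times and taking per-phase empirical
quantiles of the resampled periodic means yields the confidence band; the
band for a 95% level runs from the 2.5th to the 97.5th percentile at every
phase of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kzft import PCComponent
from .series import RegularSeries

__all__ = [
    "BootstrapConfig",
    "CIBand",
    "periodic_mean",
    "gsbb_resample",
    "bootstrap_band",
    "band_to_frame",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling parameters shared by every bootstrap in the pipeline.

    B : number of independent resamples (1000 in the reference analysis).
    alpha : two-sided level of the band (0.05 gives the 2.5/97.5 band).
    seed : master seed; all randomness derives from it deterministically.
    block_period : optional default period when an operation is not given
        one explicitly.
    """

    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    block_period: int | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.block_period is not None and self.block_period < 2:
            raise ValueError("block_period must be >= 2")


@dataclass
class CIBand:
    """Phase-indexed percentile band for one period.

    ``lower``/``upper`` are the per-phase alpha/2 and 1-alpha/2 quantiles of
    the bootstrapped periodic means; ``point_estimate`` is the periodic mean
    of the input itself.  ``anchor`` is the calendar date of phase 0 (the
    first valid observation) when known, so phases can be labeled by
    weekday or month.
    """

    p: int
    lower: np.ndarray
    upper: np.ndarray
    point_estimate: np.ndarray
    alpha: float
    anchor: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        for name in ("lower", "upper", "point_estimate"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != len(self.lower):
                raise ValueError("band arrays must share one length")
            setattr(self, name, arr)
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def scaled(self, c: float) -> "CIBand":
        """Band of the series scaled by a positive constant."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return CIBand(
            p=self.p,
            lower=c * self.lower,
            upper=c * self.upper,
            point_estimate=c * self.point_estimate,
            alpha=self.alpha,
            anchor=self.anchor,
        )


def _valid_segment(x) -> tuple[np.ndarray, int, object]:
    """(contiguous valid values, absolute first-valid index, start date)."""
    if isinstance(x, PCComponent):
        x = x.series
    if isinstance(x, RegularSeries):
        return x.valid_values(), x.first_valid, x.start
    v = np.asarray(x, dtype=float)
    return v, 0, None


def periodic_mean(x, p: int) -> np.ndarray:
    """Per-phase mean: entry j averages valid observations at positions
    congruent to j (mod p), counted from the first valid index."""
    if p < 2:
        raise ValueError("period must be >= 2")
    v, _, _ = _valid_segment(x)
    n = v.size
    if n < p:
        raise ValueError(f"need at least one observation per phase: n={n} < p={p}")
    out = np.empty(p)
    for j in range(p):
        out[j] = v[j::p].mean()
    return out


def _cycle_matrix(v: np.ndarray, p: int) -> np.ndarray:
    """Complete cycles of v as an (n_cycles, p) matrix; the trailing partial
    cycle is dropped so every block is full length."""
    n_cycles = v.size // p
    if n_cycles < 2:
        raise ValueError(
            f"need at least two complete cycles to resample: {v.size} points, period {p}"
        )
    return v[: n_cycles * p].reshape(n_cycles, p)


def gsbb_resample(
    x, p: int, rng: np.random.Generator, return_indices: bool = False
):
    """One period-aligned block resample.

    The input's complete cycles form blocks of length p starting at
    positions r*p; each output block is an independently, uniformly chosen
    input block.  By construction every output position keeps the phase of
    its source position.  Returns the resampled values (length
    ``p * (n // p)``), optionally with the source indices relative to the
    first valid observation.
    """
    v, _, _ = _valid_segment(x)
    blocks = _cycle_matrix(v, p)
    n_cycles = blocks.shape[0]
    r = rng.integers(0, n_cycles, size=n_cycles)
    out = blocks[r].reshape(-1)
    if return_indices:
        src = (r[:, None] * p + np.arange(p)[None, :]).reshape(-1)
        return out, src
    return out


def bootstrap_band(x, p: int | None = None, cfg: BootstrapConfig | None = None) -> CIBand:
    """Percentile CI band of the periodic mean under period-aligned resampling.

    For b = 1..B the periodic mean of an independent resample is computed;
    lower/upper are the per-phase alpha/2 and 1-alpha/2 empirical quantiles
    (linear interpolation).  The band is a pure function of
    (x, p, B, alpha, seed).
    """
    cfg = cfg or BootstrapConfig()
    if p is None:
        p = cfg.block_period
    if p is None:
        raise ValueError("a block period is required")
    v, first_valid, start = _valid_segment(x)
    blocks = _cycle_matrix(v, p)
    n_cycles = blocks.shape[0]
    rng = np.random.default_rng(cfg.seed)
    means = np.empty((cfg.B, p))
    for b in range(cfg.B):
        r = rng.integers(0, n_cycles, size=n_cycles)
        means[b] = blocks[r].mean(axis=0)
    lower, upper = np.quantile(
        means, [cfg.alpha / 2.0, 1.0 - cfg.alpha / 2.0], axis=0, method="linear"
    )
    anchor = None
    if start is not None:
        anchor = pd.Timestamp(start) + pd.Timedelta(days=first_valid)
    return CIBand(
        p=p,
        lower=lower,
        upper=upper,
        point_estimate=periodic_mean(v, p),
        alpha=cfg.alpha,
        anchor=anchor,
    )


def band_to_frame(band: CIBand) -> pd.DataFrame:
    """Tabular form of a band: phase, calendar-derived label, bounds."""
    phases = np.arange(band.lower.size)
    if band.anchor is not None:
        dates = band.anchor + pd.to_timedelta(phases, unit="D")
        if band.p == 7:
            labels = dates.strftime("%A")
        else:
            labels = dates.strftime("%Y-%m-%d")
    else:
        labels = [f"phase-{j}" for j in phases]
    return pd.DataFrame(
        {
            "phase_index": phases,
            "anchor_label": list(labels),
            "lower": band.lower,
            "point_estimate": band.point_estimate,
            "upper": band.upper,
        }
    )
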