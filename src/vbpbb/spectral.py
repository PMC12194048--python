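"""Raw FFT periodogram for identifying candidate periodicities.

The periodogram here is the classical untapered, unsmoothed one: after
removing the mean (and, by default, a linear trend), the power at Fourier
frequency j/n is ``|DFT_j|^2 / n``.  A pure cosine of amplitude A at a
Fourier frequency then shows a single spike of power ``n A^2 / 4``.  Peaks
are used only to nominate candidate periods; domain-motivated periods (the
7-day work week, for instance) can be merged in regardless of their power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .series import RegularSeries

__all__ = ["Periodogram", "periodogram", "top_periods"]


@dataclass
class Periodogram:
    """One-sided periodogram on the Fourier grid j/n, j = 1 ... n//2."""

    frequencies: np.ndarray
    power: np.ndarray

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.frequencies


def periodogram(x: RegularSeries, detrend: bool = True) -> Periodogram:
    """Periodogram of the valid part of ``x``.

    Parameters
    ----------
    detrend : bool
        Remove a least-squares linear trend before the FFT (the mean is
        always removed).  Keeping slow drift out of the spectrum stops the
        lowest frequencies from swamping the display.
    """
    v = x.valid_values()
    n = v.size
    if n < 4:
        raise ValueError("periodogram needs at least 4 observations")
    v = scipy.signal.detrend(v, type="linear" if detrend else "constant")
    coef = np.fft.rfft(v)
    j = np.arange(1, n // 2 + 1)
    power = np.abs(coef[j]) ** 2 / n
    return Periodogram(frequencies=j / n, power=power)


def top_periods(
    pg: Periodogram,
    count: int,
    candidate_periods: list[float] | None = None,
) -> list[tuple[float, float]]:
    """Highest-power periods, merged with user-nominated candidates.

    Candidates off the Fourier grid are looked up at the nearest Fourier
    frequency but reported at their nominal period.  Returns (period, power)
    pairs sorted by descending power.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    order = np.argsort(pg.power)[::-1][:count]
    entries: dict[int, tuple[float, float]] = {
        int(i): (float(1.0 / pg.frequencies[i]), float(pg.power[i])) for i in order
    }
    for period in candidate_periods or []:
        if period <= 0:
            raise ValueError(f"candidate period must be positive, got {period}")
        i = int(np.argmin(np.abs(pg.frequencies - 1.0 / period)))
        entries.setdefault(i, (float(period), float(pg.power[i])))
    return sorted(entries.values(), key=lambda e: e[1], reverse=True)
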