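"""Regularly sampled univariate series with an optional calendar anchor.

All stages of the pipeline (simulation, filtering, bootstrapping) operate on
:class:`RegularSeries`: an equally spaced array of values at a fixed daily
step, optionally anchored to a start date, with a boolean validity mask.
The mask exists because symmetric filters cannot produce output within half
a window of either end of the record; those positions are retained (so
indices stay aligned with the calendar) but flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegularSeries"]


@dataclass
class RegularSeries:
    """An equally spaced univariate time series.

    Parameters
    ----------
    values : array-like of float
        Observations at consecutive steps.  Must be finite wherever
        ``valid_mask`` is true.
    start : pandas.Timestamp or None
        Calendar date of index 0.  ``None`` for abstract (index-anchored)
        series such as simulations without a calendar.
    step_days : int
        Sampling interval in days (the analysis assumes daily data).
    valid_mask : ndarray of bool or None
        Positions carrying usable values.  ``None`` means all positions
        are valid.
    """

    values: np.ndarray
    start: pd.Timestamp | None = None
    step_days: int = 1
    valid_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a one-dimensional array of length >= 1")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask must match values in shape")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite values on the valid support")
        if self.start is not None:
            self.start = pd.Timestamp(self.start)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def first_valid(self) -> int:
        """Index of the first valid observation."""
        idx = np.flatnonzero(self.valid_mask)
        if idx.size == 0:
            raise ValueError("series has no valid observations")
        return int(idx[0])

    def valid_values(self) -> np.ndarray:
        """Contiguous valid segment of the series.

        The filters in this package only invalidate symmetric margins, so
        the valid support is required to be one contiguous run.
        """
        idx = np.flatnonzero(self.valid_mask)
        if idx.size == 0:
            raise ValueError("series has no valid observations")
        if idx[-1] - idx[0] + 1 != idx.size:
            raise ValueError("valid support is not contiguous")
        return self.values[idx[0] : idx[-1] + 1]

    def dates(self) -> pd.DatetimeIndex | None:
        """Calendar dates for every index, or None when unanchored."""
        if self.start is None:
            return None
        return pd.date_range(self.start, periods=len(self), freq=f"{self.step_days}D")

    def date_of(self, index: int) -> pd.Timestamp | None:
        if self.start is None:
            return None
        return self.start + pd.Timedelta(days=self.step_days * index)
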