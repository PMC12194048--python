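"""Kolmogorov-Zurbenko (KZ) filter and its Fourier-transform variant (KZFT).

The KZ filter is a k-fold iterated simple moving average with odd window
length m.  Its weights are the coefficients of the polynomial
``(1 + z + ... + z^(m-1))^k / m^k`` — a symmetric, nonnegative kernel of
length ``k(m-1)+1`` that sums to one.  The KZFT applies the same kernel
after demodulating by ``exp(-i 2 pi nu s)``, turning the low-pass KZ into a
bandpass filter centered at frequency ``nu`` (cycles per sample):

    KZFT[X](t) = sum_s  a_s X(t+s) exp(-i 2 pi nu s),
    s = -k(m-1)/2 ... k(m-1)/2.

The complex output is a demodulate: a pure cosine at the center frequency
comes out as ``exp(i(2 pi nu t + phase))/2``, so the real periodic component
is recovered as twice the real part.  The transfer magnitude at an offset
``d = nu' - nu`` from the center is the Dirichlet kernel raised to k,

    |sin(pi m d) / (m sin(pi d))| ** k,

which vanishes whenever ``m d`` is a nonzero integer — the property used to
place interfering periodicities at exact nulls of the filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .series import RegularSeries

__all__ = [
    "FilterCoefficients",
    "KZFTSpec",
    "ComplexDemodulate",
    "PCComponent",
    "kz_coefficients",
    "apply_kz",
    "apply_kzft",
    "reconstruct",
    "gain",
    "default_window",
]


@dataclass(frozen=True)
class FilterCoefficients:
    """Symmetric KZ kernel a_s for window m and iteration k."""

    m: int
    k: int
    weights: np.ndarray

    @property
    def half_width(self) -> int:
        """Margin k(m-1)/2 lost at each end of a filtered series."""
        return self.k * (self.m - 1) // 2


@dataclass
class KZFTSpec:
    """Arguments of one bandpass filter: window m (odd), iterations k,
    center frequency nu in cycles/sample.

    ``nu * m`` should be an integer; otherwise the filter's nulls miss the
    harmonics of the target period, a phase shift appears and fidelity
    drops.  The condition is recorded in ``nu_m_integer`` and a warning is
    emitted when the filter is applied.
    """

    m: int
    k: int = 1
    nu: float = 0.0
    nu_m_integer: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.m < 1 or self.m % 2 == 0:
            raise ValueError(f"window length m must be a positive odd integer, got {self.m}")
        if self.k < 1:
            raise ValueError(f"iterations k must be >= 1, got {self.k}")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError(f"frequency nu must lie in [0, 0.5], got {self.nu}")
        prod = self.nu * self.m
        self.nu_m_integer = bool(np.isclose(prod, np.round(prod), atol=1e-9))


@dataclass
class ComplexDemodulate:
    """Complex bandpass output z(t) with its validity mask."""

    z: np.ndarray
    valid_mask: np.ndarray
    nu: float
    start: object = None


@dataclass
class PCComponent:
    """A real, bandpass-isolated periodic component.

    ``series`` holds the reconstructed real values (invalid at the filter
    margins); ``nu`` is the center frequency and ``p`` the integer period
    used downstream to set the bootstrap block length.
    """

    series: RegularSeries
    nu: float
    p: int | None
    valid_mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def first_valid(self) -> int:
        return self.series.first_valid

    def valid_values(self) -> np.ndarray:
        return self.series.valid_values()


def kz_coefficients(m: int, k: int) -> FilterCoefficients:
    """Weights of the KZ(m, k) filter.

    Computed as the k-fold self-convolution of the uniform length-m window,
    i.e. the coefficients of ``(1 + z + ... + z^(m-1))^k / m^k``.
    """
    if m < 1 or m % 2 == 0:
        raise ValueError(f"window length m must be a positive odd integer, got {m}")
    if k < 1:
        raise ValueError(f"iterations k must be >= 1, got {k}")
    # convolve in exact integers (float64 holds them exactly), divide once:
    # the weights then equal the polynomial coefficients over m^k bit-for-bit
    box = np.ones(m)
    w = box
    for _ in range(k - 1):
        w = np.convolve(w, box)
    return FilterCoefficients(m=m, k=k, weights=w / float(m) ** k)


def _kzft_values(values: np.ndarray, coeffs: FilterCoefficients, nu: float):
    """Core demodulate-filter-remodulate step on a plain array.

    Accepts real or complex input (complex probes are used to measure the
    transfer function).  Returns (z, valid_mask).
    """
    x = np.asarray(values)
    n = x.size
    h = coeffs.half_width
    if n < 2 * h + 1:
        raise ValueError(
            f"series of length {n} is shorter than one filter window ({2 * h + 1})"
        )
    if h == 0:
        # degenerate window: the filter is the identity, exactly
        z = x.astype(complex) if not np.iscomplexobj(x) else x.copy()
    elif nu == 0.0:
        z = np.convolve(x, coeffs.weights, mode="same")
    else:
        t = np.arange(n)
        carrier = np.exp(-2j * np.pi * nu * t)
        # symmetric kernel: convolution and correlation coincide
        z = np.convolve(x * carrier, coeffs.weights, mode="same") * np.conj(carrier)
    mask = np.zeros(n, dtype=bool)
    mask[h : n - h] = True
    return z, mask


def apply_kz(x: RegularSeries, spec: KZFTSpec) -> RegularSeries:
    """Low-pass KZ filter (the spec's ``nu`` is ignored).

    Valid output is the weighted sum over the full window; the k(m-1)/2
    positions at each end are marked invalid.
    """
    coeffs = kz_coefficients(spec.m, spec.k)
    z, mask = _kzft_values(x.values, coeffs, 0.0)
    out = np.where(mask, z.real if np.iscomplexobj(z) else z, 0.0)
    return RegularSeries(out, start=x.start, step_days=x.step_days, valid_mask=mask)


def apply_kzft(x: RegularSeries, spec: KZFTSpec) -> ComplexDemodulate:
    """Bandpass filter centered at ``spec.nu``; returns the complex demodulate."""
    if not spec.nu_m_integer:
        warnings.warn(
            f"nu*m = {spec.nu * spec.m:.6g} is not an integer for (m={spec.m}, "
            f"nu={spec.nu:.6g}); expect a phase shift and reduced fidelity",
            UserWarning,
            stacklevel=2,
        )
    coeffs = kz_coefficients(spec.m, spec.k)
    z, mask = _kzft_values(x.values, coeffs, spec.nu)
    z = np.where(mask, z, 0.0 + 0.0j)
    return ComplexDemodulate(z=z, valid_mask=mask, nu=spec.nu, start=x.start)


def reconstruct(zd: ComplexDemodulate, p: int | None = None) -> PCComponent:
    """Real periodic component from a complex demodulate.

    For ``nu > 0`` the component is ``2 Re(z)`` (the one-sided spectrum is
    doubled so a unit cosine comes back with unit amplitude); for ``nu = 0``
    it is ``Re(z)``.  The bootstrap period defaults to ``round(1/nu)``.
    """
    nu = zd.nu
    if nu > 0:
        comp = 2.0 * zd.z.real
        if p is None:
            p = int(round(1.0 / nu))
    else:
        comp = np.asarray(zd.z).real.copy()
        # no doubling at zero frequency; a period must be given explicitly
    comp = np.where(zd.valid_mask, comp, 0.0)
    series = RegularSeries(comp, start=zd.start, valid_mask=zd.valid_mask.copy())
    if p is not None and p < 2:
        raise ValueError(f"bootstrap period must be >= 2, got {p}")
    return PCComponent(series=series, nu=nu, p=p, valid_mask=zd.valid_mask.copy())


def gain(spec: KZFTSpec, probe_nu) -> np.ndarray | float:
    """Analytic transfer magnitude of KZFT(m, k, nu) at probe frequencies.

    ``|sin(pi m d) / (m sin(pi d))|^k`` with ``d = probe_nu - nu``; equal to
    1 at the center (and at aliases where d is an integer).
    """
    d = np.asarray(probe_nu, dtype=float) - spec.nu
    denom = spec.m * np.sin(np.pi * d)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.sin(np.pi * spec.m * d) / denom
    # d -> integer: the kernel tends to +-1, so the magnitude tends to 1
    ratio = np.where(np.isclose(np.sin(np.pi * d), 0.0, atol=1e-12), 1.0, ratio)
    g = np.abs(ratio) ** spec.k
    return float(g) if np.isscalar(probe_nu) else g


def default_window(p: float, multiple: int = 3) -> int:
    """Window length: a multiple of the period rounded up to the next odd integer."""
    m = int(np.ceil(multiple * p))
    if m % 2 == 0:
        m += 1
    return m
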