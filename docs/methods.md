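# Methods

## Model and procedure

A periodically correlated (PC) component of a daily series X(t) is a part
of the signal whose mean repeats with period p. The pipeline estimates the
periodic mean of each candidate component and a bootstrap confidence band
around it, in four steps per period:

1. **Center.** X is reduced by its sample mean, so every band lives on a
   zero-anchored scale and "no periodic structure" means a band around 0.
2. **Bandpass.** The KZFT filter at frequency ν = 1/p with window m and
   iterations k produces the complex demodulate
   z(t) = Σ_s a_s X(t+s) e^(−i2πνs); the real component is 2·Re(z).
   The weights a_s are the exact coefficients of
   (1+z+…+z^(m−1))^k / m^k, applied in a single convolution pass
   (identical to k iterated moving averages). The transfer magnitude at
   an offset d from the center is |sin(πmd)/(m sin(πd))|^k.
3. **Resample.** The component's valid support is cut into ⌊n/p⌋ complete
   blocks of length exactly p starting at phase-0 positions; a resample
   concatenates that many uniformly drawn blocks, so every position keeps
   its phase mod p. The trailing partial cycle is dropped from resampling
   (the point estimate still uses it).
4. **Band and verdict.** Per phase, the α/2 and 1−α/2 empirical quantiles
   (linear interpolation) of the B resampled periodic means form the band.
   A component is significant when 0 lies strictly inside the range over
   phases of the upper bounds *and* strictly inside the range of the lower
   bounds — the band then excludes every constant periodic mean.

The unfiltered baseline applies steps 3–4 directly to the centered raw
series; `compare_bands` reports the median over phases of the
baseline/filtered width ratio (phases with zero filtered width are
excluded and counted). `sum_components` resamples each significant
component independently with its own period, tiles each draw's periodic
mean along the common valid timeline, sums pointwise, and takes pointwise
quantiles; the default span is the LCM of the periods capped at two years
and at the common window.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| m | filter window (odd, days) | 3× period, next odd | places the first kernel nulls at ν ± 1/m, three periods wide; the six-period reference plan uses 1095/1095/1095/741/729/729 |
| k | filter iterations | 1 | higher k sharpens the stopband at the price of k(m−1)/2 lost days per end; 1 suffices for bands this narrow |
| ν | center frequency (cycles/day) | 1/p (harmonics: 2/365, 3/365) | the component of interest |
| p | bootstrap period (days) | round(1/ν) | block length must be an integer; harmonics use 183 and 122 |
| B | resamples | 1000 | stable 2.5/97.5 percentiles |
| α | band level | 0.05 | 95% band |
| seed | master seed | — | per-component seeds are spawned from it (SeedSequence), so components are independent yet reproducible |

Filter edges are never padded or shrunk: k(m−1)/2 positions at each end
are marked invalid and excluded from resampling. Phase 0 is anchored at
the first valid observation and its calendar date is reported, so weekly
bands can be labeled by weekday and annual bands by date.

ν·m should be an integer; otherwise the kernel's nulls miss the
neighbouring harmonics and a phase shift appears. The reference window
choices 741 (p=20) and 729 (p=13, 7) violate this (ν·m = 37.05, 56.08,
104.14); the package reproduces them but records the condition on the
filter spec and warns when such a filter runs.

## Synthetic data

`vbpbb.synthetic` generates trend + Σ periodic components + stationary
AR(1) noise. Components may be sinusoid, square or sawtooth (the latter
two leak harmonics outside any single band, exercising the isolation
premise) and may have non-integer periods. The AR(1) noise is initialized
from its stationary distribution (marginal sd `noise_sd/√(1−φ²)`). The
generator returns the exact deterministic periodic mean of every
component, the ground truth for calibration studies.

The study conditions used by `scripts/acceptance.py` emulate the
motivating dataset's shape: n = 5,844 daily values (~16 years), periodic
components at 183 (amplitude 2.0), 122 (1.0) and 7 (0.7) days — plus a
weak annual term (0.8) in the full pipeline run — with AR(1) noise
(sd 2.0, φ 0.5). Amplitudes are ordered like the magnitudes of the
reference bands (semi-annual largest, weekly smallest) and the noise sd
is set so the raw series is noise-dominated at the weekly scale, which is
the regime where bandpass filtering matters. Calibration simulations use
the smaller design n = 2,184 (312 weeks), weekly amplitude 1 (coverage)
or 0/2 (type-I/power), noise sd 1, φ 0.3, B = 500, 200 replicates —
sizes chosen to keep the full suite fast while leaving Monte-Carlo error
well inside the asserted margins.

What the generator does *not* emulate: long-memory or seasonal
heteroskedastic noise, slowly drifting amplitudes or phases, measurement
artifacts, and missing data (the pipeline rejects gaps rather than
imputing). Passing calibration here shows the machinery is correct under
stationary AR(1) noise with fixed periodic means, not that real pollutant
series satisfy those assumptions.

## Numerical choices

- Coefficients are convolved in exact integer arithmetic (held in float64)
  and divided by m^k once, so they equal the polynomial coefficients
  bit-for-bit; they are symmetric, nonnegative and sum to 1 within 1e−12.
- The degenerate window m = 1 returns the input exactly (no
  demodulate/remodulate roundoff), so with m=1, k=1 the filtered band
  equals exactly 2× the unfiltered band under a shared seed — the
  documented reduction of the filtered bootstrap to the plain one, up to
  the one-sided factor 2 of the reconstruction convention.
- The analytic gain at offsets where sin(πd) = 0 is taken as its limit 1.
- Quantiles use numpy's inclusive linear-interpolation method.
- A constant series yields an all-zero periodogram; that is a valid
  result, not an error. Candidate periods off the Fourier grid are looked
  up at the nearest Fourier frequency.

## Limitations

- **Filtered-component verdicts are anti-conservative under broadband
  noise.** After a bandpass of window m, period-p blocks are correlated
  over roughly m/p lags, but the resampler draws blocks independently, so
  the bootstrap understates the phase-mean sd by about √(m/p) (measured:
  ×1.7 at m=21, p=7; ×13 at m=729, p=7). On pure-noise input the
  significance rule then flags filtered components far more often than α
  would suggest. This is inherent to block-length-equals-period
  resampling of a heavily smoothed series, not an implementation defect;
  the calibration guarantees (coverage, type-I, power) therefore attach to
  the band of the *raw* series, and filtered verdicts should be read
  together with the band magnitudes. Off-period verdicts on series with a
  strong true component at another period are nevertheless reliably
  negative, because the leaked true component inflates the off-period
  band.
- Band coverage is pointwise per phase, not simultaneous across the cycle.
- No multiple-testing correction is applied across tested periods.
- The filter loses k(m−1)/2 days per end; with m = 1095 that is 1.5 years
  of a 16-year record per side, which is why only ~13 complete annual
  cycles remain for the annual band.
- m and k are taken as given; no automatic bandwidth selection.
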