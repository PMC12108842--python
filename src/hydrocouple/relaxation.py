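"""Autocorrelation, gap-aware segmentation and relaxation-time estimation.

The relaxation time of a scalar observable is the truncated integral of its
normalized autocorrelation function C(tau)/C(0) from tau = 0 up to T, the
lag where it first reaches 0.1 (found by linear interpolation between the
bracketing lags).  For an exactly exponential C(tau) = exp(-tau/tau0) this
equals 0.9 * tau0, which serves as the closed-form oracle in the tests.

Because the per-residue order-parameter series contains gaps (frames with
no contact water), the series is split into maximal gap-free segments; a
segment's estimate is kept only if a 0.1-crossing exists and the estimated
relaxation time does not exceed 10% of the segment duration — segments
failing either check are discarded, and the residue's relaxation time is
the mean over the surviving segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DegenerateSeriesError
from .series import GappedSeries, Segment

CROSSING_THRESHOLD = 0.1
TAU_VALIDITY_FRACTION = 0.1
MIN_SEGMENT_FRAMES = 50
ACF_MAX_LAG_FRACTION = 0.5
_VAR_TINY = 1e-30


def autocorrelation(values: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Normalized autocorrelation C(0..max_lag) of a gap-free series.

    The lag-tau covariance is averaged over the n - tau available pairs and
    divided by the full-series variance, so C(0) = 1 exactly.  Because of
    the per-lag pair normalization |C| can marginally exceed 1 at large
    lags; lags above n/2 are never used by default.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ConfigurationError("autocorrelation requires a 1-D series, n >= 2")
    n = len(x)
    if max_lag is None:
        max_lag = n // 2
    max_lag = int(min(max_lag, n - 1))
    xc = x - x.mean()
    var = float(np.mean(xc * xc))
    if var <= _VAR_TINY:
        raise DegenerateSeriesError("series has zero variance")
    # FFT-based sum_t xc[t] * xc[t+tau]; exact up to float rounding.
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    sums = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    pairs = n - np.arange(max_lag + 1)
    return (sums / pairs) / var


def split_segments(series: GappedSeries, min_length: int = MIN_SEGMENT_FRAMES):
    """Maximal gap-free runs of a series; runs shorter than ``min_length``
    are dropped.  Returns (segments, n_dropped_short)."""
    mask = series.defined_mask.astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
    starts, ends = edges[0::2], edges[1::2]
    segments, dropped = [], 0
    for s, e in zip(starts, ends):
        if e - s >= max(min_length, 2):
            segments.append(Segment(int(s), int(e), series.values[s:e],
                                    series.dt))
        else:
            dropped += 1
    return segments, dropped


def relaxation_time(
    c: np.ndarray,
    dt: float,
    threshold: float = CROSSING_THRESHOLD,
) -> float:
    """Truncated-integral relaxation time (ps) of an ACF sequence.

    Returns NaN (invalid) when the normalized ACF never reaches the
    threshold within the sequence.
    """
    c = np.asarray(c, dtype=np.float64)
    if len(c) < 2 or not c[0] > 0:
        raise ConfigurationError("ACF must have C(0) > 0 and length >= 2")
    cn = c / c[0]
    below = np.flatnonzero(cn <= threshold)
    if len(below) == 0:
        return float("nan")
    k = int(below[0])
    if k == 0:  # C(0)=1 > threshold always; defensive
        return 0.0
    # Linear interpolation of the crossing inside [k-1, k].
    frac = (cn[k - 1] - threshold) / (cn[k - 1] - cn[k])
    t_cross = dt * (k - 1 + frac)
    integral = float(np.trapezoid(cn[:k], dx=dt))
    integral += 0.5 * (cn[k - 1] + threshold) * (t_cross - dt * (k - 1))
    return integral


@dataclass
class RelaxationResult:
    """Segment-level and residue-mean relaxation times for one series."""

    residue: int
    quantity: str
    segment_taus: list[float] = field(default_factory=list)
    valid: list[bool] = field(default_factory=list)
    n_dropped_short: int = 0
    n_no_crossing: int = 0
    n_filtered: int = 0  # taus exceeding 10% of segment duration
    n_degenerate: int = 0

    @property
    def n_valid(self) -> int:
        return sum(self.valid)

    @property
    def residue_tau(self) -> float:
        taus = [t for t, v in zip(self.segment_taus, self.valid) if v]
        return float(np.mean(taus)) if taus else float("nan")


def residue_relaxation(
    series: GappedSeries,
    min_length: int = MIN_SEGMENT_FRAMES,
    threshold: float = CROSSING_THRESHOLD,
    validity_fraction: float = TAU_VALIDITY_FRACTION,
    max_lag_fraction: float = ACF_MAX_LAG_FRACTION,
) -> RelaxationResult:
    """Segment-wise relaxation-time estimate with the 10%-of-segment filter."""
    segments, dropped = split_segments(series, min_length)
    result = RelaxationResult(series.residue, series.quantity,
                              n_dropped_short=dropped)
    for seg in segments:
        try:
            c = autocorrelation(seg.values,
                                max_lag=int(len(seg) * max_lag_fraction))
        except DegenerateSeriesError:
            result.n_degenerate += 1
            continue
        tau = relaxation_time(c, seg.dt, threshold)
        if np.isnan(tau):
            result.n_no_crossing += 1
            result.segment_taus.append(tau)
            result.valid.append(False)
            continue
        ok = tau <= validity_fraction * seg.duration
        if not ok:
            result.n_filtered += 1
        result.segment_taus.append(tau)
        result.valid.append(bool(ok))
    return result


def order_velocity(series: GappedSeries, delta_t: float) -> np.ndarray:
    """Finite-difference rate of change v = (x(t+dt) - x(t)) / dt (A/ps).

    ``delta_t`` must be an integer multiple of the series spacing; windows
    containing any undefined entry are skipped.
    """
    ratio = delta_t / series.dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ConfigurationError(
            f"delta_t={delta_t} is not an integer multiple of dt={series.dt}"
        )
    v = series.values
    if len(v) <= k:
        return np.empty(0)
    ok = series.defined_mask
    # Window [i, i+k] fully defined <=> running sum of mask equals k+1.
    csum = np.concatenate(([0], np.cumsum(ok)))
    full = (csum[k + 1:] - csum[:-k - 1]) == k + 1
    idx = np.flatnonzero(full)
    return (v[idx + k] - v[idx]) / delta_t


def distribution_halfwidth(
    samples: np.ndarray,
    bin_width: float = 0.1,
) -> float:
    """Full width at half maximum of a histogram density.

    The half-height crossings on either flank are located by linear
    interpolation between bin centers; with multimodal flanks the
    outermost crossings are used.
    """
    x = np.asarray(samples, dtype=np.float64)
    x = x[np.isfinite(x)]
    if len(x) < 100:
        raise ConfigurationError("halfwidth requires at least 100 samples")
    lo, hi = x.min(), x.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    dens, edges = np.histogram(x, bins=n_bins,
                               range=(lo, lo + n_bins * bin_width),
                               density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # Zero-padding guarantees a crossing on both flanks.
    dens = np.concatenate(([0.0], dens, [0.0]))
    centers = np.concatenate(
        ([centers[0] - bin_width], centers, [centers[-1] + bin_width])
    )
    half = dens.max() / 2.0
    above = np.flatnonzero(dens >= half)
    l, r = above[0], above[-1]
    left = centers[l - 1] + (centers[l] - centers[l - 1]) * (
        (half - dens[l - 1]) / (dens[l] - dens[l - 1])
    )
    right = centers[r] + (centers[r + 1] - centers[r]) * (
        (dens[r] - half) / (dens[r] - dens[r + 1])
    )
    return float(right - left)
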