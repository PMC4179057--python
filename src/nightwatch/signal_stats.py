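"""Windowed load-cell statistics and Otsu threshold estimation.

The load cell under a bed leg reports a signed ADC readout at a nominal
80 Hz; dividing by the voltage-to-weight ratio (default -41943.0 counts
per kg) converts it to kilograms.  Bed occupancy shows up in two window
statistics over the most recent 40 samples (half a second): the median
weight m_w jumps by the body weight resting on the leg, and the standard
deviation sigma_w picks up voluntary and involuntary body movements that
an empty (or statically loaded) bed does not produce.

Per-resident decision thresholds on each statistic are found with Otsu's
method: the value distribution is histogrammed and the cut maximizing the
between-class variance sigma_B^2(t) = w0 w1 (mu0 - mu1)^2 separates the
occupied and empty clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: ADC counts per kilogram for the reference load-cell amplifier.
VOLTAGE_WEIGHT_RATIO = -41943.0

#: Window length in samples; 40 samples at 80 Hz is half a second.
DEFAULT_WINDOW = 40


class DegenerateDistributionError(ValueError):
    """Raised when a threshold is requested on a constant input."""


@dataclass(frozen=True)
class WindowStats:
    """Summary of one window of the weight signal (all in kg)."""

    m_w: float          # median weight
    mean_w: float       # mean weight
    sigma_w: float      # population standard deviation
    window_end_ts: float = 0.0   # seconds from night start
    n: int = DEFAULT_WINDOW


def adc_to_weight(adc_out: float, ratio: float = VOLTAGE_WEIGHT_RATIO) -> float:
    """Convert an ADC readout to kilograms: ``adc_out / ratio``."""
    if ratio == 0:
        raise ValueError("voltage-weight ratio must be nonzero")
    return adc_out / ratio


def window_stats(
    samples, n: int = DEFAULT_WINDOW, window_end_ts: float = 0.0
) -> WindowStats:
    """Median, mean and population std of exactly ``n`` weight samples."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ValueError(f"expected exactly {n} samples, got shape {arr.shape}")
    return WindowStats(
        m_w=float(np.median(arr)),
        mean_w=float(arr.mean()),
        sigma_w=float(arr.std()),  # ddof=0: fixed-size signal window
        window_end_ts=window_end_ts,
        n=n,
    )


def rolling_window_stats(weights: np.ndarray, n: int = DEFAULT_WINDOW):
    """Per-window statistics over consecutive non-overlapping windows.

    Vectorized equivalent of calling :func:`window_stats` on each full
    block of ``n`` samples (trailing partial block dropped).  Returns
    ``(m_w, mean_w, sigma_w)`` arrays, one entry per window.
    """
    weights = np.asarray(weights, dtype=float)
    k = weights.size // n
    if k == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    blocks = weights[: k * n].reshape(k, n)
    return (
        np.median(blocks, axis=1),
        blocks.mean(axis=1),
        blocks.std(axis=1),
    )


def _binned(values: np.ndarray, n_bins: int):
    lo = values.min()
    hi = values.max()
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return hist.astype(float), edges


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Otsu's threshold on a 1-D value distribution.

    The values are histogrammed into ``n_bins`` uniform bins over
    ``[min, max]`` and every boundary between adjacent bins is scored by
    the between-class variance of the two induced clusters; the boundary
    with the highest score wins (ties broken toward the smaller
    threshold).  Raises :class:`DegenerateDistributionError` when the
    input has fewer than two distinct values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or np.ptp(v) == 0:
        raise DegenerateDistributionError(
            "Otsu threshold needs at least two distinct values"
        )
    hist, edges = _binned(v, n_bins)
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    omega0 = np.cumsum(p)[:-1]          # class 0 = bins up to the boundary
    omega1 = 1.0 - omega0
    cum_mean = np.cumsum(p * centers)[:-1]
    mu_total = float(np.sum(p * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - cum_mean) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))  # argmax takes the first max: smaller threshold
    return float(edges[k + 1])


def between_class_variance(values, threshold: float) -> float:
    """sigma_B^2 = w0 w1 (mu0 - mu1)^2 for the split ``values <= threshold``."""
    v = np.asarray(values, dtype=float).ravel()
    left = v <= threshold
    n0 = left.sum()
    n1 = v.size - n0
    if n0 == 0 or n1 == 0:
        return 0.0
    w0 = n0 / v.size
    w1 = n1 / v.size
    return float(w0 * w1 * (v[left].mean() - v[~left].mean()) ** 2)


def separability(values, threshold: float) -> float:
    """Otsu's effectiveness measure eta = sigma_B^2 / sigma_T^2 in [0, 1].

    Near 1 for well-separated bimodal data; a single Gaussian cluster
    cannot exceed ~0.64 at any cut.  Used to reject degenerate
    calibrations.
    """
    v = np.asarray(values, dtype=float).ravel()
    total = float(v.var())
    if total == 0:
        return 0.0
    return between_class_variance(v, threshold) / total
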