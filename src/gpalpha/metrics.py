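"""Alpha-band biomarkers extracted from power spectra.

Two alpha summaries are used throughout: mean power over the canonical
7-14 Hz band, and mean power in a ±2.5 Hz window centered on the individual
alpha peak frequency (taken from the fitted Gaussian peaks when one lies in
the band, otherwise from the largest local maximum of the periodic spectrum).
Band power is the trapezoidal integral divided by the band width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import PowerSpectrum, SpectralFit

CANONICAL_ALPHA = (7.0, 14.0)
PEAK_HALF_WIDTH = 2.5


@dataclass
class AlphaMetrics:
    source: tuple | str | None
    spectrum_kind: str
    canonical_alpha: float
    peak_freq: float | None
    peak_alpha: float | None


def band_power(spec: PowerSpectrum, lo: float, hi: float) -> float:
    """Average power over [lo, hi]: trapezoidal integral / band width."""
    if lo >= hi:
        raise ValueError("band bounds must satisfy lo < hi")
    if spec.freqs[0] > lo or spec.freqs[-1] < hi:
        raise ValueError(f"band {lo}-{hi} Hz outside the spectrum grid")
    # include the exact band edges by interpolating onto them
    inner = (spec.freqs > lo) & (spec.freqs < hi)
    f = np.concatenate([[lo], spec.freqs[inner], [hi]])
    p = np.interp(f, spec.freqs, spec.power)
    return float(np.trapezoid(p, f) / (hi - lo))


def individual_alpha_peak(
    fit: SpectralFit | None,
    periodic: PowerSpectrum,
    band: tuple[float, float] = CANONICAL_ALPHA,
) -> float | None:
    """Individual alpha peak frequency, or None when no peak exists.

    Prefers the largest-amplitude fitted Gaussian whose center lies in the
    band; falls back to the largest interior local maximum of the periodic
    spectrum; returns None when neither exists.
    """
    lo, hi = band
    if fit is not None and fit.peaks.size:
        in_band = fit.peaks[(fit.peaks[:, 1] >= lo) & (fit.peaks[:, 1] <= hi)]
        if in_band.size:
            return float(in_band[np.argmax(in_band[:, 0]), 1])
    m = (periodic.freqs >= lo) & (periodic.freqs <= hi)
    f, p = periodic.freqs[m], periodic.power[m]
    if p.size < 3:
        return None
    interior = np.flatnonzero((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:])) + 1
    if interior.size == 0:
        return None
    return float(f[interior[np.argmax(p[interior])]])


def peak_alpha_power(spec: PowerSpectrum, peak: float | None,
                     half_width: float = PEAK_HALF_WIDTH) -> float:
    """Mean power in a ±2.5 Hz window around the individual peak.

    The window is clipped to the spectrum grid when it overruns an edge.
    """
    if peak is None:
        raise ValueError("no alpha peak; use the canonical band instead")
    lo = max(peak - half_width, float(spec.freqs[0]))
    hi = min(peak + half_width, float(spec.freqs[-1]))
    return band_power(spec, lo, hi)


def hemisphere_summary(values: list[float], strategy: str = "max_pair") -> float:
    """Summarize the bipolar pairs of one hemisphere.

    ``max_pair`` keeps the pair with the highest alpha power; ``mean_pairs``
    averages across pairs.
    """
    if not values:
        raise ValueError("no pair metrics to summarize")
    if strategy == "max_pair":
        return float(np.max(values))
    if strategy == "mean_pairs":
        return float(np.mean(values))
    raise ValueError(f"unknown strategy {strategy!r}")


def minmax_normalize(values: np.ndarray | list[float]) -> tuple[np.ndarray, bool]:
    """Min-max normalize one lead's contact estimates to [0, 1].

    Returns (normalized, degenerate); a lead with identical values maps to
    all zeros with ``degenerate=True`` instead of erroring, so cohort runs
    survive flat leads.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to normalize")
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v), True
    return (v - v.min()) / span, False
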