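"""Power spectra and periodic/aperiodic decomposition.

Spectra are estimated with Welch's method (1-s Hann windows, 50% overlap,
FFT zero-padded to twice the window so a 1-s window yields 0.5 Hz bins;
windows touching a reconstructed gap are skipped).  Log-power spectra are then
decomposed into an aperiodic Lorentzian-with-knee background

    L(f) = A * (f_k^chi + f_min^chi) / (f_k^chi + f^chi)

plus a sum of Gaussian peaks in log10-power units,

    log10 P(f) = log10 L(f) + sum_n a_n * exp(-(f - fc_n)^2 / (2 w_n^2)).

``A`` is the power at the minimal reliable frequency ``f_min`` (1 Hz here),
``f_k`` the knee frequency (for f_k >> f_min the frequency where power has
decayed to A/2), and ``chi`` the high-frequency log-log slope.  Absence of a
knee is encoded by the fit converging to ``f_k < f_min``; no model-selection
step between knee and no-knee variants is needed.  A regularization term
penalizes the mass of Gaussians leaking into negative frequencies
(weight ``lambda`` = 100), keeping low-frequency peaks identifiable.  Line
noise at 60 Hz is absorbed as an ordinary Gaussian peak rather than notch
filtered, because notches distort the spectrum the model must fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.special import ndtr

from .io import Recording

logger = logging.getLogger("gpalpha")


# ---------------------------------------------------------------------------
# power spectra

@dataclass
class PowerSpectrum:
    """A one-sided power spectrum on a uniform frequency grid.

    ``kind`` is one of ``absolute`` (µV²/Hz), ``relative`` (% of 3-100 Hz
    total) or ``periodic`` (log10-power residual above the aperiodic fit).
    """

    freqs: np.ndarray
    power: np.ndarray
    kind: str = "absolute"
    source: tuple | str | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if self.freqs.size >= 2:
            df = np.diff(self.freqs)
            if np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-6):
                raise ValueError("frequency grid must be strictly increasing and uniform")
        if self.kind not in ("absolute", "relative", "periodic"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band(self, lo: float, hi: float) -> "PowerSpectrum":
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return PowerSpectrum(self.freqs[m], self.power[m], self.kind, self.source)


def welch_psd(rec: Recording, window_s: float = 1.0, pad_factor: int = 2) -> PowerSpectrum:
    """Welch PSD with Hann windows, 50% overlap and gap-aware window skipping.

    Windows containing any reconstructed (gap) sample are excluded; fewer than
    three clean windows is an error.  The FFT is zero-padded by ``pad_factor``
    so 1-s windows realize 0.5 Hz bins.
    """
    nperseg = int(round(rec.fs * window_s))
    if rec.samples.size < 2 * nperseg:
        raise ValueError("recording too short for spectral estimation")
    hop = nperseg // 2
    nfft = pad_factor * nperseg
    win = signal.windows.hann(nperseg, sym=False)
    scale = 1.0 / (rec.fs * (win**2).sum())

    segments = []
    for start in range(0, rec.samples.size - nperseg + 1, hop):
        if rec.gap_mask[start:start + nperseg].any():
            continue
        seg = rec.samples[start:start + nperseg]
        segments.append(seg - seg.mean())
    if len(segments) < 3:
        raise ValueError("insufficient clean data")

    spec = np.fft.rfft(np.asarray(segments) * win, n=nfft, axis=1)
    psd = (spec.real**2 + spec.imag**2) * scale
    psd[:, 1:-1] *= 2.0  # one-sided density; DC and Nyquist are not doubled
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)
    return PowerSpectrum(freqs, psd.mean(axis=0), "absolute", rec.key())


def average_session_psd(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Arithmetic mean of repeated snippets' spectra (per bin)."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.freqs.shape != first.freqs.shape or not np.allclose(s.freqs, first.freqs):
            raise ValueError("mismatched frequency grids")
        if s.kind != first.kind:
            raise ValueError("mismatched spectrum kinds")
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(first.freqs.copy(), power, first.kind, first.source)


def relative_spectrum(psd: PowerSpectrum, lo: float = 3.0, hi: float = 100.0) -> PowerSpectrum:
    """Normalize an absolute spectrum to percent of its 3-100 Hz total."""
    if psd.kind != "absolute":
        raise ValueError("relative_spectrum expects an absolute spectrum")
    if psd.freqs[0] > lo or psd.freqs[-1] < hi:
        raise ValueError(f"grid must cover {lo}-{hi} Hz")
    m = (psd.freqs >= lo) & (psd.freqs <= hi)
    total = psd.power[m].sum()
    if total <= 0:
        raise ValueError("zero total power in normalization range")
    return PowerSpectrum(psd.freqs.copy(), 100.0 * psd.power / total, "relative", psd.source)


# ---------------------------------------------------------------------------
# spectral parameterization

@dataclass
class SpecparamSettings:
    """Settings of the periodic/aperiodic decomposition."""

    fit_range: tuple[float, float] = (1.0, 65.0)
    peak_width_limits: tuple[float, float] = (1.0, 15.0)  # bounds on w_n (Hz)
    max_n_peaks: int = 8
    min_peak_height: float = 0.1  # log10 units
    peak_threshold: float = 2.0   # multiples of the flattened-spectrum SD
    f_min: float = 1.0
    lam: float = 100.0            # negative-frequency mass penalty weight
    # optimizer bounds keeping the aperiodic fit in the physical regime while
    # still allowing f_k < f_min to encode "no knee"
    exponent_bounds: tuple[float, float] = (-1.0, 4.0)
    knee_bounds_hz: tuple[float, float] = (0.01, 65.0)


@dataclass
class SpectralFit:
    """Fitted aperiodic parameters, Gaussian peaks and diagnostics.

    ``peaks`` is an (n, 3) array of (a_n, fc_n, w_n): log10-power amplitude,
    center frequency (Hz) and Gaussian standard deviation (Hz).
    """

    offset: float          # A: power at f_min (linear units)
    knee_hz: float         # f_k
    exponent: float        # chi
    f_min: float
    peaks: np.ndarray
    r_squared: float
    error: np.ndarray      # per-bin |log10 P - model|
    freqs: np.ndarray      # fit-range grid
    settings: SpecparamSettings = field(default_factory=SpecparamSettings)
    converged: bool = True

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.shape[0])

    def aperiodic(self, f: np.ndarray) -> np.ndarray:
        return aperiodic_model(f, self.offset, self.knee_hz, self.exponent, self.f_min)

    def model_log10(self, f: np.ndarray) -> np.ndarray:
        out = np.log10(self.aperiodic(f))
        for a, fc, w in self.peaks:
            out = out + a * np.exp(-((f - fc) ** 2) / (2 * w**2))
        return out


class FitError(RuntimeError):
    """Raised on non-convergence; carries the best iterate in ``.fit``."""

    def __init__(self, message: str, fit: SpectralFit):
        super().__init__(message)
        self.fit = fit


def aperiodic_model(f, A: float, f_k: float, chi: float, f_min: float = 1.0):
    """Lorentzian-with-knee aperiodic background L(f).

    ``L(f_min) = A`` exactly; for ``f_k >> f_min`` the power at ``f_k`` is
    A/2; ``chi`` sets the high-frequency decay.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    if f_min <= 0:
        raise ValueError("f_min must be positive")
    if f_k <= 0:
        raise ValueError("knee frequency must be positive")
    return A * (f_k**chi + f_min**chi) / (f_k**chi + f**chi)


def _gaussians(freqs: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    out = np.zeros_like(freqs)
    for a, fc, w in peaks:
        out += a * np.exp(-((freqs - fc) ** 2) / (2 * w**2))
    return out


def _neg_freq_mass(peaks: np.ndarray) -> np.ndarray:
    """Closed-form integral of each Gaussian over (-inf, 0]."""
    if peaks.size == 0:
        return np.zeros(0)
    a, fc, w = peaks[:, 0], peaks[:, 1], peaks[:, 2]
    return a * w * np.sqrt(2 * np.pi) * ndtr(-fc / w)


def _seed_peaks(freqs: np.ndarray, flat: np.ndarray, st: SpecparamSettings) -> np.ndarray:
    """Iteratively seed Gaussian peaks from the largest residual."""
    flat = flat.copy()
    guesses = []
    w_lo, w_hi = st.peak_width_limits
    while len(guesses) < st.max_n_peaks:
        i = int(np.argmax(flat))
        height = flat[i]
        if height < max(st.min_peak_height, st.peak_threshold * np.std(flat)):
            break
        fc = freqs[i]
        # width from the half-height extent around the maximum
        half = height / 2.0
        li = i
        while li > 0 and flat[li] > half:
            li -= 1
        ri = i
        while ri < flat.size - 1 and flat[ri] > half:
            ri += 1
        fwhm = max(freqs[ri] - freqs[li], freqs[1] - freqs[0])
        w = float(np.clip(fwhm / 2.355, w_lo, w_hi))
        guesses.append((height, fc, w))
        flat -= height * np.exp(-((freqs - fc) ** 2) / (2 * w**2))
    return np.asarray(guesses, dtype=float).reshape(-1, 3)


def fit_specparam(
    psd: PowerSpectrum, settings: SpecparamSettings | None = None
) -> SpectralFit:
    """Decompose an absolute spectrum into aperiodic + Gaussian-peak parts.

    Minimizes squared error of log10 power against the model over the fit
    range plus ``lambda`` times the total Gaussian mass over negative
    frequencies; peaks are seeded iteratively from the largest residual, then
    all parameters are refined jointly.
    """
    st = settings or SpecparamSettings()
    lo, hi = st.fit_range
    if psd.freqs[0] > lo or psd.freqs[-1] < hi:
        raise ValueError(f"grid must cover the fit range {st.fit_range}")
    m = (psd.freqs >= lo) & (psd.freqs <= hi)
    freqs = psd.freqs[m]
    power = psd.power[m]
    if np.any(power <= 0):
        raise ValueError("nonpositive power inside the fit range")
    logp = np.log10(power)

    fmin_chi = lambda chi: 10.0 ** (chi * np.log10(st.f_min)) if st.f_min != 1.0 else 1.0
    logf = np.log10(freqs)

    def ap_log(p):
        log_a, log_fk, chi = p
        fk_chi = 10.0 ** (chi * log_fk)
        return log_a + np.log10(fk_chi + fmin_chi(chi)) - np.log10(
            fk_chi + 10.0 ** (chi * logf))

    ap_bounds_lo = [-15.0, np.log10(st.knee_bounds_hz[0]), st.exponent_bounds[0]]
    ap_bounds_hi = [15.0, np.log10(st.knee_bounds_hz[1]), st.exponent_bounds[1]]

    # --- initial aperiodic fit, then a robust refit on sub-model points
    slope0 = (logp[-1] - logp[0]) / (logf[-1] - logf[0])
    p0 = np.array([logp[0], np.log10(st.f_min) - 0.3,
                   float(np.clip(-slope0, *st.exponent_bounds))])
    p0 = np.clip(p0, ap_bounds_lo, ap_bounds_hi)

    res = optimize.least_squares(lambda p: ap_log(p) - logp, p0,
                                 bounds=(ap_bounds_lo, ap_bounds_hi))
    # robust refit: drop bins sitting clearly above the first fit (peaks),
    # keeping everything at or below it plus the lowest positive residuals
    flat = logp - ap_log(res.x)
    keep = flat <= np.percentile(np.clip(flat, 0, None), 2.5)
    if keep.sum() >= 4:
        res = optimize.least_squares(lambda p: (ap_log(p) - logp)[keep], res.x,
                                     bounds=(ap_bounds_lo, ap_bounds_hi))
    ap_p = res.x

    # --- iterative peak seeding on the flattened spectrum
    flat = logp - ap_log(ap_p)
    guesses = _seed_peaks(freqs, flat, st)
    n_pk = guesses.shape[0]

    # --- joint refinement of aperiodic + peak parameters
    w_lo, w_hi = st.peak_width_limits

    def pack(ap, peaks):
        return np.concatenate([ap, peaks.ravel()])

    def unpack(x):
        return x[:3], x[3:].reshape(-1, 3)

    def full_resid(x):
        ap, peaks = unpack(x)
        model = ap_log(ap) + _gaussians(freqs, peaks)
        resid = model - logp
        if peaks.size:
            pen = np.sqrt(st.lam * np.maximum(_neg_freq_mass(peaks), 0.0))
            resid = np.concatenate([resid, pen])
        return resid

    x0 = pack(ap_p, guesses)
    lo_b = pack(np.asarray(ap_bounds_lo),
                np.tile([0.0, lo, w_lo], (n_pk, 1)).reshape(-1, 3))
    hi_b = pack(np.asarray(ap_bounds_hi),
                np.tile([np.inf, hi, w_hi], (n_pk, 1)).reshape(-1, 3))
    x0 = np.clip(x0, lo_b, hi_b)
    result = optimize.least_squares(full_resid, x0, bounds=(lo_b, hi_b),
                                    max_nfev=400 * (1 + n_pk))
    ap_fit, peaks = unpack(result.x)
    if peaks.size:
        # the joint refit may shrink a seeded peak below the detection floor;
        # such peaks are noise and are not retained
        peaks = peaks[peaks[:, 0] >= st.min_peak_height]
        peaks = peaks[np.argsort(peaks[:, 1])]

    model = ap_log(ap_fit) + _gaussians(freqs, peaks)
    ss_res = float(np.sum((logp - model) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    fit = SpectralFit(
        offset=float(10.0 ** ap_fit[0]),
        knee_hz=float(10.0 ** ap_fit[1]),
        exponent=float(ap_fit[2]),
        f_min=st.f_min,
        peaks=peaks,
        r_squared=r2,
        error=np.abs(logp - model),
        freqs=freqs,
        settings=st,
        converged=bool(result.success),
    )
    if not result.success:
        raise FitError(f"spectral fit did not converge: {result.message}", fit)
    return fit


def periodic_spectrum(psd: PowerSpectrum, fit: SpectralFit) -> PowerSpectrum:
    """log10-power residual above the aperiodic fit, over the fit range."""
    lo, hi = fit.settings.fit_range
    m = (psd.freqs >= lo) & (psd.freqs <= hi)
    freqs = psd.freqs[m]
    if freqs.shape != fit.freqs.shape or not np.allclose(freqs, fit.freqs):
        raise ValueError("spectrum grid does not match the fit grid")
    resid = np.log10(psd.power[m]) - np.log10(fit.aperiodic(freqs))
    return PowerSpectrum(freqs, resid, "periodic", psd.source)


def classify_knee(fit: SpectralFit) -> bool:
    """A knee is present iff the fitted knee frequency exceeds f_min."""
    return fit.knee_hz > fit.f_min


def model_psd(
    freqs: np.ndarray,
    offset: float,
    knee_hz: float,
    exponent: float,
    peaks: np.ndarray | list,
    f_min: float = 1.0,
) -> np.ndarray:
    """Evaluate the generative spectral model in linear power units.

    Frequencies at or below zero get zero power (used when synthesizing time
    series whose DC bin is meaningless).
    """
    freqs = np.asarray(freqs, dtype=float)
    out = np.zeros_like(freqs)
    pos = freqs > 0
    lp = np.log10(aperiodic_model(freqs[pos], offset, knee_hz, exponent, f_min))
    lp += _gaussians(freqs[pos], np.asarray(peaks, dtype=float).reshape(-1, 3))
    out[pos] = 10.0 ** lp
    return out
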