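"""Power spectra, log-log slope fits, fluctuation scaling and consistency checks.

The spectrum of a length-T series s_t is the squared modulus of the
normalized discrete Fourier transform,

    C(f) = (1/T) sum_t s_t exp(-i 2 pi t f / T),      S(f) = |C(f)|^2,

reported at the positive frequencies f = 1 .. floor(T/2) (cycles/sample,
or Hz when a sampling interval is supplied).  No window or detrend is
applied: the transform is raw, and because the DFT basis is orthogonal
the sample mean affects only the DC bin, which is excluded from every
fit.  An optional linear detrend is available for recorded signals.

A power-law spectrum S ~ C f^beta appears as a straight line of slope
beta in log-log coordinates; `fit_slope` reports the signed OLS slope
(so pink noise reports about -1.0).  Plain OLS over linearly spaced
frequency bins concentrates nearly all weight in the top octave of the
band, which badly underestimates exponents that hold over several
decades; pass ``n_log_bins`` to average the spectrum into equal
log-frequency bins first (the neuron-trace and recording pipelines use
12 bins).  `dual_regime_slopes` fits the two regimes below/above a
crossover frequency independently (the split bin belongs to the low
regime).

`rms_fluctuation` measures F(dt), the window-local RMS deviation about
each window's own mean, averaged over non-overlapping windows, and its
scaling exponent alpha; for a power-law signal the theoretical value is
alpha = (1 + |beta|) / 2.  `wiener_khinchin_residual` verifies that the
transform of the circular autocorrelation reproduces the power spectrum
exactly (the discrete, circular form of the Wiener-Khinchin theorem).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .info import SweepResult, detect_rr
from .network import ConditionSpec, WeightMatrix, sample_weights, simulate_batch

__all__ = [
    "PowerSpectrum",
    "SlopeFit",
    "FluctuationScaling",
    "AutocorrFn",
    "power_spectrum",
    "dft_power",
    "average_spectra",
    "fit_slope",
    "dual_regime_slopes",
    "alpha_theo",
    "rms_fluctuation",
    "autocorrelation",
    "wiener_khinchin_residual",
    "neuron_trace_spectrum",
    "low_half_band",
    "high_half_band",
    "spectral_noise_default",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """Positive-frequency power spectrum, possibly trial-averaged."""

    frequencies: np.ndarray
    power: np.ndarray
    n_trials: int
    T: int
    dt: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of log10 S against log10 f over a frequency band."""

    slope: float
    intercept: float
    band: tuple[float, float]
    r_squared: float
    n_points: int
    n_zero_excluded: int = 0


@dataclass(frozen=True)
class FluctuationScaling:
    """Window-local RMS fluctuation F(dt) and its scaling exponent."""

    window_sizes: np.ndarray
    F_values: np.ndarray
    alpha_fit: float


@dataclass(frozen=True)
class AutocorrFn:
    lags: np.ndarray
    values: np.ndarray


def dft_power(series: np.ndarray) -> np.ndarray:
    """All-T-bin power |C(f)|^2 (DC included), Eq-normalized by 1/T.

    Satisfies the Parseval identity sum_f S(f) = (1/T) sum_t s_t^2.
    """
    s = np.asarray(series, dtype=float)
    c = np.fft.fft(s) / len(s)
    return np.abs(c) ** 2


def power_spectrum(series: np.ndarray, sampling_interval: float | None = None,
                   detrend: bool = False) -> PowerSpectrum:
    """Raw periodogram at the positive frequencies 1..floor(T/2)."""
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) < 8:
        raise ValueError("series must be one-dimensional with T >= 8")
    if not np.all(np.isfinite(s)):
        raise ValueError("series contains non-finite samples")
    if detrend:
        t = np.arange(len(s), dtype=float)
        s = s - np.polyval(np.polyfit(t, s, 1), t)
    T = len(s)
    half = T // 2
    S = dft_power(s)[1:half + 1]
    k = np.arange(1, half + 1, dtype=float)
    freqs = k / (T * sampling_interval) if sampling_interval else k / T
    return PowerSpectrum(frequencies=freqs, power=S, n_trials=1, T=T,
                         dt=sampling_interval)


def average_spectra(spectra) -> PowerSpectrum:
    """Pointwise mean power over spectra on identical frequency grids."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].frequencies
    for sp in spectra[1:]:
        if len(sp.frequencies) != len(f0) or not np.allclose(sp.frequencies, f0):
            raise ValueError("frequency grids do not match")
    power = np.mean([sp.power for sp in spectra], axis=0)
    return PowerSpectrum(frequencies=f0.copy(), power=power,
                         n_trials=sum(sp.n_trials for sp in spectra),
                         T=spectra[0].T, dt=spectra[0].dt)


def _ols_loglog(lf: np.ndarray, lS: np.ndarray, band, n_excluded: int) -> SlopeFit:
    slope, intercept = np.polyfit(lf, lS, 1)
    pred = slope * lf + intercept
    ss_res = float(np.sum((lS - pred) ** 2))
    ss_tot = float(np.sum((lS - lS.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SlopeFit(slope=float(slope), intercept=float(intercept),
                    band=(float(band[0]), float(band[1])),
                    r_squared=r2, n_points=len(lf), n_zero_excluded=n_excluded)


def fit_slope(spec: PowerSpectrum, band: tuple[float, float] | None = None,
              n_log_bins: int | None = None) -> SlopeFit:
    """Fit log10 S on log10 f over the band (inclusive).

    Zero-power bins are excluded and counted.  With ``n_log_bins`` the
    in-band spectrum is first averaged into that many equal
    log-frequency bins so every decade carries the same weight.
    """
    f, S = spec.frequencies, spec.power
    if band is None:
        band = (f[0], f[-1])
    sel = (f >= band[0]) & (f <= band[1])
    zero = sel & (S <= 0)
    sel &= S > 0
    if sel.sum() < 3:
        raise ValueError("need at least 3 positive-power bins in the band")
    lf, lS = np.log10(f[sel]), np.log10(S[sel])
    if n_log_bins:
        edges = np.linspace(lf.min(), lf.max() + 1e-12, n_log_bins + 1)
        bx, by = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            m = (lf >= a) & (lf < b)
            if m.any():
                bx.append(lf[m].mean())
                by.append(np.log10(np.mean(10.0 ** lS[m])))
        lf, lS = np.asarray(bx), np.asarray(by)
        if len(lf) < 3:
            raise ValueError("fewer than 3 occupied log bins in the band")
    return _ols_loglog(lf, lS, band, int(zero.sum()))


def dual_regime_slopes(spec: PowerSpectrum, f_split: float = 1e-2,
                       n_log_bins: int | None = None) -> tuple[SlopeFit, SlopeFit]:
    """Independent fits below and above a crossover frequency.

    The split frequency itself belongs to the low regime (f <= f_split).
    """
    f = spec.frequencies
    n_low = int(np.sum(f <= f_split))
    if n_low < 3:
        raise ValueError("low-frequency regime has fewer than 3 bins")
    if len(f) - n_low < 3:
        raise ValueError("high-frequency regime has fewer than 3 bins")
    low = fit_slope(spec, (f[0], f_split), n_log_bins=n_log_bins)
    high = fit_slope(spec, (f[n_low], f[-1]), n_log_bins=n_log_bins)
    return low, high


def alpha_theo(beta: float) -> float:
    """Theoretical RMS-fluctuation exponent (1 + |beta|) / 2."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return (1.0 + abs(float(beta))) / 2.0


def rms_fluctuation(series: np.ndarray, window_sizes) -> FluctuationScaling:
    """F(dt): mean over non-overlapping windows of each window's RMS
    deviation about its own mean; alpha_fit is the OLS slope of
    log F against log dt."""
    v = np.asarray(series, dtype=float)
    v = v - v.mean()
    T = len(v)
    windows = np.asarray(sorted(int(w) for w in window_sizes))
    if np.any(windows < 2):
        raise ValueError("windows must span at least 2 samples")
    if np.any(windows > T // 4):
        raise ValueError(f"largest window {windows.max()} exceeds T/4 = {T // 4}")
    F = np.empty(len(windows))
    for i, w in enumerate(windows):
        k = T // w
        seg = v[: k * w].reshape(k, w)
        F[i] = np.sqrt(((seg - seg.mean(axis=1, keepdims=True)) ** 2)
                       .mean(axis=1)).mean()
    good = F > 0
    if good.sum() < 2:
        raise ValueError("fluctuation is zero on (almost) all windows")
    alpha = float(np.polyfit(np.log10(windows[good]), np.log10(F[good]), 1)[0])
    return FluctuationScaling(window_sizes=windows, F_values=F, alpha_fit=alpha)


def autocorrelation(series: np.ndarray, max_lag: int) -> AutocorrFn:
    """Biased estimator R(tau) = (1/T) sum_t v_t v_{t+tau}, mean removed."""
    v = np.asarray(series, dtype=float)
    T = len(v)
    if max_lag >= T:
        raise ValueError("max_lag must be smaller than the series length")
    v = v - v.mean()
    vals = np.array([np.dot(v[: T - tau], v[tau:]) / T
                     for tau in range(max_lag + 1)])
    return AutocorrFn(lags=np.arange(max_lag + 1), values=vals)


def wiener_khinchin_residual(series: np.ndarray) -> float:
    """Max |DFT(circular autocorrelation)/T - S| on the mean-removed series.

    Identically zero (to round-off) in the discrete circular setting:
    the circular autocorrelation is (1/T) IFFT(|FFT(v)|^2) and its
    forward transform divided by T recovers |FFT(v)/T|^2 bin by bin.
    """
    v = np.asarray(series, dtype=float)
    if len(v) < 8:
        raise ValueError("series too short")
    v = v - v.mean()
    T = len(v)
    S = dft_power(v)
    r_circ = np.fft.ifft(np.abs(np.fft.fft(v)) ** 2).real / T
    S_from_R = np.fft.fft(r_circ).real / T
    return float(np.max(np.abs(S_from_R - S)))


def low_half_band(spec: PowerSpectrum) -> tuple[float, float]:
    """The lower half of the positive-frequency support (f <= Nyquist/2)."""
    return (float(spec.frequencies[0]), float(spec.frequencies[-1]) / 2.0)


def high_half_band(spec: PowerSpectrum) -> tuple[float, float]:
    """The upper half of the positive-frequency support (f > Nyquist/2)."""
    f = spec.frequencies
    above = f[f > f[-1] / 2.0]
    return (float(above[0]), float(f[-1]))


def spectral_noise_default(sweep: SweepResult, W: float, margin: float = 0.05) -> float:
    """Default operating noise for spectral runs of a condition.

    The midpoint of the half-maximum recurrence-resonance region found
    by `detect_rr` — a noise strength squarely inside the RR region.
    When the condition shows no resonance the midpoint of the sweep's
    noise grid is used instead.
    """
    det = detect_rr(sweep, W, margin=margin)
    if det.is_resonant:
        return det.noise_mid
    grid = sweep.noise_grid
    return 0.5 * (grid[0] + grid[-1])


def neuron_trace_spectrum(
    spec_or_weights: ConditionSpec | WeightMatrix,
    W: float,
    r: float,
    T: int,
    n_trials: int,
    neuron: int = 0,
    seed: int | None = None,
    resample_weights: bool = True,
    binary: bool = False,
    threshold: float = 0.0,
) -> PowerSpectrum:
    """Trial-averaged spectrum of one neuron's state time series.

    Each trial starts from fresh random initial values; when a
    `ConditionSpec` is given and ``resample_weights`` is true (the
    default) each trial also draws a fresh weight matrix, so the average
    characterizes the condition as an ensemble of networks.  This
    ensemble average is what produces 1/f scaling under the clustered
    (quantum/diagonal) conditions: each network realization contributes
    a telegraph-like switching process whose rate depends exponentially
    on its own weight draw, and the superposition of such processes with
    rates spread over decades has a 1/f-like spectrum.

    ``binary=True`` transforms the sign-thresholded series instead of
    the raw states.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seeds = (np.random.SeedSequence(seed).generate_state(2 * n_trials, np.uint32)
             & np.uint32(0x7FFFFFFF)).reshape(n_trials, 2)
    if isinstance(spec_or_weights, WeightMatrix) or not resample_weights:
        if isinstance(spec_or_weights, ConditionSpec):
            wstack = sample_weights(spec_or_weights, int(seeds[0][0])).entries
        else:
            wstack = spec_or_weights.entries
    else:
        wstack = np.stack([
            sample_weights(spec_or_weights, int(s)).entries
            for s in seeds[:, 0]
        ])
    traces = simulate_batch(wstack, W, r, T, [int(s) for s in seeds[:, 1]],
                            record=[int(neuron)])[:, :, 0]
    if binary:
        traces = (traces > threshold).astype(float)
    half = T // 2
    S = np.mean(np.abs(np.fft.rfft(traces, axis=1) / T) ** 2, axis=0)[1:half + 1]
    freqs = np.arange(1, half + 1, dtype=float) / T
    return PowerSpectrum(frequencies=freqs, power=S, n_trials=n_trials, T=T)
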