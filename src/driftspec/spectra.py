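"""Spectral estimation and 1/f^alpha slope fitting for windowed gaze signals.

A gaze signal's spectral color summarizes whether it is white (flat power
spectrum, alpha = 0, spiky measurement noise) or colored (power falling with
frequency, alpha > 0, smooth drift-like signal).  The scaling exponent alpha
of the power-law 1/f^alpha is the negative slope of an ordinary least-squares
line fit to log10(power) vs log10(f), with the DC bin excluded; alpha = 2
corresponds to a random walk and to ~6 dB per octave.

Estimators: the rectangular-window periodogram (the workhorse), a DPSS
multitaper estimate (lower variance, used for display-quality amplitude
spectra) and the Lomb-Scargle periodogram (valid for uneven sampling, used to
check that timestamp jitter does not distort the slope estimates).  All three
share one normalization contract: one-sided power density in deg^2/Hz whose
non-DC sum times the bin width equals the variance of the (mean-removed)
window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .errors import DomainError, InvalidConfigError

__all__ = [
    "Spectrum",
    "SlopeFit",
    "periodogram_rect",
    "amplitude_from_power",
    "multitaper_spectrum",
    "lombscargle_spectrum",
    "lombscargle_default_grid",
    "average_spectra",
    "fit_alpha",
    "alpha_to_db_per_octave",
    "compute_isi_jitter",
]

MIN_SAMPLES = 8


@dataclass(frozen=True)
class Spectrum:
    """One-sided spectrum of one channel of one window (or window average)."""

    freqs_hz: np.ndarray
    power: np.ndarray  # density (deg^2/Hz); amplitude (deg/sqrt(Hz)) if kind='amplitude'
    fs_hz: float
    estimator: str  # periodogram | multitaper | lombscargle
    channel: str = "horizontal"
    n_windows_averaged: int = 1
    kind: str = "power"  # power | amplitude

    def __post_init__(self):
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs_hz.shape != self.power.shape:
            raise DomainError("frequency grid and power must have the same shape")


@dataclass(frozen=True)
class SlopeFit:
    """Power-law scaling exponent from a log-log line fit.

    Sign convention: positive alpha means power decreasing with frequency
    (colored signal); alpha ~ 0 is white.
    """

    alpha: float
    intercept: float
    f_lo_hz: float
    f_hi_hz: float
    r_squared: float
    channel: str = "horizontal"
    n_bins: int = 0


def periodogram_rect(window_samples, fs_hz: float, channel: str = "horizontal") -> Spectrum:
    """Rectangular-window periodogram, one-sided power density.

    No detrending or mean removal is applied (the DC bin absorbs the mean and
    is excluded from slope fits).  Parseval contract: sum(power[1:]) * df
    equals the variance of the window to ~1e-9 relative error.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.size < MIN_SAMPLES:
        raise DomainError(f"periodogram needs >= {MIN_SAMPLES} samples, got {x.size}")
    f, p = sps.periodogram(x, fs=fs_hz, window="boxcar", detrend=False,
                           scaling="density")
    return Spectrum(freqs_hz=f, power=p, fs_hz=fs_hz, estimator="periodogram",
                    channel=channel)


def amplitude_from_power(spectrum: Spectrum) -> Spectrum:
    """Elementwise square root of a power spectrum (for display)."""
    if spectrum.kind != "power":
        raise DomainError("input is not a power spectrum")
    if np.any(spectrum.power < 0):
        raise DomainError("power spectrum contains negative values")
    return replace(spectrum, power=np.sqrt(spectrum.power), kind="amplitude")


def multitaper_spectrum(
    window_samples, fs_hz: float, nw: float = 4.0, k: int = 7,
    channel: str = "horizontal",
) -> Spectrum:
    """DPSS multitaper estimate: the mean of k eigenspectra.

    Requires k <= 2*nw - 1 (tapers beyond that leak badly).  Shares the
    periodogram's density normalization, with the usual caveat that tapering
    weights the window interior more than its edges.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.size < MIN_SAMPLES:
        raise DomainError(f"multitaper needs >= {MIN_SAMPLES} samples, got {x.size}")
    if k < 1 or nw <= 0 or k > 2 * nw - 1:
        raise InvalidConfigError("multitaper requires 1 <= k <= 2*nw - 1")
    tapers = sps.windows.dpss(x.size, nw, Kmax=k)
    tapers = np.atleast_2d(tapers)
    specs = []
    f = None
    for taper in tapers:
        f, p = sps.periodogram(x, fs=fs_hz, window=taper, detrend=False,
                               scaling="density")
        specs.append(p)
    return Spectrum(freqs_hz=f, power=np.mean(specs, axis=0), fs_hz=fs_hz,
                    estimator="multitaper", channel=channel)


def lombscargle_default_grid(n_samples: int, fs_hz: float) -> np.ndarray:
    """The even-sampling periodogram grid without DC and Nyquist.

    DC carries no least-squares power and the Nyquist bin is degenerate in
    the Lomb-Scargle normal equations, so both are omitted; the remaining
    bins coincide with the periodogram's, enabling bin-wise comparison.
    """
    f = np.fft.rfftfreq(n_samples, 1.0 / fs_hz)
    if n_samples % 2 == 0:
        return f[1:-1]
    return f[1:]


def lombscargle_spectrum(
    timestamps_ms, values, freqs_hz, fs_hz: Optional[float] = None,
    channel: str = "horizontal",
) -> Spectrum:
    """Lomb-Scargle power density on the requested frequency grid.

    The raw Lomb-Scargle statistic is rescaled by 2/fs so that on evenly
    sampled input it reproduces the rectangular periodogram's one-sided
    density bin for bin.  Values are mean-centred before estimation.
    """
    t = np.asarray(timestamps_ms, dtype=float) / 1000.0
    x = np.asarray(values, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if x.size < MIN_SAMPLES:
        raise DomainError(f"lombscargle needs >= {MIN_SAMPLES} samples, got {x.size}")
    if x.size != t.size:
        raise DomainError("timestamps and values differ in length")
    if np.any(np.diff(t) <= 0):
        raise DomainError("timestamps must be strictly increasing")
    if np.any(freqs_hz <= 0):
        raise DomainError("Lomb-Scargle grid must contain positive frequencies only")
    if fs_hz is None:
        fs_hz = (x.size - 1) / (t[-1] - t[0])
    if np.ptp(x) == 0:
        power = np.zeros_like(freqs_hz)
    else:
        raw = sps.lombscargle(t, x - x.mean(), 2.0 * np.pi * freqs_hz)
        power = raw * 2.0 / fs_hz
    return Spectrum(freqs_hz=freqs_hz, power=power, fs_hz=float(fs_hz),
                    estimator="lombscargle", channel=channel)


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Elementwise mean power across windows (same grid, estimator, channel)."""
    if len(spectra) == 0:
        raise DomainError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.freqs_hz.shape != first.freqs_hz.shape or not np.allclose(
            s.freqs_hz, first.freqs_hz
        ):
            raise DomainError("cannot average spectra on different frequency grids")
        if s.estimator != first.estimator or s.channel != first.channel or s.kind != first.kind:
            raise DomainError("cannot average spectra with mismatched metadata")
    mean_power = np.mean([s.power for s in spectra], axis=0)
    n = sum(s.n_windows_averaged for s in spectra)
    return replace(first, power=mean_power, n_windows_averaged=n)


def fit_alpha(spectrum: Spectrum, f_hi_hz: Optional[float] = None,
              min_bins: int = 4) -> SlopeFit:
    """Fit 1/f^alpha by OLS of log10(power) on log10(f) over (0, f_hi].

    The DC bin is always excluded; zero-power bins are unusable on the log
    scale and are dropped.  ``f_hi_hz`` defaults to the Nyquist frequency
    (the full band); pass 100 for the fixational-eye-movement band, which is
    only meaningful when Nyquist exceeds 100 Hz.
    """
    if spectrum.kind != "power":
        raise DomainError("alpha is fit to the power spectrum, not the amplitude spectrum")
    f = spectrum.freqs_hz
    p = spectrum.power
    if f_hi_hz is None:
        f_hi_hz = spectrum.fs_hz / 2.0
    band = (f > 0) & (f <= f_hi_hz)
    usable = band & (p > 0)
    if not np.any(usable):
        raise DomainError("no positive-power bins in the fit band")
    if np.count_nonzero(usable) < min_bins:
        raise DomainError(
            f"need >= {min_bins} usable bins to fit a slope, got {np.count_nonzero(usable)}"
        )
    lf = np.log10(f[usable])
    lp = np.log10(p[usable])
    slope, intercept = np.polyfit(lf, lp, 1)
    resid = lp - (slope * lf + intercept)
    ss_tot = np.sum((lp - lp.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return SlopeFit(
        alpha=float(-slope),
        intercept=float(intercept),
        f_lo_hz=float(f[usable][0]),
        f_hi_hz=float(f_hi_hz),
        r_squared=float(r2),
        channel=spectrum.channel,
        n_bins=int(np.count_nonzero(usable)),
    )


def alpha_to_db_per_octave(alpha: float) -> float:
    """Power-density decay per frequency doubling: 10 * alpha * log10(2).

    alpha = 2 (a random walk) gives ~6.02 dB/octave.
    """
    if not np.isfinite(alpha):
        raise DomainError("alpha must be finite")
    return 10.0 * alpha * np.log10(2.0)


def compute_isi_jitter(timestamps_ms, nominal_isi_ms: float) -> float:
    """Timestamp jitter as a percentage of the nominal inter-sample interval:
    100 * SD(successive differences) / nominal ISI."""
    t = np.asarray(timestamps_ms, dtype=float)
    if t.size < 3:
        raise DomainError("need >= 3 timestamps to estimate ISI variability")
    if nominal_isi_ms <= 0:
        raise DomainError("nominal ISI must be positive")
    return float(100.0 * np.std(np.diff(t)) / nominal_isi_ms)
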