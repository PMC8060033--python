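"""TCSPC decay data model and phasor transforms.

A TCSPC acquisition records, per pixel or per sample, a histogram of photon
arrival times relative to the laser pulse.  The first-harmonic phasor of such
a histogram,

    g = sum_k c_k cos(w t_k) / sum_k c_k,
    s = sum_k c_k sin(w t_k) / sum_k c_k,      w = 2*pi*harmonic*f_rep,

maps monoexponential decays onto the universal semicircle
(g - 1/2)^2 + s^2 = 1/4 and mixtures onto chords between their component
positions.  Under periodic excitation (photons from preceding pulses wrap
into the observation window) the discrete phasor of a monoexponential decay
matches the continuous-wave closed form

    g = 1 / (1 + (w tau)^2),   s = w tau / (1 + (w tau)^2)

up to binning and window-truncation effects well below 1%.

Angular frequency uses the laser repetition rate (12.5 ns period at 80 MHz),
not the slightly shorter acquisition window; no discretization or IRF
correction is applied, so raw phasors are directly comparable between
calibration and measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import optimize

from .exceptions import EmptyDecayError, InsufficientDataError

__all__ = [
    "AcquisitionParams",
    "DecayHistogram",
    "Phasor",
    "MonoExpFit",
    "phasor_transform",
    "phasor_of_monoexponential",
    "lifetime_from_phasor",
    "PhasorLifetime",
    "fit_monoexponential",
    "noise_gate",
    "estimate_noise_radius",
    "semicircle_distance",
    "phasor_array",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """TCSPC acquisition geometry.

    Defaults describe an 80 MHz two-photon system with 55 ps time bins and a
    12.4 ns observation window (225 bins), IRF FWHM ~80 ps.
    """

    laser_rep_rate: float = 8.0e7  # Hz
    bin_width: float = 5.5e-11  # s
    n_bins: int = 225
    irf_width: float = 8.0e-11  # s, FWHM
    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.laser_rep_rate <= 0:
            raise ValueError("laser_rep_rate must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_bins < 8:
            raise ValueError("n_bins must be at least 8")
        if self.harmonic < 1:
            raise ValueError("harmonic must be a positive integer")
        if self.n_bins * self.bin_width > 1.0 / self.laser_rep_rate + 1e-15:
            raise ValueError(
                "acquisition window exceeds the laser period: "
                f"{self.n_bins * self.bin_width:.3e} s > "
                f"{1.0 / self.laser_rep_rate:.3e} s"
            )

    @property
    def omega(self) -> float:
        """Angular frequency of the analysis harmonic, rad/s."""
        return 2.0 * math.pi * self.harmonic * self.laser_rep_rate

    @property
    def period(self) -> float:
        """Laser pulse period, s."""
        return 1.0 / self.laser_rep_rate

    @property
    def window(self) -> float:
        """Observed time window, s."""
        return self.n_bins * self.bin_width

    def bin_centers(self) -> np.ndarray:
        """Bin centers t_k = (k + 1/2) * bin_width, time zero at the first bin edge."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts over TCSPC time bins (one pixel, object, or sample)."""

    counts: np.ndarray
    params: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size != self.params.n_bins:
            raise ValueError(
                f"counts length {counts.size} != params.n_bins {self.params.n_bins}"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class Phasor:
    """First-harmonic phasor coordinates of a decay, with its photon weight."""

    g: float
    s: float
    weight: float = 1.0

    @property
    def modulus(self) -> float:
        return math.hypot(self.g, self.s)


@dataclass(frozen=True)
class MonoExpFit:
    """Result of fitting F(t) = y0 + A exp(-t/tau) to a decay histogram."""

    tau: float  # s
    amplitude: float  # counts at t = 0
    background: float  # counts per bin
    rss: float
    converged: bool
    tau_se: float = float("nan")


def phasor_array(phasors: Iterable[Phasor] | np.ndarray) -> np.ndarray:
    """Coerce a collection of phasors to an (N, 2) array of (g, s)."""
    if isinstance(phasors, np.ndarray):
        arr = np.atleast_2d(np.asarray(phasors, dtype=float))
        if arr.shape[-1] != 2:
            raise ValueError("phasor array must have shape (N, 2)")
        return arr
    return np.array([(p.g, p.s) for p in phasors], dtype=float).reshape(-1, 2)


def phasor_transform(decay: DecayHistogram) -> Phasor:
    """First-harmonic phasor of a decay histogram.

    Raises
    ------
    EmptyDecayError
        If the histogram contains no photons.
    """
    total = decay.total_photons
    if total <= 0:
        raise EmptyDecayError("cannot compute the phasor of a zero-photon decay")
    t = decay.params.bin_centers()
    w = decay.params.omega
    g = float(np.dot(decay.counts, np.cos(w * t)) / total)
    s = float(np.dot(decay.counts, np.sin(w * t)) / total)
    return Phasor(g=g, s=s, weight=total)


def phasor_of_monoexponential(tau: float, params: AcquisitionParams | None = None) -> Phasor:
    """Closed-form semicircle position of a monoexponential lifetime.

    g = 1/(1 + (w tau)^2), s = w tau/(1 + (w tau)^2); exact for continuous-wave
    periodic excitation, and the analytic oracle for the discrete transform.
    """
    if tau < 0:
        raise ValueError("lifetime must be nonnegative")
    params = params or AcquisitionParams()
    wt = params.omega * tau
    g = 1.0 / (1.0 + wt * wt)
    return Phasor(g=g, s=wt * g, weight=1.0)


def semicircle_distance(p: Phasor) -> float:
    """Distance of a phasor from the universal semicircle |p - (1/2, 0)| = 1/2."""
    return abs(math.hypot(p.g - 0.5, p.s) - 0.5)


@dataclass(frozen=True)
class PhasorLifetime:
    """A monoexponential lifetime read off a phasor position."""

    tau: float  # s
    off_semicircle: float
    reliable: bool  # False when the point is > 0.05 off the semicircle

    def __float__(self) -> float:
        return self.tau


def lifetime_from_phasor(p: Phasor, params: AcquisitionParams | None = None) -> PhasorLifetime:
    """Monoexponential lifetime reading tau = s / (g * omega).

    Meaningful only near the semicircle; the result flags positions more than
    0.05 away from it as unreliable (mixtures, background).
    """
    if p.g <= 0:
        raise ValueError("lifetime undefined for phasors with g <= 0")
    params = params or AcquisitionParams()
    off = semicircle_distance(p)
    return PhasorLifetime(
        tau=p.s / (p.g * params.omega), off_semicircle=off, reliable=off <= 0.05
    )


def _initial_monoexp_guess(
    t: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Initialize (tau, A, y0) by log-linear regression of the background-subtracted tail."""
    n_tail = max(3, y.size // 20)
    y0 = float(np.median(y[-n_tail:]))
    y0 = min(y0, float(y.min()))
    resid = y - y0
    peak = resid.max()
    usable = resid > max(peak * 1e-3, 1e-12)
    if usable.sum() >= 2 and peak > 0:
        slope, intercept = np.polyfit(t[usable], np.log(resid[usable]), 1)
        tau = -1.0 / slope if slope < 0 else t[-1]
        amp = math.exp(intercept)
    else:
        tau = (t[-1] - t[0]) / 3.0
        amp = max(peak, 1.0)
    return max(tau, 1e-13), amp, max(y0, 0.0)


def fit_monoexponential(
    decay: DecayHistogram,
    fit_range: tuple[int, int] | None = None,
    poisson_weights: bool = False,
    max_iterations: int = 2000,
) -> MonoExpFit:
    """Levenberg-Marquardt least-squares fit of F(t) = y0 + A exp(-t/tau).

    Parameters
    ----------
    fit_range
        Optional (start_bin, stop_bin) half-open interval; default is the full
        histogram.
    poisson_weights
        When True, weight residuals by 1/sqrt(max(counts, 1)); default is the
        unweighted fit.

    The fit is flagged non-converged (never clamped) when the optimizer fails
    or the result is degenerate (tau <= 0 or tau > 5x the observation window).
    """
    t_all = decay.params.bin_centers()
    y_all = decay.counts
    if fit_range is not None:
        lo, hi = fit_range
        t, y = t_all[lo:hi], y_all[lo:hi]
    else:
        t, y = t_all, y_all
    if y.sum() <= 0:
        raise EmptyDecayError("cannot fit an all-zero decay")
    if np.count_nonzero(y) < 8:
        raise InsufficientDataError(
            "monoexponential fit requires at least 8 bins with photons"
        )

    p0 = _initial_monoexp_guess(t, y)

    def model(tt: np.ndarray, tau: float, amp: float, y0: float) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            return y0 + amp * np.exp(np.clip(-tt / tau, -700.0, 700.0))

    sigma = np.sqrt(np.maximum(y, 1.0)) if poisson_weights else None
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, sigma=sigma, method="lm", maxfev=max_iterations
        )
        tau, amp, y0 = (float(v) for v in popt)
        tau_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
        ok = True
    except RuntimeError:
        tau, amp, y0 = p0
        tau_se = float("nan")
        ok = False
    resid = y - model(t, tau, amp, y0)
    rss = float(np.dot(resid, resid))
    degenerate = tau <= 0 or tau > 5.0 * decay.params.window or amp < 0
    return MonoExpFit(
        tau=tau,
        amplitude=max(amp, 0.0) if not degenerate else amp,
        background=max(y0, 0.0),
        rss=rss,
        converged=ok and not degenerate,
        tau_se=tau_se,
    )


def noise_gate(
    phasors: Iterable[Phasor] | np.ndarray, radius: float = 0.3
) -> np.ndarray:
    """Boolean keep-mask: True where |p| >= radius (open exclusion disk).

    Detector noise has an effectively infinite lifetime and accumulates around
    the phasor origin; points strictly inside the gate radius are excluded.
    """
    if radius <= 0:
        raise ValueError("gate radius must be positive")
    arr = phasor_array(phasors)
    if arr.size == 0:
        return np.zeros(0, dtype=bool)
    return np.hypot(arr[:, 0], arr[:, 1]) >= radius


def _gaussian_sigma_from_histogram(values: np.ndarray) -> float:
    """Gaussian sigma fitted to the histogram of a sample (falls back to the sample std)."""
    std = float(np.std(values))
    if std == 0.0:
        return 0.0
    n_bins = max(10, int(math.sqrt(values.size)))
    freq, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gauss,
            centers,
            freq,
            p0=(float(freq.max()), float(np.mean(values)), std),
            maxfev=2000,
        )
        sigma = abs(float(popt[2]))
    except RuntimeError:
        sigma = std
    return sigma


_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def estimate_noise_radius(noise_phasors: Iterable[Phasor] | np.ndarray) -> float:
    """Noise-gate radius from a cloud of pure-noise phasors.

    Gaussians are fitted to the g and s marginals independently; with the
    larger of the two sigmas, FWHM = 2 sqrt(2 ln 2) sigma and the returned
    radius is (3/4) FWHM.
    """
    arr = phasor_array(noise_phasors)
    if arr.shape[0] < 100:
        raise InsufficientDataError(
            f"noise-radius estimation needs >= 100 phasors, got {arr.shape[0]}"
        )
    sigma = max(
        _gaussian_sigma_from_histogram(arr[:, 0]),
        _gaussian_sigma_from_histogram(arr[:, 1]),
    )
    return 0.75 * _FWHM_PER_SIGMA * sigma
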