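"""Ratiometric FRET traces and colocalization-contact classification.

Ratiometric analysis tracks the acceptor/donor intensity ratio R over time;
the relative change dR/R over a baseline classifies a cell as a responder
when it exceeds 20%.  Two ratio conventions are supported: the simple
acceptor/donor ratio ch2/ch1 (in vitro confocal convention) and the
spectral-overlap-corrected percentage

    FRET% = 1.2 ch2 / (2.7 ch1 + 2.5 ch2) * 100

used for two-photon in vivo data, whose coefficients fold in the measured
donor bleed-through into the acceptor channel (0.52/0.48) and the detector
sensitivities (0.37 / 0.40); they are stored as configurable constants.

Colocalization analysis bins per-object overlap intensities, fits the
binned frequencies with a biexponential, and thresholds contacts where the
fitted curve decays below 10% of its zero-intensity value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import InsufficientDataError

__all__ = [
    "RatioTrace",
    "ColocModel",
    "DEFAULT_FRET_COEFFICIENTS",
    "ratiometric_fret",
    "delta_r_over_r",
    "DeltaRResult",
    "ColocHistogramModel",
    "ColocHistogramResult",
    "fit_coloc_threshold",
    "classify_contacts",
    "RESPONDER_THRESHOLD",
]

#: dR/R level above which a cell counts as a responder.
RESPONDER_THRESHOLD = 0.20

#: (numerator ch2, denominator ch1, denominator ch2) of the corrected FRET%.
DEFAULT_FRET_COEFFICIENTS = (1.2, 2.7, 2.5)


@dataclass(frozen=True)
class RatioTrace:
    """A two-channel intensity trace (donor ch1, acceptor ch2) over time."""

    time_s: np.ndarray
    ch1: np.ndarray
    ch2: np.ndarray
    events: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        c1 = np.asarray(self.ch1, dtype=float)
        c2 = np.asarray(self.ch2, dtype=float)
        if not (t.shape == c1.shape == c2.shape) or t.ndim != 1:
            raise ValueError("time_s, ch1, ch2 must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(c1 < 0) or np.any(c2 < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "ch1", c1)
        object.__setattr__(self, "ch2", c2)

    def __len__(self) -> int:
        return self.time_s.size


def ratiometric_fret(
    ch1: float | np.ndarray,
    ch2: float | np.ndarray,
    coefficients: tuple[float, float, float] = DEFAULT_FRET_COEFFICIENTS,
) -> float | np.ndarray:
    """Spectral-overlap-corrected FRET percentage of a two-channel sample.

    FRET% = c0 * ch2 / (c1 * ch1 + c2 * ch2) * 100.  Scale-invariant in the
    channel pair; strictly increasing in ch2 at fixed ch1 > 0 and bounded in
    (0, 100 c0/c2] (48% with the default coefficients).
    """
    c0, c1, c2 = coefficients
    ch1_arr = np.asarray(ch1, dtype=float)
    ch2_arr = np.asarray(ch2, dtype=float)
    denom = c1 * ch1_arr + c2 * ch2_arr
    if np.any(denom <= 0):
        raise ValueError("FRET ratio undefined: both channels are zero")
    out = c0 * ch2_arr / denom * 100.0
    return float(out) if np.isscalar(ch1) and np.isscalar(ch2) else out


@dataclass(frozen=True)
class DeltaRResult:
    """dR/R series with its baseline and responder classification."""

    dr_over_r: np.ndarray
    r: np.ndarray
    r0: float
    responder: bool
    threshold: float = RESPONDER_THRESHOLD


def delta_r_over_r(
    trace: RatioTrace,
    baseline: Literal["pre_stimulus", "minimum"],
    convention: Literal["ratio", "fret_percent"] = "ratio",
    threshold: float = RESPONDER_THRESHOLD,
    coefficients: tuple[float, float, float] = DEFAULT_FRET_COEFFICIENTS,
) -> DeltaRResult:
    """Relative FRET-ratio change dR/R = (R - R0)/R0 with responder flag.

    `baseline` must be chosen per dataset: 'pre_stimulus' averages R before
    the first stimulus event (in vitro convention, requires at least one
    pre-event sample), 'minimum' uses the trace minimum (in vivo convention).
    `convention` selects R = ch2/ch1 ('ratio') or the corrected FRET
    percentage ('fret_percent').  A trace is a responder when max dR/R
    reaches `threshold` (20% by default).
    """
    if len(trace) < 3:
        raise InsufficientDataError("dR/R analysis requires at least 3 samples")
    if convention == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            r = trace.ch2 / trace.ch1
        if np.any(~np.isfinite(r)):
            raise ValueError("simple ratio undefined where ch1 = 0")
    elif convention == "fret_percent":
        r = np.asarray(ratiometric_fret(trace.ch1, trace.ch2, coefficients))
    else:
        raise ValueError(f"unknown ratio convention {convention!r}")

    if baseline == "pre_stimulus":
        if not trace.events:
            raise ValueError("pre_stimulus baseline requires stimulus events")
        pre = trace.time_s < min(trace.events)
        if not np.any(pre):
            raise InsufficientDataError("no samples before the first stimulus event")
        r0 = float(r[pre].mean())
    elif baseline == "minimum":
        r0 = float(r.min())
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if r0 == 0:
        raise ValueError("baseline ratio is zero; dR/R undefined")
    dr = (r - r0) / r0
    return DeltaRResult(
        dr_over_r=dr,
        r=r,
        r0=r0,
        responder=bool(dr.max() >= threshold),
        threshold=threshold,
    )


@dataclass(frozen=True)
class ColocModel:
    """Biexponential model of a colocalization-intensity histogram.

    f(x) = a1 exp(-x/lambda1) + a2 exp(-x/lambda2); `threshold` is the
    intensity where f drops to `decay_level` (10%) of f(0).
    """

    a1: float
    lambda1: float
    a2: float
    lambda2: float
    bin_width: float = 20.0
    threshold: float | None = None
    decay_level: float = 0.10

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("decay constants must be positive")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be nonnegative")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        xx = np.asarray(x, dtype=float)
        out = self.a1 * np.exp(-xx / self.lambda1) + self.a2 * np.exp(-xx / self.lambda2)
        return float(out) if np.isscalar(x) else out


def _threshold_from_curve(model: ColocModel, decay_level: float) -> float:
    """Smallest x >= 0 with f(x)/f(0) <= decay_level, by bisection on the fit."""
    f0 = model(0.0)
    if f0 <= 0:
        raise ValueError("degenerate fit: f(0) = 0")
    target = decay_level * f0
    hi = 10.0 * max(model.lambda1, model.lambda2)
    if model(hi) > target:
        raise ValueError("fitted curve never decays to the threshold level")
    return float(optimize.brentq(lambda x: model(x) - target, 0.0, hi, xtol=1e-9))


class ColocHistogramModel:
    """Biexponential fit of a binned colocalization-intensity histogram."""

    def __init__(
        self,
        intensity_au: Sequence[float] | np.ndarray,
        frequency: Sequence[float] | np.ndarray,
        bin_width: float = 20.0,
        decay_level: float = 0.10,
    ) -> None:
        x = np.asarray(intensity_au, dtype=float)
        y = np.asarray(frequency, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("intensity_au and frequency must be 1-D, equal length")
        if np.count_nonzero(y) < 6:
            raise InsufficientDataError(
                "biexponential fit requires >= 6 nonzero histogram bins"
            )
        self.x, self.y = x, y
        self.bin_width = bin_width
        self.decay_level = decay_level

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "ColocHistogramModel":
        return cls(df["intensity_au"].to_numpy(), df["frequency"].to_numpy(), **kwargs)

    def fit(self) -> "ColocHistogramResult":
        x, y = self.x, self.y
        ymax = float(y.max())
        span = float(x.max() - x.min()) or 1.0

        def biexp(xx, a1, l1, a2, l2):
            return a1 * np.exp(-xx / l1) + a2 * np.exp(-xx / l2)

        # two-stage log-linear initialization: tail -> slow component,
        # residual head -> fast component
        p0 = [ymax, max(span / 20.0, 1e-6), ymax / 50.0, span / 2.0]
        tail = y[x >= x.min() + span / 2] > 0
        if tail.sum() >= 2:
            xs, ys = x[x >= x.min() + span / 2][tail], y[x >= x.min() + span / 2][tail]
            slope, icept = np.polyfit(xs, np.log(ys), 1)
            if slope < 0:
                p0[3] = -1.0 / slope
                p0[2] = math.exp(icept)
                resid = y - p0[2] * np.exp(-x / p0[3])
                head = (x <= x.min() + span / 4) & (resid > 0)
                if head.sum() >= 2:
                    slope, icept = np.polyfit(x[head], np.log(resid[head]), 1)
                    if slope < 0:
                        p0[1] = -1.0 / slope
                        p0[0] = math.exp(icept)
        try:
            popt, pcov = optimize.curve_fit(
                biexp,
                x,
                y,
                p0=p0,
                bounds=([0, 1e-12, 0, 1e-12], [np.inf] * 4),
                x_scale="jac",
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise ValueError(f"biexponential fit did not converge: {exc}") from exc
        a1, l1, a2, l2 = (float(v) for v in popt)
        # order components fast-first for stable reporting
        if l1 > l2:
            a1, l1, a2, l2 = a2, l2, a1, l1
        model = ColocModel(
            a1=a1, lambda1=l1, a2=a2, lambda2=l2,
            bin_width=self.bin_width, decay_level=self.decay_level,
        )
        threshold = _threshold_from_curve(model, self.decay_level)
        model = replace(model, threshold=threshold)
        resid = y - model(x)
        perr = (
            np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
        )
        return ColocHistogramResult(
            model=model,
            param_se=tuple(float(v) for v in perr),
            rss=float(np.dot(resid, resid)),
            n_bins=int(x.size),
        )


@dataclass(frozen=True)
class ColocHistogramResult:
    """Fitted biexponential colocalization model with the contact threshold."""

    model: ColocModel
    param_se: tuple[float, float, float, float]
    rss: float
    n_bins: int

    @property
    def threshold(self) -> float:
        return self.model.threshold

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "Colocalization histogram fit",
                "============================",
                f"  a1      {m.a1:12.2f}  (se {self.param_se[0]:.2f})",
                f"  lambda1 {m.lambda1:12.2f}  (se {self.param_se[1]:.2f})",
                f"  a2      {m.a2:12.2f}  (se {self.param_se[2]:.2f})",
                f"  lambda2 {m.lambda2:12.2f}  (se {self.param_se[3]:.2f})",
                f"  {m.decay_level:.0%}-decay threshold  {m.threshold:.1f} AU",
                f"  n bins  {self.n_bins},  rss {self.rss:.4g}",
            ]
        )


def fit_coloc_threshold(
    histogram: pd.DataFrame | tuple[Sequence[float], Sequence[float]],
    bin_width: float = 20.0,
    decay_level: float = 0.10,
) -> ColocModel:
    """Fit the biexponential contact-intensity model and its decay threshold.

    `histogram` is a DataFrame with columns (intensity_au, frequency) or an
    (intensities, frequencies) pair.  Returns the fitted ColocModel with the
    threshold filled in.
    """
    if isinstance(histogram, pd.DataFrame):
        model = ColocHistogramModel.from_frame(
            histogram, bin_width=bin_width, decay_level=decay_level
        )
    else:
        model = ColocHistogramModel(
            histogram[0], histogram[1], bin_width=bin_width, decay_level=decay_level
        )
    return model.fit().model


def classify_contacts(
    intensities: Sequence[float] | np.ndarray,
    lower: float = 1.0,
    upper: float = 150.0,
) -> np.ndarray:
    """Classify per-object colocalization intensities into contact classes.

    intensity < lower: 'none' (not colocalized); lower <= intensity <= upper:
    'transient'; intensity > upper: 'strong'.  The boundaries are inclusive
    for the transient class; `upper` may come from the fitted decay threshold.
    Classes are exhaustive and mutually exclusive.
    """
    x = np.asarray(intensities, dtype=float)
    if np.any(x < 0):
        raise ValueError("colocalization intensities must be nonnegative")
    if not lower <= upper:
        raise ValueError("lower threshold must not exceed upper threshold")
    return np.select([x < lower, x <= upper], ["none", "transient"], default="strong")
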