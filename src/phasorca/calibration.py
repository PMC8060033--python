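"""Biosensor calibration and inversion to absolute calcium.

The donor lifetime of the FRET calcium sensor follows a sigmoid of the free
calcium concentration (Hill form, slope negative because FRET quenching
shortens the lifetime as calcium rises):

    tau(c) = tau_FRET + (tau_free - tau_FRET)
             / (1 + 10^(-(log10 c - log10 Kd) * h)),      h < 0.

Inversion of this sigmoid is the *time-domain pathway* (fit a
monoexponential lifetime, solve for c).  The *phase-domain pathway* uses the
phasor mixture rule: a two-state sensor places every measured phasor on the
chord between the calcium-free endpoint p_free and the calcium-saturated
endpoint p_FRET, at the FRET-species intensity fraction w.  Three inversion
modes from phasor to concentration are provided:

``empirical`` (default)
    Invert a Hill curve fitted to the segment fraction w against the
    titration concentrations.  This is the only reading under which the two
    pathways agree within a few percent across the linear range, because it
    calibrates the phasor axis against the same titration as the sigmoid.
``literal_eq11``
    c = Kd * (eps_free/eps_FRET) * |p - p_free| / |p_FRET - p|, the distance
    ratio formula with the relative-brightness factor
    eps_free/eps_FRET = tau_free/tau_FRET.  Kept verbatim for fidelity; it is
    consistent with the sigmoid only for unit Hill slope.
``hill_generalized``
    c = Kd * [(eps_free/eps_FRET) * d_free/d_FRET]^(-1/h), which reduces to
    the literal formula at h = -1 and to the sigmoid inversion on-segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize

from .decay import (
    AcquisitionParams,
    DecayHistogram,
    Phasor,
    fit_monoexponential,
    noise_gate,
    phasor_array,
    phasor_transform,
)
from .exceptions import (
    ConfigurationError,
    DegenerateTitrationError,
    InsufficientDataError,
    UnstableCalibrationError,
)

__all__ = [
    "HillCalibration",
    "PhasorCalibration",
    "SegmentHill",
    "CalciumEstimate",
    "LifetimeInversion",
    "lifetime_from_calcium",
    "calcium_from_lifetime",
    "HillTitrationModel",
    "HillTitrationResult",
    "fit_hill_titration",
    "build_phasor_calibration",
    "project_fraction",
    "calcium_from_phasor",
    "linear_range",
    "crossvalidate_pathways",
    "DYNAMIC_RANGE_NM",
]

#: Sensor dynamic range in nM (printed constants; the defining saturation
#: convention is not reproducible from the other calibration numbers, so the
#: bounds are kept as configuration values).
DYNAMIC_RANGE_NM: tuple[float, float] = (100.0, 4000.0)

InversionMode = Literal["empirical", "literal_eq11", "hill_generalized"]


@dataclass(frozen=True)
class HillCalibration:
    """Hill-sigmoid titration parameters of the sensor.

    Defaults are the lysate calibration of the TN-XXL construct:
    Kd = 475 nM, Hill slope = -1.43, tau_free = 2312 ps, tau_FRET = 744 ps.
    """

    kd: float = 475.0  # nM
    hill_slope: float = -1.43
    tau_free: float = 2312e-12  # s
    tau_fret: float = 744e-12  # s

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.hill_slope >= 0:
            raise ValueError("hill_slope must be negative")
        if not (self.tau_free > self.tau_fret > 0):
            raise ValueError("lifetimes must satisfy tau_free > tau_fret > 0")

    @property
    def brightness_ratio(self) -> float:
        """Relative donor brightness eps_free/eps_FRET = tau_free/tau_FRET."""
        return self.tau_free / self.tau_fret

    def saturation_fraction(self, ca_nM: float | np.ndarray) -> float | np.ndarray:
        """FRET-species intensity fraction w(c) = (c/Kd)^|h| / (1 + (c/Kd)^|h|)."""
        ca = np.asarray(ca_nM, dtype=float)
        beta = -self.hill_slope
        r = np.power(ca / self.kd, beta)
        with np.errstate(invalid="ignore"):
            out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
        return float(out) if np.isscalar(ca_nM) else out


@dataclass(frozen=True)
class SegmentHill:
    """Hill curve of the phasor segment fraction w against calcium."""

    kd: float  # nM
    hill_slope: float  # negative, mirroring the lifetime convention

    def fraction(self, ca_nM: float | np.ndarray) -> float | np.ndarray:
        ca = np.asarray(ca_nM, dtype=float)
        r = np.power(ca / self.kd, -self.hill_slope)
        out = r / (1.0 + r)
        return float(out) if np.isscalar(ca_nM) else out

    def invert(self, w: float | np.ndarray) -> float | np.ndarray:
        """Calcium (nM) at segment fraction w; 0 at w=0, inf at w=1."""
        w_arr = np.asarray(w, dtype=float)
        beta = -self.hill_slope
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.kd * np.power(w_arr / (1.0 - w_arr), 1.0 / beta)
        out = np.where(w_arr <= 0.0, 0.0, out)
        out = np.where(w_arr >= 1.0, np.inf, out)
        return float(out) if np.isscalar(w) else out


@dataclass(frozen=True)
class PhasorCalibration:
    """Phasor-segment calibration: endpoints, brightness ratio, inversion mode."""

    p_free: Phasor
    p_fret: Phasor
    hill: HillCalibration
    brightness_ratio: float
    segment_hill: SegmentHill | None = None
    inversion_mode: InversionMode = "empirical"
    gate_radius: float = 0.3
    acquisition: AcquisitionParams | None = None

    def __post_init__(self) -> None:
        if (self.p_free.g, self.p_free.s) == (self.p_fret.g, self.p_fret.s):
            raise ValueError("p_free and p_fret must differ")
        if self.brightness_ratio <= 1:
            raise ValueError("brightness_ratio must exceed 1")
        for name, p in (("p_free", self.p_free), ("p_fret", self.p_fret)):
            if p.modulus < self.gate_radius:
                raise ValueError(f"{name} lies inside the noise gate")
        if self.inversion_mode not in ("empirical", "literal_eq11", "hill_generalized"):
            raise ConfigurationError(f"unknown inversion mode {self.inversion_mode!r}")


# ---------------------------------------------------------------------------
# Time-domain pathway
# ---------------------------------------------------------------------------


def lifetime_from_calcium(
    ca_nM: float | np.ndarray, hill: HillCalibration | None = None
) -> float | np.ndarray:
    """Donor lifetime (s) at a free calcium concentration (nM).

    Monotonically decreasing; ca = 0 returns tau_free (the unquenched
    asymptote), ca -> inf approaches tau_FRET.
    """
    hill = hill or HillCalibration()
    ca = np.asarray(ca_nM, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration must be nonnegative")
    pos = ca > 0
    x = np.log10(ca, where=pos, out=np.zeros_like(ca, dtype=float))
    denom = 1.0 + np.power(10.0, -(x - math.log10(hill.kd)) * hill.hill_slope)
    tau = hill.tau_fret + (hill.tau_free - hill.tau_fret) / denom
    tau = np.where(pos, tau, hill.tau_free)
    return float(tau) if np.isscalar(ca_nM) else tau


@dataclass(frozen=True)
class LifetimeInversion:
    """Calcium read from a lifetime; `saturated` marks out-of-range lifetimes."""

    ca_nM: float
    saturated: Literal["low", "high"] | None = None

    def __float__(self) -> float:
        return self.ca_nM


def calcium_from_lifetime(
    tau: float, hill: HillCalibration | None = None
) -> LifetimeInversion:
    """Invert the lifetime sigmoid: exact inverse of :func:`lifetime_from_calcium`.

    Lifetimes at or above tau_free return 0 nM flagged 'low'; lifetimes at or
    below tau_FRET return inf flagged 'high' (saturated sensor), never an
    exception.
    """
    hill = hill or HillCalibration()
    if tau >= hill.tau_free:
        return LifetimeInversion(0.0, "low")
    if tau <= hill.tau_fret:
        return LifetimeInversion(math.inf, "high")
    ratio = (hill.tau_free - hill.tau_fret) / (tau - hill.tau_fret) - 1.0
    log_ca = math.log10(hill.kd) - math.log10(ratio) / hill.hill_slope
    return LifetimeInversion(10.0**log_ca, None)


# ---------------------------------------------------------------------------
# Titration fit (Model / Results)
# ---------------------------------------------------------------------------


class HillTitrationModel:
    """Sigmoid titration model: donor lifetime against log10 free calcium.

    The 0 nM and saturating anchors fix tau_free and tau_FRET (averaging
    replicates); Kd and the Hill slope are then estimated from the
    intermediate points by nonlinear least squares, which stabilizes the fit
    compared with a four-parameter sigmoid.

    Parameters
    ----------
    ca_nM, tau_s
        Paired concentrations (nM) and fitted lifetimes (s).  Must include at
        least one 0 nM point, the saturating anchor and >= 4 intermediates.
    sat_ca_nM
        Concentration of the saturating anchor; defaults to the largest
        concentration present.
    """

    def __init__(
        self,
        ca_nM: Sequence[float] | np.ndarray,
        tau_s: Sequence[float] | np.ndarray,
        sat_ca_nM: float | None = None,
    ) -> None:
        ca = np.asarray(ca_nM, dtype=float)
        tau = np.asarray(tau_s, dtype=float)
        if ca.shape != tau.shape or ca.ndim != 1:
            raise ValueError("ca_nM and tau_s must be 1-D arrays of equal length")
        if np.any(ca < 0):
            raise ValueError("concentrations must be nonnegative")
        self.ca = ca
        self.tau = tau
        self.sat_ca = float(sat_ca_nM) if sat_ca_nM is not None else float(ca.max())
        if not np.any(ca == 0):
            raise InsufficientDataError("titration requires a 0 nM anchor")
        if not np.any(ca == self.sat_ca) or self.sat_ca <= 0:
            raise InsufficientDataError("titration requires a saturating anchor")

    @classmethod
    def from_points(
        cls, points: Iterable[tuple[float, float]], sat_ca_nM: float | None = None
    ) -> "HillTitrationModel":
        pts = list(points)
        return cls([p[0] for p in pts], [p[1] for p in pts], sat_ca_nM=sat_ca_nM)

    def fit(self) -> "HillTitrationResult":
        free_mask = self.ca == 0
        sat_mask = self.ca == self.sat_ca
        mid_mask = ~(free_mask | sat_mask)
        tau_free = float(self.tau[free_mask].mean())
        tau_fret = float(self.tau[sat_mask].mean())
        ca_mid, tau_mid = self.ca[mid_mask], self.tau[mid_mask]
        if ca_mid.size < 4:
            raise InsufficientDataError(
                f"need >= 4 intermediate titration points, got {ca_mid.size}"
            )
        span = (tau_mid.max() - tau_mid.min()) / (tau_free - tau_fret)
        if span < 0.10:
            raise DegenerateTitrationError(
                f"intermediate lifetimes span only {span:.1%} of the sensor range"
            )
        x = np.log10(ca_mid)

        def model(xx: np.ndarray, log_kd: float, slope: float) -> np.ndarray:
            return tau_fret + (tau_free - tau_fret) / (
                1.0 + np.power(10.0, -(xx - log_kd) * slope)
            )

        popt, pcov = optimize.curve_fit(
            model, x, tau_mid, p0=(float(np.median(x)), -1.0), maxfev=5000
        )
        log_kd, slope = (float(v) for v in popt)
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
        kd = 10.0**log_kd
        # delta method: se(kd) = kd ln(10) se(log10 kd)
        kd_se = kd * math.log(10.0) * float(perr[0])
        resid = tau_mid - model(x, *popt)
        cal = HillCalibration(
            kd=kd, hill_slope=slope, tau_free=tau_free, tau_fret=tau_fret
        )
        return HillTitrationResult(
            calibration=cal,
            kd_se=kd_se,
            slope_se=float(perr[1]),
            rss=float(np.dot(resid, resid)),
            n_points=int(ca_mid.size),
            model=self,
        )


@dataclass(frozen=True)
class HillTitrationResult:
    """Fitted titration calibration with parameter uncertainties."""

    calibration: HillCalibration
    kd_se: float
    slope_se: float
    rss: float
    n_points: int
    model: HillTitrationModel = field(repr=False, compare=False, default=None)

    def summary(self) -> str:
        c = self.calibration
        lines = [
            "Hill titration fit",
            "==================",
            f"  Kd          {c.kd:10.1f} nM   (se {self.kd_se:.1f})",
            f"  Hill slope  {c.hill_slope:10.3f}      (se {self.slope_se:.3f})",
            f"  tau_free    {c.tau_free * 1e12:10.1f} ps   (anchor, fixed)",
            f"  tau_FRET    {c.tau_fret * 1e12:10.1f} ps   (anchor, fixed)",
            f"  n intermediate points  {self.n_points}",
            f"  residual sum of squares  {self.rss:.4g}",
        ]
        return "\n".join(lines)


def fit_hill_titration(
    points: Iterable[tuple[float, float]], sat_ca_nM: float | None = None
) -> HillTitrationResult:
    """Fit the titration sigmoid to (ca_nM, tau_s) pairs (convenience wrapper)."""
    return HillTitrationModel.from_points(points, sat_ca_nM=sat_ca_nM).fit()


# ---------------------------------------------------------------------------
# Phase-domain pathway
# ---------------------------------------------------------------------------


def _project_raw(
    g: np.ndarray, s: np.ndarray, cal: PhasorCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Unclamped signed fraction along p_free -> p_FRET, and off-segment distance."""
    vg = cal.p_fret.g - cal.p_free.g
    vs = cal.p_fret.s - cal.p_free.s
    norm2 = vg * vg + vs * vs
    dg = g - cal.p_free.g
    ds = s - cal.p_free.s
    w = (dg * vg + ds * vs) / norm2
    off = np.hypot(dg - w * vg, ds - w * vs)
    return w, off


def project_fraction(p: Phasor, cal: PhasorCalibration) -> tuple[float, float]:
    """Orthogonal projection of a phasor onto the calibration segment.

    Returns (w, off_segment): w is the FRET-species intensity fraction, the
    signed fractional position along p_free -> p_FRET clamped to [0, 1];
    off_segment is the perpendicular distance from the segment line.
    """
    w, off = _project_raw(np.asarray(p.g), np.asarray(p.s), cal)
    return float(np.clip(w, 0.0, 1.0)), float(off)


def build_phasor_calibration(
    cloud_free: Iterable[Phasor] | np.ndarray,
    cloud_sat: Iterable[Phasor] | np.ndarray,
    hill: HillCalibration,
    centroid: Literal["mean", "median"] = "mean",
    titration_clouds: Mapping[float, Iterable[Phasor] | np.ndarray] | None = None,
    gate_radius: float = 0.3,
    inversion_mode: InversionMode = "empirical",
    acquisition: AcquisitionParams | None = None,
    min_cloud: int = 50,
) -> PhasorCalibration:
    """Build the phasor calibration segment from anchor clouds.

    Endpoints are the chosen centroid (mean or median, coordinate-wise) of the
    noise-gated 0 nM and saturating clouds.  When `titration_clouds` maps
    intermediate concentrations to phasor clouds, a Hill curve is fitted to
    the segment fraction of each cloud centroid, enabling the default
    empirical inversion.

    Raises
    ------
    InsufficientDataError
        If a gated anchor cloud has fewer than `min_cloud` phasors.
    UnstableCalibrationError
        If the endpoints are closer than 3x the larger cloud spread.
    """
    if centroid not in ("mean", "median"):
        raise ConfigurationError(f"unknown centroid {centroid!r}")
    reduce = np.mean if centroid == "mean" else np.median

    def gated_cloud(cloud, name: str) -> np.ndarray:
        arr = phasor_array(cloud)
        kept = arr[noise_gate(arr, gate_radius)]
        if kept.shape[0] < min_cloud:
            raise InsufficientDataError(
                f"{name} cloud has {kept.shape[0]} gated phasors (< {min_cloud})"
            )
        return kept

    free_arr = gated_cloud(cloud_free, "0 nM")
    sat_arr = gated_cloud(cloud_sat, "saturating")
    p_free = Phasor(*(float(reduce(free_arr[:, i])) for i in (0, 1)))
    p_fret = Phasor(*(float(reduce(sat_arr[:, i])) for i in (0, 1)))

    spread = max(
        float(np.std(free_arr, axis=0).max()), float(np.std(sat_arr, axis=0).max())
    )
    dist = math.hypot(p_fret.g - p_free.g, p_fret.s - p_free.s)
    if dist < 3.0 * spread:
        raise UnstableCalibrationError(
            f"anchor clouds overlap: endpoint distance {dist:.3g} < 3 sigma {3 * spread:.3g}"
        )

    cal = PhasorCalibration(
        p_free=p_free,
        p_fret=p_fret,
        hill=hill,
        brightness_ratio=hill.brightness_ratio,
        segment_hill=None,
        inversion_mode=inversion_mode,
        gate_radius=gate_radius,
        acquisition=acquisition,
    )

    if titration_clouds is not None:
        cas, ws = [], []
        for ca, cloud in titration_clouds.items():
            if ca <= 0:
                continue
            arr = phasor_array(cloud)
            cg = float(reduce(arr[:, 0]))
            cs = float(reduce(arr[:, 1]))
            w_raw, _ = _project_raw(np.asarray(cg), np.asarray(cs), cal)
            w_val = float(w_raw)
            if 0.0 < w_val < 1.0:
                cas.append(ca)
                ws.append(w_val)
        if len(cas) < 3:
            raise InsufficientDataError(
                "segment-fraction fit needs >= 3 intermediate clouds with 0 < w < 1"
            )
        x = np.log10(np.asarray(cas))
        y = np.asarray(ws)

        def wmodel(xx: np.ndarray, log_kd: float, beta: float) -> np.ndarray:
            r = np.power(10.0, (xx - log_kd) * beta)
            return r / (1.0 + r)

        popt, _ = optimize.curve_fit(
            wmodel, x, y, p0=(math.log10(hill.kd), -hill.hill_slope), maxfev=5000
        )
        seg = SegmentHill(kd=10.0 ** float(popt[0]), hill_slope=-float(popt[1]))
        cal = replace(cal, segment_hill=seg)
    return cal


@dataclass(frozen=True)
class CalciumEstimate:
    """Calcium read from a phasor, with gating and range flags."""

    ca_nM: float
    status: Literal["ok", "gated"]
    flags: tuple[str, ...] = ()
    w: float = float("nan")
    off_segment: float = float("nan")

    def __float__(self) -> float:
        return self.ca_nM


def _range_flags(
    ca: float, hill: HillCalibration, dynamic_range: tuple[float, float]
) -> tuple[str, ...]:
    flags: list[str] = []
    lo_dyn, hi_dyn = dynamic_range
    if ca < lo_dyn:
        flags.append("below_dynamic_range")
    elif ca > hi_dyn:
        flags.append("above_dynamic_range")
    lo_lin, hi_lin = linear_range(hill)
    if ca < lo_lin:
        flags.append("below_linear_range")
    elif ca > hi_lin:
        flags.append("above_linear_range")
    return tuple(flags)


def calcium_from_phasor(
    p: Phasor,
    cal: PhasorCalibration,
    mode: InversionMode | None = None,
    dynamic_range: tuple[float, float] = DYNAMIC_RANGE_NM,
) -> CalciumEstimate:
    """Invert a phasor position to a free calcium concentration (nM).

    Phasors inside the noise gate are returned with status 'gated' and no
    concentration.  Concentrations are reported unclamped; flags mark values
    outside the sensor's dynamic range (100 nM - 4 uM) and its linear range.
    """
    mode = mode or cal.inversion_mode
    if p.modulus < cal.gate_radius:
        return CalciumEstimate(float("nan"), "gated")
    w, off = project_fraction(p, cal)
    if mode == "empirical":
        if cal.segment_hill is None:
            raise ConfigurationError(
                "empirical inversion requires a fitted segment_hill curve"
            )
        ca = float(cal.segment_hill.invert(w))
    else:
        d_free = math.hypot(p.g - cal.p_free.g, p.s - cal.p_free.s)
        d_fret = math.hypot(cal.p_fret.g - p.g, cal.p_fret.s - p.s)
        if d_free == 0.0:
            ca = 0.0
        elif d_fret == 0.0:
            ca = math.inf
        else:
            ratio = cal.brightness_ratio * d_free / d_fret
            if mode == "literal_eq11":
                ca = cal.hill.kd * ratio
            elif mode == "hill_generalized":
                ca = cal.hill.kd * ratio ** (-1.0 / cal.hill.hill_slope)
            else:
                raise ConfigurationError(f"unknown inversion mode {mode!r}")
    return CalciumEstimate(
        ca_nM=ca,
        status="ok",
        flags=_range_flags(ca, cal.hill, dynamic_range),
        w=w,
        off_segment=off,
    )


def linear_range(
    hill: HillCalibration | None = None, f_lo: float = 0.30, f_hi: float = 0.70
) -> tuple[float, float]:
    """Concentrations (nM) bounding the sensor's linear response.

    The bounds are the concentrations at which the saturation fraction
    (tau_free - tau)/(tau_free - tau_FRET) reaches `f_lo` and `f_hi`
    (30%/70% by convention):  c = Kd (f/(1-f))^(1/|h|).
    """
    hill = hill or HillCalibration()
    beta = -hill.hill_slope
    lo = hill.kd * (f_lo / (1.0 - f_lo)) ** (1.0 / beta)
    hi = hill.kd * (f_hi / (1.0 - f_hi)) ** (1.0 / beta)
    return lo, hi


def dual_calibration_from_titration(
    pairs: Sequence[tuple[float, DecayHistogram]],
    sat_ca_nM: float | None = None,
    centroid: Literal["mean", "median"] = "mean",
    gate_radius: float = 0.3,
    inversion_mode: InversionMode = "empirical",
    min_cloud: int = 1,
    max_fits_per_level: int = 10,
) -> tuple[HillTitrationResult, PhasorCalibration]:
    """Build both pathway calibrations from one titration dataset.

    Time-domain: per-level mean monoexponential lifetime, then the Hill
    sigmoid fit with anchors fixed.  Phase-domain: per-level phasor clouds
    (one phasor per replicate decay), centroids for the endpoints and a
    segment-fraction Hill curve from the intermediate levels.
    """
    by_level: dict[float, list[DecayHistogram]] = {}
    for ca, decay in pairs:
        by_level.setdefault(float(ca), []).append(decay)
    if sat_ca_nM is None:
        sat_ca_nM = max(by_level)
    points = [
        (ca, float(np.mean([fit_monoexponential(d).tau for d in ds[:max_fits_per_level]])))
        for ca, ds in by_level.items()
    ]
    result = HillTitrationModel.from_points(points, sat_ca_nM=sat_ca_nM).fit()
    clouds = {
        ca: np.array([[p.g, p.s] for p in map(phasor_transform, ds)])
        for ca, ds in by_level.items()
    }
    cal = build_phasor_calibration(
        clouds[0.0],
        clouds[sat_ca_nM],
        result.calibration,
        centroid=centroid,
        titration_clouds={c: v for c, v in clouds.items() if 0 < c < sat_ca_nM},
        gate_radius=gate_radius,
        inversion_mode=inversion_mode,
        min_cloud=min_cloud,
    )
    return result, cal


def crossvalidate_pathways(
    decays: Sequence[DecayHistogram],
    hill: HillCalibration,
    cal: PhasorCalibration,
    mode: InversionMode | None = None,
    fit_range: tuple[int, int] | None = None,
) -> float:
    """Maximum relative deviation (%) between the two calcium pathways.

    For each decay, calcium is computed via the time-domain pathway
    (monoexponential fit, then sigmoid inversion) and the phase-domain
    pathway (phasor transform, then the calibration's inversion mode); the
    maximum over decays of |c_time - c_phasor| / mean(c_time, c_phasor) * 100
    is returned.  Decays inverting outside the sensor's dynamic range
    (saturated anchors, gated phasors, concentrations beyond 100 nM - 4 uM)
    carry no comparable concentration and are excluded from the maximum.
    """
    if len(decays) == 0:
        raise ValueError("crossvalidation requires at least one decay")
    deviations = []
    for decay in decays:
        fit = fit_monoexponential(decay, fit_range=fit_range)
        inv = calcium_from_lifetime(fit.tau, hill)
        est = calcium_from_phasor(phasor_transform(decay), cal, mode=mode)
        if inv.saturated is not None or est.status != "ok":
            # saturated/endpoint/gated decays carry no comparable concentration
            continue
        c_time, c_phasor = inv.ca_nM, est.ca_nM
        lo_dyn, hi_dyn = DYNAMIC_RANGE_NM
        if not all(lo_dyn <= c <= hi_dyn for c in (c_time, c_phasor)):
            continue
        mean = 0.5 * (c_time + c_phasor)
        if mean <= 0 or not math.isfinite(mean):
            continue
        deviations.append(abs(c_time - c_phasor) / mean * 100.0)
    if not deviations:
        raise ValueError(
            "no crossvalidation decay inverted inside the measurable range"
        )
    return max(deviations)
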