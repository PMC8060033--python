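"""Synthetic TCSPC data generation.

Every analysis input the package reads can be generated here with a fixed
seed: single decays, titration sets, FLIM image scenes with ground truth,
pure detector-noise frames, two-channel ratiometric traces and
colocalization-intensity histograms.

Decays are simulated in the periodic steady state: at an 80 MHz repetition
rate the donor lifetime (0.7-2.3 ns) is a sizeable fraction of the 12.5 ns
period, so photons excited by preceding pulses wrap into the observation
window.  Within one period the wrapped monoexponential decay remains
proportional to exp(-t/tau), which makes the discrete phasor of a noise-free
simulated decay match the continuous-wave closed form - the property the
phasor calibration relies on when reading lifetimes off the semicircle.

Two decay modes are provided:

``monoexp``
    A single apparent lifetime tau = lifetime_from_calcium(ca); models the
    time-domain titration where each buffer condition is fitted with one
    lifetime.
``biexp``
    A two-species intensity mixture of the calcium-free (tau_free) and
    calcium-saturated (tau_FRET) donor states whose FRET intensity fraction
    w(ca) = (ca/Kd)^|h| / (1 + (ca/Kd)^|h|) makes the intensity-weighted mean
    lifetime follow the titration sigmoid exactly; models the real sensor,
    whose decay is a mixture, and places phasors on the calibration segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .calibration import HillCalibration, lifetime_from_calcium
from .decay import AcquisitionParams, DecayHistogram
from .quantify import FlimStack
from .traces import ColocModel, RatioTrace

__all__ = [
    "SyntheticCell",
    "GroundTruthScene",
    "simulate_decay",
    "simulate_titration",
    "TitrationSet",
    "simulate_flim_scene",
    "SceneData",
    "simulate_noise_frame",
    "simulate_ratiometric_trace",
    "simulate_coloc_histogram",
]

DecayMode = Literal["monoexp", "biexp"]


def _rng(seed: int | None, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _bin_fractions(tau: float, params: AcquisitionParams) -> np.ndarray:
    """Expected fraction of detected photons per bin for a periodic monoexponential.

    The periodic steady-state decay is proportional to exp(-t/tau) within the
    period; each bin receives its exact integral, normalized over the observed
    window (the ~1% of the period past the last bin is undetected).
    """
    edges = params.bin_edges()
    if tau <= 0:
        frac = np.zeros(params.n_bins)
        frac[0] = 1.0
        return frac
    cdf = -np.expm1(-edges / tau)  # 1 - exp(-t/tau), stable for small bins
    frac = np.diff(cdf)
    return frac / frac.sum()


def _gaussian_irf_kernel(
    params: AcquisitionParams, fwhm: float, center_s: float
) -> np.ndarray:
    """Circular Gaussian IRF kernel over one laser period (index 0 = zero lag)."""
    n_ext = int(round(params.period / params.bin_width))
    lags = np.arange(n_ext) * params.bin_width
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    # wrap lags onto (-T/2, T/2]: a center at 0 straddles the wrap point
    d = (lags - center_s + 0.5 * params.period) % params.period - 0.5 * params.period
    kernel = np.exp(-0.5 * (d / sigma) ** 2)
    return kernel / kernel.sum()


def _decay_shape(
    ca_nM: float,
    hill: HillCalibration,
    params: AcquisitionParams,
    mode: DecayMode,
    irf_fwhm: float | None,
    irf_center_s: float,
) -> np.ndarray:
    """Normalized expected decay shape (sums to 1 over the observed bins)."""
    if mode == "monoexp":
        shape = _bin_fractions(float(lifetime_from_calcium(ca_nM, hill)), params)
    elif mode == "biexp":
        w = hill.saturation_fraction(ca_nM)
        shape = w * _bin_fractions(hill.tau_fret, params) + (1.0 - w) * _bin_fractions(
            hill.tau_free, params
        )
    else:
        raise ValueError(f"unknown decay mode {mode!r}")
    if irf_fwhm:
        n_ext = int(round(params.period / params.bin_width))
        ext = np.zeros(n_ext)
        ext[: params.n_bins] = shape
        kernel = _gaussian_irf_kernel(params, irf_fwhm, irf_center_s)
        conv = np.fft.irfft(np.fft.rfft(ext) * np.fft.rfft(kernel), n=n_ext)
        shape = np.clip(conv[: params.n_bins], 0.0, None)
        shape = shape / shape.sum()
    return shape


def simulate_decay(
    ca_nM: float,
    n_photons: float,
    hill: HillCalibration | None = None,
    params: AcquisitionParams | None = None,
    mode: DecayMode = "biexp",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    background_rate: float = 0.0,
    irf_fwhm: float | None = None,
    irf_center_s: float = 0.0,
) -> DecayHistogram:
    """Simulate a TCSPC decay at a given free calcium concentration.

    Parameters
    ----------
    ca_nM
        Free calcium, nM (>= 0).
    n_photons
        Expected detected signal photons.
    mode
        'monoexp' (single apparent lifetime) or 'biexp' (two-species
        mixture); see the module docstring.
    noise
        Apply per-bin Poisson noise (True) or return the noise-free expected
        histogram (False).
    background_rate
        Uniform detector background, expected counts per bin.
    irf_fwhm, irf_center_s
        Optional Gaussian instrument response (FWHM in s) convolved
        circularly over the laser period.  The default center 0 straddles the
        wrap point symmetrically, leaving the phasor phase untouched.
    """
    if ca_nM < 0:
        raise ValueError("calcium concentration must be nonnegative")
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    hill = hill or HillCalibration()
    params = params or AcquisitionParams()
    lam = n_photons * _decay_shape(ca_nM, hill, params, mode, irf_fwhm, irf_center_s)
    if background_rate:
        lam = lam + background_rate
    counts = _rng(seed, rng).poisson(lam).astype(float) if noise else lam
    return DecayHistogram(counts=counts, params=params)


@dataclass(frozen=True)
class TitrationSet:
    """A simulated titration: decays per nominal concentration plus a manifest."""

    decays: tuple[tuple[float, DecayHistogram], ...]  # (ca_nM, decay)
    manifest: pd.DataFrame  # columns ca_nM, replicate
    sat_ca_nM: float
    seed: int | None

    def by_level(self) -> dict[float, list[DecayHistogram]]:
        out: dict[float, list[DecayHistogram]] = {}
        for ca, d in self.decays:
            out.setdefault(ca, []).append(d)
        return out


DEFAULT_TITRATION_LEVELS: tuple[float, ...] = (
    0.0,
    *np.geomspace(50.0, 10_000.0, 11).round(3),
    39_000.0,
)


def simulate_titration(
    levels: Sequence[float] | None = None,
    n_photons: float = 1e6,
    hill: HillCalibration | None = None,
    params: AcquisitionParams | None = None,
    mode: DecayMode = "monoexp",
    seed: int | None = 0,
    sat_ca_nM: float = 39_000.0,
    n_replicates: int = 1,
    **decay_kwargs,
) -> TitrationSet:
    """Simulate a buffer titration: one (or more) decays per calcium level.

    `levels` must include the 0 nM anchor and the saturating anchor
    (`sat_ca_nM`, default 39 uM); the default ladder adds 11 log-spaced
    levels between 50 nM and 10 uM.

    The two anchors are emitted as the pure endpoint states (unquenched
    tau_free at 0 nM, fully quenched tau_FRET at the saturating level):
    operationally they *define* the sensor's extreme states, which is how a
    calibration titration treats its endpoint buffers.  Intermediate levels
    follow the Hill model exactly.
    """
    if levels is None:
        levels = DEFAULT_TITRATION_LEVELS
    levels = list(levels)
    if not levels:
        raise ValueError("titration levels must not be empty")
    if 0.0 not in levels:
        raise ValueError("titration requires a 0 nM anchor level")
    if sat_ca_nM not in levels:
        raise ValueError(f"titration requires the saturating anchor {sat_ca_nM} nM")
    rng = np.random.default_rng(seed)
    decays: list[tuple[float, DecayHistogram]] = []
    rows = []
    for ca in levels:
        # anchors define the endpoint states: saturating level -> pure FRET state
        ca_sim = math.inf if ca == sat_ca_nM else ca
        for rep in range(n_replicates):
            decays.append(
                (
                    ca,
                    simulate_decay(
                        ca_sim, n_photons, hill=hill, params=params, mode=mode,
                        rng=rng, **decay_kwargs,
                    ),
                )
            )
            rows.append({"ca_nM": ca, "replicate": rep})
    return TitrationSet(
        decays=tuple(decays),
        manifest=pd.DataFrame(rows),
        sat_ca_nM=sat_ca_nM,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Image scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCell:
    """An elliptical cell with a per-frame calcium trace and photon budget."""

    label_id: int
    center: tuple[float, float]  # (row, col), pixels
    radii: tuple[float, float]  # (row, col) semi-axes, pixels
    ca_trace_nM: tuple[float, ...]  # one value per frame
    photons_per_frame: float
    rotation: float = 0.0  # radians
    subset_tag: str = ""
    coloc_intensity_au: float = 0.0

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValueError("label_id must be positive")
        if self.photons_per_frame <= 0:
            raise ValueError("photons_per_frame must be positive")
        if any(c < 0 for c in self.ca_trace_nM):
            raise ValueError("calcium trace values must be nonnegative")


@dataclass(frozen=True)
class GroundTruthScene:
    """Ground truth of a synthetic FLIM scene (cells, background, acquisition)."""

    shape: tuple[int, int] = (64, 64)
    cells: tuple[SyntheticCell, ...] = ()
    background_rate: float = 0.0  # expected counts per pixel per frame (all bins)
    params: AcquisitionParams = field(default_factory=AcquisitionParams)
    n_frames: int = 1
    pixel_size_um: float = 1.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        for cell in self.cells:
            if len(cell.ca_trace_nM) != self.n_frames:
                raise ValueError(
                    f"cell {cell.label_id}: calcium trace length "
                    f"{len(cell.ca_trace_nM)} != n_frames {self.n_frames}"
                )


@dataclass(frozen=True)
class SceneData:
    """Rendered synthetic scene: per-frame stacks, label mask and truth table."""

    stacks: tuple[FlimStack, ...]
    mask: np.ndarray  # uint16 label image, 0 = background
    truth: pd.DataFrame  # frame_index, label_id, ca_nM, photons, subset_tag, coloc

    def __iter__(self):
        return iter(self.stacks)


def render_mask(scene: GroundTruthScene) -> np.ndarray:
    """Rasterize the scene's ellipses into a label mask; cells must be disjoint."""
    mask = np.zeros(scene.shape, dtype=np.uint16)
    for cell in scene.cells:
        rr, cc = draw_ellipse(
            cell.center[0],
            cell.center[1],
            cell.radii[0],
            cell.radii[1],
            shape=scene.shape,
            rotation=cell.rotation,
        )
        if rr.size == 0:
            raise ValueError(f"cell {cell.label_id} lies outside the image")
        if np.any(mask[rr, cc] != 0):
            raise ValueError(f"cell {cell.label_id} overlaps another cell")
        mask[rr, cc] = cell.label_id
    return mask


def simulate_flim_scene(
    scene: GroundTruthScene,
    hill: HillCalibration | None = None,
    mode: DecayMode = "biexp",
    **decay_kwargs,
) -> SceneData:
    """Render a ground-truth scene into per-frame FLIM stacks + mask + truth CSV.

    Each cell's photon budget is split uniformly across its member pixels;
    per-pixel counts are Poisson draws from the cell's decay shape at its
    current calcium.  Background pixels draw uniform-in-time counts at the
    scene's background rate.  Deterministic under the scene's seed.
    """
    hill = hill or HillCalibration()
    params = scene.params
    mask = render_mask(scene)
    rng = np.random.default_rng(scene.seed)
    n_bins = params.n_bins
    stacks = []
    rows = []
    member_pixels = {
        cell.label_id: np.nonzero(mask == cell.label_id) for cell in scene.cells
    }
    for frame in range(scene.n_frames):
        lam = np.full(
            (*scene.shape, n_bins), scene.background_rate / n_bins, dtype=float
        )
        for cell in scene.cells:
            ca = cell.ca_trace_nM[frame]
            shape_t = _decay_shape(
                ca, hill, params, mode,
                decay_kwargs.get("irf_fwhm"), decay_kwargs.get("irf_center_s", 0.0),
            )
            rr, cc = member_pixels[cell.label_id]
            per_pixel = cell.photons_per_frame / rr.size
            lam[rr, cc, :] += per_pixel * shape_t
            rows.append(
                {
                    "frame_index": frame,
                    "label_id": cell.label_id,
                    "ca_nM": ca,
                    "photons": cell.photons_per_frame,
                    "subset_tag": cell.subset_tag,
                    "coloc_intensity_au": cell.coloc_intensity_au,
                }
            )
        voxels = rng.poisson(lam)
        stacks.append(
            FlimStack(
                voxels=voxels,
                params=params,
                frame_index=frame,
                pixel_size_um=scene.pixel_size_um,
            )
        )
    return SceneData(stacks=tuple(stacks), mask=mask, truth=pd.DataFrame(rows))


def simulate_noise_frame(
    params: AcquisitionParams | None = None,
    rate: float = 5.0,
    size: tuple[int, int] = (64, 64),
    seed: int | None = 0,
) -> FlimStack:
    """Pure detector-noise frame: uniform-in-time Poisson counts per bin.

    `rate` is the expected counts per bin per pixel.  Pixel phasors
    concentrate around the origin with spread ~ 1/sqrt(2 N_photons).
    """
    if rate < 0:
        raise ValueError("noise rate must be nonnegative")
    params = params or AcquisitionParams()
    rng = np.random.default_rng(seed)
    voxels = rng.poisson(rate, size=(*size, params.n_bins))
    return FlimStack(voxels=voxels, params=params, frame_index=0)


# ---------------------------------------------------------------------------
# Ratiometric traces and colocalization histograms
# ---------------------------------------------------------------------------


def simulate_ratiometric_trace(
    events: Sequence[float] = (),
    amplitude: float | Sequence[float] = 0.3,
    duration_s: float = 300.0,
    dt_s: float = 3.0,
    tau_rise_s: float = 5.0,
    tau_decay_s: float = 40.0,
    ch1_baseline: float = 160.0,
    ch2_baseline: float = 40.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> RatioTrace:
    """Two-channel donor/acceptor trace with stimulus-evoked FRET transients.

    Each event transiently moves intensity from the donor channel (ch1) to
    the acceptor channel (ch2) with rise/decay kinetics, conserving
    ch1 + ch2 up to additive Gaussian noise.  `amplitude` is the target peak
    of the simple-ratio (ch2/ch1) relative change dR/R per event, used to
    size the transferred intensity.
    """
    events = list(events)
    amps = (
        [float(amplitude)] * len(events)
        if np.isscalar(amplitude)
        else [float(a) for a in amplitude]
    )
    if len(amps) != len(events):
        raise ValueError("one amplitude per event required")
    if any(a < 0 for a in amps):
        raise ValueError("event amplitudes must be nonnegative")
    if any(not (0 <= e <= duration_s) for e in events):
        raise ValueError("events must lie within the trace duration")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    transfer = np.zeros_like(t)
    a, b = ch1_baseline, ch2_baseline
    for t0, amp in zip(events, amps):
        # peak transfer q moving ratio from b/a to (1+amp) b/a
        kappa = 1.0 + amp
        q = b * (kappa - 1.0) / (1.0 + kappa * b / a)
        dt_ev = t - t0
        pulse = np.where(
            dt_ev >= 0,
            np.exp(-dt_ev / tau_decay_s) - np.exp(-dt_ev / tau_rise_s),
            0.0,
        )
        peak = pulse.max()
        if peak > 0:
            transfer += q * pulse / peak
    rng = np.random.default_rng(seed)
    ch1 = a - transfer
    ch2 = b + transfer
    if noise_sd:
        ch1 = ch1 + rng.normal(0.0, noise_sd, t.size)
        ch2 = ch2 + rng.normal(0.0, noise_sd, t.size)
    ch1 = np.clip(ch1, 0.0, None)
    ch2 = np.clip(ch2, 0.0, None)
    return RatioTrace(time_s=t, ch1=ch1, ch2=ch2, events=tuple(events))


def simulate_coloc_histogram(
    model: ColocModel,
    n_objects: int = 6869,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Draw per-object colocalization intensities from a biexponential mixture.

    The frequency curve a1 exp(-x/l1) + a2 exp(-x/l2) corresponds to a
    mixture of two exponential densities with component probabilities
    proportional to a_i * l_i; intensities are binned at the model's bin
    width.  Returns a DataFrame with columns `intensity_au` (bin centers)
    and `frequency`.
    """
    if n_objects <= 0:
        raise ValueError("n_objects must be positive")
    rng = np.random.default_rng(seed)
    w1 = model.a1 * model.lambda1
    w2 = model.a2 * model.lambda2
    p1 = w1 / (w1 + w2)
    comp = rng.random(n_objects) < p1
    x = np.where(
        comp,
        rng.exponential(model.lambda1, n_objects),
        rng.exponential(model.lambda2, n_objects),
    )
    n_edges = int(np.ceil(x.max() / model.bin_width)) + 1
    edges = np.arange(n_edges + 1) * model.bin_width
    freq, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"intensity_au": centers, "frequency": freq})
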