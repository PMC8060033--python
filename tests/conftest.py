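"""Shared fixtures: default calibrations and reusable simulated datasets."""

import numpy as np
import pytest

import phasorca as pc
from phasorca.calibration import SegmentHill


@pytest.fixture(scope="session")
def hill() -> pc.HillCalibration:
    """Lysate titration constants: Kd 475 nM, slope -1.43, 2312/744 ps."""
    return pc.HillCalibration()


@pytest.fixture(scope="session")
def params() -> pc.AcquisitionParams:
    """80 MHz, 55 ps bins, 225-bin window."""
    return pc.AcquisitionParams()


@pytest.fixture(scope="session")
def semicircle_cal(hill, params) -> pc.PhasorCalibration:
    """Phasor calibration with ideal (semicircle) endpoints.

    The segment-fraction Hill curve equals the lifetime sigmoid's saturation
    fraction exactly under the two-species mixture model, so the empirical
    inversion is analytically exact for noise-free mixture decays.
    """
    return pc.PhasorCalibration(
        p_free=pc.phasor_of_monoexponential(hill.tau_free, params),
        p_fret=pc.phasor_of_monoexponential(hill.tau_fret, params),
        hill=hill,
        brightness_ratio=hill.brightness_ratio,
        segment_hill=SegmentHill(kd=hill.kd, hill_slope=hill.hill_slope),
        acquisition=params,
    )


@pytest.fixture(scope="session")
def measured_cal(hill) -> pc.PhasorCalibration:
    """Phasor calibration at the measured lysate cloud endpoints."""
    return pc.PhasorCalibration(
        p_free=pc.Phasor(0.4035, 0.45801),
        p_fret=pc.Phasor(0.82377, 0.3225),
        hill=hill,
        brightness_ratio=hill.brightness_ratio,
        segment_hill=SegmentHill(kd=hill.kd, hill_slope=hill.hill_slope),
    )


@pytest.fixture(scope="session")
def calibrated_workflow(hill):
    """One simulated two-species titration and both calibrations built from it.

    60 replicate decays per level at 1e6 photons; the time-domain sigmoid is
    fitted to per-level mean monoexponential lifetimes, and the phasor
    calibration (with segment-fraction Hill curve) to the per-level phasor
    clouds.  Shared by the cross-pathway tests.
    """
    from phasorca.synth import simulate_titration

    tit = simulate_titration(mode="biexp", n_photons=1e6, seed=7, n_replicates=60)
    by_level = tit.by_level()
    points = [
        (ca, float(np.mean([pc.fit_monoexponential(d).tau for d in ds[:10]])))
        for ca, ds in by_level.items()
    ]
    hill_fit = pc.fit_hill_titration(points, sat_ca_nM=39000.0).calibration
    clouds = {
        ca: np.array([[(p := pc.phasor_transform(d)).g, p.s] for d in ds])
        for ca, ds in by_level.items()
    }
    cal = pc.build_phasor_calibration(
        clouds[0.0],
        clouds[39000.0],
        hill_fit,
        titration_clouds={c: v for c, v in clouds.items() if 0 < c < 39000.0},
    )
    return hill_fit, cal
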