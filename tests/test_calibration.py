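"""Titration sigmoid, its inversion, the phasor calibration and cross-pathway checks."""

import math

import numpy as np
import pytest

import phasorca as pc
from phasorca.calibration import SegmentHill
from phasorca.exceptions import (
    ConfigurationError,
    InsufficientDataError,
    UnstableCalibrationError,
)
from phasorca.synth import simulate_decay, simulate_titration


class TestLifetimeSigmoid:
    def test_halfway_at_kd(self, hill):
        assert pc.lifetime_from_calcium(475.0, hill) == pytest.approx(1528e-12)

    def test_zero_calcium_asymptote(self, hill):
        assert pc.lifetime_from_calcium(0.0, hill) == pytest.approx(2312e-12)

    def test_saturating_anchor(self, hill):
        # direct evaluation: 744 + 1568/(1 + (39000/475)^1.43) = 746.86 ps
        tau = pc.lifetime_from_calcium(39_000.0, hill)
        assert tau == pytest.approx(746.864e-12, rel=1e-4)
        assert tau - hill.tau_fret < 3e-12

    def test_monotone_decreasing(self, hill):
        cas = np.geomspace(1.0, 1e5, 200)
        taus = pc.lifetime_from_calcium(cas, hill)
        assert np.all(np.diff(taus) < 0)

    def test_negative_concentration_rejected(self, hill):
        with pytest.raises(ValueError):
            pc.lifetime_from_calcium(-1.0, hill)


class TestLifetimeInversion:
    def test_halfway_returns_kd(self, hill):
        inv = pc.calcium_from_lifetime(1528e-12, hill)
        assert inv.ca_nM == pytest.approx(475.0, rel=1e-9)
        assert inv.saturated is None

    def test_mid_lifetime(self, hill):
        assert pc.calcium_from_lifetime(1000e-12, hill).ca_nM == pytest.approx(
            1489.0, rel=1e-3
        )

    def test_unquenched_boundary_flagged_low(self, hill):
        inv = pc.calcium_from_lifetime(2312e-12, hill)
        assert inv.ca_nM == 0.0
        assert inv.saturated == "low"

    def test_quenched_boundary_flagged_high(self, hill):
        inv = pc.calcium_from_lifetime(700e-12, hill)
        assert math.isinf(inv.ca_nM)
        assert inv.saturated == "high"

    def test_round_trip_exact(self, hill):
        """Forward sigmoid then inversion is the identity to 1e-9 relative."""
        for ca in np.geomspace(1.0, 1e5, 100):
            tau = pc.lifetime_from_calcium(ca, hill)
            assert pc.calcium_from_lifetime(tau, hill).ca_nM == pytest.approx(
                ca, rel=1e-9
            )


class TestHillTitrationFit:
    def test_noise_free_round_trip(self, hill):
        # anchors carry the pure endpoint states; intermediates follow the sigmoid
        pts = [(0.0, hill.tau_free), (39_000.0, hill.tau_fret)] + [
            (ca, pc.lifetime_from_calcium(ca, hill))
            for ca in np.geomspace(50, 10_000, 8)
        ]
        res = pc.fit_hill_titration(pts, sat_ca_nM=39_000.0)
        assert res.calibration.kd == pytest.approx(475.0, rel=1e-6)
        assert res.calibration.hill_slope == pytest.approx(-1.43, rel=1e-6)
        assert "Kd" in res.summary()

    def test_recovery_from_noisy_decays(self, hill, params):
        """Poisson-noise titration at 1e6 photons recovers Kd and slope within
        the calibration's quoted uncertainties (+/-46 nM, +/-0.17)."""
        tit = simulate_titration(
            mode="monoexp", n_photons=1e6, hill=hill, params=params, seed=3
        )
        pts = [(ca, pc.fit_monoexponential(d).tau) for ca, d in tit.decays]
        res = pc.fit_hill_titration(pts, sat_ca_nM=39_000.0)
        assert res.calibration.kd == pytest.approx(475.0, abs=46.0)
        assert res.calibration.hill_slope == pytest.approx(-1.43, abs=0.17)

    def test_recovery_across_seeds(self, hill):
        """Kd within 10% and slope within 0.15 in >= 9/10 seeded runs."""
        hits = 0
        for seed in range(10):
            tit = simulate_titration(mode="monoexp", n_photons=1e6, hill=hill, seed=seed)
            pts = [(ca, pc.fit_monoexponential(d).tau) for ca, d in tit.decays]
            c = pc.fit_hill_titration(pts, sat_ca_nM=39_000.0).calibration
            if abs(c.kd - 475.0) / 475.0 <= 0.10 and abs(c.hill_slope + 1.43) <= 0.15:
                hits += 1
        assert hits >= 9

    def test_too_few_points_rejected(self, hill):
        pts = [(0.0, hill.tau_free), (39_000.0, hill.tau_fret), (475.0, 1.5e-9)]
        with pytest.raises(InsufficientDataError):
            pc.fit_hill_titration(pts, sat_ca_nM=39_000.0)


def _cloud(rng, center, sigma=0.01, n=200):
    return rng.normal(center, sigma, size=(n, 2))


class TestPhasorCalibrationBuild:
    def test_centroids_recover_measured_endpoints(self, hill):
        rng = np.random.default_rng(8)
        free = _cloud(rng, [0.4035, 0.45801])
        sat = _cloud(rng, [0.82377, 0.3225])
        cal = pc.build_phasor_calibration(free, sat, hill, inversion_mode="literal_eq11")
        se = 0.01 / math.sqrt(200) * 4
        assert cal.p_free.g == pytest.approx(0.4035, abs=se)
        assert cal.p_free.s == pytest.approx(0.45801, abs=se)
        assert cal.p_fret.g == pytest.approx(0.82377, abs=se)
        assert cal.p_fret.s == pytest.approx(0.3225, abs=se)
        assert cal.brightness_ratio == pytest.approx(2312.0 / 744.0, rel=1e-12)
        assert cal.brightness_ratio == pytest.approx(3.108, abs=1e-3)

    def test_identical_clouds_rejected(self, hill):
        rng = np.random.default_rng(9)
        cloud = _cloud(rng, [0.6, 0.4])
        with pytest.raises(UnstableCalibrationError):
            pc.build_phasor_calibration(cloud, cloud, hill)

    def test_small_clouds_rejected(self, hill):
        rng = np.random.default_rng(10)
        with pytest.raises(InsufficientDataError):
            pc.build_phasor_calibration(
                _cloud(rng, [0.4, 0.46], n=10), _cloud(rng, [0.82, 0.32]), hill
            )

    def test_centroid_converges_with_cloud_size(self, hill):
        """Centroid error shrinks ~1/sqrt(N) toward the generating endpoint."""
        errs = {}
        for n in (100, 1000):
            rng = np.random.default_rng(123)
            cal = pc.build_phasor_calibration(
                _cloud(rng, [0.4035, 0.45801], sigma=0.03, n=n),
                _cloud(rng, [0.82377, 0.3225], sigma=0.03, n=n),
                hill,
                inversion_mode="literal_eq11",
            )
            errs[n] = math.hypot(cal.p_free.g - 0.4035, cal.p_free.s - 0.45801)
        assert errs[1000] < errs[100]
        assert errs[1000] < 4 * 0.03 / math.sqrt(1000)


class TestProjection:
    def test_endpoint_and_midpoint(self, semicircle_cal):
        w, off = pc.project_fraction(semicircle_cal.p_free, semicircle_cal)
        assert (w, off) == (0.0, pytest.approx(0.0, abs=1e-12))
        mid = pc.Phasor(
            (semicircle_cal.p_free.g + semicircle_cal.p_fret.g) / 2,
            (semicircle_cal.p_free.s + semicircle_cal.p_fret.s) / 2,
        )
        w, _ = pc.project_fraction(mid, semicircle_cal)
        assert w == pytest.approx(0.5, abs=1e-12)

    def test_interior_point(self, semicircle_cal):
        w, _ = pc.project_fraction(pc.Phasor(0.62898, 0.48308), semicircle_cal)
        assert w == pytest.approx(0.405, abs=0.01)


class TestCalciumFromPhasor:
    def test_free_endpoint_is_zero_in_all_modes(self, semicircle_cal):
        for mode in ("empirical", "literal_eq11", "hill_generalized"):
            est = pc.calcium_from_phasor(semicircle_cal.p_free, semicircle_cal, mode=mode)
            assert est.ca_nM == 0.0
            assert est.status == "ok"

    def test_midpoint_literal_and_generalized(self, semicircle_cal):
        mid = pc.Phasor(
            (semicircle_cal.p_free.g + semicircle_cal.p_fret.g) / 2,
            (semicircle_cal.p_free.s + semicircle_cal.p_fret.s) / 2,
        )
        lit = pc.calcium_from_phasor(mid, semicircle_cal, mode="literal_eq11")
        assert lit.ca_nM == pytest.approx(475.0 * 2312.0 / 744.0, rel=1e-6)
        assert lit.ca_nM == pytest.approx(1476.0, abs=1.0)
        gen = pc.calcium_from_phasor(mid, semicircle_cal, mode="hill_generalized")
        assert gen.ca_nM == pytest.approx(475.0 * (2312.0 / 744.0) ** (1 / 1.43), rel=1e-6)
        assert gen.ca_nM == pytest.approx(1049.0, abs=1.0)

    def test_gated_phasor_carries_no_concentration(self, semicircle_cal):
        est = pc.calcium_from_phasor(pc.Phasor(0.1, 0.1), semicircle_cal)
        assert est.status == "gated"
        assert math.isnan(est.ca_nM)

    def test_empirical_mode_requires_segment_hill(self, semicircle_cal):
        from dataclasses import replace

        bare = replace(semicircle_cal, segment_hill=None)
        with pytest.raises(ConfigurationError):
            pc.calcium_from_phasor(bare.p_fret, bare, mode="empirical")

    def test_strictly_increasing_along_segment(self, semicircle_cal):
        """Every inversion mode is strictly increasing in the segment fraction."""
        ws = np.linspace(0.02, 0.98, 40)
        for mode in ("empirical", "literal_eq11", "hill_generalized"):
            cas = []
            for w in ws:
                p = pc.Phasor(
                    semicircle_cal.p_free.g
                    + w * (semicircle_cal.p_fret.g - semicircle_cal.p_free.g),
                    semicircle_cal.p_free.s
                    + w * (semicircle_cal.p_fret.s - semicircle_cal.p_free.s),
                )
                cas.append(pc.calcium_from_phasor(p, semicircle_cal, mode=mode).ca_nM)
            assert np.all(np.diff(cas) > 0), mode

    def test_generalized_reduces_to_literal_at_unit_slope(self, params):
        hill1 = pc.HillCalibration(kd=475.0, hill_slope=-1.0)
        cal = pc.PhasorCalibration(
            p_free=pc.phasor_of_monoexponential(hill1.tau_free, params),
            p_fret=pc.phasor_of_monoexponential(hill1.tau_fret, params),
            hill=hill1,
            brightness_ratio=hill1.brightness_ratio,
        )
        for w in (0.1, 0.37, 0.8):
            p = pc.Phasor(
                cal.p_free.g + w * (cal.p_fret.g - cal.p_free.g),
                cal.p_free.s + w * (cal.p_fret.s - cal.p_free.s),
            )
            lit = pc.calcium_from_phasor(p, cal, mode="literal_eq11").ca_nM
            gen = pc.calcium_from_phasor(p, cal, mode="hill_generalized").ca_nM
            assert gen == pytest.approx(lit, rel=1e-12)

    def test_dynamic_range_flags(self, semicircle_cal):
        low = pc.calcium_from_phasor(
            semicircle_cal.p_free, semicircle_cal, mode="empirical"
        )
        assert "below_dynamic_range" in low.flags
        high = pc.calcium_from_phasor(
            pc.Phasor(
                semicircle_cal.p_free.g
                + 0.98 * (semicircle_cal.p_fret.g - semicircle_cal.p_free.g),
                semicircle_cal.p_free.s
                + 0.98 * (semicircle_cal.p_fret.s - semicircle_cal.p_free.s),
            ),
            semicircle_cal,
        )
        assert "above_dynamic_range" in high.flags


class TestLinearRange:
    def test_reproduces_published_bounds(self, hill):
        lo, hi = pc.linear_range(hill)
        assert lo == pytest.approx(265.0, rel=0.02)
        assert hi == pytest.approx(857.0, rel=0.02)

    def test_unit_slope_closed_form(self):
        lo, hi = pc.linear_range(pc.HillCalibration(kd=100.0, hill_slope=-1.0))
        assert lo == pytest.approx(100.0 * 3.0 / 7.0, rel=1e-12)
        assert hi == pytest.approx(100.0 * 7.0 / 3.0, rel=1e-12)

    def test_symmetric_thresholds_product(self, hill):
        """At symmetric saturation thresholds, lo*hi = Kd^2 for any slope."""
        for slope in (-0.7, -1.43, -2.5):
            h = pc.HillCalibration(kd=475.0, hill_slope=slope)
            lo, hi = pc.linear_range(h)
            assert lo * hi == pytest.approx(475.0**2, rel=1e-9)


class TestCrossValidation:
    def test_noise_free_decay_at_kd_self_consistent(self, hill, params, calibrated_workflow):
        """With both calibrations from one titration, the pathways agree at Kd.

        The time-domain sigmoid is fitted to apparent (monoexponentially
        fitted) lifetimes of two-component decays, so it inverts a fresh
        mixture decay consistently with the phasor pathway even though the
        apparent parameters differ from the generating ones.  A ~1.6%
        structural residual remains at Kd because the sigmoid only
        approximates the apparent-lifetime curve of monoexponentially fitted
        mixtures; it stays well inside the 5% cross-pathway envelope.
        """
        hill_fit, cal = calibrated_workflow
        decay = simulate_decay(475.0, 1e6, hill, params, mode="biexp", noise=False)
        dev = pc.crossvalidate_pathways([decay], hill_fit, cal)
        assert dev <= 2.0

    def test_duplicate_decays_deterministic(self, hill, params, semicircle_cal):
        decay = simulate_decay(475.0, 1e6, hill, params, mode="biexp", seed=4)
        d1 = pc.crossvalidate_pathways([decay], hill, semicircle_cal)
        d2 = pc.crossvalidate_pathways([decay, decay], hill, semicircle_cal)
        assert d1 == d2

    def test_empty_input_rejected(self, hill, semicircle_cal):
        with pytest.raises(ValueError):
            pc.crossvalidate_pathways([], hill, semicircle_cal)


class TestSegmentHill:
    def test_invert_limits(self):
        seg = SegmentHill(kd=475.0, hill_slope=-1.43)
        assert seg.invert(0.0) == 0.0
        assert math.isinf(seg.invert(1.0))
        assert seg.invert(0.5) == pytest.approx(475.0, rel=1e-12)

    def test_round_trip(self):
        seg = SegmentHill(kd=475.0, hill_slope=-1.43)
        for ca in np.geomspace(10, 1e4, 20):
            assert seg.invert(seg.fraction(ca)) == pytest.approx(ca, rel=1e-9)
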