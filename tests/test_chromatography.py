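import numpy as np
import pytest
from conftest import gaussian_eic

import tracerscreen as ts
from tracerscreen.chromatography import pick_peaks
from tracerscreen.msdata import EIC

RT = np.arange(400.0, 800.5, 0.5)


class TestPickPeaks:
    @pytest.mark.parametrize("sigma", [2.0, 4.0, 6.0])
    def test_gaussian_recovery_against_closed_form(self, sigma):
        height = 1e6
        eic = gaussian_eic(RT, 600.0, sigma, height)
        peaks = pick_peaks(eic)
        assert len(peaks) == 1
        peak = peaks[0]
        assert abs(peak.apex_rt - 600.0) <= 0.5  # one scan interval
        analytic = height * sigma * np.sqrt(2.0 * np.pi)
        assert peak.area == pytest.approx(analytic, rel=0.05)

    def test_flat_zero_trace(self):
        assert pick_peaks(EIC(300.0, 5.0, RT, np.zeros_like(RT))) == []

    def test_wide_hump_rejected_by_width_bounds(self):
        # 60 s wide (sigma = 15 s) exceeds the 25 s maximum peak width
        eic = gaussian_eic(RT, 600.0, 15.0, 1e6)
        assert pick_peaks(eic) == []

    def test_narrow_spike_rejected_by_width_bounds(self):
        eic = gaussian_eic(RT, 600.0, 0.8, 1e6)  # ~3 s wide < 5 s minimum
        assert pick_peaks(eic) == []

    def test_low_snr_peak_rejected(self, rng):
        noise = rng.uniform(0, 2e5, RT.size)
        signal = 1e5 * np.exp(-((RT - 600.0) ** 2) / (2 * 3.0**2))
        peaks = pick_peaks(EIC(300.0, 5.0, RT, signal + noise), snr_min=3.0)
        assert all(abs(p.apex_rt - 600.0) > 2.0 for p in peaks)

    def test_area_scales_linearly_with_height(self):
        areas = [
            pick_peaks(gaussian_eic(RT, 600.0, 3.0, h))[0].area for h in (1e5, 2e5, 4e5)
        ]
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=1e-6)
        assert areas[2] / areas[0] == pytest.approx(4.0, rel=1e-6)

    def test_too_short_eic(self):
        rt = np.array([0.0, 0.5, 1.0])
        assert pick_peaks(EIC(300.0, 5.0, rt, np.array([0.0, 1e6, 0.0]))) == []

    def test_resolved_isomers_give_two_peaks(self):
        signal = 1e6 * np.exp(-((RT - 590.0) ** 2) / 18.0) + 8e5 * np.exp(
            -((RT - 620.0) ** 2) / 18.0
        )
        peaks = pick_peaks(EIC(300.0, 5.0, RT, signal))
        assert len(peaks) == 2
        assert peaks[0].bounds[1] <= peaks[1].bounds[0] + 0.51


class TestCoelutionR:
    def test_scaled_trace_correlates_perfectly(self):
        a = gaussian_eic(RT, 600.0, 3.0, 1e6)
        b = gaussian_eic(RT, 600.0, 3.0, 5e5)
        assert ts.coelution_r(a, b, (590, 610)) == pytest.approx(1.0)

    def test_three_sigma_shift_fails_the_gate(self):
        a = gaussian_eic(RT, 600.0, 3.0, 1e6)
        b = gaussian_eic(RT, 609.0, 3.0, 1e6)
        assert ts.coelution_r(a, b, (592, 608)) < 0.85

    def test_one_percent_noise_keeps_high_correlation(self, rng):
        a = gaussian_eic(RT, 600.0, 3.0, 1e6)
        noisy = EIC(301.0, 5.0, RT, a.intensity * (1 + 0.01 * rng.standard_normal(RT.size)))
        assert ts.coelution_r(a, noisy, (595.0, 605.0)) >= 0.99

    def test_zero_variance_is_a_coelution_failure(self):
        a = gaussian_eic(RT, 600.0, 3.0, 1e6)
        flat = EIC(301.0, 5.0, RT, np.zeros_like(RT))
        assert np.isnan(ts.coelution_r(a, flat, (590, 610)))

    def test_mismatched_grids_are_rejected(self):
        a = gaussian_eic(RT, 600.0, 3.0, 1e6)
        b = gaussian_eic(RT[:-1], 600.0, 3.0, 1e6)
        with pytest.raises(ValueError):
            ts.coelution_r(a, b)


def _single_compound_candidates(truth, run, ruleset):
    return ts.cluster_candidates(ts.screen_run(run, ruleset))


class TestVerifyFeature:
    def test_compliant_pattern_verifies_with_coelution(self, std_ruleset):
        model = ts.IncorporationModel(n_units=9, q=0.12, n_carbons=18)
        compound = ts.PlantedCompound(x_mz=350.0, rt_apex=60.0, model=model, height=2e6)
        truth = ts.SyntheticTruth([compound], seed=3, rt_span=(0.0, 120.0))
        run = ts.generate_run(truth)
        (candidate,) = _single_compound_candidates(truth, run, std_ruleset)
        features, rejections = ts.verify_feature(run, candidate, std_ruleset)
        assert rejections == []
        assert len(features) == 1
        feature = features[0]
        assert set(feature.peaks) == {0, 1, 2, 3, 4}
        assert feature.coelution_r >= 0.85
        assert abs(feature.apex_rt - 60.0) <= 0.5

    def test_shifted_satellite_is_rejected(self, std_ruleset):
        """An X+2 trace eluting 9 s (3 sigma) late breaks the coelution gate
        even when the scan-level ratios happen to pass near the crossover."""
        model = ts.IncorporationModel(n_units=9, q=0.12, n_carbons=18)
        compound = ts.PlantedCompound(x_mz=350.0, rt_apex=60.0, model=model, height=2e6)
        truth = ts.SyntheticTruth([compound], seed=3, rt_span=(0.0, 120.0))
        run = ts.generate_run(truth)
        (candidate,) = _single_compound_candidates(truth, run, std_ruleset)

        # graft a shifted X+2 trace onto the otherwise compliant run
        shifted = ts.generate_run(
            ts.SyntheticTruth(
                [ts.PlantedCompound(
                    x_mz=350.0, rt_apex=69.0, model=model, height=2e6
                )],
                seed=3,
                rt_span=(0.0, 120.0),
            )
        )
        x2_mz = ts.expected_mz(350.0, 2)
        for scan, donor in zip(run.scans, shifted.scans):
            keep = np.abs(scan.mz - x2_mz) / x2_mz * 1e6 > 5
            take = np.abs(donor.mz - x2_mz) / x2_mz * 1e6 <= 5
            mz = np.concatenate([scan.mz[keep], donor.mz[take]])
            order = np.argsort(mz)
            scan.mz = mz[order]
            scan.intensity = np.concatenate([scan.intensity[keep], donor.intensity[take]])[order]
        features, rejections = ts.verify_feature(run, candidate, std_ruleset)
        assert features == []
        assert rejections and any(
            "coeluting" in r or "coelution" in r for r in rejections
        )

    def test_apex_only_ratio_compliance_fails_area_recheck(self, std_ruleset):
        """A half-width X+1 trace matches the ratios at the apex scan but its
        peak area is too small, so the area-domain re-evaluation rejects it."""
        model = ts.IncorporationModel(n_units=9, q=0.12, n_carbons=18)
        compound = ts.PlantedCompound(
            x_mz=350.0, rt_apex=60.0, model=model, height=2e6,
            decoy_violation="narrow_satellite",
        )
        truth = ts.SyntheticTruth([compound], seed=3, rt_span=(0.0, 120.0))
        run = ts.generate_run(truth)
        candidates = _single_compound_candidates(truth, run, std_ruleset)
        assert candidates, "apex scans should pass the scan-level rules"
        features, rejections = ts.verify_feature(run, candidates[0], std_ruleset)
        assert features == []
        assert any("area re-check" in r for r in rejections)

    def test_no_x_peak_is_reported(self, std_ruleset):
        truth = ts.SyntheticTruth(compounds=[], seed=1, rt_span=(0.0, 60.0))
        run = ts.generate_run(truth)
        candidate = ts.FeatureCandidate(mean_mz=300.0, rt_window=(20.0, 30.0), members=[])
        features, rejections = ts.verify_feature(run, candidate, std_ruleset)
        assert features == []
        assert any("no chromatographic peak" in r for r in rejections)

    def test_scanlevel_pass_apex_is_implied_by_feature_pass(self, std_ruleset):
        model = ts.IncorporationModel(n_units=9, q=0.10, n_carbons=18)
        compound = ts.PlantedCompound(x_mz=420.0, rt_apex=50.0, model=model, height=2e6)
        truth = ts.SyntheticTruth([compound], seed=9, rt_span=(0.0, 100.0))
        run = ts.generate_run(truth)
        (candidate,) = _single_compound_candidates(truth, run, std_ruleset)
        features, _ = ts.verify_feature(run, candidate, std_ruleset)
        assert features
        apex_scan = min(run.scans, key=lambda s: abs(s.rt - features[0].apex_rt))
        scan_hits = ts.screen_scan(apex_scan, std_ruleset)
        assert any(abs(c.x_mz - 420.0) < 0.01 for c in scan_hits)
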