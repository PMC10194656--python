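"""Feature extraction: peak, post-peak log-slope series, (tau, kmax)."""

import numpy as np
import pytest

from kadirect import (ConcProfile, disposition_slopes, extract_features,
                      find_tmax_cmax, locate_kmax)
from kadirect.exceptions import NoTwoCompartmentSignatureError, ProfileError
from kadirect.pkmodels import hybrid_constants
from kadirect.study import SETTING_LEVELS, StudyConfig, build_grid, simulate_group
from tests.conftest import GROUP_MEDIUM


class TestFindTmax:
    def test_medium_group_peaks_at_two_hours(self, medium_profile):
        tmax, cmax = find_tmax_cmax(medium_profile)
        assert tmax == pytest.approx(2.0)
        assert cmax > 0

    def test_slow_group_peaks_late(self, slow_profile):
        tmax, _ = find_tmax_cmax(slow_profile)
        assert tmax == pytest.approx(3.4)

    def test_interior_spike(self):
        tmax, cmax = find_tmax_cmax(ConcProfile([0, 1, 2], [0, 1, 0]))
        assert (tmax, cmax) == (1.0, 1.0)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ProfileError):
            find_tmax_cmax(ConcProfile([0, 1, 2], [0, 0, 0]))

    def test_exact_ties_resolve_to_latest(self):
        tmax, _ = find_tmax_cmax(ConcProfile([0, 1, 2, 3], [0, 5, 5, 1]))
        assert tmax == 2.0


class TestDispositionSlopes:
    def test_mono_exponential_gives_constant_slope(self):
        t = np.array([1.0, 2.0, 3.0])
        series = disposition_slopes(ConcProfile(t, np.exp(-0.3 * t)), tmax=0.0)
        assert np.allclose(series.slopes, 0.3)
        assert np.allclose(series.interval_starts, [1.0, 2.0])

    def test_decreasing_sequence_has_positive_slopes(self):
        t = np.arange(6.0)
        series = disposition_slopes(ConcProfile(t, [9, 7, 5, 3.1, 2, 1.5]), tmax=0.0)
        assert np.all(series.slopes > 0)

    def test_requires_two_positive_post_peak_points(self):
        with pytest.raises(ProfileError):
            disposition_slopes(ConcProfile([0, 1, 2], [1, 2, 3]), tmax=1.5)

    def test_nonpositive_concentrations_dropped(self):
        t = np.arange(6.0)
        c = np.array([5, 4, 0.0, 2, 1, 0.5])
        series = disposition_slopes(ConcProfile(t, c), tmax=0.0)
        # intervals touching the zero sample vanish
        assert len(series.slopes) == 2

    def test_slope_series_tracks_analytic_disposition_rate(self, medium_profile):
        # oracle: the apparent rate -C'(t)/C(t) from the closed form
        series = disposition_slopes(medium_profile, tmax=2.0)
        p = GROUP_MEDIUM
        hyb = hybrid_constants(p)

        def neg_dlnc(t):
            rs = np.array([p.ka, hyb.alpha, hyb.beta])
            k21 = p.k21
            coef = np.array([
                (k21 - p.ka) / ((hyb.alpha - p.ka) * (hyb.beta - p.ka)),
                (k21 - hyb.alpha) / ((p.ka - hyb.alpha) * (hyb.beta - hyb.alpha)),
                (k21 - hyb.beta) / ((p.ka - hyb.beta) * (hyb.alpha - hyb.beta)),
            ])
            num = np.sum(coef * rs * np.exp(-rs * t))
            den = np.sum(coef * np.exp(-rs * t))
            return num / den

        mid = 0.5 * (series.interval_starts + series.interval_ends)
        analytic = np.array([neg_dlnc(t) for t in mid])
        assert np.allclose(series.slopes, analytic, atol=2e-4)
        # rises to a peak near t=5 then declines toward beta
        assert series.slopes[np.argmax(series.slopes)] > series.slopes[0]
        assert series.slopes[-1] == pytest.approx(hyb.beta, rel=0.05)


class TestLocateKmax:
    def test_medium_group_printed_values(self, medium_profile):
        series = disposition_slopes(medium_profile, tmax=2.0)
        tau, kmax = locate_kmax(series)
        assert tau == pytest.approx(5.0, abs=0.1)
        assert kmax == pytest.approx(0.211, abs=0.002)

    def test_slow_group_printed_kmax(self, slow_profile):
        series = disposition_slopes(slow_profile, tmax=3.4)
        tau, kmax = locate_kmax(series)
        assert kmax == pytest.approx(0.148, abs=0.002)
        assert tau == pytest.approx(9.9, abs=0.11)

    def test_mono_exponential_has_no_signature(self):
        t = np.linspace(1, 30, 40)
        series = disposition_slopes(ConcProfile(t, 10 * np.exp(-0.2 * t)), tmax=0.0)
        with pytest.raises(NoTwoCompartmentSignatureError):
            locate_kmax(series)

    def test_right_endpoint_convention_is_one_step_later(self, medium_profile):
        series = disposition_slopes(medium_profile, tmax=2.0)
        tau_l, k_l = locate_kmax(series, tau_convention="left")
        tau_r, k_r = locate_kmax(series, tau_convention="right")
        assert k_l == k_r
        assert tau_r == pytest.approx(tau_l + 0.1)


# printed feature rows of the validation table: (ka,k12,k21,k10) -> (tmax,tau,kmax)
PRINTED_FEATURES = {
    (1.098, 0.525, 0.176, 0.571): (0.9, 2.5, 0.507),
    (1.098, 0.525, 0.176, 0.271): (1.1, 2.7, 0.360),
    (1.098, 0.525, 0.176, 0.100): (1.3, 2.8, 0.261),
    (1.098, 0.525, 0.067, 0.571): (0.9, 3.0, 0.627),
    (1.098, 0.525, 0.067, 0.271): (1.1, 3.1, 0.476),
    (1.098, 0.525, 0.067, 0.100): (1.2, 3.2, 0.373),
    (1.098, 0.525, 0.025, 0.571): (0.9, 3.5, 0.722),
    (1.098, 0.525, 0.025, 0.271): (1.1, 3.7, 0.566),
    (1.098, 0.525, 0.025, 0.100): (1.2, 3.9, 0.457),
    (1.098, 0.211, 0.176, 0.571): (1.1, 3.3, 0.484),
    (1.098, 0.211, 0.176, 0.271): (1.4, 3.5, 0.291),
    (1.098, 0.211, 0.176, 0.100): (1.7, 3.7, 0.164),
    (1.098, 0.211, 0.067, 0.571): (1.1, 3.8, 0.559),
    (1.098, 0.211, 0.067, 0.271): (1.4, 4.0, 0.353),
    (1.098, 0.211, 0.067, 0.100): (1.6, 4.1, 0.220),
    (1.098, 0.211, 0.025, 0.571): (1.1, 4.4, 0.620),
    (1.098, 0.211, 0.025, 0.271): (1.3, 4.7, 0.403),
    (1.098, 0.211, 0.025, 0.100): (1.6, 4.8, 0.259),
    (1.098, 0.133, 0.067, 0.571): (1.1, 4.2, 0.543),
    (1.098, 0.133, 0.067, 0.271): (1.5, 4.4, 0.320),
    (1.098, 0.133, 0.067, 0.100): (1.8, 4.5, 0.176),
    (1.098, 0.133, 0.025, 0.571): (1.1, 4.8, 0.590),
    (1.098, 0.133, 0.025, 0.271): (1.4, 5.1, 0.354),
    (1.098, 0.133, 0.025, 0.100): (1.8, 5.2, 0.202),
    (0.603, 0.211, 0.176, 0.271): (2.0, 5.0, 0.211),
    (0.603, 0.211, 0.176, 0.100): (2.5, 5.3, 0.114),
    (0.603, 0.211, 0.067, 0.271): (1.9, 5.5, 0.273),
    (0.603, 0.211, 0.067, 0.100): (2.4, 5.8, 0.171),
    (0.603, 0.211, 0.025, 0.271): (1.9, 6.4, 0.325),
    (0.603, 0.211, 0.025, 0.100): (2.3, 6.8, 0.218),
    (0.603, 0.133, 0.067, 0.271): (2.1, 6.2, 0.259),
    (0.603, 0.133, 0.067, 0.100): (2.7, 6.5, 0.144),
    (0.603, 0.133, 0.025, 0.271): (2.0, 7.2, 0.300),
    (0.603, 0.133, 0.025, 0.100): (2.6, 7.6, 0.177),
    (0.375, 0.211, 0.176, 0.100): (3.5, 7.1, 0.077),
    (0.375, 0.211, 0.067, 0.100): (3.1, 7.4, 0.127),
    (0.375, 0.211, 0.025, 0.100): (3.0, 8.5, 0.173),
    (0.375, 0.133, 0.067, 0.100): (3.5, 8.6, 0.113),
    (0.375, 0.133, 0.025, 0.100): (3.4, 9.9, 0.148),
}


@pytest.fixture(scope="module")
def grid_features():
    cfg = StudyConfig(run_fits=False)
    out = {}
    for params in build_grid(SETTING_LEVELS):
        profile = simulate_group(params, cfg)
        out[(params.ka, params.k12, params.k21, params.k10)] = (
            extract_features(profile), params)
    return out


class TestGridFeatureRegression:
    def test_printed_kmax_and_tau_reproduced(self, grid_features):
        """kmax within 0.002 1/h everywhere; tau within one grid step on all
        but the flattest maximum. Group (0.375, 0.211, 0.025, 0.100) has
        adjacent interval slopes equal to <2e-4, and the recomputed maximum
        sits two steps after the tabulated one — documented, not hidden."""
        off_by_two = 0
        for key, (printed_t, printed_tau, printed_kmax) in PRINTED_FEATURES.items():
            feats, _ = grid_features[key]
            assert feats.kmax == pytest.approx(printed_kmax, abs=0.002), key
            assert feats.tau == pytest.approx(printed_tau, abs=0.201), key
            if abs(feats.tau - printed_tau) > 0.101:
                off_by_two += 1
        assert off_by_two <= 1

    def test_tau_endpoint_calibration(self, grid_features):
        """Calibration of the tau endpoint convention against the tabulated
        (tau, kmax) pairs: the left endpoint of the maximizing interval
        matches far more rows than the right endpoint, and is therefore the
        documented default."""
        cfg = StudyConfig(run_fits=False)
        hits = {"left": 0, "right": 0}
        for key, (_, params) in grid_features.items():
            profile = simulate_group(params, cfg)
            printed_tau = PRINTED_FEATURES[key][1]
            for conv in ("left", "right"):
                feats = extract_features(profile, tau_convention=conv)
                if abs(feats.tau - printed_tau) < 0.05:
                    hits[conv] += 1
        assert hits["left"] > hits["right"]
        assert hits["left"] >= 26  # exact agreement on the clear-cut rows

    def test_kmax_between_terminal_and_total_removal_rate(self, grid_features):
        for key, (feats, params) in grid_features.items():
            beta = hybrid_constants(params).beta
            assert beta < feats.kmax < params.k12 + params.k10, key

    def test_tau_always_after_peak(self, grid_features):
        for key, (feats, _) in grid_features.items():
            assert feats.tau > feats.tmax, key
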