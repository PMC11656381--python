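import numpy as np
import pytest

from specdecon import Spectrum, cost, detect_peaks, fit, model_sum, profile_eval
from specdecon.profiles import ProfileParams
from specdecon.synth import GroundTruth, make_spectrum


def _spectrum_from(components, x_min=0.0, x_max=100.0, n=2000,
                   noise_sigma=0.0, seed=0):
    gt = GroundTruth(components=tuple(components), noise_sigma=noise_sigma,
                     seed=seed)
    s, gt = make_spectrum(gt, x_min, x_max, n)
    return s, gt


def _detect(s):
    return detect_peaks(s, 45, threshold=0.05, min_amplitude=0.05)


def _detect_clean(s, gt):
    """Seed positions from the noise-free model: these tests measure the
    optimizer's recovery on noisy data, not detector robustness."""
    clean = Spectrum(s.x, gt.clean_signal(s.x))
    return _detect(clean)


TRUTHS = {
    "gaussian": [
        ProfileParams("gaussian", 25.0, 1.0, sigma=2.0),
        ProfileParams("gaussian", 50.0, 0.7, sigma=2.5),
        ProfileParams("gaussian", 75.0, 0.9, sigma=1.8),
    ],
    "lorentzian": [
        ProfileParams("lorentzian", 25.0, 1.0, gamma=1.5),
        ProfileParams("lorentzian", 50.0, 0.7, gamma=2.0),
        ProfileParams("lorentzian", 75.0, 0.9, gamma=1.6),
    ],
    "voigt": [
        ProfileParams("voigt", 25.0, 1.0, sigma=1.2, gamma=0.8),
        ProfileParams("voigt", 50.0, 0.7, sigma=1.5, gamma=1.0),
        ProfileParams("voigt", 75.0, 0.9, sigma=1.0, gamma=1.2),
    ],
}


class TestProfiles:
    def test_gaussian_value_at_center_is_amplitude(self):
        p = ProfileParams("gaussian", 5.0, 0.8, sigma=1.0)
        assert profile_eval(p, np.array([5.0]))[0] == pytest.approx(0.8)

    def test_lorentzian_half_height_at_gamma(self):
        p = ProfileParams("lorentzian", 0.0, 1.0, gamma=2.5)
        vals = profile_eval(p, np.array([-2.5, 0.0, 2.5]))
        np.testing.assert_allclose(vals, [0.5, 1.0, 0.5])

    def test_voigt_gaussian_limit(self):
        x = np.linspace(-10, 10, 501)
        v = profile_eval(ProfileParams("voigt", 0.0, 1.0, sigma=2.0,
                                       gamma=1e-8), x)
        g = profile_eval(ProfileParams("gaussian", 0.0, 1.0, sigma=2.0), x)
        np.testing.assert_allclose(v, g, atol=1e-6)

    def test_voigt_lorentzian_limit(self):
        x = np.linspace(-10, 10, 501)
        v = profile_eval(ProfileParams("voigt", 0.0, 1.0, sigma=1e-9,
                                       gamma=2.0), x)
        lor = profile_eval(ProfileParams("lorentzian", 0.0, 1.0, gamma=2.0), x)
        np.testing.assert_allclose(v, lor, atol=1e-6)

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError):
            ProfileParams("gaussian", 0.0, 1.0, sigma=0.0)
        with pytest.raises(ValueError):
            ProfileParams("lorentzian", 0.0, 1.0, gamma=-1.0)

    def test_model_sum_linearity(self):
        x = np.linspace(0, 10, 101)
        p = ProfileParams("gaussian", 5.0, 1.0, sigma=1.0)
        one = model_sum([p], x)
        np.testing.assert_allclose(model_sum([p, p], x), 2 * one)
        np.testing.assert_allclose(one, profile_eval(p, x))

    def test_disjoint_components_max_is_componentwise_max(self):
        x = np.linspace(0, 100, 4001)
        comps = [
            ProfileParams("gaussian", 20.0, 1.0, sigma=0.5),
            ProfileParams("gaussian", 80.0, 0.6, sigma=0.5),
        ]
        total = model_sum(comps, x)
        assert total.max() == pytest.approx(1.0, abs=1e-6)


class TestCost:
    def test_exact_model_costs_zero_for_every_loss(self):
        x = np.linspace(0, 100, 500)
        comps = TRUTHS["gaussian"]
        s_hat = model_sum(comps, x)
        for loss in ("linear", "soft_l1", "huber", "arctan"):
            assert cost(comps, s_hat, x, loss) == pytest.approx(0.0, abs=1e-20)

    def test_linear_loss_is_sum_of_squares(self, rng):
        x = np.linspace(0, 100, 300)
        comps = TRUTHS["gaussian"]
        s_hat = model_sum(comps, x) + rng.normal(0, 0.1, 300)
        r = model_sum(comps, x) - s_hat
        assert cost(comps, s_hat, x, "linear") == pytest.approx(np.sum(r**2))

    def test_soft_l1_never_exceeds_linear(self, rng):
        x = np.linspace(0, 100, 300)
        comps = TRUTHS["gaussian"]
        s_hat = model_sum(comps, x) + rng.normal(0, 0.5, 300)
        assert (cost(comps, s_hat, x, "soft_l1")
                <= cost(comps, s_hat, x, "linear"))

    def test_unknown_loss_rejected(self):
        x = np.linspace(0, 10, 50)
        with pytest.raises(ValueError):
            cost(TRUTHS["gaussian"], np.zeros(50), x, "cauchy")


class TestFit:
    @pytest.mark.parametrize("family", ["gaussian", "lorentzian", "voigt"])
    def test_noiseless_parameter_recovery(self, family):
        truth = TRUTHS[family]
        s, _ = _spectrum_from(truth)
        ps = _detect(s)
        assert len(ps) == 3
        dec = fit(s, ps, family=family, loss="linear", max_iter=200)
        h = s.grid_step()
        for t, f in zip(truth, sorted(dec.components, key=lambda c: c.center)):
            assert abs(f.center - t.center) < 1e-3 * h
            assert abs(f.amplitude - t.amplitude) / t.amplitude < 0.01
            if t.sigma is not None:
                assert abs(f.sigma - t.sigma) / t.sigma < 0.02
            if t.gamma is not None:
                assert abs(f.gamma - t.gamma) / t.gamma < 0.02

    def test_noisy_center_recovery_within_half_step(self):
        truth = TRUTHS["gaussian"]
        s, gt = _spectrum_from(truth, noise_sigma=0.01, seed=7)
        ps = _detect_clean(s, gt)
        dec = fit(s, ps, family="gaussian", loss="linear", max_iter=200)
        h = s.grid_step()
        fitted = np.sort([c.center for c in dec.components])
        assert np.all(np.abs(fitted - [25.0, 50.0, 75.0]) < 0.5 * h)

    def test_warm_start_at_truth_is_fixed_point(self):
        truth = TRUTHS["gaussian"]
        s, _ = _spectrum_from(truth)
        ps = _detect(s)
        from specdecon.decompose import Decomposition
        warm = Decomposition(components=list(truth), family="gaussian",
                             loss="linear", cost=0.0, n_iter=0,
                             reconstruction=np.empty(0))
        dec = fit(s, ps, family="gaussian", loss="linear", max_iter=50,
                  warm_start=warm)
        assert dec.cost < 1e-10
        for t, f in zip(truth, dec.components):
            assert abs(f.center - t.center) < 1e-6
            assert abs(f.amplitude - t.amplitude) < 1e-6
            assert abs(f.sigma - t.sigma) < 1e-6

    def test_chained_warm_starts_never_increase_cost(self):
        truth = TRUTHS["lorentzian"]
        s, gt = _spectrum_from(truth, noise_sigma=0.005, seed=3)
        ps = _detect_clean(s, gt)
        costs = []
        dec = None
        for _ in range(4):
            dec = fit(s, ps, family="lorentzian", loss="soft_l1",
                      max_iter=8, warm_start=dec)
            costs.append(dec.cost)
        assert all(c2 <= c1 + 1e-12 for c1, c2 in zip(costs, costs[1:]))

    def test_fit_does_not_exceed_initial_cost(self):
        truth = TRUTHS["gaussian"]
        s, gt = _spectrum_from(truth, noise_sigma=0.02, seed=5)
        ps = _detect_clean(s, gt)
        from specdecon.decompose import _initial_components
        init = _initial_components(s, ps, "gaussian")
        c0 = cost(init, s.y, s.x, "linear")
        dec = fit(s, ps, family="gaussian", loss="linear", max_iter=100)
        assert dec.cost <= c0 + 1e-12

    def test_voigt_family_fits_voigt_signal_best(self):
        truth = TRUTHS["voigt"]
        s, _ = _spectrum_from(truth)
        ps = _detect(s)
        results = {
            fam: fit(s, ps, family=fam, loss="linear", max_iter=300).cost
            for fam in ("voigt", "lorentzian", "gaussian")
        }
        assert results["voigt"] <= results["lorentzian"]
        assert results["voigt"] <= results["gaussian"]

    def test_reconstruction_matches_model_sum(self):
        truth = TRUTHS["gaussian"]
        s, _ = _spectrum_from(truth)
        ps = _detect(s)
        dec = fit(s, ps, family="gaussian", max_iter=100)
        np.testing.assert_array_equal(
            dec.reconstruction, model_sum(dec.components, s.x)
        )

    def test_single_gaussian_matches_moment_estimate(self):
        comp = ProfileParams("gaussian", 40.0, 1.0, sigma=3.0)
        s, _ = _spectrum_from([comp])
        ps = detect_peaks(s, 45, 0.05, 0.05)
        dec = fit(s, ps, family="gaussian", max_iter=200)
        f = dec.components[0]
        # closed-form moments of the sampled profile
        c_m = np.sum(s.x * s.y) / np.sum(s.y)
        sigma_m = np.sqrt(np.sum(s.y * (s.x - c_m) ** 2) / np.sum(s.y))
        assert abs(f.center - c_m) < 1e-6
        assert abs(f.sigma - sigma_m) < 1e-3

    def test_no_peaks_rejected(self):
        s, _ = _spectrum_from(TRUTHS["gaussian"])
        from specdecon.peaks import PeakSet
        with pytest.raises(ValueError):
            fit(s, PeakSet(peaks=()), family="gaussian")

    def test_unknown_family_rejected(self):
        s, _ = _spectrum_from(TRUTHS["gaussian"])
        ps = _detect(s)
        with pytest.raises(ValueError):
            fit(s, ps, family="pseudovoigt")
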