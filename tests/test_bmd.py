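"""Benchmark-dose engine: fitting, GOF screening, BMD root, model averaging."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ivive.bmd import (
    BMDModelFit,
    BMDNotReached,
    BMRSpec,
    DoseResponseData,
    bmd_from_fit,
    fit_all,
    fit_model,
    goodness_of_fit,
    model_average,
)

DOSES = np.array([0.0, 1.0, 2.5, 5.0, 10.0])


def exp5_truth(x, a=100.0, b=0.04, c=0.2, d=1.2):
    x = np.asarray(x, dtype=float)
    return a * (c + (1.0 - c) * np.exp(-b * x**d))


def clean_data(sd=1e-4, n=5):
    return DoseResponseData(
        doses=DOSES, means=exp5_truth(DOSES), sds=np.full(DOSES.size, sd),
        ns=np.full(DOSES.size, n),
    )


def noisy_data(seed=1, sd=5.0, n=5):
    rng = np.random.default_rng(seed)
    means = rng.normal(exp5_truth(DOSES), sd / np.sqrt(n))
    sds = sd * np.sqrt(rng.chisquare(n - 1, DOSES.size) / (n - 1))
    return DoseResponseData(doses=DOSES, means=means, sds=sds, ns=np.full(DOSES.size, n))


class TestFitModel:
    def test_recovers_generating_curve_parameters(self):
        """Noise-free data on an exponential curve are recovered within 1%."""
        fit = fit_model(clean_data(), "exponential-5")
        assert fit.params["a"] == pytest.approx(100.0, rel=0.01)
        assert fit.params["b"] == pytest.approx(0.04, rel=0.01)
        assert fit.params["c"] == pytest.approx(0.2, rel=0.01)
        assert fit.params["d"] == pytest.approx(1.2, rel=0.01)

    def test_flat_data_yields_no_bmr_crossing(self):
        data = DoseResponseData(
            doses=DOSES, means=np.full(5, 100.0), sds=np.full(5, 5.0),
            ns=np.full(5, 5),
        )
        fit = fit_model(data, "exponential-3")
        # potency collapses: the curve is essentially flat over the dose range
        drop = fit.predict(np.array([0.0]))[0] - fit.predict(np.array([10.0]))[0]
        assert abs(drop) < 1e-3 * 100.0
        assert fit.bmd_point is None

    def test_fitted_curve_is_decreasing(self):
        fit = fit_model(noisy_data(seed=2), "hill-5")
        x = np.linspace(0, 10, 50)
        y = fit.predict(x)
        assert np.all(np.diff(y) <= 1e-9)

    def test_requires_three_groups(self):
        data = DoseResponseData(
            doses=np.array([0.0, 1.0]), means=np.array([100.0, 90.0]),
            sds=np.array([5.0, 5.0]), ns=np.array([5, 5]),
        )
        with pytest.raises(ValueError):
            fit_model(data, "exponential-3")

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError, match="unknown family"):
            fit_model(noisy_data(), "polynomial-2")


class TestGoodnessOfFit:
    def test_saturated_like_fit_has_p_one(self):
        """A model that interpolates the group means gets p ~= 1."""
        fit = fit_model(clean_data(sd=1.0), "exponential-5")
        p = goodness_of_fit(fit, clean_data(sd=1.0))
        assert p > 0.99

    def test_flat_model_on_decreasing_data_rejected(self):
        data = noisy_data(seed=3)
        flat = BMDModelFit(
            family="exponential-3",
            params={"a": 100.0, "b": 0.0, "d": 1.0},
            sigma=5.0, loglik=0.0, aic=0.0, gof_p=None, gof_df=2,
            bmd_point=None, n_curve_params=3, xscale=10.0, yscale=100.0,
            theta_internal=np.array([1.0, -16.0, 1.0]),
        )
        assert goodness_of_fit(flat, data) < 0.05

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_p_value_in_unit_interval(self, seed):
        for fit in fit_all(noisy_data(seed=seed)):
            assert 0.0 <= fit.gof_p <= 1.0


class TestBmdFromFit:
    def test_matches_independent_root_finder(self):
        """BMD equals the root of f(0) - f(x) = BMR * SD found independently."""
        fit = fit_model(noisy_data(seed=5), "exponential-3")
        a, b, d = fit.params["a"], fit.params["b"], fit.params["d"]
        sd = 4.0
        expected = brentq(
            lambda x: a - a * np.exp(-b * x**d) - sd, 1e-12, 1e3, rtol=1e-10
        )
        got = bmd_from_fit(fit, BMRSpec(magnitude=1.0), background_sd=sd)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_bmd_vanishes_with_bmr(self):
        fit = fit_model(noisy_data(seed=5), "exponential-3")
        bmds = [
            bmd_from_fit(fit, BMRSpec(magnitude=m), background_sd=1.0)
            for m in (1.0, 0.1, 0.01, 0.001)
        ]
        assert all(np.diff(bmds) < 0) and bmds[-1] < 1e-2 * bmds[0]

    def test_unreachable_bmr_raises(self):
        fit = fit_model(clean_data(sd=1.0), "exponential-5")
        # maximum decline is 80% of control; ask for far more
        with pytest.raises(BMDNotReached):
            bmd_from_fit(fit, BMRSpec(magnitude=1.0), background_sd=500.0)


class TestModelAverage:
    def test_degenerate_bootstrap_is_tight(self):
        """Single accepted fit on near-noise-free data: spread below 2%."""
        data = clean_data(sd=1e-3)
        fit = fit_model(data, "exponential-5")
        res = model_average([fit], data, n_boot=400, seed=11)
        assert res.bmdu / res.bmdl < 1.02
        assert res.bmdl <= res.bmd <= res.bmdu

    def test_two_identical_fits_match_single(self):
        data = noisy_data(seed=6)
        fit = fit_model(data, "exponential-5")
        one = model_average([fit], data, n_boot=200, seed=9)
        two = model_average([fit, fit], data, n_boot=200, seed=9)
        assert two.bmd == pytest.approx(one.bmd, rel=1e-9)
        assert two.bmdl == pytest.approx(one.bmdl, rel=0.05)
        assert two.bmdu == pytest.approx(one.bmdu, rel=0.05)

    def test_ordering_invariant(self):
        data = noisy_data(seed=7)
        fits = [f for f in fit_all(data) if f.accepted]
        res = model_average(fits, data, n_boot=200, seed=1)
        assert res.bmdl <= res.bmd <= res.bmdu

    def test_seeded_reproducibility(self):
        data = noisy_data(seed=8)
        fits = [f for f in fit_all(data) if f.accepted]
        r1 = model_average(fits, data, n_boot=200, seed=5)
        r2 = model_average(fits, data, n_boot=200, seed=5)
        assert (r1.bmd, r1.bmdl, r1.bmdu) == (r2.bmd, r2.bmdl, r2.bmdu)

    def test_rejects_small_bootstrap(self):
        data = noisy_data(seed=8)
        fits = [f for f in fit_all(data) if f.accepted]
        with pytest.raises(ValueError):
            model_average(fits, data, n_boot=50, seed=1)


class TestScaleEquivariance:
    @pytest.mark.parametrize("k", [0.1, 10.0])
    def test_bmd_scales_with_dose_units(self, k):
        base = noisy_data(seed=10)
        scaled = DoseResponseData(
            doses=base.doses * k, means=base.means, sds=base.sds, ns=base.ns
        )
        for family in ("exponential-3", "hill-5"):
            f1 = fit_model(base, family)
            f2 = fit_model(scaled, family)
            b1 = bmd_from_fit(f1, BMRSpec(), f1.sigma)
            b2 = bmd_from_fit(f2, BMRSpec(), f2.sigma)
            assert b2 == pytest.approx(k * b1, rel=1e-6)


class TestAddedGroupOnCurve:
    def test_gof_not_materially_decreased(self):
        """Appending a group exactly on the fitted curve keeps the fit acceptable."""
        data = noisy_data(seed=12)
        fit = fit_model(data, "exponential-5")
        new_dose = 7.5
        new_mean = float(fit.predict(np.array([new_dose]))[0])
        augmented = DoseResponseData(
            doses=np.append(data.doses, new_dose),
            means=np.append(data.means, new_mean),
            sds=np.append(data.sds, fit.sigma),
            ns=np.append(data.ns, 5),
        )
        refit = fit_model(augmented, "exponential-5")
        assert refit.gof_p > fit.gof_p - 0.2
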