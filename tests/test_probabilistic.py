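import math

import numpy as np
import pytest

from pyrethroid_hbm.errors import DomainError, FitError
from pyrethroid_hbm.probabilistic import (
    BELGIAN_EXPOSURE_LOGLOGISTIC,
    DEFAULT_FUE_TRIANGULAR,
    FUE_WEIBULL,
    McSettings,
    cdf,
    derive_triangular_from_rates,
    fit_to_quantiles,
    loglogistic,
    mc_exceedance,
    mc_screening_distribution,
    point,
    quantile,
    survival,
    triangular,
    weibull,
)

LL = loglogistic(**BELGIAN_EXPOSURE_LOGLOGISTIC)
WB = weibull(**FUE_WEIBULL)
TRI = triangular(*DEFAULT_FUE_TRIANGULAR)


class TestClosedForms:
    def test_exposure_p95_brackets_the_reported_percentile(self):
        # analytic quantile α(p/(1−p))^(1/β) at p=0.95
        a, b = LL.params["scale"], LL.params["shape"]
        expected = a * (0.95 / 0.05) ** (1 / b)
        assert quantile(LL, 0.95) == pytest.approx(expected, rel=1e-12)
        assert quantile(LL, 0.95) == pytest.approx(7.22, abs=0.005)

    def test_loglogistic_median_is_the_scale(self):
        assert quantile(LL, 0.5) == pytest.approx(LL.params["scale"], rel=1e-12)

    def test_weibull_cdf_at_scale(self):
        assert cdf(WB, WB.params["scale"]) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_weibull_quantile_closed_form(self):
        k, lam = WB.params["shape"], WB.params["scale"]
        assert quantile(WB, 0.3) == pytest.approx(
            lam * (-math.log(1 - 0.3)) ** (1 / k), rel=1e-12
        )

    @pytest.mark.parametrize("dist", [LL, WB, TRI], ids=["loglogistic", "weibull", "triangular"])
    def test_cdf_quantile_inverse_identity(self, dist):
        grid = np.linspace(0.01, 0.99, 20)
        assert np.allclose(cdf(dist, quantile(dist, grid)), grid, atol=1e-10)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.4])
    def test_quantile_domain(self, p):
        with pytest.raises(DomainError):
            quantile(LL, p)


class TestFitToQuantiles:
    PROBS = (0.05, 0.25, 0.5, 0.75, 0.95)

    @pytest.mark.parametrize("truth", [loglogistic(2.0, 1.7), weibull(2.4009431, 0.3465461)])
    def test_round_trip_recovery(self, truth):
        pairs = [(p, quantile(truth, p)) for p in self.PROBS]
        fit = fit_to_quantiles(pairs, truth.family)
        assert fit.spec.params["shape"] == pytest.approx(truth.params["shape"], abs=1e-6)
        assert fit.spec.params["scale"] == pytest.approx(truth.params["scale"], abs=1e-6)
        assert fit.objective < 1e-12

    def test_two_points_exactly_determine_the_fit(self):
        truth = loglogistic(3.0, 2.0)
        pairs = [(0.25, quantile(truth, 0.25)), (0.9, quantile(truth, 0.9))]
        fit = fit_to_quantiles(pairs, "loglogistic")
        assert fit.objective == pytest.approx(0.0, abs=1e-18)
        assert fit.spec.params["shape"] == pytest.approx(3.0, rel=1e-9)

    def test_recovery_under_small_perturbation(self):
        rng = np.random.default_rng(11)
        truth = loglogistic(2.025207, 1.687245)
        pairs = [
            (p, quantile(truth, p) * (1 + rng.normal(0, 0.005))) for p in self.PROBS
        ]
        fit = fit_to_quantiles(pairs, "loglogistic")
        assert fit.spec.params["shape"] == pytest.approx(truth.params["shape"], rel=0.01)
        assert fit.spec.params["scale"] == pytest.approx(truth.params["scale"], rel=0.01)

    def test_linear_objective_agrees_on_exact_data(self):
        truth = weibull(1.8, 0.5)
        pairs = [(p, quantile(truth, p)) for p in self.PROBS]
        fit = fit_to_quantiles(pairs, "weibull", objective="linear")
        assert fit.spec.params["shape"] == pytest.approx(1.8, rel=1e-4)

    def test_non_monotone_pairs_rejected(self):
        with pytest.raises(FitError, match="increasing"):
            fit_to_quantiles([(0.25, 2.0), (0.75, 1.0)], "loglogistic")

    def test_single_pair_rejected(self):
        with pytest.raises(FitError):
            fit_to_quantiles([(0.5, 1.0)], "weibull")


class TestScreeningDistribution:
    def test_point_mass_reproduces_the_deterministic_value(self, registry):
        result = mc_screening_distribution(
            registry, "children", fue_dist=point(0.09),
            settings=McSettings(n_iterations=500, seed=1),
        )
        assert result.samples is not None
        assert np.allclose(result.samples, 3.1947, atol=0.001)

    def test_triangular_median_matches_analytic_oracle(self, registry):
        settings = McSettings(n_iterations=10_000, seed=7)
        result = mc_screening_distribution(registry, "children", settings=settings)
        lo, mode, hi = DEFAULT_FUE_TRIANGULAR
        # analytic triangular median (upper piece)
        median_fue = hi - math.sqrt((1 - 0.5) * (hi - lo) * (hi - mode))
        base_per_fue = 3.194707 / 0.09
        expected = base_per_fue * median_fue
        assert result.sample_quantiles["p50"] == pytest.approx(expected, rel=0.02)

    def test_default_iteration_count_is_ten_thousand(self):
        assert McSettings().n_iterations == 10_000


class TestExceedance:
    def test_point_fue_matches_loglogistic_survival_oracle(self, registry):
        settings = McSettings(n_iterations=10_000, seed=5)
        result = mc_exceedance(LL, point(0.307), registry, settings)
        gv = 3.194707 / 0.09 * 0.307
        oracle = survival(LL, gv)
        assert abs(result.exceedance_probability - oracle) < 3 * result.diagnostics["mcse"]
        # with a point fraction the central and joint estimates coincide
        assert result.exceedance_probability == result.diagnostics["joint_exceedance"]

    def test_weibull_central_estimate_near_two_percent(self, registry):
        result = mc_exceedance(LL, WB, registry, McSettings(n_iterations=10_000, seed=5))
        assert result.exceedance_probability == pytest.approx(0.0224, abs=0.005)
        # joint integration over the fraction's uncertainty sits below 5%
        assert 0.03 < result.diagnostics["joint_exceedance"] < 0.07

    def test_mixed_adi_band_below_single_most_toxic(self, registry):
        single = mc_exceedance(LL, WB, registry, McSettings(seed=9))
        mixed = mc_exceedance(
            LL, WB, registry, McSettings(seed=9, scenario="mixed_adi")
        )
        assert mixed.exceedance_probability < single.exceedance_probability
        assert mixed.diagnostics["exceedance_min_substance"] <= 0.001
        assert mixed.diagnostics["exceedance_max_substance"] == pytest.approx(
            single.exceedance_probability, abs=0.01
        )

    def test_unreachable_guidance_value_gives_zero(self, registry):
        # a point exposure far below any guidance value can never exceed it
        result = mc_exceedance(
            point(1e-6), point(0.307), registry, McSettings(n_iterations=100, seed=0)
        )
        assert result.exceedance_probability == 0.0

    def test_seeded_runs_are_bit_identical(self, registry):
        a = mc_exceedance(LL, WB, registry, McSettings(seed=123))
        b = mc_exceedance(LL, WB, registry, McSettings(seed=123))
        assert a.exceedance_probability == b.exceedance_probability
        assert a.diagnostics == b.diagnostics
        assert a.sample_quantiles == b.sample_quantiles

    def test_monotone_non_increasing_in_adi(self, registry):
        """Raising the ADI raises the guidance value and cannot raise risk."""
        from pyrethroid_hbm.registry import Registry, SubstanceRecord

        previous = None
        for adi_scale in (1.0, 2.0, 4.0, 8.0):
            subs = dict(registry.substances)
            ref = subs["lambda-cyhalothrin"]
            subs["lambda-cyhalothrin"] = SubstanceRecord(
                id=ref.id, adi=ref.adi * adi_scale, mw_parent=ref.mw_parent,
                adi_source=ref.adi_source, approved_uses=ref.approved_uses,
                assessable=ref.assessable,
            )
            scaled = Registry(
                substances=subs, metabolites=registry.metabolites,
                fues=registry.fues, populations=registry.populations,
            )
            result = mc_exceedance(LL, WB, scaled, McSettings(seed=21))
            if previous is not None:
                assert result.exceedance_probability <= previous + 1e-12
            previous = result.exceedance_probability

    def test_monotone_non_increasing_in_fue(self, registry):
        previous = None
        for fue in (0.1, 0.2, 0.4, 0.8):
            result = mc_exceedance(LL, point(fue), registry, McSettings(seed=22))
            if previous is not None:
                assert result.exceedance_probability <= previous + 1e-12
            previous = result.exceedance_probability


def test_triangular_from_pooled_rates():
    spec = derive_triangular_from_rates([0.09, 0.13, 0.15, 0.16, 0.25, 0.27, 0.37, 0.39, 0.46, 0.85])
    assert spec.family == "triangular"
    assert spec.params["min"] == 0.09
    assert spec.params["min"] <= spec.params["mode"] <= spec.params["max"]
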