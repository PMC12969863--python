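"""Design construction, IRLS gamma GLM, stepwise selection, rate ratios."""

import math

import numpy as np
import pytest

from itnvalue.price_model import (
    CollinearityError,
    GlmFit,
    ItnPriceModel,
    ModelSpec,
    backward_eliminate,
    build_design,
    fit_design,
    fit_gamma_glm,
    rate_ratio,
)
from itnvalue.records import NetType, Region
from itnvalue.synthetic import DEFAULT_TRUTH, MarketScenarioConfig, generate_transactions


def _truth_vector(columns):
    return np.array([DEFAULT_TRUTH.get(c, 0.0) for c in columns])


class TestBuildDesign:
    def test_reference_cell_has_only_intercept_and_continuous(self, rec):
        r = rec(year=2010, net_type=NetType.PYRETHROID, region=Region.SSA)
        d = build_design([r], ModelSpec(brand_mode="omit"),
                         market_size_by_year={2010: 100.0}, hhi_by_year={2010: 2500.0})
        row = dict(zip(d.columns, d.X[0]))
        # pre-regime SSA pyrethroid: every dummy and regime interaction is 0
        assert row["net_type[PBO]"] == 0 and row["net_type[DUAL_AI]"] == 0
        assert row["gfmss"] == 0
        assert row["oil_tens:gfmss[present]"] == 0
        assert row["nets_shipped_millions:gfmss[present]"] == 0
        assert all(v == 0 for c, v in row.items() if c.startswith("region["))
        assert row["intercept"] == 1
        assert row["area_m2"] == 15.0

    def test_pbo_dummy_coding(self, rec):
        d = build_design([rec(net_type=NetType.PBO)], ModelSpec(brand_mode="omit"))
        row = dict(zip(d.columns, d.X[0]))
        assert row["net_type[PBO]"] == 1.0 and row["net_type[DUAL_AI]"] == 0.0

    def test_continuous_scalings(self, rec):
        r = rec(year=2018, oil_price_real=65.0, quantity=80_000_000)
        d = build_design([r], ModelSpec(brand_mode="omit"), hhi_by_year={2018: 2500.0})
        row = dict(zip(d.columns, d.X[0]))
        assert row["hhi_thousands"] == pytest.approx(2.5)  # HHI in thousands
        assert row["oil_tens:gfmss[present]"] == pytest.approx(6.5)  # tens of USD/bbl
        assert row["nets_shipped_millions"] == pytest.approx(80.0)  # millions of nets

    def test_hhi_lag_uses_previous_year(self, rec):
        records = [rec(year=2017), rec(year=2018)]
        d = build_design(records, ModelSpec(brand_mode="omit"),
                         hhi_by_year={2017: 4000.0, 2018: 1000.0})
        col = d.columns.index("hhi_thousands")
        # 2017 (first year) falls back on itself; 2018 sees 2017's HHI
        assert d.X[0, col] == pytest.approx(4.0)
        assert d.X[1, col] == pytest.approx(4.0)

    def test_untreated_level_rejected(self, rec):
        with pytest.raises(ValueError, match="UNTREATED"):
            build_design([rec(net_type=NetType.UNTREATED)], ModelSpec(brand_mode="omit"))

    def test_missing_real_price_rejected(self, rec):
        with pytest.raises(ValueError, match="deflate"):
            build_design([rec(unit_price_real=None)], ModelSpec(brand_mode="omit"))

    def test_brand_modes_add_columns(self, rec):
        records = [rec(brand=f"Acme-B{i}") for i in (1, 2, 3)]
        omit = build_design(records, ModelSpec(brand_mode="omit"))
        fixed = build_design(records, ModelSpec(brand_mode="fixed"))
        ridge = build_design(records, ModelSpec(brand_mode="ridge"))
        assert len(fixed.columns) == len(omit.columns) + 2  # reference level dropped
        assert len(ridge.columns) == len(omit.columns) + 3
        assert len(ridge.penalized) == 3 and fixed.penalized == ()


class TestFitGammaGlm:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(5.0, 0.5, size=200)
        fit = fit_gamma_glm(np.ones((200, 1)), y, columns=["intercept"])
        assert fit.beta[0] == pytest.approx(math.log(y.mean()), abs=1e-10)
        assert fit.converged

    def test_binary_covariate_closed_form(self):
        # saturated two-group model: slope is the log ratio of group means
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        X = np.column_stack([np.ones(6), x])
        fit = fit_gamma_glm(X, y, columns=["intercept", "x"])
        assert fit.beta[0] == pytest.approx(math.log(2.0), abs=1e-8)
        assert fit.beta[1] == pytest.approx(math.log(6.0 / 2.0), abs=1e-8)

    def test_agrees_with_statsmodels_oracle(self):
        import statsmodels.api as sm

        records = generate_transactions(
            MarketScenarioConfig(n_transactions_per_year=100, brand_sd=0.0), seed=11
        )
        d = build_design(records, ModelSpec(brand_mode="omit"))
        fit = fit_gamma_glm(d.X, d.y, columns=d.columns, tol=1e-13, max_iter=200)
        ref = sm.GLM(d.y, d.X, family=sm.families.Gamma(sm.families.links.Log())).fit(
            tol=1e-12
        )
        assert np.max(np.abs(fit.beta - ref.params)) < 1e-6
        assert np.max(np.abs(np.sqrt(np.diag(fit.cov)) - ref.bse)) < 1e-6
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-8)

    def test_noiseless_data_recovered_exactly(self):
        records = generate_transactions(
            MarketScenarioConfig(n_transactions_per_year=80, brand_sd=0.0, gamma_shape=None),
            seed=5,
        )
        d = build_design(records, ModelSpec(brand_mode="omit"))
        fit = fit_design(d)
        assert np.max(np.abs(fit.beta - _truth_vector(d.columns))) < 1e-8

    def test_scale_equivariance(self):
        records = generate_transactions(
            MarketScenarioConfig(n_transactions_per_year=60, brand_sd=0.0), seed=7
        )
        d = build_design(records, ModelSpec(brand_mode="omit"))
        fit1 = fit_gamma_glm(d.X, d.y, columns=d.columns, tol=1e-12)
        fit2 = fit_gamma_glm(d.X, 3.7 * d.y, columns=d.columns, tol=1e-12)
        i = d.columns.index("intercept")
        shift = fit2.beta - fit1.beta
        assert shift[i] == pytest.approx(math.log(3.7), abs=1e-8)
        slopes = np.delete(shift, i)
        assert np.max(np.abs(slopes)) < 1e-8

    def test_deviance_trace_non_increasing(self):
        records = generate_transactions(
            MarketScenarioConfig(n_transactions_per_year=60, brand_sd=0.0), seed=13
        )
        d = build_design(records, ModelSpec(brand_mode="omit"))
        fit = fit_design(d)
        trace = np.array(fit.deviance_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)

    def test_rank_deficiency_reported(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(CollinearityError) as err:
            fit_gamma_glm(X, np.ones(10) + np.arange(10.0), columns=["intercept", "a", "b"])
        assert {"a", "b"} <= set(err.value.columns)

    def test_nonconvergence_flagged_not_silent(self):
        records = generate_transactions(
            MarketScenarioConfig(n_transactions_per_year=60, brand_sd=0.0), seed=3
        )
        d = build_design(records, ModelSpec(brand_mode="omit"))
        fit = fit_gamma_glm(d.X, d.y, columns=d.columns, max_iter=1)
        assert not fit.converged and fit.iterations == 1

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_glm(np.ones((3, 1)), np.array([1.0, 0.0, 2.0]))


class TestRateRatio:
    @staticmethod
    def _fit(beta, se):
        p = len(beta)
        return GlmFit(
            columns=tuple(f"t{i}" for i in range(p)),
            beta=np.asarray(beta, dtype=float),
            cov=np.diag(np.square(se)),
            dispersion=1.0,
            deviance=0.0,
            n_obs=10,
            converged=True,
            iterations=1,
            deviance_trace=(0.0,),
        )

    def test_known_backtransforms(self):
        fit = self._fit([-0.738, 0.293], [0.102, 0.0526])
        assert round(rate_ratio(fit, "t0")[0], 3) == 0.478
        assert round(rate_ratio(fit, "t1")[0], 2) == 1.34

    def test_zero_coefficient_is_unity(self):
        fit = self._fit([0.0], [0.1])
        ratio, lo, hi = rate_ratio(fit, "t0")
        assert ratio == 1.0 and lo < 1.0 < hi

    def test_reciprocal_symmetry(self):
        for x in (0.01, 0.3, 1.7):
            f = self._fit([x, -x], [0.1, 0.1])
            assert rate_ratio(f, "t0")[0] * rate_ratio(f, "t1")[0] == pytest.approx(1.0)

    def test_unknown_term_errors(self):
        with pytest.raises(KeyError):
            rate_ratio(self._fit([0.0], [0.1]), "nope")


class TestBackwardElimination:
    def test_zero_effect_fibre_dropped_true_effects_kept(self):
        # fibre type has no effect in the generating process; every other
        # term block carries real signal
        records = generate_transactions(
            MarketScenarioConfig(n_transactions_per_year=280), seed=1
        )
        spec, trace = backward_eliminate(records, ModelSpec.initial())
        dropped = [t for t, _ in trace]
        assert dropped == ["fibre_type"]
        assert "hhi_thousands" in spec.terms and "gfmss" in spec.terms

    def test_already_parsimonious_spec_unchanged(self):
        records = generate_transactions(
            MarketScenarioConfig(n_transactions_per_year=280), seed=2
        )
        spec, trace = backward_eliminate(records, ModelSpec.default())
        assert trace == [] and spec.terms == ModelSpec.default().terms

    def test_alpha_validated(self, rec):
        with pytest.raises(ValueError):
            backward_eliminate([rec()], alpha=1.5)


@pytest.fixture(scope="module")
def fitted():
    records = generate_transactions(
        MarketScenarioConfig(n_transactions_per_year=120), seed=21
    )
    return ItnPriceModel(records).fit()


class TestModelResultsObjects:
    def test_params_align_with_design(self, fitted):
        assert fitted.params.index[0] == "intercept"
        assert fitted.converged
        assert (fitted.bse > 0).all()

    def test_conf_int_is_wald(self, fitted):
        ci = fitted.conf_int()
        lo = fitted.params - 1.96 * fitted.bse
        assert np.allclose(ci["lower"], lo)

    def test_rate_ratios_exclude_brand_columns(self, fitted):
        rr = fitted.rate_ratios()
        assert not any(ix.startswith("brand[") for ix in rr.index)
        assert (rr["ci_low"] <= rr["ratio"]).all() and (rr["ratio"] <= rr["ci_high"]).all()

    def test_summary_and_dict_exports(self, fitted):
        text = fitted.summary()
        assert "hhi_thousands" in text and "dispersion" in text
        d = fitted.to_dict()
        assert set(d) >= {"coefficients", "std_errors", "rate_ratios", "dispersion"}

    def test_from_dataframe_matches_records(self, fitted):
        from itnvalue.io import records_to_frame

        df = records_to_frame(fitted.model.records)
        res2 = ItnPriceModel.from_dataframe(df).fit()
        assert np.allclose(res2.params.values, fitted.params.values)
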