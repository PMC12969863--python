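"""Distribution sampling and Monte Carlo propagation contracts."""

import math

import numpy as np
import pytest

from itnvalue.records import CountryProfile, DistributionSpec
from itnvalue.simulate import (
    SimulationSummary,
    run_country_simulations,
    sample,
    simulate_eac_per_person,
    simulate_wtp,
    stream_rng,
)
from itnvalue.value import Scenario, eac_per_person, equivalent_annual_cost, wtp


class TestSample:
    def test_point_spec(self):
        assert sample(DistributionSpec.point(2.0), 5, 0).tolist() == [2.0] * 5

    def test_same_seed_identical(self):
        spec = DistributionSpec.triangular(1.0, 2.0, 4.0)
        assert np.array_equal(sample(spec, 100, 7), sample(spec, 100, 7))

    def test_uniform_law_of_large_numbers(self):
        x = sample(DistributionSpec.uniform(1, 4), 100_000, 1)
        assert x.mean() == pytest.approx(2.5, abs=0.01)

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec.uniform(1, 4),
            DistributionSpec.triangular(1, 2, 3.5),
            DistributionSpec.pert(1, 2, 3.5),
            DistributionSpec.normal_truncated(2.0, 1.0, 0.5, 4.0),
            DistributionSpec.gamma(5.0, 0.4),
        ],
    )
    def test_draws_within_support(self, spec):
        x = sample(spec, 5000, 3)
        lo, hi = spec.support()
        assert x.min() >= lo and x.max() <= hi

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec.pert(1, 2, 4),
            DistributionSpec.triangular(1, 1.5, 4),
            DistributionSpec.normal_truncated(2.0, 0.5, 0.0, math.inf),
            DistributionSpec.gamma(4.0, 0.5),
        ],
    )
    def test_sample_mean_matches_analytic_mean(self, spec):
        x = sample(spec, 200_000, 5)
        se = x.std() / math.sqrt(x.size)
        assert abs(x.mean() - spec.mean()) < 4 * se

    def test_n_validated(self):
        with pytest.raises(ValueError):
            sample(DistributionSpec.point(1.0), 0, 0)


def test_stream_rng_stable_per_label():
    a1 = stream_rng(7, "Benin", "pyrethroid", "eac").normal(size=4)
    a2 = stream_rng(7, "Benin", "pyrethroid", "eac").normal(size=4)
    b = stream_rng(7, "Chad", "pyrethroid", "eac").normal(size=4)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)


class TestSimulateEacPerPerson:
    def test_point_specs_collapse_to_deterministic_pipeline(self, point_profile):
        profile = point_profile(price=2.0, b=2.0, persons=2.0, rate=0.03)
        s = simulate_eac_per_person(profile, "pyrethroid", 1000, seed=1)
        exact = eac_per_person(equivalent_annual_cost(2.0, 0.03, 2.0), 2.0)
        assert s.mean == s.median == s.p05 == s.p95 == exact

    def test_uniform_persons_expectation(self, point_profile):
        # E[EAC / U(1,4)] = EAC * ln(4) / 3
        base = point_profile(price=2.0, b=2.0, persons=1.0, rate=0.03)
        profile = CountryProfile(
            country=base.country,
            retention_median_b=base.retention_median_b,
            retention_interval=base.retention_interval,
            price_by_class=base.price_by_class,
            persons_per_net=DistributionSpec.uniform(1, 4),
            discount_rate_r=base.discount_rate_r,
        )
        n = 100_000
        s = simulate_eac_per_person(profile, "pyrethroid", n, seed=2)
        eac = equivalent_annual_cost(2.0, 0.03, 2.0)
        expected = eac * math.log(4.0) / 3.0
        # MC standard error of mean(EAC/U): sd(1/U) = sqrt(1/4 - (ln4/3)^2)
        sd = eac * math.sqrt(0.25 - (math.log(4.0) / 3.0) ** 2)
        assert abs(s.mean - expected) < 3 * sd / math.sqrt(n)

    def test_wider_persons_spec_widens_interval(self, point_profile):
        base = point_profile(price=2.0, b=2.0)
        widths = []
        for hi in (2.0, 3.0, 4.0):
            profile = CountryProfile(
                country=base.country,
                retention_median_b=base.retention_median_b,
                retention_interval=base.retention_interval,
                price_by_class=base.price_by_class,
                persons_per_net=DistributionSpec.uniform(1, hi),
                discount_rate_r=base.discount_rate_r,
            )
            s = simulate_eac_per_person(profile, "pyrethroid", 20_000, seed=3)
            widths.append(s.p95 - s.p05)
        assert widths[0] < widths[1] < widths[2]

    def test_unknown_net_class_errors(self, point_profile):
        with pytest.raises(KeyError, match="pbo_dual"):
            simulate_eac_per_person(point_profile(), "pbo_dual", 10, seed=0)


class TestSimulateWtp:
    def test_point_l_equals_b_gives_zero_premium(self, point_profile):
        profile = point_profile(price=2.0, b=3.0)
        res = simulate_wtp(profile, "pyrethroid", Scenario.TO_THREE_YEARS, 500, seed=1)
        assert res.premium.mean == res.premium.p95 == 0.0
        assert res.relative_increase_a.mean == 1.0

    def test_point_inputs_match_deterministic_wtp(self, point_profile):
        profile = point_profile(price=2.0, b=2.0, rate=0.03)
        res = simulate_wtp(profile, "pyrethroid", Scenario.TO_THREE_YEARS, 500, seed=1)
        exact = wtp(2.0, 0.03, 2.0, Scenario.TO_THREE_YEARS)
        assert res.threshold_price.mean == exact.threshold_price_Pl
        assert res.threshold_price.mean == pytest.approx(2.956526, abs=5e-7)

    def test_threshold_price_decreases_with_baseline_retention(self, point_profile):
        means = []
        for b in (1.2, 1.8, 2.4, 3.0, 3.4):
            profile = point_profile(price=2.0, b=b, country=f"L{b}")
            res = simulate_wtp(profile, "pyrethroid", Scenario.TO_THREE_YEARS, 2000, seed=4)
            means.append(res.threshold_price.mean)
        assert all(m1 > m2 for m1, m2 in zip(means, means[1:]))

    def test_seed_reproducibility(self, point_profile):
        base = point_profile()
        profile = CountryProfile(
            country=base.country,
            retention_median_b=2.0,
            retention_interval=(1.5, 2.6),
            price_by_class={"pyrethroid": DistributionSpec.normal_truncated(2.0, 0.3, 0.0, math.inf)},
            persons_per_net=DistributionSpec.uniform(1, 4),
            discount_rate_r=0.03,
        )
        r1 = simulate_wtp(profile, "pyrethroid", Scenario.PLUS_SIX_MONTHS, 2000, seed=9)
        r2 = simulate_wtp(profile, "pyrethroid", Scenario.PLUS_SIX_MONTHS, 2000, seed=9)
        assert r1 == r2


def test_monte_carlo_error_scales_as_inverse_sqrt_n(point_profile):
    """sd of the simulated mean shrinks ~sqrt(10) per tenfold n increase."""
    base = point_profile(price=2.0, b=2.0)
    profile = CountryProfile(
        country=base.country,
        retention_median_b=base.retention_median_b,
        retention_interval=base.retention_interval,
        price_by_class=base.price_by_class,
        persons_per_net=DistributionSpec.uniform(1, 4),
        discount_rate_r=base.discount_rate_r,
    )

    def sd_of_means(n, n_rep=30):
        means = [
            simulate_eac_per_person(profile, "pyrethroid", n, seed=s).mean
            for s in range(n_rep)
        ]
        return np.std(means)

    s3, s4 = sd_of_means(1000), sd_of_means(10_000)
    ratio = s3 / s4
    assert 2.0 < ratio < 5.0  # ideal sqrt(10) ~ 3.16, wide band for noise


def test_summary_percentile_ordering_enforced():
    with pytest.raises(ValueError):
        SimulationSummary(10, 0.0, q25=0.5, median=0.4, q75=0.6, p05=0.1, p95=0.9)
    s = SimulationSummary.from_samples(np.arange(101.0))
    assert (s.p05, s.median, s.p95) == (5.0, 50.0, 95.0)


def test_run_country_simulations_long_format(point_profile):
    profiles = [point_profile(b=1.5, country="A"), point_profile(b=2.5, country="B")]
    df = run_country_simulations(profiles, n_iter=200, seed=5)
    # per country/class: 1 EAC row + 2 scenarios x 3 quantities
    assert len(df) == 2 * (1 + 2 * 3)
    assert set(df["quantity"]) == {"eac_per_person", "a", "threshold_price", "premium"}
    assert (df["n"] == 200).all()
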