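# itnvalue

Market-structure and value-for-money analysis for insecticide-treated
bednets (ITNs), the core commodity of malaria prevention. The package is
aimed at health economists and malaria-programme analysts who want to ask,
from procurement transaction data and country retention estimates:

1. **How concentrated is the ITN supplier market?** Per-year market shares,
   the Herfindahl–Hirschman Index (HHI = Σ sᵢ², shares in percent, 10,000 =
   monopoly; >1,000 concentrated, >2,000 highly concentrated) and top-k
   concentration ratios (CR₅ > 60% indicates oligopoly), with sensitivity
   bounds for shipments whose supplier is unrecorded.
2. **What drives ITN prices?** A gamma GLM with log link on the
   inflation-adjusted unit price, fitted by iteratively reweighted least
   squares implemented in-repo, with net type, net area, market size, HHI,
   a market-shaping regime indicator and oil-price / region effects
   stratified by regime, backward stepwise selection by Wald block tests,
   and rate-ratio (exp β) reporting.
3. **What is a longer-lasting net worth?** The equivalent annual cost

       EAC = P·r / (1 − (1+r)⁻ᵇ)

   of a net priced P and retained b years at discount rate r, divided by
   persons protected per net; and the threshold price P_l = a·P of a net
   retained l years, where

       a = (1 − (1+r)⁻ˡ) / (1 − (1+r)⁻ᵇ)

   equates the two EACs. P_l − P is the premium a value-maximising buyer
   should be willing to pay for the extra retention. Two scenarios are
   built in: retention raised to exactly 3 years, and retention extended by
   6 months. A seeded Monte Carlo engine propagates uncertainty in price,
   retention, persons-per-net and the discount rate.

Because real ITN procurement databases are not redistributable, the package
ships a first-class synthetic-data module that generates transaction tables
and country profiles with the statistical structure the analysis assumes
(gamma-distributed prices with log-linear effects, supplier share
trajectories, retention medians spanning ~1–3.5 years), so the whole
pipeline is testable end to end.

## Worked example

```python
import itnvalue as iv

# synthetic market: 18 years, supplier field moving from monopoly to six firms
records = iv.generate_transactions(iv.MarketScenarioConfig(n_transactions_per_year=300), seed=7)

for r in (iv.concentration_by_year(records, k=5)[i] for i in (0, -1)):
    print(f"{r.year}: HHI={r.hhi:.0f} [{r.hhi_bounds[0]:.0f}, {r.hhi_bounds[1]:.0f}] "
          f"CR5={r.cr_k:.1f}% {r.classification.value}")
# 2004: HHI=10000 [10000, 10000] CR5=100.0% HIGH
# 2021: HHI=1868 [1485, 2068] CR5=92.3% MODERATE

res = iv.ItnPriceModel(records).fit()          # gamma GLM, log link, brand ridge
for term in ["net_type[PBO]", "hhi_thousands", "gfmss"]:
    ratio, lo, hi = res.rate_ratios().loc[term]
    print(f"{term}: ratio {ratio:.3f} (95% CI {lo:.3f}-{hi:.3f})")
# net_type[PBO]: ratio 1.324 (95% CI 1.307-1.342)
# hhi_thousands: ratio 1.283 (95% CI 1.279-1.287)
# gfmss: ratio 0.473 (95% CI 0.447-0.502)
```

The PBO rate ratio says PBO nets cost ~32% more than pyrethroid-only nets
at equal covariates; each 1,000 HHI points add ~28% to the expected price;
the market-shaping regime halves prices, all close to the generating truth
(e^0.293 = 1.34, e^0.253 = 1.29, e^−0.738 = 0.478).

```python
prof = iv.CountryProfile(
    country="ExampleCountry", retention_median_b=1.8, retention_interval=(1.4, 2.3),
    price_by_class={"pyrethroid": iv.DistributionSpec.normal_truncated(1.95, 0.29, 0.0, float("inf"))},
    persons_per_net=iv.DistributionSpec.uniform(1, 4), discount_rate_r=0.03)

s = iv.simulate_eac_per_person(prof, "pyrethroid", 100_000, seed=7)
print(f"EAC/person: mean {s.mean:.3f}, 90% CI [{s.p05:.3f}, {s.p95:.3f}]")
# EAC/person: mean 0.517, 90% CI [0.255, 1.002]

w = iv.simulate_wtp(prof, "pyrethroid", iv.Scenario.TO_THREE_YEARS, 100_000, seed=7)
print(f"P_l mean {w.threshold_price.mean:.2f}, premium mean {w.premium.mean:.2f}")
# P_l mean 3.16, premium mean 1.22
```

Protecting people with this country's $1.95 nets costs about $0.52 per
person-year; a net retained a full 3 years instead of 1.8 would be worth
about $3.16, i.e. a premium of roughly $1.22 over the baseline price.

The same stages are available from the shell:

```sh
itnvalue simulate-data --seed 7 --out data/
itnvalue concentration --in data/transactions.csv --k 5 --out concentration.csv
itnvalue price-model   --in data/transactions.csv --alpha 0.05 --out fit.json
itnvalue wtp           --countries data/countries.yaml --scenario three_years --out wtp.csv
itnvalue simulate      --countries data/countries.yaml --iterations 10000 --seed 7 --out summaries.csv
```

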