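# Methods

## Scope and data model

The package analyses a market for insecticide-treated bednets (ITNs) at the
level of individual procurement transactions (year, supplier, brand, buyer,
unit price, quantity, net type, fibre, net area, destination region, oil
price as a raw-materials proxy) and, for the value-for-money model, at the
level of country profiles (median net retention time with an uncertainty
interval, baseline price distributions per net class, persons protected per
net, discount rate). Prices are USD per net; "real" prices are deflated to
a configurable base year with a user-supplied deflator table (year →
multiplier, base-year factor 1). The base year defaults to the final data
year, and fetching deflator series is out of scope — the table is an input.

Before analysis, transactions pass a filter that (a) removes untreated
nets, which are not price-comparable with insecticide-treated ones, and
(b) removes price outliers above an absolute cap (default 50 USD/net, far
above any plausible unit price; configurable). The filter partitions its
input — every excluded record carries the rule that excluded it — and all
pipeline stages log record counts in and out.

## Market concentration

Supplier market share in a year is the percentage of all nets shipped that
year supplied by that firm (quantity-weighted, not transaction-weighted).
Contract manufacturers can be folded into their parent suppliers through a
relabelling map before aggregation. HHI is the sum of squared percentage
shares; classification thresholds are 1,000 (concentrated) and 2,000
(highly concentrated), and CR₅ > 60% marks an oligopoly.

Unrecorded suppliers are a first-class label (`UNKNOWN`), not missing data.
The headline HHI excludes unknown volume and renormalizes named shares to
100% (policies to treat it as a single firm, or to atomize it, are also
implemented), and every per-year result carries sensitivity bounds: the
minimum HHI splits unknown volume across vanishingly small independent
firms; the maximum assigns it all to the largest named supplier. The bounds
bracket the unobservable truth and coincide exactly when nothing is
unknown. Renormalized share sums can overshoot 100 by a few ulps, so HHI
and CR are clamped at their theoretical maxima (10,000 and 100).

## Price model

The response is the real unit price; the family is gamma with a log link,
so coefficients are log price ratios and exp(β) is a multiplicative price
effect. The design implements: net-type dummies (reference pyrethroid-only),
optional fibre dummy (reference polyester), net area (m²), market size
(millions of nets shipped that year), HHI (thousands), a binary
market-shaping regime indicator (years ≥ 2016 by default), oil price (tens
of USD/bbl) and region dummies (reference sub-Saharan Africa) entered as
pure within-regime interactions (separate slopes before/after the regime),
and a market-size × regime interaction. Year-level covariates (market size,
HHI) are computed from the transaction table itself unless supplied. The
HHI driving a year's prices is the previous year's realized HHI (the first
year uses its own); the lag is configurable. This avoids the simultaneity
of regressing a year's prices on concentration computed from the same
year's shipments and matches the data-generating process of the synthetic
market, making end-to-end recovery meaningful.

Fitting is IRLS. For a gamma GLM with log link the working weights are
identically one (the variance function μ² cancels the squared link
derivative), so each step solves ordinary normal equations on the working
response z = η + (y − μ)/μ. Start values are zero with intercept
log(mean y); convergence is a relative deviance change below 1e-8 with a
100-iteration cap; a fit that hits the cap is returned flagged, never
silently. Rank deficiency is detected up front and reported with the
collinear columns (from the SVD null space). Dispersion is the moment
estimator, Pearson χ² / (n − p). Inference is Wald throughout: symmetric
95% CIs at ±1.96 SE, per-term block χ² tests for elimination. The in-repo
fit is cross-checked against an established GLM implementation in the test
suite (agreement to well below 1e-6 on a shared fixture); that library is a
test dependency only.

Brand is a grouping factor. Three adjustment modes exist: omit, brand fixed
effects, and the default ridge-penalized brand intercepts with penalty
λ = dispersion / brand-prior-variance (the standard variance-ratio
shrinkage; prior variance default 0.01 on the log scale, matching the
synthetic generator's brand spread). Exact integration over a random brand
intercept is deliberately not attempted; the ridge mode captures the
shrinkage behaviour that matters for the fixed effects reported here.

Backward elimination drops, one at a time, the least significant term block
with p > α (default 0.05), refitting after each drop; interaction terms are
dropped before the main effects they reference, and the intercept and brand
adjustment are never candidates. Eliminating everything returns the
intercept-only model with a warning. Whether selection should use Wald or
likelihood-ratio tests is an open choice; Wald was chosen for consistency
with the reported symmetric CIs.

## Value-for-money model

Equivalent annual cost annuitizes the purchase price over the retention
time: EAC = P·r / (1 − (1+r)⁻ᵇ). Retention b is used in fractional years
directly. At r = 0 the formula is undefined; the analytic limit P/b is
returned instead (rates below 1e-12 count as zero), since a zero discount
rate is a legitimate configuration, not an error. EAC per person protected
divides by persons per net (support [1, 4] by default). The threshold price
of a net retained l years is P_l = a·P with a the annuity-factor ratio; the
premium is P_l − P and is negative when l < b (for the 3-year scenario this
happens exactly when baseline retention already exceeds 3 years). The
default discount rate is 3%, the common health-economics convention, and is
configurable per country.

## Monte Carlo engine

Uncertain inputs are described by parametric distribution specs: POINT,
UNIFORM, TRIANGULAR, beta-PERT (shape 4), truncated normal (sampled by
inverse CDF so the draw count is exact), and gamma. Default shapes: price
truncated-normal at the class mean with configurable spread, truncated at
0; retention triangular over (low, median, high) from the country interval;
persons-per-net continuous uniform on (1, 4); discount rate a point mass
unless configured. Inputs are drawn independently; correlated sampling is
out of scope.

Each (country, net class, scenario) combination gets its own generator
seeded by SeedSequence(master seed, SHA-256 of the labels), so results are
reproducible bit-for-bit and invariant to how many other streams run. Draws
violating model preconditions are rejected and redrawn (counted and
logged). Summaries report mean, quartiles and the 5th/95th percentiles
using numpy's linear-interpolation percentile convention; a degenerate
(all-equal) sample reports the value itself as its mean so that all-POINT
simulations equal the deterministic pipeline exactly — the closed-form
functions are numpy-vectorized and both paths share the same code.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any
particular historical trajectory. Named suppliers follow linear target-share
trajectories (default: one firm at 100% decaying to six firms plus a ~10%
unknown remainder, i.e. monopoly → moderate concentration); supplier labels
are drawn per transaction from those targets, and quantities are lognormal,
scaled to a per-year market size drawn uniformly from 50–250 million nets.
Covariates use uniform ranges a practitioner would recognise for this
market's era: net area 10–25 m², real oil price 20–110 USD/bbl; regions are
drawn with sub-Saharan Africa dominant (80%), and net types at 70/20/10
pyrethroid/PBO/dual-AI.

Each record's expected price is exp(x·β) where x is the *exact* design row
the price model builds for these records (records are generated first with
placeholder prices, the design matrix is built, then prices are drawn), so
the concentration→price link and the year-level covariates are consistent
between generation and fitting by construction. Default β values are
realistic log-scale effects for this market (PBO +0.293, dual-AI +0.214,
area +0.042/m², HHI +0.253/thousand, regime −0.738, oil pass-through
+0.061 per 10 USD/bbl reversing to −0.042 under the regime, etc.); fibre
type carries a true zero effect, which is what stepwise selection is
expected to eliminate. Realized prices are gamma with shape 25 (CV ≈ 20%, a
realistic in-year price spread for a commodity of this kind; no published
dispersion exists to calibrate against); shape `None` means noiseless,
prices equal their means exactly. Brands are nested two-per-supplier with
N(0, 0.1²) log-scale intercepts.

Country profiles default to 40 countries with retention medians uniform on
1.0–3.5 years (the span of median ITN retention estimates across African
countries), interval half-widths 15–35% of the median, baseline prices
truncated-normal around $1.95 (pyrethroid) and $2.67 (PBO/dual-AI) — the
late-period market level — with 15% CV, uniform 1–4 persons per net and a
3% discount rate.

What passing tests on these data do and do not show: they demonstrate that
the estimators and simulations are correct *under the assumed structure*
(log-linear effects, gamma noise, independent covariate draws, linear share
trajectories). Real procurement data have features the generator omits —
serial correlation in prices within buyer–supplier relationships, bulk
discounts, currency effects, non-random missingness of suppliers — so
passing here does not certify conclusions drawn from any particular real
dataset.

## Problem sizes and numerical choices

Parameter-recovery checks use ~5,000 transactions (18 years × 280/yr) and
20 seeded replicates, comfortably informative for ~18 coefficients at the
default noise; recovery is asserted as aggregate 2-SE coverage ≥ 90% across
replicate×coefficient pairs (expected ≈ 95% under correct SEs). Monte Carlo
contract checks use 10⁵ iterations with three-standard-error bands.
Noiseless fixtures must recover coefficients to 1e-8 and the EAC/threshold
self-consistency identity holds to 1e-9 over 1,000 random parameter draws.

## Known limitations

- The brand adjustment is shrinkage with a fixed variance ratio, not a
  marginal-likelihood random-effects fit; brand-variance estimation is out
  of scope.
- Buyer-side concentration (the market's few large funders) is described by
  the data model but no oligopsony index is computed.
- No budget constraint, distribution costs or campaign-cycle trade-offs
  enter the value model; the threshold price is a pure like-for-like
  EAC-equating price.
- Deflator and country input tables are user-supplied; nothing is fetched.
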