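# Methods

## Model structure

The simulation is cross-sectional: one baseline year, one policy change,
no dynamics.  A country scenario consists of four market shares (discount
and premium tiers of home and café smoking, the tiers split at the median
price within each location), a national indirect-tax policy, a CIF
(import) price per 20 g unit — assumed equal to the ex-factory price of
domestically produced tobacco — an illicit-trade share, waterpipe smoking
prevalence, and the adult (15+) population.

Evaluating a policy proceeds per share: decompose the baseline retail
price into CIF, import duty, specific excise, ad valorem excise, VAT and
industry margin; recompose a new price under the changed tax with CIF and
margin held fixed (full pass-through); project demand with the share's
constant own-price elasticity; then aggregate.  The tax-base chain is:
duty on CIF; ad valorem on CIF + duty; VAT on the full pre-VAT price
including the margin.  Corporate/direct taxes and cross-price substitution
between shares or products are out of scope.

Key conventions:

* **Quantities are legal (taxed) consumption.**  Survey-derived totals
  include illicit purchases, so they are downscaled by the illicit share
  once, at scenario construction; the same quantities feed both revenue
  and consumption outputs, keeping the reported burden, revenue and
  expenditure mutually consistent.  (`evaluate_policy` can rescale the
  health inputs back to total consumption, but because the deaths formula
  depends only on the relative consumption drop and the smoker count, a
  joint rescaling leaves deaths unchanged.)
* **Market-weighted burden** is total tax revenue over total retail
  expenditure (expenditure weighting), which makes burden × expenditure
  equal revenue exactly.  The **weighted price** uses quantity weights
  (average price per unit sold); expenditure weighting is available as an
  option.  Policy aggregates use the policy scenario's own post-response
  quantities as weights (a flag retains baseline weights).  This is why a
  uniform specific-tax rise can raise the weighted price by more than
  (1+v)·Δs: cheap shares see much larger relative price rises, demand
  shifts toward premium shares, and the weights move with it.
* **Import duty** applies only where the market is (fully) imported; a
  per-country boolean zeroes the duty rate otherwise.
* **Over/undershifting** scales the retail-price *change* rather than the
  margin: the consumer-facing price is the single behavioural driver, and
  VAT and margin are re-derived from the shifted price so the additive
  identity always holds (the residual margin then differs from baseline —
  that is the industry absorbing or pocketing part of the tax change).
* **Negative margins** (price below tax-inclusive cost) are a hard error
  when constructing a baseline but only a warning inside sweeps and the
  goal-seek, where they flag tax levels the current retail price cannot
  absorb.

## Demand and health

Demand follows `Q1 = Q0 * (P1/P0)**eps` — exact exponential decay in log
price rather than a linear approximation, so large tax rises are not
overstated.  Deaths averted use the standard cigarette-modelling
assumption: a fraction 0.5 of the unit reduction is attributed to quitting
and 0.35 of quitters would have died prematurely.  The unit reduction is
converted to quitters by dividing by the baseline per-smoker intensity
`q0 / smokers`, with `smokers = prevalence × adult population`.  This
operationalisation is a modelling choice; published headline
deaths-averted figures for these countries are not reproducible from
published aggregates under it (or any operationalisation we could
construct), so the deaths output is validated by its formula properties
(zero at no change, linear in the quit fraction, invariant to a joint
rescaling of quantities) rather than against external numbers.

## Goal-seek and sweeps

`solve_specific` scans the bracket (default $0–$50, 257 points) for the
first sign change of the objective and refines it with Brent's method to
1e-6 USD.  The burden objective is strictly monotone in the specific
excise, so its root is unique; the excise-revenue objective follows a
single-peaked Laffer curve, so a revenue target can be hit twice and the
smallest root (the cheaper tax) is returned.  An unattainable target
raises an error reporting the attainable range.  `sweep` evaluates a
sorted grid of specific-excise levels and returns units, excise revenue,
total revenue, burden and weighted price per point.

## Calibration and sensitivity

`calibrate` multiplies all share quantities by a single factor `k` so that
baseline revenue matches an external revenue anchor (`mode="match"`,
`k = anchor / revenue`, the default) or is only capped by it
(`mode="cap"`, scale down but never up).  Scale-free statistics (weighted
price and burden) are unchanged by construction.  `revenue_plausible`
asserts the weaker consistency requirement that modelled waterpipe revenue
not exceed a country's reported all-tobacco tax revenue.

`run_sensitivity` re-runs the policy under each grid cell: CIF scaled by
0.5/1.5 before decomposition, pass-through 0.9/1.1, elasticities swapped
to their 95% CI bounds — one at a time by default, with a full 3×3×3
factorial available.  By default each perturbed scenario *re-solves* the
policy target (the solved excise adapts); a flag freezes the main solved
excise instead, since either reading of a published sensitivity design is
defensible.  Outcomes (consumption, total revenue, deaths) are reported as
percentage differences from the main scenario; the identity cell is zero
by construction and per-cell solver failures are recorded, not raised.

## Synthetic data

`generate` draws a market with the structure the analysis assumes: prices
ordered discount < premium within each location and café above home (café
smoking includes the café service in the price); a café industry margin of
at least 60% of the retail price, enforced through an upper bound on the
CIF price; elasticities uniform on [−2.0, −0.2] (spanning very inelastic
to elastic national markets) with symmetric CIs of ±25% of the point
estimate; Dirichlet share weights; an illicit share in [5%, 30%]; VAT in
[8%, 20%]; and a total consumption of 50–250 million units.  Every
generated scenario is checked to admit a feasible (non-negative-margin)
decomposition for all four shares, and generation is deterministic given
the seed.

`anchor_fit` builds a scenario whose *aggregates* match published
country-level anchors: share prices and free share weights come from a
least-squares fit in which the market-weighted price is a heavily weighted
residual and per-label price hints are soft; the VAT rate is then solved
in closed form from the anchored VAT (or excise) revenue via
`v/(1+v) = VAT revenue / expenditure`, and the ad valorem rate absorbs the
remaining tax take.  The stored anchors for Jordan, Lebanon and Palestine
pin the published weighted price, weighted burden, total units and one
revenue component to within 1%.  Anchored quantities are treated as the
legal consumption totals (the published revenue figures are consistent
with taxes applied to exactly those totals), with the illicit share kept
as metadata.  Where anchor inputs are not published the fixtures use
representative values chosen once:

* elasticities: a single per-country value implied by the published
  aggregate price and consumption response (−0.80 Jordan, −1.45 Lebanon,
  −0.43 Palestine), applied uniformly across shares with ±25% CIs;
* adult (15+) populations: approximate 2019 figures (6.7 M Jordan, 5.3 M
  Lebanon, 1.9 M West Bank);
* CIF as a fixed fraction of the cheapest retail price (15% Jordan, 30%
  Lebanon, 8% Palestine — the Lebanese value keeps the implied ad valorem
  rate near its actual three-digit-percentage scale, and the Palestinian
  value leaves room for the large specific excise in discount shares);
* Palestine's published aggregates are mutually inconsistent under
  quantity weighting (48.1% of units at $2.40 with a $7.62 maximum price
  cannot average $5.34), so its soft price hints, including a $5.00
  premium-home hint, let the fit resolve the tension while the hard
  aggregate anchors stay within 1%.

Passing anchored-fixture tests therefore shows that the *pipeline*
reproduces the published aggregate arithmetic, not that the per-share
detail matches the unpublished survey inputs.

## Numerical choices

Additive identity tolerance 1e-9 USD; goal-seek tolerance 1e-6 USD on the
excise; solver bracket scan of 257 points; anchored-fit verification
tolerance 1% relative on each hard target.  All computation is double
precision; monetary values are rounded only at presentation.

## Problem sizes

Every market has four shares, so all pipelines are tiny: a full country
solve is milliseconds, the dense sweeps and 10,000-point grid-search
cross-checks in the tests run in seconds, and the whole suite plus the
acceptance script completes in well under a minute on one CPU.

## Limitations

Cross-sectional only (no dynamic projections or discounting); no
cross-price substitution between shares or products; constant illicit
share, CIF and margin under policy; the deaths conversion is a fixed
two-parameter rule, not a life-table; anchored fixtures are synthetic
stand-ins whose per-share structure is not identified by the published
aggregates.
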