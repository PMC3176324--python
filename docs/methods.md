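# Methods

`mortfeas` analyses the economic feasibility of the *informant method* — an
exhaustive, key-informant-driven search for recent deaths in a community —
against conventional retrospective mortality surveys. This note records the
models, conventions and design choices behind each module, and what the
synthetic data can and cannot establish.

## Mortality rates (`mortfeas.rates`)

Rates are period rates on the humanitarian reporting scale, deaths per
10,000 person-days:

    rate = deaths / (population x recall_days) x 10,000

The denominator holds the stratum population (all ages, or under-fives)
constant over the recall window: no half person-time deduction for
decedents and no migration adjustment. This is deliberate — it is the
convention under which a published site table's death counts and population
denominators reproduce its printed rates, and it is how field reports are
actually computed. Full precision is kept internally; rounding half-up to
two decimals happens only at presentation.

Detection sensitivity is `100 x detected / reference`, where the reference
count is an external best estimate (e.g. from capture-recapture) treated
as a given input. Values above 100% are returned unclamped so callers can
flag them; a zero reference raises.

Confidence intervals are *not* part of the core estimates: interval methods
for exhaustive (non-sampled) death searches are not settled, and the
published intervals this package's fixtures derive from are not
reproducible from the printed inputs. An exact (Garwood) Poisson interval
on the death count is available behind `ci=True`, clearly an extension.

Known non-reproduction: the rural-district site (Chiradzulu) prints a CMR
of 0.30 while deaths/person-time gives 0.28; the village-sampling weighting
behind the printed value is not described in the source and is not
implemented. Tests assert only the three census/surveillance-denominator
sites.

## Sample-size projection (`mortfeas.design`)

On the period scale each person carries death risk `p = CMR x recall /
10,000`; precision `d` is absolute (rate scale) or relative (`d = f x p`).
Required persons:

    n = DEFF x z^2 x V / d^2,  V = p (Poisson) or p(1 - p) (binomial)

Defaults: Poisson variance, z = 1.96, DEFF 2, mean household size 5.
Poisson is the default because it is the variance form under which the
standard worked humanitarian designs come out exactly; the binomial option
is strictly smaller for 0 < p < 1.

**Household rounding is truncation (floor), not nearest.** With z = 1.96
the three canonical worked designs give 5691.26, 3201.33 and 6402.67
persons/5; the published values are 5691, 3201 and 6402. Truncation is the
only single convention that reproduces all three (nearest rounding would
give 6403 for the third). Cluster counts use ceiling, with an explicit
override so a stated design can be carried verbatim even when internally
inconsistent ("200 clusters of 32 = 6402 households").

`achievable_precision` inverts the formula; the round-trip identity is
property-tested to 1 part in 10^9.

## Costing engine (`mortfeas.costing`)

Micro-costing decomposes an exercise into seven activities (preparation,
population estimation, FGD, training, data collection, data entry/analysis,
report) consuming person-time from eight roles. Time rules are a small
declarative language (see the module docstring for the rule inventory);
scenarios are YAML files shipping one per site and recall period.

Evaluation order: non-proportional rules first, then proportional rules in
topological order of their source roles within each activity; a dependency
cycle raises rather than being silently broken. The working day is 8 hours.

Semantics chosen where the source assumptions table was ambiguous:

* *Teams of two*: `per_household` minutes accrue per staff member present
  (`staff_per_household = 2` doubles person-time), because the source lists
  "2 data collectors/household" as a separate multiplier.
* *Observed copy*: copies the entire activity row (all roles, hours and
  US$) from the observed informant-method ledger — used for survey
  preparation, assumed identical to the observed exercise.

Pricing: paid roles cost hours x hourly US$; respondents, FGD participants
and key informants are unpaid and price to $0; one-off lump sums (e.g.
$264 to household enumerators for a population count) attach once to their
activity cell. `hours_rounding="cell"` (the default in `project_survey`)
rounds each (activity, role) hour cell half-up to whole hours before
pricing; published cost tables were evidently priced that way (45 h x
$22.6 = $1017, where full precision gives 44.8 h = $1012.5). Full-precision
pricing remains available.

Presentation: activity cells round half-up to whole hours/dollars and the
printed-style grand total sums the *rounded* cells (329.5 raw
data-collection hours present as 330 and enter the total as 330).

Cells known not to be rule-derivable (the urban and rural cluster sites'
6-month data-collection and entry/analysis totals imply an unstated
travel/overhead component) are not forced: site comparisons fall back to
the as-printed ledger fixtures, which are shipped clearly labelled
(`*_as_printed.csv`). The shipped published totals differ from the sum of
published cells by up to 1 hour / 5 US$ — a rounding artefact of the
source tables; both views are shipped and tests carry exactly that slack.

## Comparison reports (`mortfeas.compare`)

Savings are `survey - informant`, as absolute difference and as a percent
of the survey total; negative savings (informant costlier) are preserved,
not clamped. The multi-site headline is the **unweighted mean of per-site
percentages**, not a pooled-total percentage: pooling weights big sites
more and gives a visibly different number (33.9% vs 29.4% on the 6-month
time comparison). Percent rounding, half-up to integers, is presentation
only.

Per-death efficiency is total person-hours (or US$) over deaths detected.
The verbal-autopsy budget is `n x (interview + analysis minutes) / 60`,
expressed as a share of a site's total person-time.

## Population estimation (`mortfeas.population`)

Three rapid estimators: structure counts x sampled mean occupancy (strata
combined by simple summation — no other combination rule is documented);
pooled quadrant density scaled to total area (exact under spatially
constant density, which is property-tested); and centric systematic area
sampling. For CSAS, "cells mostly within the region" is operationalised as
intersection fraction > 0.5 (configurable); distance is planar Euclidean on
km coordinates (sites are small; geodesy out of scope); ties break
lexicographically on village id; villages are selected at most once, cells
processed in row-major order. A sequential brute-force scan is the test
oracle. A bootstrap interval over the occupancy sample is provided as a
labelled extension; rapid field estimates are normally reported without
uncertainty.

## Field simulator (`mortfeas.fieldsim`)

The stated world, chosen once: 2,000 households across 24 sectors, sizes
zero-truncated Poisson with mean 5 (the planning convention for mean
household size), under-five fraction 0.18 (the midpoint of the four study
sites' 12–20%), true CMR 0.15 per 10,000 per day over a 60-day recall (the
urban site's scale), 15-minute interviews plus 10 minutes travel per
visited household.

Deaths are Bernoulli per person with period risk `p = CMR x recall /
10,000` — a period-risk reading of the rate that keeps detected deaths a
subset of true deaths by construction. Informant knowledge is sector-local:
each of the (default 2) key informants per sector knows each sector death
independently with `p_informant_knows = 0.37`, so the informant round alone
detects `1 - 0.63^2 ~ 60%` of deaths — the calibration anchor, since the
observed field sensitivities spanned 55–73% and roughly 60% is the stated
incremental-cost reference point. Snowball referral is a directed random
graph among bereaved households within a sector (`p_household_refers =
0.2`); the search visits the closure of the informant-seeded set and counts
rounds until a round adds nothing. Non-response is available
(`p_nonresponse`, default 0 — observed household response was effectively
100%).

All uniforms are drawn up-front in a fixed order from one seeded generator,
so equal-seed runs are *coupled* across parameter values: raising either
referral probability can only turn indicators on, making detection monotone
run-by-run (tested), not merely in distribution.

What a green simulator test establishes: the estimation pipeline is
consistent (estimated CMR = sensitivity x true CMR per run; unbiased at
full detection within Monte-Carlo error), the exhaustion logic terminates
within its combinatorial bound, and default calibration lands the mean
sensitivity inside the observed 55–73% band. What it does not establish:
anything about real informant behaviour — no social network structure, no
recall decay or date misreporting, no migration; the knowledge probability
is a free parameter with no quantitative field model behind it.

## Numerical conventions

* Half-up rounding everywhere at presentation (with a 1e-9 guard against
  float noise on exact halves); banker's rounding is never used.
* Ledgers are sparse dictionaries; margin conservation (activity total =
  role total = grand total) is exact by construction and property-tested.
* Stochastic tests fix seeds and use 3-standard-error tolerances; the
  hypothesis profile is derandomised.

## Known limitations

* No uncertainty intervals for informant-method rates (see above).
* Survey cells with undocumented overhead are consumed as printed, not
  modelled.
* The simulator's time ledger covers data collection only; it does not
  synthesise preparation/training/FGD time.
* CSAS assigns villages to cells greedily in row-major cell order; a
  village equidistant between two centroids goes to the earlier cell.
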