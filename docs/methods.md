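# Methods

## Scope and modelling approach

`vegchain` is a discrete-event simulator of a three-level perishable
vegetable supply chain: village markets where produce enters, a tiered
network of wholesale markets that aggregate and trade laterally, and
retail locations where most consumer purchases occur. Farm production is
represented implicitly by the mass entering village markets each day;
intermediaries are represented implicitly by transport routes. Prices,
economic behaviour, substitution between crops and demand response are
deliberately out of scope: the model isolates the physical logistics of
perishability — where produce accumulates, how long it spends in the
chain, and how much expires or breaks before purchase.

The clock is continuous, in hours. Every state change is an event:
production entry (05:00), vehicle departures (around 06:00), vehicle
arrivals, consumer-arrival batches (each market's mean hour: 10:00 at
villages, 12:00 at wholesale markets, 17:00 at retail), the daily
information-sharing review (15:00), export draws (18:00) and a nightly
aging/expiration sweep (23:30). Same-time events are processed in a fixed
kind priority — arrivals before departures before reviews before consumer
arrivals — so stock arriving at an instant can be sold at that instant.
Ties beyond that fall back to insertion order, making every run a pure
function of (network, crops, config, seed). Randomness is drawn from four
labelled PCG64 streams (supply noise, consumer arrivals, breakage,
departure jitter), each seeded from (seed, CRC32(label)), so adding draws
to one process does not perturb the others.

## Perishability

Lots age linearly: one effective day per elapsed day in ambient storage or
transit, `cold_aging_factor` days per day in cold storage. A lot expires
when its effective age reaches the crop's ambient lifespan; the boundary
is closed (age = lifespan is expired) so the rule is deterministic and
testable. The default network contains no cold storage, reflecting its
scarcity for vegetables in the modelled setting; the mechanism exists for
extensions. Transit ages at the ambient rate — nothing in the modelled
system refrigerates vehicles.

Breakage is Poisson per supply-chain level and per transport leg, with
mean rate 0.02 throughout. Continuous mass is discretised into
`unit_mass_kg = 1` kg units so the Poisson count is well defined; broken
units are capped at the mass handled. One draw is applied when mass enters
a storage level (at production/import entry, and on vehicle arrival at the
destination) and one per transport leg. A storage draw per *entry* rather
than per day in storage keeps the per-stage rate at the configured 2%
regardless of dwell time, so a three-stage path loses
`1 − 0.98³ ≈ 5.9%` to breakage in expectation and a full
village-to-retail path (three levels, two legs) about 9.6%.

## Supply, demand, and trade

The simulated calendar has twelve 30-day months. Each crop's monthly
season weights are normalised to mean 1; statewide annual-mean production
is `production_ratio × statewide demand`, distributed over village markets
proportionally to catchment population and over the year by the weights,
with unit-mean lognormal day-to-day noise (σ = 0.1; the daily noise law is
a modelling choice, not an observed quantity). For each month, production
below the (constant) consumer demand is imported at Tier-1 markets, and
production above it is exported from Tier-1/2 markets, so supply equals
demand every month — the chain always contains enough in aggregate. The
experiment multiplier scales in-state production only; a `scale_imports`
flag extends it to imports when a fully scaled inflow is wanted (the
linearity checks use it).

Consumer arrivals at each selling location are a daily Poisson count with
mean `catchment × direct_sale_fraction` (0.05 at village and wholesale
markets; retail catchments are stated directly as consumer counts). An
arrival requests each crop's per-capita daily demand; dispatch is FEFO;
fulfillment is binary per crop per arrival, with partial quantities sold
but counted unfulfilled. Demand is constant through the year.

Replenishment: villages push their stock (minus a one-day local reserve)
to the nearest wholesale market daily; retailers fetch from the nearest
wholesale market under an order-up-to policy targeting
`(review period + safety stock) = 3` days of expected demand; Tier-3
wholesale markets each have one trading partner (the nearest Tier-1/2
market) while Tier-1/2 markets are fully interconnected. At the daily
review each wholesale market shares its estimate (downstream daily demand,
usable stock, inbound mass) with direct partners only; markets whose
position falls below one day of coverage request a top-up to three days
from the partner with the largest surplus, and a sender never ships below
one day of its own local demand. Estimates count only *usable* stock —
lots that will survive at least one more day — because a market ordering
against nearly expired inventory would systematically under-replenish.
Exports are drawn last, after local consumers, and keep a one-day
downstream reserve on hand; without that reserve the export sink can
starve the next morning's retail fetches, which breaks the analytical
contract that a minimal loss-free chain fulfils all demand. Vehicle
loading sorts lots by (crop lifespan ascending, effective age descending)
and packs greedily, splitting the boundary lot — the simplest rule that
prioritises perishables when truck space binds. Departure times jitter
around each route's mean hour by `K − λ` integer hours with
`K ~ Poisson(λ)`, λ = 2, clamped to the same day; an early village truck
can therefore occasionally leave before the day's produce arrives, which
is retained as a realistic source of supply irregularity.

## Metrics and accounting

All loss fractions are mass-based (volume is derivable through bulk
density). The denominator for loss fractions is mass entering the chain
during the measured window plus the stock carried in at the burn-in
boundary, so fractions stay in [0, 1]. Exports count as successful exits,
not losses. Time-in-chain samples are recorded for every unit of mass
exiting — consumption, export, expiration or breakage; for in-transit
losses the shipment's mass-weighted mean entry time stands in for the
individual lot history lost in the per-crop breakage draw. The master
invariant, enforced in tests, is mass conservation:
`entered + carried_in = purchased + exported + expired + broken +
ending stock + ending in-transit`, with relative residual below 1e-6
(observed at machine precision). Scenario metrics are arithmetic means
over iterations run at seeds `seed, seed+1, …` (default 5 iterations; the
number averaged is configurable).

Tallies accumulate only from the end of the 7-day burn-in that fills the
initially empty chain. Because burn-in stock is snapshotted and carried
into the balance, runs of any length conserve mass, and a zero-length
horizon yields empty tallies.

## Synthetic networks and defaults

The generator places locations uniformly in a bounding box (default ~3°
square at Odisha-like latitudes), samples village and wholesale catchment
populations lognormally (medians 5 500 and 79 000, σ = 0.8, giving ~390
and ~5 400 expected direct-sale consumers respectively), assigns wholesale
tiers in a configurable ratio (full-scale systems are on the order of
4 : 8 : 395; the test-scale default is 1/2/10 with 50 villages and 156
retailers), and derives retail consumer counts so retail carries 90% of
expected purchase visits. Routes and the partner graph follow geographic
proximity (haversine distance, Earth radius 6 371 km; ties broken by
lower id). Default travel times are field-typical averages: ~27 min
village→wholesale, 5 h between wholesale markets, ~24 min
wholesale→retail.

The five default crops are stored in `data/default_crops.csv` as synthetic
defaults anchored to printed ranges: lifespans potato 21 d, onion 15 d,
cabbage 7 d, tomato 6 d, brinjal 4 d; per-capita demands 90/45/45/50/36 g
(sum 266 g/person/day; the split across crops is a labelled assumption);
bulk densities 650/500/600/400/350 kg/m³; potato and onion harvested in
2–3 months, tomato and brinjal near-year-round; production-to-demand
ratios 0.4/1.3/1.5/5.2/1.4 (brinjal's 5.2 is the anchored point; potato
is mostly imported). What the generator does *not* emulate: real
geography, census-derived catchments, road networks, market-day
schedules, price formation. Passing tests on these networks demonstrate
the mechanisms' internal consistency and directional behaviour, not
calibrated predictions for any real region.

## Problem sizes and numerical choices

The packaged experiments run at desk scale by design: the default network
(219 selling locations) with a 90-day horizon simulates in a few seconds,
and the scenario suite and test suite use 30–90-day horizons and 2–5
iterations. Tolerance choices: Monte-Carlo assertions use 3-standard-error
bands; mass-balance uses 1e-6 relative; FEFO removal and vehicle packing
use 1e-9–1e-12 guards against float dust when splitting lots. Degenerate
inputs are contracts, not crashes: a zero-arrival fulfillment query raises
a distinct error rather than returning 0, zero-mass entries are skipped,
and a zero horizon produces empty tallies.

## Known limitations

Breakage applies uniformly at 2% per stage; stage-specific rates would
need per-location configuration. End-of-market-day discards, markdown
behaviour, quality grading below the expiration threshold and nutrient- or
value-based accounting are not modelled. Lateral trade uses single-donor
requests per crop per day; a market in deficit against several partners
converges over days rather than instantly. The 30-day-month calendar
shifts real month boundaries by up to two days. Consumer arrivals are
served as one daily batch per location at its mean market hour;
intra-day interleaving of sales with vehicle arrivals is limited to the
event order of that day's schedule.
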