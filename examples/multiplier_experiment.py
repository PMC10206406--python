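"""Production-multiplier experiment at reduced scale.

Runs the scenario suite (production multiplied by 1, 1.25, 1.5, 2, 3, 5)
on a small network with two iterations each and prints the scenario
summary. The headline pattern: increasing production barely moves demand
fulfillment but sharply increases the share of production lost, because
surplus accumulates and expires in storage at wholesale markets.
"""

import vegchain as vc

net = vc.generate_network(vc.GeneratorParams(
    n_village=20, n_tier1=1, n_tier2=2, n_tier3=5,
    retailers_per_wholesale=6, seed=1))
crops = vc.default_crops()
ratios = vc.default_production_ratios()

by_mult = {}
for cfg in vc.scenario_suite(vc.ScenarioConfig(seed=1, iterations=2),
                             horizon=45.0):
    by_mult[cfg.production_multiplier] = vc.run_iterations(
        net, crops, cfg, production_ratio=ratios)

summary = vc.scenario_summary(by_mult)
agg = summary.groupby("multiplier")[
    ["retail_fulfillment", "total_loss", "storage_loss",
     "transport_loss"]].mean()
print(agg.round(3).to_string())
# Across the column "total_loss" the fraction rises steeply with the
# multiplier while "retail_fulfillment" stays within a few points:
# additional production is largely absorbed by postharvest loss, not by
# better availability.
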