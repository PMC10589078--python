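"""Rearing-outcome summaries: survival percentages per diet.

Simulates in-vitro rearing with per-diet stage survival probabilities and
prints the per-diet table. Cocoon completion is a percentage of all grafted
individuals; pupation and adult survival are percentages of cocoon completers
(the adult model only includes bees that survived the larval stage).
"""

from pollenniche import SimulationConfig, generate_rearing_outcomes, survival_summary

config = SimulationConfig(seed=5)
records = generate_rearing_outcomes(config, n_per_diet=19)
table = survival_summary(records)
print(table.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
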