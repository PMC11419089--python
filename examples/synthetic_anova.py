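"""Synthetic cat dataset and the state x speed repeated-measures ANOVA.

Generates a tied-belt dataset (5 cats, 2 states, speeds 0.4-1.0 m/s)
with the model-predicted hemisection pattern -- right-hindlimb duration
transferred from stance to swing -- and runs the two-factor
repeated-measures ANOVA per side and variable.  The right-side swing and
stance show significant state effects; cycle duration does not.
"""

from hemigait import anova_table, generate_cat_dataset, predicted_effect_config

data = generate_cat_dataset(predicted_effect_config("tied"), seed=42)
table = anova_table(data)
state_rows = table[table["effect"] == "state"]
print(state_rows.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
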