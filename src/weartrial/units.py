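"""Unit conversion constants.

Weights are stored internally in kilograms; adherence-alert thresholds are
expressed in pounds, matching how consumer scales and US trial protocols
report weight change. Heights from questionnaires may arrive in inches.
"""

KG_PER_LB = 0.45359237
LB_PER_KG = 1.0 / KG_PER_LB
M_PER_IN = 0.0254
M_PER_CM = 0.01


def lb_to_kg(lb: float) -> float:
    return lb * KG_PER_LB


def kg_to_lb(kg: float) -> float:
    return kg * LB_PER_KG
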