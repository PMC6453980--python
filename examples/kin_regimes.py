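"""Relatedness and the empathic gradient.

Transforms the payoffs with an assortment coefficient r, asks whether the
evolved recruitment intensity u_D* rises with r (the empathic gradient), and
maps the (r, c+/c-) plane into inhibition / bistable / full-coordination
regimes.
"""

import numpy as np

from mindread import (
    CognitiveParams,
    EnvironmentParams,
    IntensityModel,
    PayoffParams,
    duD_dr,
    empathic_gradient_condition,
    regime_map,
)

env = EnvironmentParams(
    lambda_e=9.0, p=0.05, intensity=IntensityModel("truncnorm", 0.5, 0.1)
)
cog = CognitiveParams()

for c_plus in (9.0, 0.6):
    pay = PayoffParams(c_plus=c_plus)
    grad = duD_dr(env, cog, pay, r=0.3)
    print(
        f"c+/c- = {c_plus / pay.c_minus:.2f}  (d+/d- = 1): "
        f"empathic gradient condition {empathic_gradient_condition(pay)}, "
        f"du_D*/dr = {grad:+.4f}"
    )

tab = regime_map(np.linspace(0, 1, 12), np.linspace(0.25, 4, 12), env, cog, PayoffParams())
print("\nregime counts on the (r, c+/c-) grid:", tab.label.value_counts().to_dict())
print(
    "\nStronger contagion toward kin (du_D*/dr > 0) evolves only when the"
    " actor's benefit from coordination outweighs the observer's cost more"
    " than defection's payoffs do (c+/c- > d+/d-); at high relatedness and"
    " high c+/c-, inhibition collapses entirely (full coordination)."
)
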