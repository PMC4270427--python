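"""Outcome probabilities versus plasmodium size for the three strains.

Runs the stochastic mass-recruitment simulator at each strain's best-fit
rates over the ten experimental diameters and prints the probabilities
of choosing zero, one or two food sources.  Small plasmodia mostly make
no choice, mid-sized ones exploit a single source, and only masses past
the strain's pitchfork (Australian 3.0, American 4.0, Japanese 4.2 cm)
start exploiting both.
"""

from slimechoice import DIAMETERS_CM, MCConfig, ModelParams
from slimechoice.montecarlo import outcome_distributions_over_masses

STRAINS = {"Japan": (2.5, 1.5), "Australian": (1.5, 0.9),
           "American": (1.5, 1.2)}

for name, (k, T) in STRAINS.items():
    cfg = MCConfig(params=ModelParams(k=k, d=1.0, T=T, n=2, M=4.0),
                   seed=1, n_realisations=500)
    print(f"{name} (k={k}, T={T}):")
    print("   M     p(none)  p(one)  p(two)")
    for dist in outcome_distributions_over_masses(cfg, DIAMETERS_CM):
        print(f"  {dist.M:4.1f}   {dist.p0:6.3f}  {dist.p1:6.3f}  {dist.p2:6.3f}")
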