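"""Score a drug-sensitizer combination against the Bliss additive reference.

Two independently acting drugs should jointly inhibit
Additive = E1 + E2 - E1*E2. Observed inhibition above this reference
(positive excess) indicates synergy. Here one combination is built
exactly Bliss-additive and one with a true interaction, and both are
scored at a fixed sensitizer inhibition E2 = 0.15 (its IC15).
"""

import numpy as np
import pandas as pd

from resistkit.simulate import four_pl
from resistkit.synergy import call_synergy, score_combination

rng = np.random.default_rng(0)
doses = 1e-6 / 3.0 ** np.arange(7)
e2 = 0.15
v_single = np.clip(four_pl(doses, 3e-8, 1.0) + rng.normal(0, 0.03, 7), 0, 1.2)

combos = {
    # independent action: survivals multiply -> excess ~ 0
    "additive_combo": np.clip(v_single * (1 - e2) + rng.normal(0, 0.03, 7), 0, 1.2),
    # interaction: combination kills far more than predicted
    "synergistic_combo": np.clip(v_single * (1 - e2) * 0.45 + rng.normal(0, 0.03, 7), 0, 1.2),
}

for name, v_combo in combos.items():
    points = score_combination(
        pd.DataFrame({"dose": doses, "viability": v_single}),
        e2,
        pd.DataFrame({"dose": doses, "viability": v_combo}),
    )
    call = call_synergy(points, min_excess=0.1, seed=1, drug=name)
    print(f"\n{name}:")
    shown = points[["dose", "E1", "E_obs", "additive", "excess"]].round(3)
    shown["dose"] = points["dose"].map("{:.2e}".format)
    print(shown.to_string(index=False))
    print(f"mean excess {call.mean_excess:+.3f} "
          f"(95% CI {call.ci_low:+.3f} to {call.ci_high:+.3f}), "
          f"{call.n_doses_above_additive}/{call.n_doses} doses above additive "
          f"-> synergistic: {call.is_synergistic}")

print("\nExcess near zero is what independent action predicts; a mean excess "
      "above 0.1 with most doses positive is called synergy.")
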