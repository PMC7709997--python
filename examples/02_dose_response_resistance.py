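"""Classify drug resistance and sensitizer reversal from IC50 fold changes.

Simulates a drug panel tested on a parental and a resistant cell line
(single agent, and the resistant line combined with a fixed-dose
proteasome-inhibitor sensitizer), fits 4PL curves, and applies the
strict fold-change rules: resistant if IC50(resistant)/IC50(parental)
> 5, reversed if the combination lowers the resistant IC50 > 5-fold.
"""

import numpy as np

from resistkit.doseresponse import classify_resistance, ec_k, fit_4pl, fit_panel
from resistkit.simulate import DoseResponseSimConfig, four_pl, simulate_dose_response

cfg = DoseResponseSimConfig(n_drugs=12, seed=3)
table, truth = simulate_dose_response(cfg)
print(f"panel: {cfg.n_drugs} drugs x 3 curves x {cfg.n_doses} doses "
      f"(threefold series) x {cfg.n_replicates} replicates")

fits = fit_panel(table)
calls = classify_resistance(fits, fold_threshold=5.0)

print("\nper-drug calls (fold > 5 strict):")
cols = ["drug", "fold_change_resistance", "is_resistant", "category",
        "fold_change_reversal", "is_reversed"]
print(calls[cols].round(2).to_string(index=False))

n_res = int(calls["is_resistant"].sum())
print(f"\n{n_res}/{cfg.n_drugs} drugs resistant; "
      f"{int(calls['is_reversed'].sum())}/{n_res} of those reversed by the sensitizer")

# ECk: the dose for any target inhibition level, e.g. a sensitizer's IC15
doses = 1e-5 / 3.0 ** np.arange(7)
fit = fit_4pl(doses, four_pl(doses, 1e-6, 1.0))
ic15, _ = ec_k(fit, 15)
print(f"\nfitted IC50 {fit.ic50:.3g} M; IC15 (15% inhibition) {ic15:.3g} M — "
      "the fixed sensitizer dose used in combination arms")
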