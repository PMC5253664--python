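"""BRET dose-response pharmacology: pEC50, Emax and fold potency.

Simulates arrestin-recruitment curves for a full agonist (EC50 8.5 nM)
and a partial agonist (EC50 33 nM, half the efficacy), fits the
four-parameter logistic, and reports the potency ratio -- the classic
"n-fold lower potency" statement of receptor pharmacology.
"""

import math

from oxfoot.pharm import curve_from_table, fit_dose_response, fold_potency
from oxfoot.synthetic import simulate_bret

full = fit_dose_response(curve_from_table(
    simulate_bret(8.5e-9, emax=1.0, sigma=0.03, ligand="chemokine", seed=1),
    "chemokine"))
partial = fit_dose_response(curve_from_table(
    simulate_bret(33e-9, emax=0.52, sigma=0.03, ligand="small_molecule", seed=2),
    "small_molecule"))

for est in (full, partial):
    print(f"{est.ligand:>14s}: pEC50 = {est.pEC50:.2f} +/- {est.se_pEC50:.2f}, "
          f"EC50 = {est.EC50*1e9:.1f} nM, Emax = {est.Emax:.2f}")

fold, rounded = fold_potency(partial, full)
print(f"\npotency ratio (partial/full) = {fold:.2f} -> ~{rounded}-fold lower"
      " potency for the partial agonist")
print(f"efficacy of partial agonist: {partial.Emax/full.Emax:.0%} of full")
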