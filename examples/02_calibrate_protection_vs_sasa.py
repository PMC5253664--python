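"""Reference-state calibration: ln PF against fractional side-chain SASA.

Protection factors PF = R_i / k divide each site's intrinsic reactivity by
its measured rate, removing residue chemistry so that what remains tracks
burial. On a state with a known structure, ln PF falls linearly with
fractional SASA; the Pearson R of that line is the experiment's quality
readout (a strongly negative R means rates faithfully report exposure).
"""

import oxfoot as ox
from oxfoot.calibration import summary_text
from oxfoot.synthetic import make_fixture_structure, simulate_footprinting

structure = make_fixture_structure("two_domain_complex", n_residues=50, seed=3)
table, truth = simulate_footprinting(structure, intercept=4.0, slope=-3.5,
                                     sigma_rate=0.45, seed=7)

rates = ox.fit_rate_table(table)
pf = ox.protection_table(rates, ox.load_reactivity_table())
fsasa = truth.fsasa
model = ox.calibrate([(fsasa[row["site"]], row["lnPF"])
                      for _, row in pf.iterrows()])

print(summary_text(model))
print(f"generating line was lnPF = {truth.intercept} {truth.slope:+g} * fSASA")
print("The negative slope/R confirm oxidation rates track solvent exposure;"
      " rate noise (sigma_rate = 0.45) degrades R from the noiseless -1"
      " into the -0.7..-0.9 range typical of real calibrations.")
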