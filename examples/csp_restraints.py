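"""From chemical-shift perturbations to docking restraints.

Builds a small CSP table, classifies active/passive residues for ambiguous
interaction restraints (exposure >= 20%, CSP > 0.1 ppm active, 1-2 sigma
window or 6.5 Å proximity passive), and emits unambiguous 1.8-16 Å bounds
for PRE-bleached protons.
"""

import pandas as pd

from phgap.nmr_observables import (classify_air, compute_csp,
                                   pre_distance_restraints, restraints_to_tbl)
from phgap.structures import LabelSite

csp = pd.DataFrame({
    "residue": [388, 389, 390, 402, 408, 364],
    "group": "methyl",
    "csp": [compute_csp(0.11, 0.20, "C13"), 0.15, 0.12, 0.06, 0.05, 0.02],
    "sigma_flag": "?",
})
rel_sasa = pd.Series({388: 0.45, 389: 0.31, 390: 0.28, 402: 0.40,
                      408: 0.15, 364: 0.50})
contacts = {364: {390}, 390: {364}}

airs = classify_air(csp, rel_sasa, contacts, partner="PH")
print("active :", sorted(airs.active))   # exposed, CSP > 0.1 ppm
print("passive:", sorted(airs.passive))  # exposed, window or next to active

ratios = pd.DataFrame({"residue": [390, 402, 408], "group": "methyl",
                       "ratio": [0.15, 0.45, 0.0],
                       "detectable": [True, True, False]})
rs = pre_distance_restraints(ratios, LabelSite(38, mutation_tag="K38C"))
print(rs.unambiguous.to_string(index=False))
print(restraints_to_tbl(rs), end="")
# Residues with I/I0 < 0.2 (or bleached beyond detection) get 1.8-16 Å
# bounds to the spin-label site; residue 402 at 0.45 gets none.
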