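"""Decompose GAP-activity enhancement into its mechanistic contributions.

Computes 3-minute-endpoint C50 values (enzyme concentration for 50% GTP
hydrolysis on 1 uM membrane-anchored Arf·GTP) for the isolated catalytic
fragment and four enzyme scenarios, and reports each scenario's gain over
the fragment alone in log10 units.
"""

from phgap import gap_kinetics as gk

table = gk.decompose_enhancement(gk.DEFAULT_PARAMS)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
# recruitment-only   ~3 logs: membrane confinement (gamma ~ 1e3)
# binding-only       ~4 logs: PH captures Arf and tethers the catalytic unit
# localization-only  4-5 logs: both together, saturating below additivity
# full               adds the 1000-fold allosteric kcat enhancement (alpha)
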