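"""Unit conversion constants.

All lengths are handled in micrometres, all droplet volumes in picolitres,
and all bulk (reagent) volumes in microlitres. The two constants below are
the only conversion factors used anywhere in the package.
"""

#: cubic micrometres per picolitre (1 pL = 10^-15 L = 1000 um^3)
UM3_PER_PL: float = 1000.0

#: picolitres per microlitre (1 ul = 10^-6 L = 10^6 pL)
PL_PER_UL: float = 1.0e6
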