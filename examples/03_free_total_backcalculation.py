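"""Mass-balance back-calculation from the two analyzed fractions.

Takes analyzed chamber-level concentrations for the plasma and buffer
fractions of one specimen and reconstructs free, bound, and total drug in
the original plasma sample.
"""

from redquant import REDGeometry, original_concentrations

geometry = REDGeometry()
c_plasma, c_buffer = 100.0, 5.0  # analyzed ng/mL in the two fractions

res = original_concentrations(c_plasma, c_buffer, geometry)
print(f"free  {res.free_conc:8.3f} ng/mL   (buffer reading x (Vp+Vb)/Vp)")
print(f"bound {res.bound_conc:8.3f} ng/mL   (plasma minus buffer reading)")
print(f"total {res.total_conc:8.3f} ng/mL   (= free + bound, exactly)")
# Cross-check by amounts: (100*200 + 5*333) / 200 = 108.325 ng/mL -- the
# same total, obtained by summing drug amounts over both chambers.
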