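"""Dialysis equilibrium: where does the drug end up, and what does fu do?

Spikes plasma at 1000 ng/mL, equilibrates it across the RED membrane under
linear binding, and shows the chamber concentrations and free-amount split.
"""

from redquant import BindingModel, REDGeometry, chamber_free_partition, simulate_red_equilibrium

geometry = REDGeometry()  # 200 uL plasma / 333 uL buffer chambers
plasma_share, buffer_share = chamber_free_partition(geometry)
print(f"free-amount split  plasma {plasma_share:.1%} / buffer {buffer_share:.1%}")

for fu in (0.05, 0.02):
    binding = BindingModel(fu=fu)
    c_plasma, c_buffer = simulate_red_equilibrium(1000.0, binding, geometry)
    print(
        f"fu={fu:.2f}: plasma chamber {c_plasma:8.2f} ng/mL, "
        f"buffer chamber {c_buffer:6.2f} ng/mL"
    )
# The buffer chamber holds only free drug; a smaller fraction unbound keeps
# more drug protein-bound on the plasma side and the buffer reading drops.
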