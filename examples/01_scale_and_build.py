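"""Scale the Weibel reference lung and inspect the 251-unit network.

Builds the default 3000-ml model and prints the geometry anchors: the
scaling factor, alveolar diameter, dead space, and the Peclet profile
that separates the convection- from the diffusion-dominated zone.
"""

import numpy as np

import mbwsim as m

result, scaled = m.scale_to_volume(m.weibel_table())
print(f"unscaled model volume : {result.V_LW:8.1f} ml (reference lung)")
print(f"target lung volume    : {result.V_L:8.1f} ml (resting position)")
print(f"linear scaling factor : {result.s:8.4f}   (applied to z >= 4)")
print(f"alveolar diameter     : {result.d_alv * 1e4:8.1f} um")

model = m.default_model()
print(f"\nairway units          : {len(model)} (10 trachea + 241 segment)")
print(f"total volume          : {model.total_volume:8.1f} ml")
print(f"dead space            : {model.dead_space_volume:8.1f} ml "
      f"(transit {model.dead_space_volume / 250:.2f} s at 250 ml/s)")

flows = np.array([u.Q_hat_in for u in model.units])
pe = m.peclet(model, flows)
z_star = m.transition_generation(model, pe)
print(f"\nPe = 1 transition at generation {z_star} for He-N2 (D = 0.6 cm2/s):")
for u in model.units:
    if not u.is_tu and u.e == 0 and u.z in (14, 15, 16):
        print(f"  z={u.z}: entrance Pe = {pe[u.index]:7.3f}")
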