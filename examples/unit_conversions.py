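"""Reduced-to-physical unit mapping of the capsid model.

Prints the physical meaning of the key reduced quantities: the motor
force, the capsid radius, the electrostatic screening length and the
thermal energy scale.
"""

from phagepack import DEFAULT_UNITS, bjerrum_length_nm, packing_fraction

u = DEFAULT_UNITS

force = u.to_physical(80, "force")
print(f"motor force: 80 reduced units = {force.value:.0f} {force.unit}")

radius = u.to_physical(3.02, "length")
print(f"capsid radius: 3.02 sigma = {radius.value:.1f} {radius.unit}")

screen = u.to_physical(0.75, "length")
print(f"Debye screening length: 0.75 sigma = {screen.value:.1f} {screen.unit}")

print(f"thermal energy at T*=1 (37 degC): {u.epsilon_pNnm:.2f} pN nm")
print(f"Bjerrum length in water at 37 degC: {bjerrum_length_nm():.2f} nm")

phi = packing_fraction(100, 1.0, 3.02)
print(f"packing fraction, 100 beads in the capsid: {phi:.3f}")

# The motor force (128 pN) is larger than the ~50 pN stall force measured
# for real packaging motors; a strong driving force is needed to pack a
# charged, semiflexible chain on simulation timescales.  The packing
# fraction ~0.45 is close to physiological genome densities.
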