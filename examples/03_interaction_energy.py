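"""Switched Lennard-Jones + Coulomb interaction energy of a complex.

Generates the designed receptor/ligand binding fixture and scores the bound
placement against a far-apart placement and a clashed one, illustrating the
shape of the intermolecular score the docking search descends.
"""

import numpy as np

import swarmdock as sd

pair = sd.make_binding_pair(seed=0)
rec = sd.assign_params(pair.receptor)
lig_bound = sd.assign_params(pair.ligand_bound)

e_bound = sd.interaction_energy(rec, lig_bound)
far = lig_bound.with_coords(lig_bound.coords + 60.0)
e_far = sd.interaction_energy(rec, far)
clashed = lig_bound.with_coords(lig_bound.coords
                                - np.array([0.0, 3.0, 0.0]))
e_clash = sd.interaction_energy(rec, clashed)

print(f"bound complex   : {e_bound:9.2f} kcal/mol")
print(f"separated > 9 A : {e_far:9.2f} kcal/mol (outside the switch cutoff)")
print(f"pushed 3 A in   : {e_clash:9.2f} kcal/mol (steric wall)")
print("The bound placement sits in a deep electrostatic funnel formed by")
print("designed lysine-aspartate salt bridges; the r_on=7/r_off=9 A switch")
print("makes the score exactly zero for separated partners.")
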