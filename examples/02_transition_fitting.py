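"""Overlap and least-squares fitting of an unbound-to-bound transition.

A two-domain hinge fixture is deformed exactly along its softest elastic
mode; the analysis should attribute the whole conformational change to that
mode (overlap 1 at mode 1) and a one-mode least-squares fit should recover
the deformation amplitude.
"""

import numpy as np

import swarmdock as sd

pair = sd.make_hinge_pair(24, seed=1, mode_index=1, amplitude=2.0)
transition = sd.make_transition(pair.unbound, pair.bound)
modes = sd.compute_modes(pair.unbound)

result = sd.max_overlap(modes, transition)
print(f"maximum overlap {result.max_overlap:.4f} at mode "
      f"{result.argmax_mode} (constructed along mode 1, amplitude 2 A)")

fit = sd.lsq_fit(transition, modes, m=1, superpose=False)
print(f"one-mode fit: beta_1 = {fit.coefficients[0]:.4f} A, "
      f"RMSD {fit.initial_rmsd:.3f} -> {fit.fitted_rmsd:.2e} A "
      f"({fit.percent_reduction:.1f}% recovered)")

curve = sd.reduction_curve(transition, modes, [1, 5, 10, 20],
                           superpose=False)
print("percent RMSD reduction vs basis size:",
      dict(zip(curve.m_values, np.round(curve.percent_reduction, 2))))
print(f"mode of greatest influence: {curve.mode_of_greatest_influence}")
print("For a transition built from one mode, all of the recovery comes from")
print("that mode and adding more modes changes nothing.")
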