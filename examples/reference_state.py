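"""Build an EDS reference state and inspect energies, weights and forces.

Three harmonic end states are enveloped into a single reference potential
V_R(x; s, E).  At s = 1 the reference keeps every physical minimum; as s
shrinks the barriers between them melt away until, in the undersampling
limit, all states contribute equally everywhere.
"""

import numpy as np

from edsflow import HarmonicPotential, ReferenceState, ThermoContext

thermo = ThermoContext()  # 300 K, kB = 0.00831446 kJ/mol/K
states = [
    HarmonicPotential(np.array([1000.0]), np.array([-0.3]), 0.0, "A"),
    HarmonicPotential(np.array([2500.0]), np.array([0.0]), 6.0, "B"),
    HarmonicPotential(np.array([1500.0]), np.array([0.3]), -4.0, "C"),
]

x = np.array([0.05])
print(f"end-state energies at x = {x[0]} nm:",
      [f"{st.identifier}: {float(st.energy(x)):7.2f} kJ/mol" for st in states])

for s in [1.0, 0.1, 0.01, 1e-4]:
    ref = ReferenceState(states, s=s, offsets=np.zeros(3), thermo=thermo)
    vr = float(ref.energy(x))
    w = ref.weights(x)
    f = ref.forces(x)
    print(f"s = {s:7.4f}: V_R = {vr:8.2f} kJ/mol, weights = {np.round(w, 3)}, "
          f"force = {f[0]:8.2f} kJ/mol/nm")

# The weights are the softmax mixture factors of the reference-state force;
# at s = 1 the lowest state dominates, while at s = 1e-4 the weights
# approach the uniform 1/3 of the undersampling regime.
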