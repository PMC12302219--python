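"""FCIDUMP and property-operator file round trip for HeH+/STO-3G.

Writes the MO-basis Hamiltonian in the Molpro FCIDUMP convention plus the
JSON property-operator container, reads both back, and verifies that the
Hamiltonian and the nuclear dipole survive unchanged.
"""

import numpy as np

from xccprop import fixtures
from xccprop.integrals import (read_fcidump, read_property_operators,
                               write_fcidump, write_property_operators)

system = fixtures.make_system("heh+_sto3g")
write_fcidump(system.ints, "hehp.fcidump")
write_property_operators(system.props, "hehp.props.json")

ints = read_fcidump("hehp.fcidump")
props = read_property_operators("hehp.props.json")

print(f"n_orb={ints.n_orb}  n_elec={ints.n_elec}  "
      f"e_core={ints.e_core:.6f} Eh (= 2/1.4632 = {2/1.4632:.6f})")
print(f"max |h - h'| = {np.max(np.abs(ints.h - system.ints.h)):.1e}")
print(f"max |g - g'| = {np.max(np.abs(ints.g - system.ints.g)):.1e}")
print(f"nuclear dipole (a.u.): {props.mu_nuc}")
# e_core is the He-H point-charge repulsion; the round trip is lossless at
# double precision.
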