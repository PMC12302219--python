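"""A small slice of the HF/cc-pVDZ dipole-moment surface.

Scans the H-F bond over the turning-point region with warm-started
orbital-optimized pCCD and the in-repo FCI reference, then locates each
curve's turning point (the minimum of mu_z in the molecular frame, H at
the origin and F on +z).  Expect a few minutes of runtime: each point
solves an 18-orbital FCI.
"""

import numpy as np

from xccprop import dms

grid = np.arange(1.10, 1.46, 0.05)
res = dms.scan_dms(grid, methods=("fci", "xpccd", "xccsd"),
                   molecule="hf_ccpvdz", n_frozen=1, verbose=True)

print("\n   R (A)   mu_z FCI (D)   mu_z XpCCD   mu_z XCCSD")
for k, R in enumerate(res["fci"].R):
    print(f"  {R:5.2f}   {res['fci'].mu_z[k]:10.4f}   "
          f"{res['xpccd'].mu_z[k]:10.4f}   {res['xccsd'].mu_z[k]:10.4f}")

for m in ("fci", "xpccd", "xccsd"):
    print(f"{m:7s} turning point: {dms.turning_point(res[m]):.3f} A")
# The FCI curve turns near 1.27-1.28 A; XpCCD turns at a shorter bond
# length, XCCSD at a longer one -- the ordering the expectation-value
# densities inherit from their amplitude truncations.
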