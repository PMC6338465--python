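"""Force-dependent Michaelis-Menten parameters in both assay geometries.

For the Brownian-ratchet-rectified-by-binding cycle, prints v_max(F) and
K_M(F) in the opposing-force assay (force fights translocation directly)
and in the hairpin assay (force opens the fork and so assists).
"""

from ratchetfit import mm_parameters
from ratchetfit.conditions import (geometry_in_complex, geometry_isolated,
                                   rates_in_complex, rates_isolated)
from ratchetfit.schemes import get_scheme

scheme = get_scheme("br-binding")

print("opposing-force assay (in-complex rates):")
print(f"{'F (pN)':>7} {'v_max (bp/s)':>13} {'K_M (uM)':>10}")
for F in (0.0, 8.0, 16.0, 24.0):
    mm = mm_parameters(scheme, rates_in_complex(), F, geometry_in_complex())
    print(f"{F:>7.0f} {mm.v_max:>13.1f} {mm.K_M * 1e6:>10.1f}")

print("\nhairpin-under-tension assay (isolated rates):")
print(f"{'F (pN)':>7} {'v_max (bp/s)':>13} {'K_M (uM)':>10}")
for F in (4.0, 8.0, 12.0, 15.0):
    mm = mm_parameters(scheme, rates_isolated(), F, geometry_isolated())
    print(f"{F:>7.0f} {mm.v_max:>13.1f} {mm.K_M * 1e6:>10.1f}")

print(
    "\nIn the opposing assay the ratchet equilibrium is tilted backward by"
    "\nforce, inflating K_M exponentially while v_max stays put; in the"
    "\nhairpin assay force opens the fork, deflating the effective K_M."
)
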