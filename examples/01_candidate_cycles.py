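"""The six candidate mechano-chemical cycles and their force response.

Enumerates the candidate schemes (Brownian ratchet / power stroke x
translocation placed at ATP binding, hydrolysis, or product release) and
prints each cycle's steady-state unwinding velocity at 2 mM ATP for a few
opposing forces, using the in-complex reference rates.
"""

import numpy as np

from ratchetfit import enumerate_schemes, steady_state_velocity
from ratchetfit.conditions import geometry_in_complex, rates_in_complex

rates = rates_in_complex()
geom = geometry_in_complex()
forces = [0.0, 10.0, 20.0, 30.0]

print(f"{'scheme':<14}" + "".join(f"  v({F:>4.0f} pN)" for F in forces))
for scheme in enumerate_schemes():
    vs = [steady_state_velocity(scheme, rates, F, 2e-3, geom) for F in forces]
    print(f"{scheme.scheme_id:<14}" + "".join(f"  {v:>9.1f}" for v in vs))

print(
    "\nVelocities are in bp/s against an opposing force. All six cycles are"
    "\nforce-insensitive at low force and slow down once translocation"
    "\nbecomes rate-limiting, but they differ in how fast and through which"
    "\nMichaelis-Menten parameter the force acts - the signature used to"
    "\ndiscriminate them."
)
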